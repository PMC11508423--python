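"""Synthetic ancestors, mutated repeat copies, ITS-like arrays, and
transcripts, with a complete truth ledger for parameter-recovery tests.

The generator emulates the statistical structure the analysis assumes: a
GC-biased ancestral sequence, repeat copies produced by per-category
substitution rates over the ten substitution classes (eight directional,
two composition-neutral), geometric-length indels, a RIP-only mode
restricted to C→T/G→A, multi-copy arrays embedded in a decoy genome, and
genes with a planted intron plus their spliced transcript.

Rates are per eligible ancestral site (e.g. the C→T rate applies to each
ancestral C independently). A single seeded pseudorandom stream drives each
simulation and events are recorded in coordinate order, so the ledger is
unambiguous and identical configurations produce byte-identical output.
Indels never overlap substitutions (a substitution at a deleted site is
skipped) and two deletions are never adjacent, so every ledger event maps
to exactly one maximal alignment feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.stats import beta as _beta

from .seqio import NUCLEOTIDE, GenomicInterval, SequenceRecord, reverse_complement
from .pairalign import PairwiseAlignment
from .mutspec import MutationSpectrum

RATE_KEYS = (
    "c_to_t", "g_to_a", "t_to_c", "a_to_g",
    "c_to_a", "g_to_t", "a_to_c", "t_to_g",
    "at_neutral", "gc_neutral",
)
_RIP_KEYS = ("c_to_t", "g_to_a")

# per ancestral base: (rate key, target base), in fixed draw order
_BASE_CATEGORIES = {
    "A": (("a_to_g", "G"), ("a_to_c", "C"), ("at_neutral", "T")),
    "C": (("c_to_t", "T"), ("c_to_a", "A"), ("gc_neutral", "G")),
    "G": (("g_to_a", "A"), ("g_to_t", "T"), ("gc_neutral", "C")),
    "T": (("t_to_c", "C"), ("t_to_g", "G"), ("at_neutral", "A")),
}

_SPECTRUM_KEY = {  # ledger category -> MutationSpectrum counter
    "c_to_t": "c_to_t", "g_to_a": "g_to_a", "t_to_c": "t_to_c",
    "a_to_g": "a_to_g", "c_to_a": "c_to_a", "g_to_t": "g_to_t",
    "a_to_c": "a_to_c", "t_to_g": "t_to_g",
    "at_neutral": "at_neutral_transversions",
    "gc_neutral": "gc_neutral_transversions",
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated ancestor/copy pair.

    Defaults model a GC-biased fungal gene-sized locus: a 2 kb ancestor at
    60% GC (the genes in this system sit near 55-65% GC), no mutation
    unless rates are given. ``rip_mode`` restricts mutation to the C→T and
    G→A channels; giving any other nonzero rate alongside it is an error.
    """

    seed: int = 0
    ancestor_length: int = 2000
    ancestor_gc: float = 0.6
    substitution_rates: dict = field(default_factory=dict)
    indel_rate: float = 0.0
    indel_length_p: float = 0.25
    indel_max_len: int = 60
    rip_mode: bool = False
    n_copies: int = 1
    intron_spec: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        rates = dict(self.substitution_rates)
        for key, val in rates.items():
            if key not in RATE_KEYS:
                raise ValueError(f"unknown substitution category {key!r}")
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"rate {key}={val} outside [0, 1]")
        if self.rip_mode:
            bad = [k for k, v in rates.items() if v > 0 and k not in _RIP_KEYS]
            if bad:
                raise ValueError(
                    f"rip_mode forbids nonzero non-RIP rates: {bad}")
            if not any(rates.get(k, 0) > 0 for k in _RIP_KEYS):
                rates = {"c_to_t": 0.05, "g_to_a": 0.05}
        object.__setattr__(self, "substitution_rates", rates)
        if not 0.0 < self.ancestor_gc < 1.0:
            raise ValueError("ancestor_gc must be in (0, 1)")
        if not 0.0 <= self.indel_rate <= 1.0:
            raise ValueError("indel_rate outside [0, 1]")

    @classmethod
    def rip(cls, rate: float = 0.05, **kw) -> "SimulationConfig":
        kw.setdefault("substitution_rates", {"c_to_t": rate, "g_to_a": rate})
        return cls(rip_mode=True, **kw)


@dataclass(frozen=True)
class MutationEvent:
    """One ground-truth event: a substitution, insertion, or deletion.

    ``position`` is the 1-based ancestor coordinate (for insertions, the
    site the new sequence was placed before). ``bases`` holds the
    replacement base, the inserted sequence, or the deleted sequence.
    """

    type: str          # substitution | insertion | deletion
    category: str | None
    position: int
    bases: str


@dataclass
class TruthLedger:
    events: list
    true_alignment: PairwiseAlignment
    expected_spectrum: MutationSpectrum

    def spectrum_from_events(self) -> MutationSpectrum:
        """Recompute the expected spectrum from the event records."""
        spec = MutationSpectrum()
        for ev in self.events:
            if ev.type == "substitution":
                key = _SPECTRUM_KEY[ev.category]
                setattr(spec, key, getattr(spec, key) + 1)
            elif ev.type == "insertion":
                spec.insertion_events += 1
                spec.insertion_bases += len(ev.bases)
            else:
                spec.deletion_events += 1
                spec.deletion_bases += len(ev.bases)
        return spec


def random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    """Random nucleotide sequence at the given expected GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def _draw_substitutions(anc: np.ndarray, rates: dict,
                        rng: np.random.Generator) -> dict[int, tuple[str, str]]:
    """site index -> (category, new base); vectorized per ancestral base."""
    out: dict[int, tuple[str, str]] = {}
    for base in "ACGT":
        cats = _BASE_CATEGORIES[base]
        probs = np.array([rates.get(k, 0.0) for k, _ in cats])
        idx = np.flatnonzero(anc == base)
        if idx.size == 0:
            continue
        u = rng.random(idx.size)  # one draw per eligible site, always
        if probs.sum() == 0:
            continue
        if probs.sum() > 1.0:
            raise ValueError(
                f"summed substitution rates for base {base} exceed 1")
        cum = np.cumsum(probs)
        choice = np.searchsorted(cum, u, side="right")
        for site, ch in zip(idx[choice < 3], choice[choice < 3]):
            key, target = cats[ch]
            out[int(site)] = (key, target)
    return out


def simulate_repeat_pair(config: SimulationConfig
                         ) -> tuple[SequenceRecord, SequenceRecord, TruthLedger]:
    """Simulate an ancestor and one mutated repeat copy with a full ledger."""
    rng = np.random.default_rng(config.seed)
    n = config.ancestor_length
    ancestor = random_sequence(n, config.ancestor_gc, rng)
    anc = np.array(list(ancestor))

    subs = _draw_substitutions(anc, config.substitution_rates, rng)

    # indels: one potential event per ancestral site, coordinate order
    deleted = np.zeros(n, dtype=bool)
    insertions: dict[int, str] = {}
    del_events: list[tuple[int, int]] = []  # (start0, length)
    if config.indel_rate > 0:
        hit = np.flatnonzero(rng.random(n) < config.indel_rate)
        is_ins = rng.random(hit.size) < 0.5
        lengths = np.minimum(rng.geometric(config.indel_length_p, hit.size),
                             config.indel_max_len)
        prev_del_end = -2  # 0-based inclusive end of previous deletion
        for pos, ins, length in zip(hit, is_ins, lengths):
            pos, length = int(pos), int(length)
            if ins:
                # an insertion between two deleted sites would split one
                # deletion into two alignment gap runs; keep events 1:1
                # with maximal runs by skipping it
                if pos > 0 and deleted[pos - 1] and deleted[pos]:
                    continue
                insertions[pos] = random_sequence(length, config.ancestor_gc, rng)
            else:
                # keep deletions non-adjacent so each is one maximal gap run
                if pos <= prev_del_end + 1:
                    continue
                end = min(pos + length, n) - 1
                deleted[pos:end + 1] = True
                del_events.append((pos, end - pos + 1))
                prev_del_end = end

    # assemble events in coordinate order and build the true alignment
    events: list[MutationEvent] = []
    qrow: list[str] = []
    srow: list[str] = []
    for pos in range(n):
        if pos in insertions:
            ins_seq = insertions[pos]
            events.append(MutationEvent("insertion", None, pos + 1, ins_seq))
            qrow.append("-" * len(ins_seq))
            srow.append(ins_seq)
        qrow.append(ancestor[pos])
        if deleted[pos]:
            srow.append("-")
        else:
            if pos in subs:
                category, target = subs[pos]
                events.append(MutationEvent("substitution", category,
                                            pos + 1, target))
                srow.append(target)
            else:
                srow.append(ancestor[pos])
    for start0, length in del_events:
        events.append(MutationEvent("deletion", None, start0 + 1,
                                    ancestor[start0:start0 + length]))
    events.sort(key=lambda e: (e.position, e.type))

    aligned_q = "".join(qrow)
    aligned_s = "".join(srow)
    copy_seq = aligned_s.replace("-", "")
    if not copy_seq:
        raise ValueError("simulated copy is empty; lower the indel rate")
    ident = sum(1 for a, b in zip(aligned_q, aligned_s) if a == b and a != "-")
    true_alignment = PairwiseAlignment(
        query_id="ancestor", subject_id="copy",
        aligned_query=aligned_q, aligned_subject=aligned_s,
        score=0.0, identity_percent=100.0 * ident / len(aligned_q),
        columns=len(aligned_q), molecule=NUCLEOTIDE)

    ledger = TruthLedger(events=events, true_alignment=true_alignment,
                         expected_spectrum=MutationSpectrum())
    ledger.expected_spectrum = ledger.spectrum_from_events()
    return (SequenceRecord("ancestor", ancestor),
            SequenceRecord("copy", copy_seq),
            ledger)


@dataclass
class ArrayTruth:
    """Ground truth for a simulated multi-copy array in a decoy genome."""

    reference: SequenceRecord
    copies: list  # (GenomicInterval, SequenceRecord copy, TruthLedger)


def simulate_its_array(config: SimulationConfig, decoy_length: int,
                       placements: Sequence[tuple[int, str]],
                       per_copy_rates: Sequence[dict] | None = None,
                       ) -> tuple[SequenceRecord, ArrayTruth]:
    """Embed mutated copies of one reference at recorded positions/strands
    in a GC-matched random decoy contig.

    ``placements`` are (1-based start, orientation) pairs; each copy
    overwrites the decoy from its start. Realized copy intervals must fit
    in the decoy and must not overlap.
    """
    master = np.random.default_rng(config.seed)
    child_seeds = master.integers(0, 2**31 - 1, size=len(placements) + 2)
    ref_cfg = replace(config, seed=int(child_seeds[0]),
                      substitution_rates={}, indel_rate=0.0, rip_mode=False)
    reference, _, _ = simulate_repeat_pair(ref_cfg)
    reference = SequenceRecord("reference", reference.seq)

    decoy = list(random_sequence(decoy_length, config.ancestor_gc,
                                 np.random.default_rng(int(child_seeds[1]))))

    copies = []
    occupied: list[tuple[int, int]] = []
    for i, (start, orientation) in enumerate(placements):
        rates = (per_copy_rates[i] if per_copy_rates is not None
                 else config.substitution_rates)
        cfg_i = replace(config, seed=int(child_seeds[i + 2]),
                        substitution_rates=rates)
        # mutate the fixed reference, not a fresh ancestor
        copy_seq, ledger = _mutate_fixed(reference.seq, cfg_i)
        end = start + len(copy_seq) - 1
        if start < 1 or end > decoy_length:
            raise ValueError(f"placement {start} does not fit in decoy")
        for a, b in occupied:
            if start <= b and end >= a:
                raise ValueError(f"placement {start}..{end} overlaps {a}..{b}")
        occupied.append((start, end))
        embedded = (copy_seq if orientation == "sense"
                    else reverse_complement(copy_seq))
        decoy[start - 1:end] = list(embedded)
        interval = GenomicInterval("decoy", start, end, orientation)
        copies.append((interval, SequenceRecord(f"copy_{i}", copy_seq), ledger))

    genome = SequenceRecord("decoy", "".join(decoy))
    return genome, ArrayTruth(reference=reference, copies=copies)


def _mutate_fixed(ancestor: str, config: SimulationConfig
                  ) -> tuple[str, TruthLedger]:
    """Mutate a *given* ancestor under config (same machinery as
    simulate_repeat_pair, without regenerating the ancestor)."""
    cfg = replace(config, ancestor_length=len(ancestor))
    rng = np.random.default_rng(cfg.seed)
    _ = random_sequence(len(ancestor), cfg.ancestor_gc, rng)  # keep stream layout
    anc = np.array(list(ancestor))
    subs = _draw_substitutions(anc, cfg.substitution_rates, rng)
    srow = []
    events = []
    for pos in range(len(ancestor)):
        if pos in subs:
            category, target = subs[pos]
            events.append(MutationEvent("substitution", category, pos + 1, target))
            srow.append(target)
        else:
            srow.append(ancestor[pos])
    copy_seq = "".join(srow)
    ident = sum(1 for a, b in zip(ancestor, copy_seq) if a == b)
    aln = PairwiseAlignment("reference", "copy", ancestor, copy_seq, 0.0,
                            100.0 * ident / len(ancestor), len(ancestor),
                            molecule=NUCLEOTIDE)
    ledger = TruthLedger(events=events, true_alignment=aln,
                         expected_spectrum=MutationSpectrum())
    ledger.expected_spectrum = ledger.spectrum_from_events()
    return copy_seq, ledger


def simulate_gene_with_transcript(config: SimulationConfig
                                  ) -> tuple[SequenceRecord, SequenceRecord,
                                             GenomicInterval]:
    """A gene carrying one planted intron, plus its spliced transcript.

    ``config.intron_spec`` = (1-based exonic position the intron is inserted
    before, intron length). Returns (gene, transcript, intron interval in
    gene coordinates).
    """
    if config.intron_spec is None:
        raise ValueError("config.intron_spec is required")
    pos, length = config.intron_spec
    rng = np.random.default_rng(config.seed)
    exons = random_sequence(config.ancestor_length, config.ancestor_gc, rng)
    if not 1 <= pos <= len(exons):
        raise ValueError("intron position outside the exonic sequence")
    intron = random_sequence(length, config.ancestor_gc, rng)
    gene = exons[:pos - 1] + intron + exons[pos - 1:]
    interval = GenomicInterval("gene", pos, pos + length - 1)
    return (SequenceRecord("gene", gene),
            SequenceRecord("transcript", exons),
            interval)


@dataclass(frozen=True)
class RateEstimate:
    category: str
    estimate: float
    ci_low: float
    ci_high: float
    count: int
    eligible: int


def _eligible_sites(category: str, counts: dict[str, int]) -> int:
    base_of = {"c_to_t": "C", "c_to_a": "C", "g_to_a": "G", "g_to_t": "G",
               "t_to_c": "T", "t_to_g": "T", "a_to_g": "A", "a_to_c": "A"}
    if category == "at_neutral":
        return counts.get("A", 0) + counts.get("T", 0)
    if category == "gc_neutral":
        return counts.get("C", 0) + counts.get("G", 0)
    return counts.get(base_of[category], 0)


def estimate_rates(spectrum: MutationSpectrum, ancestor: SequenceRecord,
                   categories: Sequence[str] = RATE_KEYS,
                   confidence: float = 0.95) -> dict[str, RateEstimate]:
    """Per-category rate estimates with exact (Clopper-Pearson) binomial CIs.

    The denominator is the number of eligible ancestral sites for each
    category (e.g. the ancestor's C count for C→T) — rates are defined per
    ancestral site.
    """
    counts = {b: ancestor.seq.count(b) for b in "ACGT"}
    alpha = 1.0 - confidence
    out = {}
    for cat in categories:
        n_elig = _eligible_sites(cat, counts)
        if n_elig == 0:
            raise ValueError(f"no eligible ancestral sites for {cat!r}")
        k = getattr(spectrum, _SPECTRUM_KEY[cat])
        lo = 0.0 if k == 0 else float(_beta.ppf(alpha / 2, k, n_elig - k + 1))
        hi = 1.0 if k == n_elig else float(_beta.ppf(1 - alpha / 2, k + 1,
                                                     n_elig - k))
        out[cat] = RateEstimate(cat, k / n_elig, lo, hi, k, n_elig)
    return out
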