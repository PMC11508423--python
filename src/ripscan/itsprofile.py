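"""Locate and profile rDNA ITS repeat copies in a genome against genotype
references.

Copy finding is a seed-and-extend scan: exact k-mer seeds against the
reference on both strands, seed clustering, semi-global extension
(reference end-to-end, genome overhangs free) with the package's standard
alignment parameters, and overlap deduplication. Each accepted copy is
profiled for GC content, similarity to the GC-biased reference genotype,
its similarity range to the AT-biased reference genotypes, restriction-site
(EcoRI, GAATTC) positions, and its mutation spectrum / allelic ratio
against the GC-biased reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _stats

from . import seqio
from .seqio import GenomicInterval, SequenceRecord, base_content, reverse_complement
from .pairalign import (AlignmentParams, PairwiseAlignment, _make_aligner,
                        _terminal_overhang)
from .mutspec import MutationSpectrum, classify_alignment
from .ripstats import allelic_ratio as _allelic_ratio

ECORI = "GAATTC"


@dataclass
class GenotypeReferenceSet:
    """The GC-biased reference (gt1) and the AT-biased reference sequences."""

    gt1: SequenceRecord
    at_biased: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.gt1.molecule != seqio.NUCLEOTIDE:
            raise ValueError("references must be nucleotide")


@dataclass
class ITSCopyProfile:
    interval: GenomicInterval | None
    gc_percent: float
    similarity_to_ref: float
    at_ref_similarity_min: float | None
    at_ref_similarity_max: float | None
    ecori_positions: list
    spectrum_vs_ref: MutationSpectrum
    allelic_ratio: tuple[int, int]


def find_motif(seq: str | SequenceRecord, motif: str = ECORI) -> list[int]:
    """All 1-based start positions of exact (possibly overlapping) matches.

    For a palindromic motif a single-strand scan covers both strands.
    """
    if isinstance(seq, SequenceRecord):
        seq = seq.seq
    if not motif:
        raise ValueError("empty motif")
    motif = motif.upper()
    if set(motif) - set("ACGT"):
        raise ValueError("motif must be unambiguous nucleotide")
    positions = []
    start = seq.upper().find(motif)
    while start != -1:
        positions.append(start + 1)
        start = seq.upper().find(motif, start + 1)
    return positions


def is_palindromic(motif: str) -> bool:
    return reverse_complement(motif) == motif


def _glocal_align(region: str, reference: str, params: AlignmentParams):
    """Align reference end-to-end against a genome region whose overhangs
    are free. Returns (identity%, region start offset, region end offset,
    aligned reference columns)."""
    from dataclasses import replace as _replace
    aligner = _make_aligner(_replace(params, end_gaps_free=False),
                            seqio.NUCLEOTIDE, "global")
    # region is the target: its terminal overhangs are free; the reference
    # (query) pays normal end-gap penalties so it aligns end-to-end.
    aligner.open_end_deletion_score = 0.0
    aligner.extend_end_deletion_score = 0.0
    aln = aligner.align(region, reference)[0]
    a_region, a_ref = str(aln[0]), str(aln[1])
    # trim only the region overhang (columns where the reference is '-');
    # reference residues left unaligned at the ends stay in the core and
    # count against identity, so a truncated placement cannot outrank a
    # full-length one
    n = len(a_ref)
    lead = 0
    while lead < n and a_ref[lead] == "-":
        lead += 1
    trail = 0
    while trail < n - lead and a_ref[n - 1 - trail] == "-":
        trail += 1
    core_region = a_region[lead:n - trail]
    core_ref = a_ref[lead:n - trail]
    columns = len(core_ref)
    if columns == 0:
        return 0.0, 0, 0, 0
    ident = sum(1 for a, b in zip(core_region, core_ref)
                if a == b and a != "-")
    region_start = sum(1 for c in a_region[:lead] if c != "-")
    region_len = sum(1 for c in core_region if c != "-")
    return (100.0 * ident / columns, region_start,
            region_start + region_len, columns)


def find_repeat_copies(genome: Sequence[SequenceRecord],
                       reference: SequenceRecord,
                       min_identity: float = 80.0,
                       min_length_fraction: float = 0.8,
                       k: int = 12,
                       merge_distance: int = 50,
                       params: AlignmentParams | None = None,
                       ) -> list[GenomicInterval]:
    """Seed-and-extend scan for repeat copies of ``reference`` in a genome.

    Returns maximal non-overlapping intervals on both strands with identity
    >= ``min_identity`` and aligned footprint >= ``min_length_fraction`` of
    the reference length, sorted by contig then start. Short partial
    segments are excluded by the length fraction.
    """
    if len(reference.seq) < k:
        raise ValueError(f"reference shorter than k-mer size {k}")
    if params is None:
        params = AlignmentParams.nucleotide()
    ref_len = len(reference.seq)
    strands = {"sense": reference.seq,
               "antisense": reverse_complement(reference.seq)}
    accepted: list[tuple[GenomicInterval, float]] = []
    for record in genome:
        gseq = record.seq
        for orientation, ref in strands.items():
            kmers: dict[str, list[int]] = {}
            for i in range(ref_len - k + 1):
                kmers.setdefault(ref[i:i + k], []).append(i)
            starts = []  # implied copy start positions (0-based, may be <0)
            for j in range(len(gseq) - k + 1):
                for rpos in kmers.get(gseq[j:j + k], ()):
                    starts.append(j - rpos)
            if not starts:
                continue
            starts.sort()
            clusters: list[list[int]] = [[starts[0]]]
            for s in starts[1:]:
                if s - clusters[-1][-1] <= merge_distance:
                    clusters[-1].append(s)
                else:
                    clusters.append([s])
            for cluster in clusters:
                lo = max(0, min(cluster) - merge_distance)
                hi = min(len(gseq), max(cluster) + ref_len + merge_distance)
                region = gseq[lo:hi]
                identity, r0, r1, columns = _glocal_align(region, ref, params)
                footprint = r1 - r0
                if (identity >= min_identity
                        and footprint >= min_length_fraction * ref_len):
                    iv = GenomicInterval(record.id, lo + r0 + 1, lo + r1,
                                         orientation)
                    accepted.append((iv, identity))
    # deduplicate overlapping hits (e.g. duplicate seeds), keep best identity
    accepted.sort(key=lambda t: (-t[1], t[0].contig, t[0].start))
    kept: list[GenomicInterval] = []
    for iv, _ident in accepted:
        if any(iv.contig == other.contig
               and iv.start <= other.end and iv.end >= other.start
               for other in kept):
            continue
        kept.append(iv)
    kept.sort(key=lambda iv: (iv.contig, iv.start))
    return kept


def profile_its_copy(copy: SequenceRecord, refs: GenotypeReferenceSet,
                     params: AlignmentParams | None = None,
                     interval: GenomicInterval | None = None,
                     motif: str = ECORI) -> ITSCopyProfile:
    """Profile one (orientation-normalized) copy against the reference set."""
    from .pairalign import align_global
    if params is None:
        params = AlignmentParams.nucleotide()
    gc = base_content(copy).gc_percent
    aln = align_global(refs.gt1, copy, params)
    spectrum = classify_alignment(aln)
    ratios = _allelic_ratio(spectrum)
    at_sims = [align_global(ref, copy, params).identity_percent
               for ref in refs.at_biased]
    return ITSCopyProfile(
        interval=interval,
        gc_percent=gc,
        similarity_to_ref=aln.identity_percent,
        at_ref_similarity_min=min(at_sims) if at_sims else None,
        at_ref_similarity_max=max(at_sims) if at_sims else None,
        ecori_positions=find_motif(copy, motif),
        spectrum_vs_ref=spectrum,
        allelic_ratio=ratios)


def profile_genome_its(genome: Sequence[SequenceRecord],
                       refs: GenotypeReferenceSet,
                       min_identity: float = 80.0,
                       min_length_fraction: float = 0.8,
                       params: AlignmentParams | None = None,
                       ) -> list[ITSCopyProfile]:
    """Find all repeat copies of the GC-biased reference and profile each."""
    from .seqio import extract_interval
    intervals = find_repeat_copies(genome, refs.gt1, min_identity,
                                   min_length_fraction, params=params)
    by_id = {rec.id: rec for rec in genome}
    profiles = []
    for iv in intervals:
        copy = extract_interval(by_id[iv.contig], iv)
        profiles.append(profile_its_copy(copy, refs, params, interval=iv))
    return profiles


def compare_gc_groups(group_a: Sequence[float], group_b: Sequence[float]
                      ) -> tuple[float, float]:
    """Welch two-sample comparison of GC percentages (two-sided).

    Welch's unequal-variance t-test with Welch-Satterthwaite degrees of
    freedom. Degenerate zero-variance cases: equal means -> p = 1 by
    convention; unequal means with no variance -> p = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf"), 0.0
    stat, p = _stats.ttest_ind(a, b, equal_var=False)
    return float(stat), float(p)
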