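"""Per-column mutation-spectrum classification of authentic-gene vs
repeat-copy alignments, AT-content change categories, and per-family
categorization.

Every mismatch column of a nucleotide alignment is keyed (query base ->
subject base), with the query being the authentic gene and the subject an
orientation-normalized repeat copy. The eight directional substitution
counters cover the four transition directions and the four GC-changing
transversion directions; A<->T and C<->G transversions are composition-
neutral and tracked in dedicated counters so that every mismatch column is
accounted for exactly once. Maximal gap runs count as one indel event each,
with a parallel per-base tally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

from .seqio import ContentSummary, NUCLEOTIDE
from .pairalign import PairwiseAlignment

_DIRECTIONAL = {
    ("C", "T"): "c_to_t", ("G", "A"): "g_to_a",
    ("T", "C"): "t_to_c", ("A", "G"): "a_to_g",
    ("C", "A"): "c_to_a", ("G", "T"): "g_to_t",
    ("A", "C"): "a_to_c", ("T", "G"): "t_to_g",
}
_NEUTRAL = {
    ("A", "T"): "at_neutral_transversions", ("T", "A"): "at_neutral_transversions",
    ("C", "G"): "gc_neutral_transversions", ("G", "C"): "gc_neutral_transversions",
}

COUNTER_FIELDS = (
    "c_to_t", "g_to_a", "t_to_c", "a_to_g",
    "c_to_a", "g_to_t", "a_to_c", "t_to_g",
    "at_neutral_transversions", "gc_neutral_transversions",
    "insertion_events", "deletion_events",
    "insertion_bases", "deletion_bases",
    "ambiguous_columns",
)


@dataclass
class MutationSpectrum:
    """The eight directional substitution counters plus neutral-transversion,
    indel, and ambiguous-column counters."""

    c_to_t: int = 0
    g_to_a: int = 0
    t_to_c: int = 0
    a_to_g: int = 0
    c_to_a: int = 0
    g_to_t: int = 0
    a_to_c: int = 0
    t_to_g: int = 0
    at_neutral_transversions: int = 0
    gc_neutral_transversions: int = 0
    insertion_events: int = 0
    deletion_events: int = 0
    insertion_bases: int = 0
    deletion_bases: int = 0
    ambiguous_columns: int = 0

    # -- derived sums -------------------------------------------------
    @property
    def rip_transitions(self) -> int:
        """C→T + G→A: the transitions RIP mutagenesis produces."""
        return self.c_to_t + self.g_to_a

    @property
    def reverse_transitions(self) -> int:
        """T→C + A→G: transitions opposite to the RIP direction."""
        return self.t_to_c + self.a_to_g

    @property
    def transitions_total(self) -> int:
        return self.rip_transitions + self.reverse_transitions

    @property
    def rip_transversions(self) -> int:
        """C→A + G→T: GC-lowering transversions."""
        return self.c_to_a + self.g_to_t

    @property
    def reverse_transversions(self) -> int:
        """A→C + T→G: GC-raising transversions."""
        return self.a_to_c + self.t_to_g

    @property
    def transversions_total(self) -> int:
        """All transversions, including composition-neutral A<->T and C<->G."""
        return (self.rip_transversions + self.reverse_transversions
                + self.at_neutral_transversions + self.gc_neutral_transversions)

    @property
    def gc_to_at_total(self) -> int:
        """G or C → A or T (the "G or C to A or T" table column)."""
        return self.c_to_t + self.g_to_a + self.c_to_a + self.g_to_t

    @property
    def at_to_gc_total(self) -> int:
        """A or T → G or C."""
        return self.t_to_c + self.a_to_g + self.a_to_c + self.t_to_g

    @property
    def indel_events(self) -> int:
        return self.insertion_events + self.deletion_events

    @property
    def substitution_columns(self) -> int:
        return (self.gc_to_at_total + self.at_to_gc_total
                + self.at_neutral_transversions + self.gc_neutral_transversions)

    def __add__(self, other: "MutationSpectrum") -> "MutationSpectrum":
        return MutationSpectrum(**{
            f.name: getattr(self, f.name) + getattr(other, f.name)
            for f in fields(self)})

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d.update(
            rip_transitions=self.rip_transitions,
            reverse_transitions=self.reverse_transitions,
            gc_to_at_total=self.gc_to_at_total,
            at_to_gc_total=self.at_to_gc_total,
        )
        return d


def classify_alignment(alignment: PairwiseAlignment) -> MutationSpectrum:
    """Classify every column of a query(authentic)→subject(copy) alignment.

    Mismatch columns increment exactly one substitution counter; columns
    containing an ambiguity code increment ``ambiguous_columns`` only; a
    maximal run of '-' in the query row is one insertion event (sequence
    present only in the copy), in the subject row one deletion event, each
    with its base count.
    """
    if alignment.molecule != NUCLEOTIDE:
        raise ValueError("classify_alignment requires a nucleotide alignment")
    aq, asub = alignment.aligned_query, alignment.aligned_subject
    if len(aq) != len(asub):
        raise ValueError("alignment rows of unequal length")
    spec = MutationSpectrum()
    i = 0
    n = len(aq)
    while i < n:
        q, s = aq[i], asub[i]
        if q == "-" and s == "-":
            raise ValueError(f"column {i + 1} gapped in both rows")
        if q == "-":
            j = i
            while j < n and aq[j] == "-":
                j += 1
            spec.insertion_events += 1
            spec.insertion_bases += j - i
            i = j
            continue
        if s == "-":
            j = i
            while j < n and asub[j] == "-":
                j += 1
            spec.deletion_events += 1
            spec.deletion_bases += j - i
            i = j
            continue
        if q != s:
            key = (q, s)
            if key in _DIRECTIONAL:
                setattr(spec, _DIRECTIONAL[key],
                        getattr(spec, _DIRECTIONAL[key]) + 1)
            elif key in _NEUTRAL:
                setattr(spec, _NEUTRAL[key], getattr(spec, _NEUTRAL[key]) + 1)
            else:
                spec.ambiguous_columns += 1
        i += 1
    return spec


# -- AT-content change categories ------------------------------------

NO_CHANGE = "no_change"
SLIGHT_DECREASE = "slight_decrease"
LARGE_DECREASE = "large_decrease"
SLIGHT_INCREASE = "slight_increase"
LARGE_INCREASE = "large_increase"
HOMOLOGOUS = "homologous"
BIDIRECTIONAL = "bidirectional"


@dataclass(frozen=True)
class ATChangeCategory:
    """Change in AT content (percentage points, subject minus query).

    |delta| <= no_change_limit -> no_change; <= slight_limit -> slight;
    beyond -> large, signed by direction. Boundaries land on the smaller
    category (exactly 1 -> no_change, exactly 5 -> slight).
    """

    category: str
    delta: float


def at_change(query_content: ContentSummary, subject_content: ContentSummary,
              no_change_limit: float = 1.0,
              slight_limit: float = 5.0) -> ATChangeCategory:
    delta = subject_content.at_percent - query_content.at_percent
    mag = abs(delta)
    if mag <= no_change_limit:
        return ATChangeCategory(NO_CHANGE, delta)
    if delta > 0:
        cat = SLIGHT_INCREASE if mag <= slight_limit else LARGE_INCREASE
    else:
        cat = SLIGHT_DECREASE if mag <= slight_limit else LARGE_DECREASE
    return ATChangeCategory(cat, delta)


def family_category(copies: list[tuple[ATChangeCategory, float]],
                    homology_threshold: float = 97.0) -> str:
    """Categorize a repeat family from its copies' (AT change, similarity%).

    Homologous: every copy >= the similarity threshold with no categorical
    AT change. Bidirectional: increases and decreases beyond the +/-1-point
    band co-occur. Otherwise the strongest category in the shared direction,
    or no_change when all copies sit inside the band.
    """
    if not copies:
        raise ValueError("family_category requires at least one copy")
    cats = [c.category for c, _ in copies]
    incr = any(c in (SLIGHT_INCREASE, LARGE_INCREASE) for c in cats)
    decr = any(c in (SLIGHT_DECREASE, LARGE_DECREASE) for c in cats)
    if incr and decr:
        return BIDIRECTIONAL
    if not incr and not decr:
        if all(sim >= homology_threshold for _, sim in copies):
            return HOMOLOGOUS
        return NO_CHANGE
    if incr:
        return (LARGE_INCREASE if any(c == LARGE_INCREASE for c in cats)
                else SLIGHT_INCREASE)
    return (LARGE_DECREASE if any(c == LARGE_DECREASE for c in cats)
            else SLIGHT_DECREASE)


@dataclass
class RepeatFamilyReport:
    """Per-gene family report: one row per repeat copy plus the family call."""

    gene_id: str
    copies: list = field(default_factory=list)  # (interval, similarity, ATChangeCategory, MutationSpectrum)

    @property
    def family(self) -> str:
        return family_category([(atc, sim) for _, sim, atc, _ in self.copies])
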