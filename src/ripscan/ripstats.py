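"""RIP-signature statistics and verdicts from a mutation spectrum.

Repeat-induced point mutation (RIP) converts C:G pairs to T:A, so a repeat
copy shaped by RIP shows (i) more C→T + G→A transitions than the reverse
T→C + A→G transitions, (ii) more GC→AT changes overall than AT→GC changes,
and (iii) a mutation load dominated by transitions rather than by
insertions, deletions and transversions. The verdict codifies that verbal
argument as explicit dominance comparisons with a minimum-event guard; ties
are never coerced.
"""

from __future__ import annotations

from dataclasses import dataclass

from .mutspec import MutationSpectrum

CONSISTENT = "consistent_with_rip"
INCONSISTENT = "inconsistent_with_rip"
INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class RipSignature:
    rip_transitions: int
    reverse_transitions: int
    rip_transversions: int
    reverse_transversions: int
    gc_to_at_total: int
    at_to_gc_total: int
    indel_plus_transversion: int
    transitions_total: int

    @property
    def allelic_ratio(self) -> tuple[int, int]:
        """(insertions + deletions + transversions) : transitions."""
        return (self.indel_plus_transversion, self.transitions_total)

    @property
    def rip_dominant(self) -> bool:
        return (self.rip_transitions > self.reverse_transitions
                and self.gc_to_at_total > self.at_to_gc_total)

    @property
    def total_events(self) -> int:
        return self.indel_plus_transversion + self.transitions_total


def rip_ratios(spectrum: MutationSpectrum) -> RipSignature:
    """Derive the RIP-signature summary from a mutation spectrum."""
    return RipSignature(
        rip_transitions=spectrum.rip_transitions,
        reverse_transitions=spectrum.reverse_transitions,
        rip_transversions=spectrum.rip_transversions,
        reverse_transversions=spectrum.reverse_transversions,
        gc_to_at_total=spectrum.gc_to_at_total,
        at_to_gc_total=spectrum.at_to_gc_total,
        indel_plus_transversion=(spectrum.indel_events
                                 + spectrum.transversions_total),
        transitions_total=spectrum.transitions_total,
    )


def allelic_ratio(spectrum: MutationSpectrum) -> tuple[int, int]:
    """Insertion/deletion events plus all transversions, versus transitions."""
    return rip_ratios(spectrum).allelic_ratio


def rip_verdict(sig: RipSignature | MutationSpectrum,
                min_events: int = 10) -> str:
    """Classify a copy's mutation pattern relative to the RIP expectation.

    consistent_with_rip: RIP-direction transitions and GC→AT changes both
    dominate, and transitions outnumber indels + transversions.
    inconsistent_with_rip: reverse transitions dominate, or indels +
    transversions dominate. Anything else — ties, or fewer than
    ``min_events`` total mutations — is indeterminate.
    """
    if isinstance(sig, MutationSpectrum):
        sig = rip_ratios(sig)
    if sig.total_events < min_events:
        return INDETERMINATE
    if (sig.rip_dominant
            and sig.transitions_total > sig.indel_plus_transversion):
        return CONSISTENT
    if (sig.reverse_transitions > sig.rip_transitions
            or sig.indel_plus_transversion > sig.transitions_total):
        return INCONSISTENT
    return INDETERMINATE
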