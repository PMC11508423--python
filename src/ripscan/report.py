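"""Table rendering mirroring the analysis' published layouts.

TSVs carry percentages at 1 decimal place (half-to-even); the JSON sidecars
keep full precision. BED output is 0-based half-open with a strand column
(the conversion from the package's 1-based inclusive intervals happens
here).
"""

from __future__ import annotations

import json
from typing import Sequence

import pandas as pd

from .seqio import GenomicInterval, round1
from .mutspec import ATChangeCategory, MutationSpectrum
from .ripstats import rip_verdict, allelic_ratio
from .itsprofile import ITSCopyProfile
from .pairalign import TranscriptMapping

_ARROW = {"sense": "→", "antisense": "←"}


def format_interval(iv: GenomicInterval) -> str:
    return f"{iv.contig} ({iv.start}{_ARROW[iv.orientation]}{iv.end})"


def format_at_change(atc: ATChangeCategory, query_at: float,
                     subject_at: float) -> str:
    if atc.category == "no_change":
        return f"No change ({round1(query_at)}%)"
    arrow = "↑" if atc.delta > 0 else "↓"
    return f"{arrow} {round1(query_at)}% to {round1(subject_at)}%"


def spectrum_table(rows: Sequence[dict]) -> pd.DataFrame:
    """One row per repeat copy: similarity, AT change, the six count
    columns, indels, allelic ratio, verdict (optionally transcript
    similarity/coverage)."""
    cols = [
        "subject", "similarity_percent", "at_change",
        "c_to_t_and_g_to_a", "t_to_c_and_a_to_g",
        "c_to_a_and_g_to_t", "a_to_c_and_t_to_g",
        "gc_to_at_total", "at_to_gc_total",
        "insertion_events", "deletion_events",
        "insertion_bases", "deletion_bases",
        "allelic_ratio", "verdict",
        "transcript_similarity_percent", "transcript_coverage_percent",
    ]
    df = pd.DataFrame(rows)
    for c in cols:
        if c not in df.columns:
            df[c] = None
    for c in df.columns:
        if c.endswith("_percent"):
            df[c] = df[c].map(lambda x: None if pd.isna(x) else round1(x))
    return df[cols]


def spectrum_row(subject_id: str, similarity: float,
                 at_change_str: str, spectrum: MutationSpectrum,
                 mapping: TranscriptMapping | None = None) -> dict:
    num, den = allelic_ratio(spectrum)
    row = {
        "subject": subject_id,
        "similarity_percent": similarity,
        "at_change": at_change_str,
        "c_to_t_and_g_to_a": spectrum.rip_transitions,
        "t_to_c_and_a_to_g": spectrum.reverse_transitions,
        "c_to_a_and_g_to_t": spectrum.rip_transversions,
        "a_to_c_and_t_to_g": spectrum.reverse_transversions,
        "gc_to_at_total": spectrum.gc_to_at_total,
        "at_to_gc_total": spectrum.at_to_gc_total,
        "insertion_events": spectrum.insertion_events,
        "deletion_events": spectrum.deletion_events,
        "insertion_bases": spectrum.insertion_bases,
        "deletion_bases": spectrum.deletion_bases,
        "allelic_ratio": f"{num}:{den}",
        "verdict": rip_verdict(spectrum),
    }
    if mapping is not None and not mapping.empty:
        row["transcript_similarity_percent"] = mapping.similarity_percent
        row["transcript_coverage_percent"] = mapping.query_coverage_percent
    return row


def its_profile_table(profiles: Sequence[ITSCopyProfile]) -> pd.DataFrame:
    """GC%, similarity to the GC-biased reference, AT-reference range."""
    rows = []
    for p in profiles:
        rows.append({
            "interval": format_interval(p.interval) if p.interval else "-",
            "gc_percent": round1(p.gc_percent),
            "similarity_to_gt1_percent": round1(p.similarity_to_ref),
            "at_ref_similarity_range": (
                f"{round1(p.at_ref_similarity_min)}–"
                f"{round1(p.at_ref_similarity_max)}%"
                if p.at_ref_similarity_min is not None else "-"),
            "ecori_sites": len(p.ecori_positions),
        })
    return pd.DataFrame(rows)


def its_allele_table(profiles: Sequence[ITSCopyProfile]) -> pd.DataFrame:
    """Indel / transversion / transition counts and the allelic ratio."""
    rows = []
    for p in profiles:
        s = p.spectrum_vs_ref
        num, den = p.allelic_ratio
        rows.append({
            "interval": format_interval(p.interval) if p.interval else "-",
            "similarity_percent": round1(p.similarity_to_ref),
            "ins_del": s.indel_events,
            "transversions": s.transversions_total,
            "transitions": s.transitions_total,
            "ratio": f"{num}:{den}",
            "verdict": rip_verdict(s),
        })
    return pd.DataFrame(rows)


def intervals_to_bed(intervals: Sequence[GenomicInterval]) -> str:
    """BED (0-based half-open) with name/score/strand columns."""
    lines = []
    for i, iv in enumerate(intervals):
        strand = "+" if iv.orientation == "sense" else "-"
        lines.append(f"{iv.contig}\t{iv.start - 1}\t{iv.end}\t"
                     f"copy_{i + 1}\t0\t{strand}")
    return "\n".join(lines) + ("\n" if lines else "")


def spectrum_json(rows: Sequence[dict], spectra: Sequence[MutationSpectrum]) -> str:
    """Full-precision JSON sidecar for a spectrum table."""
    payload = []
    for row, spec in zip(rows, spectra):
        entry = dict(row)
        entry["spectrum"] = spec.to_dict()
        payload.append(entry)
    return json.dumps(payload, indent=2, ensure_ascii=False, default=str)
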