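"""FASTA input/output, genomic intervals, and base-composition summaries.

Coordinates throughout the package are 1-based and inclusive, written
``start→end`` for the sense strand and ``start←end`` for the antisense
strand, matching the convention of genome-browser style locus tables.
Conversion to Python's 0-based half-open slices happens in exactly one
place (:func:`_to_slice`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

NUCLEOTIDE = "nucleotide"
PROTEIN = "protein"

# IUPAC nucleotide codes (incl. ambiguity) and amino acids + X.
_NUC_CHARS = frozenset("ACGTUNRYSWKMBDHV")
_PROT_CHARS = frozenset("ACDEFGHIKLMNPQRSTVWYX")
_UNAMBIGUOUS = frozenset("ACGT")


@dataclass(frozen=True)
class SequenceRecord:
    """One named nucleotide or protein sequence.

    The sequence is upper-cased on construction and validated against the
    declared alphabet; the position of the first offending character is
    reported on failure.
    """

    id: str
    seq: str
    molecule: str = NUCLEOTIDE

    def __post_init__(self) -> None:
        if self.molecule not in (NUCLEOTIDE, PROTEIN):
            raise ValueError(f"unknown molecule type: {self.molecule!r}")
        seq = self.seq.upper()
        object.__setattr__(self, "seq", seq)
        if not seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        alphabet = _NUC_CHARS if self.molecule == NUCLEOTIDE else _PROT_CHARS
        for i, ch in enumerate(seq):
            if ch not in alphabet:
                raise ValueError(
                    f"record {self.id!r}: illegal {self.molecule} character "
                    f"{ch!r} at position {i + 1}"
                )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive interval on a named contig with strand."""

    contig: str
    start: int
    end: int
    orientation: str = "sense"

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"interval start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"interval end ({self.end}) precedes start ({self.start})"
            )
        if self.orientation not in ("sense", "antisense"):
            raise ValueError(f"unknown orientation: {self.orientation!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __str__(self) -> str:
        arrow = "→" if self.orientation == "sense" else "←"
        return f"{self.contig}:{self.start}{arrow}{self.end}"


@dataclass(frozen=True)
class ContentSummary:
    """Base counts and GC/AT percentages over the called (unambiguous) bases."""

    counts: dict = field(compare=False)
    gc_percent: float
    at_percent: float
    denominator: int


def _to_slice(start: int, end: int) -> slice:
    """1-based inclusive (start, end) -> 0-based half-open slice.

    The single coordinate-convention boundary in the package.
    """
    return slice(start - 1, end)


def read_fasta(path: str | Path, molecule: str = NUCLEOTIDE) -> list[SequenceRecord]:
    """Read a (possibly multi-record, wrapped) FASTA file.

    Order is preserved; sequences are upper-cased and alphabet-checked.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(id=rec.id, seq=str(rec.seq), molecule=molecule))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def reverse_complement(seq: str) -> str:
    """Reverse complement with full IUPAC ambiguity support."""
    seq = seq.upper()
    bad = set(seq) - _NUC_CHARS
    if bad:
        raise ValueError(f"non-nucleotide character(s): {sorted(bad)}")
    return str(Seq(seq).reverse_complement())


def extract_interval(record: SequenceRecord, interval: GenomicInterval) -> SequenceRecord:
    """Extract a 1-based inclusive interval; antisense returns the reverse
    complement so the result reads 5'→3' on the annotated strand."""
    if record.molecule != NUCLEOTIDE:
        raise ValueError("extract_interval requires a nucleotide record")
    if interval.end > len(record.seq):
        raise ValueError(
            f"interval {interval} out of range for {record.id!r} "
            f"(length {len(record.seq)})"
        )
    sub = record.seq[_to_slice(interval.start, interval.end)]
    if interval.orientation == "antisense":
        sub = reverse_complement(sub)
    return SequenceRecord(id=f"{record.id}:{interval.start}-{interval.end}"
                             f"({interval.orientation})",
                          seq=sub, molecule=NUCLEOTIDE)


def extract_segments(record: SequenceRecord,
                     intervals: Sequence[GenomicInterval]) -> SequenceRecord:
    """Concatenate several intervals of one contig in listed order.

    Multi-segment loci printed as "(a→b; c→d)" are concatenated in listed
    order before composition or alignment computations.
    """
    if not intervals:
        raise ValueError("no intervals given")
    parts = [extract_interval(record, iv).seq for iv in intervals]
    ident = record.id + ":" + ";".join(f"{iv.start}-{iv.end}" for iv in intervals)
    return SequenceRecord(id=ident, seq="".join(parts), molecule=NUCLEOTIDE)


_SEGMENT_RE = re.compile(r"^(\d+)\s*(→|←|->|<-)\s*(\d+)$")


def parse_interval_spec(spec: str) -> list[GenomicInterval]:
    """Parse ``contig:start(→|←)end[;start(→|←)end...]`` into intervals.

    ASCII ``->`` / ``<-`` are accepted as synonyms of the arrows. For the
    antisense arrow the printed order is (upstream, downstream) on the plus
    strand, so ``a←b`` with a < b still means plus-strand coordinates a..b
    read on the minus strand; if a > b the two are swapped.
    """
    if ":" not in spec:
        raise ValueError(f"interval spec needs 'contig:start→end', got {spec!r}")
    contig, _, rest = spec.partition(":")
    intervals = []
    for segment in rest.split(";"):
        m = _SEGMENT_RE.match(segment.strip())
        if not m:
            raise ValueError(f"cannot parse interval segment {segment!r}")
        a, arrow, b = int(m.group(1)), m.group(2), int(m.group(3))
        orientation = "sense" if arrow in ("→", "->") else "antisense"
        lo, hi = min(a, b), max(a, b)
        intervals.append(GenomicInterval(contig, lo, hi, orientation))
    return intervals


def base_content(seq: str | SequenceRecord) -> ContentSummary:
    """GC/AT percentages over called bases; ambiguity codes are excluded
    from the denominator. Strand-invariant by construction."""
    if isinstance(seq, SequenceRecord):
        if seq.molecule != NUCLEOTIDE:
            raise ValueError("base_content requires a nucleotide sequence")
        seq = seq.seq
    seq = seq.upper()
    counts = {b: 0 for b in "ACGTN"}
    for ch in seq:
        if ch in counts:
            counts[ch] += 1
        else:
            counts["N"] += 1  # any ambiguity code tallied with N
    denom = counts["A"] + counts["C"] + counts["G"] + counts["T"]
    if denom == 0:
        raise ValueError("base content undefined: no unambiguous bases")
    gc = 100.0 * (counts["G"] + counts["C"]) / denom
    at = 100.0 * (counts["A"] + counts["T"]) / denom
    return ContentSummary(counts=counts, gc_percent=gc, at_percent=at,
                          denominator=denom)


def round1(x: float) -> float:
    """Round to 1 decimal place, half-to-even (table output convention)."""
    return float(round(x, 1))
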