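"""Pairwise alignment: global/semi-global/local, identity and positives,
and transcript-to-genomic-copy mapping with intron-gap flagging.

The dynamic programming itself is delegated to ``Bio.Align.PairwiseAligner``
(affine gap penalties, optimal score, deterministic canonical traceback);
this module owns the scoring conventions, the identity/positives
bookkeeping, and the mapping logic.

Scoring conventions
-------------------
Penalties are stored as positive magnitudes. A gap of length L costs
``gap_open + (L - 1) * gap_extend``: the first gapped column is charged at
the open cost. With ``end_gaps_free`` (the default for genomic-copy vs
authentic-gene comparisons) terminal gaps cost nothing and terminal
overhang columns are excluded from the identity denominator, which is the
closest global analogue of a BLAST local identity over the reported region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import NUCLEOTIDE, PROTEIN, SequenceRecord


@dataclass(frozen=True)
class AlignmentParams:
    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 10.0
    gap_extend: float = 0.5
    protein_matrix: str = "BLOSUM62"
    end_gaps_free: bool = True

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValueError("require gap_open >= gap_extend >= 0")

    @classmethod
    def nucleotide(cls, **kw) -> "AlignmentParams":
        """BLAST-like nucleotide defaults: +5/-4, open 10, extend 0.5."""
        return cls(**kw)

    @classmethod
    def protein(cls, **kw) -> "AlignmentParams":
        """BLOSUM62 with gap open 11 / extend 1."""
        kw.setdefault("gap_open", 11.0)
        kw.setdefault("gap_extend", 1.0)
        return cls(**kw)


@dataclass
class PairwiseAlignment:
    query_id: str
    subject_id: str
    aligned_query: str
    aligned_subject: str
    score: float
    identity_percent: float
    columns: int
    positives_percent: float | None = None
    molecule: str = NUCLEOTIDE

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_subject):
            raise ValueError("aligned rows have unequal length")


@dataclass
class TranscriptMapping:
    """Best local alignment of a transcript onto a genomic copy.

    ``gap_runs`` are maximal runs of '-' as (1-based alignment column,
    length, row) with row in {"query", "subject"}; query is the transcript.
    Gap runs in the transcript row of at least ``min_intron`` columns are
    intron candidates (an intron is present in the genomic copy and spliced
    out of the transcript).
    """

    similarity_percent: float
    query_coverage_percent: float
    gap_runs: list = field(default_factory=list)
    intron_candidates: list = field(default_factory=list)
    alignment: PairwiseAlignment | None = None

    @property
    def empty(self) -> bool:
        return self.alignment is None


@lru_cache(maxsize=8)
def _matrix(name: str):
    return substitution_matrices.load(name)


def _make_aligner(params: AlignmentParams, molecule: str, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    if molecule == PROTEIN:
        aligner.substitution_matrix = _matrix(params.protein_matrix)
    else:
        aligner.match_score = params.match
        aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    if mode == "global" and params.end_gaps_free:
        aligner.open_end_gap_score = 0.0
        aligner.extend_end_gap_score = 0.0
    return aligner


def _terminal_overhang(aq: str, asub: str) -> tuple[int, int]:
    """Number of leading/trailing columns where either row is gapped."""
    n = len(aq)
    lead = 0
    while lead < n and (aq[lead] == "-" or asub[lead] == "-"):
        lead += 1
    trail = 0
    while trail < n - lead and (aq[n - 1 - trail] == "-" or asub[n - 1 - trail] == "-"):
        trail += 1
    return lead, trail


def _identity_positives(aq: str, asub: str, molecule: str,
                        params: AlignmentParams,
                        exclude_terminal: bool) -> tuple[float, float | None, int]:
    lead, trail = _terminal_overhang(aq, asub) if exclude_terminal else (0, 0)
    core_q = aq[lead:len(aq) - trail]
    core_s = asub[lead:len(asub) - trail]
    columns = len(core_q)
    if columns == 0:
        return 0.0, (0.0 if molecule == PROTEIN else None), 0
    ident = sum(1 for a, b in zip(core_q, core_s) if a == b and a != "-")
    identity = 100.0 * ident / columns
    positives = None
    if molecule == PROTEIN:
        mat = _matrix(params.protein_matrix)
        pos = 0
        for a, b in zip(core_q, core_s):
            if a != "-" and b != "-" and mat[a, b] > 0:
                pos += 1
        positives = 100.0 * pos / columns
    return identity, positives, columns


def _check_pair(query: SequenceRecord, subject: SequenceRecord) -> str:
    if query.molecule != subject.molecule:
        raise ValueError("query and subject must be the same molecule type")
    if not query.seq or not subject.seq:
        raise ValueError("empty sequence")
    return query.molecule


def _first_alignment(aligner: Align.PairwiseAligner, q: str, s: str):
    # Canonical traceback: the first reported optimal alignment; the
    # enumeration order is deterministic for fixed inputs and parameters.
    return aligner.align(q, s)[0]


def align_global(query: SequenceRecord, subject: SequenceRecord,
                 params: AlignmentParams | None = None) -> PairwiseAlignment:
    """Optimal affine-gap global alignment (semi-global if end_gaps_free)."""
    molecule = _check_pair(query, subject)
    if params is None:
        params = (AlignmentParams.protein() if molecule == PROTEIN
                  else AlignmentParams.nucleotide())
    aligner = _make_aligner(params, molecule, "global")
    aln = _first_alignment(aligner, query.seq, subject.seq)
    aq, asub = str(aln[0]), str(aln[1])
    identity, positives, columns = _identity_positives(
        aq, asub, molecule, params, exclude_terminal=params.end_gaps_free)
    return PairwiseAlignment(
        query_id=query.id, subject_id=subject.id,
        aligned_query=aq, aligned_subject=asub, score=float(aln.score),
        identity_percent=identity, positives_percent=positives,
        columns=columns, molecule=molecule)


def align_protein(query: SequenceRecord, subject: SequenceRecord,
                  params: AlignmentParams | None = None) -> PairwiseAlignment:
    """Global protein alignment with identity and positives percentages."""
    if query.molecule != PROTEIN or subject.molecule != PROTEIN:
        raise ValueError("align_protein requires protein records")
    if params is None:
        params = AlignmentParams.protein()
    return align_global(query, subject, params)


def align_local(query: SequenceRecord, subject: SequenceRecord,
                params: AlignmentParams | None = None) -> PairwiseAlignment:
    """Optimal affine-gap local (Smith-Waterman) alignment."""
    molecule = _check_pair(query, subject)
    if params is None:
        params = (AlignmentParams.protein() if molecule == PROTEIN
                  else AlignmentParams.nucleotide())
    aligner = _make_aligner(params, molecule, "local")
    try:
        aln = _first_alignment(aligner, query.seq, subject.seq)
    except IndexError:
        # no positive-scoring local alignment exists
        return PairwiseAlignment(query_id=query.id, subject_id=subject.id,
                                 aligned_query="", aligned_subject="",
                                 score=0.0, identity_percent=0.0,
                                 positives_percent=(0.0 if molecule == PROTEIN
                                                    else None),
                                 columns=0, molecule=molecule)
    aq, asub = str(aln[0]), str(aln[1])
    # Biopython renders local alignments padded to the full sequences with
    # terminal gaps; trim to the aligned core.
    lead, trail = _terminal_overhang(aq, asub)
    aq = aq[lead:len(aq) - trail]
    asub = asub[lead:len(asub) - trail]
    identity, positives, columns = _identity_positives(
        aq, asub, molecule, params, exclude_terminal=False)
    return PairwiseAlignment(
        query_id=query.id, subject_id=subject.id,
        aligned_query=aq, aligned_subject=asub, score=float(aln.score),
        identity_percent=identity, positives_percent=positives,
        columns=columns, molecule=molecule)


def gap_runs(alignment: PairwiseAlignment) -> list[tuple[int, int, str]]:
    """Maximal '-' runs as (1-based column, length, row)."""
    runs = []
    for row_name, row in (("query", alignment.aligned_query),
                          ("subject", alignment.aligned_subject)):
        i = 0
        n = len(row)
        while i < n:
            if row[i] == "-":
                j = i
                while j < n and row[j] == "-":
                    j += 1
                runs.append((i + 1, j - i, row_name))
                i = j
            else:
                i += 1
    runs.sort()
    return runs


def map_transcript(transcript: SequenceRecord, genomic_copy: SequenceRecord,
                   params: AlignmentParams | None = None,
                   min_intron: int = 20) -> TranscriptMapping:
    """Map a transcript (query) onto a genomic copy by best local alignment.

    Query coverage is the percentage of transcript bases inside the aligned
    region. Gap runs in the transcript row of length >= ``min_intron`` are
    flagged as intron candidates. A transcript with no positive-scoring
    alignment yields an empty mapping (not an error).
    """
    if transcript.molecule != NUCLEOTIDE or genomic_copy.molecule != NUCLEOTIDE:
        raise ValueError("map_transcript requires nucleotide records")
    if params is None:
        params = AlignmentParams.nucleotide()
    aln = align_local(transcript, genomic_copy, params)
    aligned_transcript_bases = sum(
        1 for c in aln.aligned_query if c != "-")
    if aln.score <= 0 or aligned_transcript_bases == 0:
        return TranscriptMapping(similarity_percent=0.0,
                                 query_coverage_percent=0.0)
    runs = gap_runs(aln)
    introns = [r for r in runs if r[2] == "query" and r[1] >= min_intron]
    coverage = 100.0 * aligned_transcript_bases / len(transcript.seq)
    return TranscriptMapping(
        similarity_percent=aln.identity_percent,
        query_coverage_percent=coverage,
        gap_runs=runs,
        intron_candidates=introns,
        alignment=aln)


def ungap(alignment: PairwiseAlignment) -> tuple[str, str]:
    """The two input sequences recovered by deleting '-' from each row."""
    return (alignment.aligned_query.replace("-", ""),
            alignment.aligned_subject.replace("-", ""))


def format_alignment(alignment: PairwiseAlignment, width: int = 60) -> str:
    """Two-row alignment text in fixed-width blocks with a match line."""
    out = []
    aq, asub = alignment.aligned_query, alignment.aligned_subject
    for start in range(0, len(aq), width):
        q = aq[start:start + width]
        s = asub[start:start + width]
        mid = "".join("|" if a == b and a != "-" else " " for a, b in zip(q, s))
        out.append(f"query   {q}\n        {mid}\nsubject {s}\n")
    return "\n".join(out)
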