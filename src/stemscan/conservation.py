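"""Cross-species percent similarity of UTRs and of structural elements.

Pairwise similarity is computed from an optimal global alignment (match 1,
mismatch 0, gap open -3, gap extend -1 by default) as
``100 * matches / aligned_length`` with gap columns counted in the
denominator.  This is a reproducible surrogate for the k-tuple heuristic
aligners used interactively in sequence-analysis suites; scoring is exposed
so users can match other conventions.

Orthologous copies of an element identified on one sequence are located by
aligning the two full sequences and projecting the element's interval
through the alignment columns.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

from .sequences import SequenceRecord, extract_region


@dataclass(frozen=True)
class AlignmentScoring:
    match: float = 1.0
    mismatch: float = 0.0
    gap_open: float = -3.0
    gap_extend: float = -1.0


@dataclass(frozen=True)
class SimilarityResult:
    id_a: str
    id_b: str
    percent_similarity: float
    aligned_length: int
    matches: int
    scoring: AlignmentScoring

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_similarity <= 100.0):
            raise ValueError("percent similarity outside [0, 100]")


def _aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def pairwise_similarity(
    a: SequenceRecord, b: SequenceRecord, scoring: AlignmentScoring | None = None
) -> SimilarityResult:
    """Percent similarity of two records under an optimal global alignment."""
    if not a.residues or not b.residues:
        raise ValueError("cannot align an empty sequence")
    scoring = scoring or AlignmentScoring()
    alignment = _aligner(scoring).align(a.residues, b.residues)[0]
    sa, sb = str(alignment[0]), str(alignment[1])
    matches = sum(x == y and x != "-" for x, y in zip(sa, sb))
    aligned_length = len(sa)
    return SimilarityResult(
        id_a=a.id,
        id_b=b.id,
        percent_similarity=100.0 * matches / aligned_length,
        aligned_length=aligned_length,
        matches=matches,
        scoring=scoring,
    )


def gc_content(seq: SequenceRecord) -> float:
    """(G + C) / length of the record."""
    if not seq.residues:
        raise ValueError("empty sequence")
    gc = seq.residues.count("G") + seq.residues.count("C")
    return gc / len(seq.residues)


def project_region(
    reference: SequenceRecord,
    target: SequenceRecord,
    start: int,
    end: int,
    scoring: AlignmentScoring | None = None,
) -> SequenceRecord:
    """Locate the ortholog of ``reference[start..end]`` on ``target``.

    The two full records are globally aligned and the reference interval is
    projected through the alignment columns; the returned record covers the
    target residues aligned inside that interval, with its offset in the
    target's own coordinates.
    """
    scoring = scoring or AlignmentScoring()
    alignment = _aligner(scoring).align(reference.residues, target.residues)[0]
    ref_idx, tgt_idx = alignment.indices  # per-column residue indices, -1 at gaps
    lo = start - reference.offset
    hi = end - reference.offset
    tgt_positions = [
        int(t) for r, t in zip(ref_idx, tgt_idx) if t >= 0 and r >= 0 and lo <= r <= hi
    ]
    if not tgt_positions:
        raise ValueError(
            f"no {target.id} residues align within {reference.id} {start}..{end}"
        )
    t_start = target.offset + min(tgt_positions)
    t_end = target.offset + max(tgt_positions)
    return extract_region(target, t_start, t_end)
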