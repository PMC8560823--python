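"""Epitope conservation across ortholog and paralog sequences.

Answers the cross-species specificity questions for a structurally defined
epitope: which epitope positions of the reference (human) receptor are
conserved in each ortholog, and is the antibody predicted to cross-react?
The prediction rule is deliberately strict — every epitope position must be
identical — because a single substitution at the centre of a binding
interface (e.g. a valine replaced by arginine) is enough to abolish binding.

Alignment is end-to-end global with affine gap penalties (open 10,
extend 0.5) under BLOSUM62, delegated to Biopython's PairwiseAligner.
Identity is counted over aligned columns where neither sequence has a gap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .structmodel import SequenceRecord

__all__ = [
    "AlignmentScoring",
    "PairwiseAlignment",
    "ConservationReport",
    "align_pair",
    "epitope_conservation",
    "paralog_similarity",
]


@dataclass(frozen=True)
class AlignmentScoring:
    """Substitution scheme + gap penalties for global alignment.

    With ``matrix`` set (default BLOSUM62) the match/mismatch scores are
    ignored; otherwise a simple match/mismatch scheme is used, which is the
    mode the brute-force oracle checks.
    """

    matrix: str | None = "BLOSUM62"
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = 10.0
    gap_extend: float = 0.5


@dataclass
class PairwiseAlignment:
    seq_a_id: str
    seq_b_id: str
    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float
    # reference (a) position -> other (b) position, over gap-free columns
    column_map: dict[tuple[int, str], tuple[int, str]] = field(default_factory=dict)
    # reference position -> aligned pair of letters (b letter None when gapped)
    residue_map: dict[tuple[int, str], tuple[str, str | None]] = field(default_factory=dict)


def _make_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if scoring.matrix is not None:
        aligner.substitution_matrix = substitution_matrices.load(scoring.matrix)
    else:
        aligner.match_score = scoring.match
        aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = -scoring.gap_open
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


def align_pair(a: SequenceRecord, b: SequenceRecord,
               scoring: AlignmentScoring = AlignmentScoring()) -> PairwiseAlignment:
    """Optimal global alignment of two sequences with author-numbering maps.

    Deterministic: of the co-optimal alignments Biopython enumerates, the
    first is taken (its traceback preference is fixed).
    """
    if not a.residues or not b.residues:
        raise ValueError("cannot align an empty sequence")
    aligner = _make_aligner(scoring)
    aln = aligner.align(a.residues, b.residues)[0]
    aligned_a, aligned_b = str(aln[0]), str(aln[1])

    ia = ib = 0
    matches = cols = 0
    column_map: dict = {}
    residue_map: dict = {}
    for ca, cb in zip(aligned_a, aligned_b):
        pos_a = a.numbering[ia] if ca != "-" else None
        pos_b = b.numbering[ib] if cb != "-" else None
        if ca != "-" and cb != "-":
            cols += 1
            if ca == cb:
                matches += 1
            column_map[pos_a] = pos_b
            residue_map[pos_a] = (ca, cb)
        elif ca != "-":
            residue_map[pos_a] = (ca, None)
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1

    identity = 100.0 * matches / cols if cols else 0.0
    return PairwiseAlignment(a.id, b.id, aligned_a, aligned_b,
                             float(aln.score), identity, column_map, residue_map)


@dataclass
class ConservationReport:
    epitope_positions: list[int]
    per_species: dict[str, dict]
    predicted_cross_reactive: dict[str, bool]

    def to_dict(self) -> dict:
        return {
            "epitope_positions": self.epitope_positions,
            "per_species": self.per_species,
            "predicted_cross_reactive": self.predicted_cross_reactive,
        }


def epitope_conservation(ref_epitope: list[int],
                         alignments: dict[str, PairwiseAlignment]) -> ConservationReport:
    """Per-species conservation of the reference epitope positions.

    Cross-reactivity is predicted iff *every* epitope position is conserved
    (strict-all rule).  A position outside alignment coverage is reported as
    uncovered and counts against conservation — never silently conserved.
    An empty epitope is vacuously cross-reactive, with a warning.
    """
    if not ref_epitope:
        warnings.warn("empty epitope list: prediction is vacuously true", stacklevel=2)
    per_species: dict[str, dict] = {}
    predicted: dict[str, bool] = {}
    for species, aln in alignments.items():
        conserved: list[int] = []
        substituted: list[tuple[int, str, str]] = []
        uncovered: list[int] = []
        for pos in ref_epitope:
            pair = aln.residue_map.get((pos, ""))
            if pair is None:
                uncovered.append(pos)
                continue
            ref_aa, other_aa = pair
            if other_aa is None:
                uncovered.append(pos)
            elif ref_aa == other_aa:
                conserved.append(pos)
            else:
                substituted.append((pos, ref_aa, other_aa))
        per_species[species] = {
            "conserved": conserved,
            "substituted": substituted,
            "uncovered": uncovered,
        }
        predicted[species] = len(conserved) == len(ref_epitope)
    return ConservationReport(list(ref_epitope), per_species, predicted)


def paralog_similarity(ref: SequenceRecord, paralog: SequenceRecord,
                       epitope: list[int],
                       scoring: AlignmentScoring = AlignmentScoring()) -> tuple[float, float]:
    """(overall identity %, epitope-column identity %) of a paralog.

    The epitope identity is computed over the alignment columns of the
    reference epitope positions only; columns where the paralog is gapped
    count as non-identical.
    """
    aln = align_pair(ref, paralog, scoring)
    matches = 0
    for pos in epitope:
        pair = aln.residue_map.get((pos, ""))
        if pair is not None and pair[1] is not None and pair[0] == pair[1]:
            matches += 1
    epitope_identity = 100.0 * matches / len(epitope) if epitope else 0.0
    return aln.identity_pct, epitope_identity
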