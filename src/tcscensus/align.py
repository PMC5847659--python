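"""Thin wrapper around Biopython's pairwise aligner.

Global alignment with BLOSUM62 scoring and free end gaps: the regions we
align (receiver domains, pre-delimited unassigned regions) are already
roughly domain-sized, so terminal overhangs should not be penalised.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBZX*")


@lru_cache(maxsize=None)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    # free end gaps (attribute names changed in recent Biopython)
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # pragma: no cover - older Biopython
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def _sanitize(seq: str) -> str:
    return "".join(c if c in _ALPHABET else "X" for c in seq.upper())


@dataclass
class PairwiseResult:
    """Summary of one global pairwise alignment (a = reference/first seq)."""

    score: float
    aligned_columns: int  # residue-residue columns
    identical: int
    a_to_b: dict[int, int]  # 1-based position in a -> 1-based position in b

    @property
    def identity(self) -> float:
        """Identical residues over aligned (residue-residue) columns."""
        if self.aligned_columns == 0:
            return 0.0
        return self.identical / self.aligned_columns


def align_pair(a: str, b: str) -> PairwiseResult:
    """Globally align two sequences and summarise the residue mapping."""
    a_s, b_s = _sanitize(a), _sanitize(b)
    if not a_s or not b_s:
        return PairwiseResult(score=0.0, aligned_columns=0, identical=0, a_to_b={})
    aln = _aligner().align(a_s, b_s)[0]
    mapping: dict[int, int] = {}
    identical = 0
    blocks_a, blocks_b = aln.aligned
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        for off in range(a1 - a0):
            ia, ib = a0 + off, b0 + off
            mapping[ia + 1] = ib + 1
            if a_s[ia] == b_s[ib]:
                identical += 1
    return PairwiseResult(
        score=float(aln.score),
        aligned_columns=len(mapping),
        identical=identical,
        a_to_b=mapping,
    )


def identity_and_coverage(a: str, b: str) -> tuple[float, float]:
    """Percent-identity over aligned columns and coverage of the shorter seq."""
    res = align_pair(a, b)
    shorter = min(len(a), len(b))
    if shorter == 0:
        return 0.0, 0.0
    return res.identity, res.aligned_columns / shorter
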