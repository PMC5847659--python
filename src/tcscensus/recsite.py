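"""Receiver-domain active-site analysis and sequence-logo matrices.

Each REC domain is aligned to a packaged CheY-like reference and the
residues found at the five canonical active-site positions are reported in
reference numbering: the Mg2+-coordinating acidic pair (12, 13), the
phosphoacceptor Asp (57), the conserved Thr/Ser (87) and the conserved Lys
(109).  Numbering includes the initiator Met of the reference, whose FASTA
header states this explicitly.

A receiver domain is predicted phosphorylatable when the phosphoacceptor
position carries Asp and at least three of the four auxiliary positions
carry their canonical residues (D/E at 12, D at 13, T/S at 87, K at 109).
That verdict rule is a package convention, configurable via
:class:`PhosphorylationRule`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .align import align_pair
from .model import RecSiteReport

log = logging.getLogger(__name__)

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
MAX_INFORMATION = math.log2(20)

#: Canonical active-site positions in reference numbering.
ACTIVE_SITE_POSITIONS = (12, 13, 57, 87, 109)

#: Alignments with identity below this floor carry no credible receiver
#: similarity; the report then has coverage 0 and a negative verdict.
IDENTITY_FLOOR = 0.20


def reference_rec_sequence() -> str:
    """The packaged CheY-like reference receiver-domain sequence."""
    ref = resources.files("tcscensus.data") / "chey_reference.fasta"
    with resources.as_file(ref) as path:
        record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq)


@dataclass(frozen=True)
class PhosphorylationRule:
    """Configurable verdict rule for predicted phosphorylatability."""

    acceptor_position: int = 57
    acceptor_allowed: frozenset[str] = frozenset({"D"})
    auxiliary: dict = None  # type: ignore[assignment]
    min_auxiliary: int = 3

    def __post_init__(self):
        if self.auxiliary is None:
            object.__setattr__(
                self,
                "auxiliary",
                {12: {"D", "E"}, 13: {"D"}, 87: {"T", "S"}, 109: {"K"}},
            )

    def verdict(self, residues: dict[int, str]) -> bool:
        if residues.get(self.acceptor_position) not in self.acceptor_allowed:
            return False
        ok = sum(
            1
            for pos, allowed in self.auxiliary.items()
            if residues.get(pos) in allowed
        )
        return ok >= self.min_auxiliary


DEFAULT_RULE = PhosphorylationRule()


def map_rec_positions(
    rec_sequence: str,
    reference: Optional[str] = None,
    protein_id: str = "",
    rec_index: int = 1,
    positions: Sequence[int] = ACTIVE_SITE_POSITIONS,
    rule: PhosphorylationRule = DEFAULT_RULE,
    identity_floor: float = IDENTITY_FLOOR,
) -> RecSiteReport:
    """Align a receiver domain to the reference and read off the active site.

    ``reference_coverage`` is the fraction of reference positions aligned
    to a residue of the query.  When alignment identity falls below
    ``identity_floor`` the domain is treated as non-alignable: coverage 0,
    all positions gapped, verdict negative.
    """
    if not rec_sequence:
        raise ValueError("empty receiver-domain sequence")
    ref = reference if reference is not None else reference_rec_sequence()
    res = align_pair(ref, rec_sequence)
    # floor on identical residues per reference position: a handful of
    # coincidental matches in an otherwise unalignable sequence must not
    # count as receiver similarity
    if res.identical / len(ref) < identity_floor:
        return RecSiteReport(
            protein_id=protein_id,
            rec_index=rec_index,
            residues={p: "-" for p in positions},
            reference_coverage=0.0,
            identity=res.identity,
            phosphorylatable=False,
        )
    residues = {}
    for pos in positions:
        q = res.a_to_b.get(pos)
        residues[pos] = rec_sequence[q - 1] if q is not None else "-"
    coverage = res.aligned_columns / len(ref)
    return RecSiteReport(
        protein_id=protein_id,
        rec_index=rec_index,
        residues=residues,
        reference_coverage=coverage,
        identity=res.identity,
        phosphorylatable=rule.verdict(residues),
    )


@dataclass
class LogoMatrix:
    """Per-column residue frequencies and information content (bits).

    Frequencies are over the 20 standard amino acids with gaps excluded
    from the denominator; information is R = log2(20) - H per column, with
    no small-sample correction.
    """

    frequencies: pd.DataFrame  # columns = AMINO_ACIDS, one row per position
    information: pd.Series  # bits, one value per position
    warnings: list[str] = field(default_factory=list)


def logo_matrix(
    alignment: Sequence[str], anchor: Optional[str] = None
) -> LogoMatrix:
    """Build a logo matrix from equal-length gapped sequences.

    With an ``anchor`` row, columns where the anchor has a gap are dropped
    first (query-anchored trimming), so positions are numbered in anchor
    coordinates.  A column containing only gaps gets information 0 with a
    warning.
    """
    if not alignment:
        raise ValueError("empty alignment")
    width = len(alignment[0])
    if any(len(s) != width for s in alignment):
        raise ValueError("alignment rows differ in length")
    if anchor is not None and len(anchor) != width:
        raise ValueError("anchor length differs from alignment width")

    keep = (
        [i for i in range(width) if anchor[i] not in "-."]
        if anchor is not None
        else list(range(width))
    )
    aa_index = {a: k for k, a in enumerate(AMINO_ACIDS)}
    freqs = np.zeros((len(keep), 20))
    info = np.zeros(len(keep))
    warnings: list[str] = []
    for out_pos, col_idx in enumerate(keep):
        counts = np.zeros(20)
        for row in alignment:
            k = aa_index.get(row[col_idx].upper())
            if k is not None:
                counts[k] += 1
        total = counts.sum()
        if total == 0:
            warnings.append(f"column {out_pos + 1} contains only gaps")
            continue
        p = counts / total
        freqs[out_pos] = p
        nz = p[p > 0]
        entropy = float(-(nz * np.log2(nz)).sum())
        info[out_pos] = MAX_INFORMATION - entropy
    if warnings:
        for w in warnings:
            log.warning(w)
    positions = pd.RangeIndex(1, len(keep) + 1, name="position")
    return LogoMatrix(
        frequencies=pd.DataFrame(freqs, index=positions, columns=list(AMINO_ACIDS)),
        information=pd.Series(info, index=positions, name="information_bits"),
        warnings=warnings,
    )


def report_to_row(report: RecSiteReport) -> dict:
    row = {
        "protein_id": report.protein_id,
        "rec_index": report.rec_index,
        "reference_coverage": round(report.reference_coverage, 4),
        "identity": round(report.identity, 4),
        "phosphorylatable": report.phosphorylatable,
    }
    for pos, res in report.residues.items():
        row[f"pos{pos}"] = res
    return row
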