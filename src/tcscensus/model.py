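"""Core data model shared by every pipeline stage.

All coordinates in this package are 1-based and inclusive, both on the
amino-acid scale (domain hits, segments, transmembrane helices) and on the
nucleotide scale (gene features).  Readers that consume 0-based formats
convert on input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence


class ModelError(ValueError):
    """Raised when a record violates a data-model invariant."""


@dataclass(frozen=True)
class DomainHit:
    """One scored hit of a named domain model on a protein.

    ``start``/``end`` are envelope coordinates (1-based, inclusive): they
    bound the full region attributable to the domain, which is what later
    stages mask when hunting for unassigned regions.
    """

    protein_id: str
    domain_name: str
    domain_accession: str
    start: int
    end: int
    score: float
    evalue: float

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ModelError(
                f"invalid hit coordinates {self.start}..{self.end} on "
                f"{self.protein_id!r} ({self.domain_name})"
            )
        if self.evalue < 0:
            raise ModelError(f"negative e-value on {self.protein_id!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ProteinRecord:
    """A protein with optional sequence and transmembrane annotation."""

    protein_id: str
    genome_id: str
    length: int
    sequence: Optional[str] = None
    tm_segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ModelError(
                f"sequence length {len(self.sequence)} != declared length "
                f"{self.length} for {self.protein_id!r}"
            )
        self.tm_segments = sorted(self.tm_segments)
        prev_end = 0
        for s, e in self.tm_segments:
            if s <= prev_end or e < s:
                raise ModelError(
                    f"overlapping or inverted TM segments on {self.protein_id!r}"
                )
            prev_end = e


@dataclass(frozen=True)
class GeneFeature:
    """A protein-coding gene located on a contig (nucleotide coordinates)."""

    genome_id: str
    contig: str
    protein_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ModelError(f"gene {self.protein_id!r}: start > end")
        if self.strand not in ("+", "-"):
            raise ModelError(f"gene {self.protein_id!r}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class Segment:
    """A resolved, accepted domain occurrence inside an architecture."""

    domain_name: str
    role: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Architecture:
    """A protein's linear domain architecture.

    ``segments`` are sorted by start and pairwise non-overlapping (up to the
    bounded overlap the resolver tolerates); ``gaps`` is the exact complement
    of the segment envelope within ``[1, length]``.
    """

    protein_id: str
    length: int
    segments: list[Segment]
    gaps: list[tuple[int, int]]

    def names(self) -> list[str]:
        return [s.domain_name for s in self.segments]

    def roles(self) -> list[str]:
        return [s.role for s in self.segments]


# Classification vocabulary ------------------------------------------------

CATEGORIES = (
    "HK",
    "hybrid_HK",
    "HisKA_no_HATPase",
    "RR",
    "not_TCS",
)

RR_SUBCLASSES = (
    "REC_only",
    "CheB",
    "transcriptional_HTH",
    "REC_HalX",
    "REC_PAS_GAF",
    "REC_HisK",
    "REC_enzymatic",
    "REC_novel_OD",
    "other",
    "n/a",
)

FLAGS = (
    "chemotaxis_associated",
    "membrane_bound",
    "cheA_like",
    "excluded_divergent",
)


@dataclass
class TCSCall:
    """The classification verdict for one protein.

    ``category`` stays stable once assigned; proteins whose receiver domain
    turns out to be divergent/truncated keep their call but acquire the
    ``excluded_divergent`` flag and are dropped from census totals.
    """

    protein_id: str
    category: str
    rr_subclass: str = "n/a"
    flags: set[str] = field(default_factory=set)
    architecture_string: str = ""
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ModelError(f"unknown category {self.category!r}")
        if self.rr_subclass not in RR_SUBCLASSES:
            raise ModelError(f"unknown RR subclass {self.rr_subclass!r}")
        if (self.category == "RR") != (self.rr_subclass != "n/a"):
            raise ModelError(
                f"{self.protein_id!r}: subclass {self.rr_subclass!r} inconsistent "
                f"with category {self.category!r}"
            )
        unknown = self.flags - set(FLAGS)
        if unknown:
            raise ModelError(f"unknown flags {sorted(unknown)}")

    @property
    def excluded(self) -> bool:
        return "excluded_divergent" in self.flags

    @property
    def is_hk(self) -> bool:
        """Counted as a histidine kinase in census totals (hybrids included)."""
        return self.category in ("HK", "hybrid_HK")

    @property
    def is_rr(self) -> bool:
        return self.category == "RR"


@dataclass(frozen=True)
class UnassignedRegion:
    """A maximal unassigned stretch long enough to harbour a novel domain."""

    protein_id: str
    start: int
    end: int
    left_flank: str  # adjacent segment name or "N-terminus"
    right_flank: str  # adjacent segment name or "C-terminus"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class NovelDomainFamily:
    """A single-linkage cluster of unassigned regions: a candidate domain."""

    family_id: str
    members: list[UnassignedRegion]
    median_length: float
    representative: UnassignedRegion
    contexts: list[str] = field(default_factory=list)


@dataclass
class RecSiteReport:
    """Residues found at the five canonical receiver-domain positions.

    Positions are expressed in the numbering of the packaged CheY-like
    reference (initiator Met included, so the phosphoacceptor Asp is 57).
    Residues are taken from the query protein, never from the reference;
    ``-`` marks a reference position the query did not align to.
    """

    protein_id: str
    rec_index: int
    residues: dict[int, str]
    reference_coverage: float
    identity: float
    phosphorylatable: bool


@dataclass
class NeighborhoodCall:
    """A relation between two adjacent genes on one contig."""

    genome_id: str
    contig: str
    protein_a: str
    protein_b: str
    relation: str  # same_operon_adjacent | divergent
    intergenic_distance: int
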