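"""Delineation of candidate novel output domains.

Assigned segments are masked, maximal unassigned regions of at least 70
amino acids are harvested, and regions are clustered into candidate
families by single linkage over pairwise global-alignment identity
(>= 30% identity over >= 70% of the shorter region by default).  Proteins
with no assigned domains at all contribute their whole chain, which is how
stand-alone copies of a novel domain are swept up.
"""

from __future__ import annotations

import logging
import statistics
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .align import align_pair
from .model import Architecture, NovelDomainFamily, ProteinRecord, UnassignedRegion

log = logging.getLogger(__name__)

DEFAULT_MIN_LENGTH = 70
DEFAULT_IDENTITY = 0.30
DEFAULT_COVERAGE = 0.70


def extract_unassigned(
    arch: Architecture, min_len: int = DEFAULT_MIN_LENGTH
) -> list[UnassignedRegion]:
    """All maximal unassigned regions of at least ``min_len`` residues,
    annotated with the names of the flanking segments (or the terminus)."""
    regions: list[UnassignedRegion] = []
    for gap_start, gap_end in arch.gaps:
        if gap_end - gap_start + 1 < min_len:
            continue
        left = "N-terminus"
        right = "C-terminus"
        for seg in arch.segments:
            if seg.end < gap_start:
                left = seg.domain_name
            if seg.start > gap_end:
                right = seg.domain_name
                break
        regions.append(
            UnassignedRegion(
                protein_id=arch.protein_id,
                start=gap_start,
                end=gap_end,
                left_flank=left,
                right_flank=right,
            )
        )
    return regions


def region_sequence(region: UnassignedRegion, protein: ProteinRecord) -> str:
    if protein.sequence is None:
        raise ValueError(f"protein {protein.protein_id!r} has no sequence")
    return protein.sequence[region.start - 1 : region.end]


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_regions(
    regions: Sequence[UnassignedRegion],
    proteins: Mapping[str, ProteinRecord],
    identity_threshold: float = DEFAULT_IDENTITY,
    coverage_threshold: float = DEFAULT_COVERAGE,
) -> list[NovelDomainFamily]:
    """Single-linkage clustering of unassigned regions into families.

    Two regions are linked when their global alignment covers at least
    ``coverage_threshold`` of the shorter region and the identical
    residues amount to at least ``identity_threshold`` of the shorter
    region.  Normalising identity by the shorter region (not by aligned
    columns) keeps gap-rich alignments of unrelated, compositionally
    biased sequences below threshold.  Families are the connected
    components; singletons are reported as one-member families.  Regions
    whose protein sequence is unavailable are skipped with a warning.
    """
    usable: list[UnassignedRegion] = []
    seqs: list[str] = []
    for r in regions:
        prot = proteins.get(r.protein_id)
        if prot is None or prot.sequence is None:
            log.warning("region %s:%d-%d has no sequence; skipped",
                        r.protein_id, r.start, r.end)
            continue
        usable.append(r)
        seqs.append(region_sequence(r, prot))

    n = len(usable)
    uf = _UnionFind(n)
    identity_matrix = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            res = align_pair(seqs[i], seqs[j])
            shorter = min(len(seqs[i]), len(seqs[j]))
            coverage = res.aligned_columns / shorter if shorter else 0.0
            identity = res.identical / shorter if shorter else 0.0
            identity_matrix[i][j] = identity_matrix[j][i] = identity
            if identity >= identity_threshold and coverage >= coverage_threshold:
                uf.union(i, j)

    groups: dict[int, list[int]] = {}
    # deterministic order: by protein id then coordinates
    order = sorted(range(n), key=lambda k: (usable[k].protein_id, usable[k].start))
    for idx in order:
        groups.setdefault(uf.find(idx), []).append(idx)

    families: list[NovelDomainFamily] = []
    for fam_no, (_, members_idx) in enumerate(
        sorted(groups.items(), key=lambda kv: (-len(kv[1]), usable[kv[1][0]].protein_id)),
        start=1,
    ):
        members = [usable[i] for i in members_idx]
        # medoid: member with maximal summed identity to the others
        best = max(
            members_idx,
            key=lambda i: (sum(identity_matrix[i][j] for j in members_idx), -usable[i].start),
        )
        families.append(
            NovelDomainFamily(
                family_id=f"NOD{fam_no:03d}",
                members=members,
                median_length=float(statistics.median(m.length for m in members)),
                representative=usable[best],
            )
        )
    return families


def family_contexts(
    family: NovelDomainFamily, architectures: Mapping[str, Architecture]
) -> list[str]:
    """Architecture strings with the family symbol spliced into its gap."""
    contexts = []
    for member in family.members:
        arch = architectures.get(member.protein_id)
        if arch is None:
            contexts.append(family.family_id)
            continue
        events = [(s.start, s.domain_name) for s in arch.segments]
        events.append((member.start, family.family_id))
        contexts.append("-".join(name for _, name in sorted(events)))
    return contexts


def family_report(
    families: Sequence[NovelDomainFamily],
    architectures: Optional[Mapping[str, Architecture]] = None,
    proteins: Optional[Mapping[str, ProteinRecord]] = None,
    taxonomy: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Per-family summary: size, median length, contexts, distribution."""
    rows = []
    for fam in families:
        contexts = (
            family_contexts(fam, architectures) if architectures is not None else []
        )
        fam.contexts = sorted(set(contexts))
        genomes = sorted(
            {
                proteins[m.protein_id].genome_id
                for m in fam.members
                if proteins is not None and m.protein_id in proteins
            }
        )
        taxa = sorted({taxonomy.get(g, "unclassified") for g in genomes}) if taxonomy else []
        rows.append(
            {
                "family_id": fam.family_id,
                "n_members": len(fam.members),
                "median_length": fam.median_length,
                "representative": f"{fam.representative.protein_id}:"
                f"{fam.representative.start}-{fam.representative.end}",
                "contexts": ";".join(fam.contexts),
                "genomes": ";".join(genomes),
                "taxa": ";".join(taxa),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "family_id", "n_members", "median_length", "representative",
            "contexts", "genomes", "taxa",
        ],
    )


def harvest_regions(
    architectures: Mapping[str, Architecture],
    min_len: int = DEFAULT_MIN_LENGTH,
    rec_containing_only: bool = True,
    include_standalone: bool = True,
) -> list[UnassignedRegion]:
    """Collect candidate regions across a dataset.

    By default only receiver-domain-containing proteins are screened (the
    regulator-focused convention), plus proteins with no assigned domains
    at all, whose whole chain is a candidate stand-alone domain.
    """
    regions: list[UnassignedRegion] = []
    for arch in architectures.values():
        has_rec = any(s.role == "receiver" for s in arch.segments)
        standalone = not arch.segments
        if rec_containing_only and not (has_rec or (standalone and include_standalone)):
            continue
        regions.extend(extract_unassigned(arch, min_len=min_len))
    return regions
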