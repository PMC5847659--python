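"""Histidine-kinase / response-regulator classification.

The counting conventions follow the census practice for archaeal
two-component systems:

* a protein combining receiver (REC) and kinase modules is a response
  regulator when the REC domain precedes the kinase core (REC-HisK type)
  and a hybrid histidine kinase when the REC domain follows it;
* proteins with a dimerization (HisKA-like) domain but no ATPase domain are
  kinase-dead HK-like proteins and are tallied separately;
* an ATPase domain accompanied by Hpt and/or CheW but no HisKA marks a
  CheA-type chemotaxis kinase;
* response-regulator subclasses are assigned by output-domain priority
  (CheB > DNA-binding HTH > HalX > enzymatic > novel output domain >
  PAS/GAF-only > stand-alone REC > other), so the subclasses are disjoint.

A REC domain flanked by nothing but unassigned sequence of 70 aa or more is
treated as carrying a putative novel output domain: that unassigned-region
threshold is the same one the novel-domain finder uses.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional

from .model import Architecture, RecSiteReport, Segment, TCSCall
from .roles import DomainRoleDictionary, UNKNOWN_ROLE, is_novel_output_name

log = logging.getLogger(__name__)

#: Minimum unassigned-region length that counts as a putative novel output
#: domain when deciding between REC_only and REC_novel_OD.
NOVEL_GAP_MIN = 70

#: REC segments shorter than this are considered truncated.
MIN_REC_LENGTH = 80

#: REC segments aligning to less than this fraction of the reference
#: receiver domain are considered highly divergent.
MIN_REC_COVERAGE = 0.60

_HK_ROLES = {"phosphotransfer_dimerization", "phosphotransfer_atpase"}


def classify(
    arch: Architecture,
    roles: Optional[DomainRoleDictionary] = None,
    architecture_str: Optional[str] = None,
) -> TCSCall:
    """Assign exactly one category (and RR subclass) to an architecture."""
    if roles is None:
        roles = DomainRoleDictionary.default()
    from .architecture import architecture_string  # cycle-free local import

    arch_str = (
        architecture_str
        if architecture_str is not None
        else architecture_string(arch, collapse_repeats=True)
    )

    segs = arch.segments
    rec = [s for s in segs if s.role == "receiver"]
    hiska = [s for s in segs if s.role == "phosphotransfer_dimerization"]
    hatpase = [s for s in segs if s.role == "phosphotransfer_atpase"]
    hpt = [s for s in segs if s.role == "hpt"]
    chew = [s for s in segs if s.role == "chew"]

    def call(category: str, subclass: str = "n/a", flags: set[str] | None = None,
             warnings: list[str] | None = None) -> TCSCall:
        return TCSCall(
            protein_id=arch.protein_id,
            category=category,
            rr_subclass=subclass,
            flags=flags or set(),
            architecture_string=arch_str,
            warnings=warnings or [],
        )

    # (1) no TCS modules at all
    if not rec and not hiska and not hatpase:
        return call("not_TCS")

    # (2) kinase modules without a receiver domain
    if not rec:
        if hiska and hatpase:
            return call("HK")
        if hiska:
            return call("HisKA_no_HATPase")
        # HATPase without HisKA: CheA-type when Hpt/CheW support it
        flags = {"cheA_like"} if (hpt or chew) else set()
        return call("HK", flags=flags)

    # (3) receiver + kinase modules: position of REC decides
    if hiska or hatpase:
        hk_first = min(s.start for s in segs if s.role in _HK_ROLES)
        hk_last_end = max(s.end for s in segs if s.role in _HK_ROLES)
        n_term = any(s.start < hk_first for s in rec)
        c_term = any(s.start > hk_last_end for s in rec)
        warnings = []
        if n_term and c_term:
            warnings.append(
                f"{arch.protein_id}: REC domains both precede and follow the "
                "kinase core; counted as a response regulator (REC-HisK)"
            )
            log.warning(warnings[-1])
        if n_term:
            return call("RR", "REC_HisK", warnings=warnings)
        if c_term:
            return call("hybrid_HK")
        warnings.append(
            f"{arch.protein_id}: REC domain embedded inside the kinase core; "
            "counted as a hybrid HK"
        )
        log.warning(warnings[-1])
        return call("hybrid_HK", warnings=warnings)

    # (4) receiver domain(s) without kinase modules: subclass by output
    return call("RR", _rr_subclass(arch, rec, roles))


def _rr_subclass(
    arch: Architecture, rec: list[Segment], roles: DomainRoleDictionary
) -> str:
    non_rec = [s for s in arch.segments if s.role != "receiver"]
    if any(roles.is_cheb(s.domain_name) for s in non_rec):
        return "CheB"
    if any(s.role == "output_dna_binding" for s in non_rec):
        return "transcriptional_HTH"
    if any(roles.is_halx(s.domain_name) for s in non_rec):
        return "REC_HalX"
    if any(s.role == "output_enzymatic" for s in non_rec):
        return "REC_enzymatic"
    if any(
        s.role == UNKNOWN_ROLE or is_novel_output_name(s.domain_name)
        for s in non_rec
    ):
        return "REC_novel_OD"
    long_gap = any(e - s + 1 >= NOVEL_GAP_MIN for s, e in arch.gaps)
    if not non_rec:
        # A REC plus a long unassigned stretch is a candidate novel-OD
        # regulator, exactly what the unassigned-region screen harvests.
        return "REC_novel_OD" if long_gap else "REC_only"
    if all(s.role == "sensor" for s in non_rec):
        return "REC_PAS_GAF"
    return "other"


def mark_divergent_rec(
    call: TCSCall,
    arch: Architecture,
    rec_reports: Iterable[RecSiteReport] = (),
    min_rec_length: int = MIN_REC_LENGTH,
    min_coverage: float = MIN_REC_COVERAGE,
) -> TCSCall:
    """Flag calls whose receiver domains are truncated or highly divergent.

    A REC segment shorter than ``min_rec_length`` residues, or aligning to
    less than ``min_coverage`` of the reference receiver domain, marks the
    protein ``excluded_divergent``: it keeps its call but is omitted from
    census totals.
    """
    rec_segments = [s for s in arch.segments if s.role == "receiver"]
    divergent = any(s.length < min_rec_length for s in rec_segments)
    for report in rec_reports:
        if report.reference_coverage < min_coverage:
            divergent = True
    if not divergent:
        return call
    return TCSCall(
        protein_id=call.protein_id,
        category=call.category,
        rr_subclass=call.rr_subclass,
        flags=set(call.flags) | {"excluded_divergent"},
        architecture_string=call.architecture_string,
        warnings=list(call.warnings),
    )


def classify_all(
    architectures: Mapping[str, Architecture],
    roles: Optional[DomainRoleDictionary] = None,
) -> dict[str, TCSCall]:
    if roles is None:
        roles = DomainRoleDictionary.default()
    return {pid: classify(arch, roles) for pid, arch in architectures.items()}
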