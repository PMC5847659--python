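"""Resolve raw domain hits into a linear, non-redundant architecture.

Hit tables from profile searches routinely contain overlapping evidence for
the same region (clan relatives, tandem models, duplicate rows).  The
resolver applies a greedy, e-value-ordered acceptance rule with a bounded
overlap tolerance and renders canonical dash-joined architecture strings
such as ``REC-(PAS)2-HisKA-HATPase``.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

from .model import Architecture, DomainHit, ProteinRecord, Segment
from .roles import DomainRoleDictionary

log = logging.getLogger(__name__)

#: A hit may overlap every previously accepted hit by at most this fraction
#: of the shorter of the two.
DEFAULT_OVERLAP_TOLERANCE = 0.30

#: Unassigned stretches at least this long are rendered as "X" placeholders
#: when gaps are requested in the architecture string.
GAP_PLACEHOLDER_MIN = 70


def overlap_length(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def priority_key(hit: DomainHit) -> tuple[float, float, int]:
    """Greedy acceptance order: best e-value, then score, then position."""
    return (hit.evalue, -hit.score, hit.start)


def resolve_hits(
    hits: Sequence[DomainHit],
    protein: ProteinRecord,
    roles: Optional[DomainRoleDictionary] = None,
    overlap_tolerance: float = DEFAULT_OVERLAP_TOLERANCE,
) -> Architecture:
    """Select a consistent subset of hits and lay it out along the protein.

    Hits are visited by ascending e-value (ties: descending score, then
    ascending start) and accepted iff they overlap every previously
    accepted hit by at most ``overlap_tolerance`` of the shorter of the
    two.  Accepted hits are kept verbatim (no trimming); hits running past
    the protein end are discarded with a warning.
    """
    if roles is None:
        roles = DomainRoleDictionary.default()
    mismatched = [h for h in hits if h.protein_id != protein.protein_id]
    if mismatched:
        raise ValueError(
            f"hits for {mismatched[0].protein_id!r} passed with protein "
            f"{protein.protein_id!r}"
        )
    usable = []
    for h in hits:
        if h.end > protein.length:
            log.warning(
                "hit %s %d..%d runs past end of %s (len %d); discarded",
                h.domain_name, h.start, h.end, protein.protein_id, protein.length,
            )
            continue
        usable.append(h)

    accepted: list[DomainHit] = []
    for hit in sorted(usable, key=priority_key):
        span = (hit.start, hit.end)
        ok = all(
            overlap_length(span, (a.start, a.end))
            <= overlap_tolerance * min(hit.length, a.length)
            for a in accepted
        )
        if ok:
            accepted.append(hit)

    accepted.sort(key=lambda h: (h.start, h.end))
    segments = [
        Segment(
            domain_name=h.domain_name,
            role=roles.role(h.domain_name, h.domain_accession),
            start=h.start,
            end=h.end,
        )
        for h in accepted
    ]
    return Architecture(
        protein_id=protein.protein_id,
        length=protein.length,
        segments=segments,
        gaps=_complement(segments, protein.length),
    )


def _complement(segments: Sequence[Segment], length: int) -> list[tuple[int, int]]:
    """Maximal unassigned intervals within [1, length]."""
    gaps: list[tuple[int, int]] = []
    cursor = 1
    for seg in segments:
        if seg.start > cursor:
            gaps.append((cursor, seg.start - 1))
        cursor = max(cursor, seg.end + 1)
    if cursor <= length:
        gaps.append((cursor, length))
    return gaps


def architecture_string(
    arch: Architecture,
    collapse_repeats: bool = False,
    show_gaps: bool = False,
    gap_min: int = GAP_PLACEHOLDER_MIN,
) -> str:
    """Render the canonical dash-joined architecture string.

    With ``collapse_repeats``, k >= 2 consecutive identical names become
    ``(NAME)k``.  With ``show_gaps``, unassigned stretches of at least
    ``gap_min`` residues appear as ``X`` placeholders in sequence order.
    """
    tokens: list[str] = []
    if show_gaps:
        events: list[tuple[int, str]] = [(s.start, s.domain_name) for s in arch.segments]
        events += [(g[0], "X") for g in arch.gaps if g[1] - g[0] + 1 >= gap_min]
        tokens = [name for _, name in sorted(events)]
    else:
        tokens = arch.names()
    if collapse_repeats:
        tokens = _collapse(tokens)
    return "-".join(tokens)


def _collapse(tokens: Sequence[str]) -> list[str]:
    out: list[str] = []
    i = 0
    while i < len(tokens):
        j = i
        while j < len(tokens) and tokens[j] == tokens[i]:
            j += 1
        k = j - i
        out.append(tokens[i] if k == 1 else f"({tokens[i]}){k}")
        i = j
    return out


def total_gap_aa(arch: Architecture) -> int:
    return sum(e - s + 1 for s, e in arch.gaps)


def resolve_all(
    hits: Iterable[DomainHit],
    proteins: Iterable[ProteinRecord],
    roles: Optional[DomainRoleDictionary] = None,
    overlap_tolerance: float = DEFAULT_OVERLAP_TOLERANCE,
) -> dict[str, Architecture]:
    """Resolve every protein's hits; proteins without hits get an all-gap
    architecture (eligible as stand-alone novel-domain candidates)."""
    by_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    out: dict[str, Architecture] = {}
    for p in proteins:
        out[p.protein_id] = resolve_hits(
            by_protein.get(p.protein_id, []), p, roles=roles,
            overlap_tolerance=overlap_tolerance,
        )
    return out
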