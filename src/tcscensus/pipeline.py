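"""Convenience orchestration of the pipeline stages.

Thin glue used by the command-line interface, the test suite and the
acceptance script; all scientific logic lives in the stage modules.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .architecture import architecture_string, resolve_all, total_gap_aa
from .classify import classify, mark_divergent_rec
from .model import Architecture, DomainHit, ProteinRecord, TCSCall
from .recsite import map_rec_positions, report_to_row
from .roles import DomainRoleDictionary


def classify_proteins(
    hits: Iterable[DomainHit],
    proteins: Sequence[ProteinRecord],
    roles: Optional[DomainRoleDictionary] = None,
    flag_divergent: bool = True,
) -> tuple[dict[str, Architecture], dict[str, TCSCall]]:
    """Resolve architectures and classify every protein.

    With ``flag_divergent``, truncated receiver domains (length rule) are
    flagged ``excluded_divergent`` immediately; alignment-based divergence
    flagging additionally needs sequences (see :func:`rec_site_table`).
    """
    if roles is None:
        roles = DomainRoleDictionary.default()
    architectures = resolve_all(hits, proteins, roles=roles)
    calls: dict[str, TCSCall] = {}
    for pid, arch in architectures.items():
        call = classify(arch, roles)
        if flag_divergent:
            call = mark_divergent_rec(call, arch)
        calls[pid] = call
    return architectures, calls


def architectures_table(architectures: Mapping[str, Architecture]) -> pd.DataFrame:
    rows = [
        {
            "protein_id": pid,
            "architecture_string": architecture_string(arch, collapse_repeats=True),
            "n_segments": len(arch.segments),
            "total_gap_aa": total_gap_aa(arch),
        }
        for pid, arch in sorted(architectures.items())
    ]
    return pd.DataFrame(
        rows, columns=["protein_id", "architecture_string", "n_segments", "total_gap_aa"]
    )


def rec_site_table(
    architectures: Mapping[str, Architecture],
    proteins: Mapping[str, ProteinRecord],
    reference: Optional[str] = None,
) -> pd.DataFrame:
    """Active-site report for every receiver domain with a sequence."""
    rows = []
    for pid in sorted(architectures):
        prot = proteins.get(pid)
        if prot is None or prot.sequence is None:
            continue
        rec_segments = [
            s for s in architectures[pid].segments if s.role == "receiver"
        ]
        for i, seg in enumerate(rec_segments, start=1):
            sub = prot.sequence[seg.start - 1 : seg.end]
            report = map_rec_positions(
                sub, reference=reference, protein_id=pid, rec_index=i
            )
            rows.append(report_to_row(report))
    return pd.DataFrame(rows)
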