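"""The domain-role dictionary.

Maps domain model names/accessions onto the functional roles used by the
classifier (receiver, dimerization, ATPase, sensor, output families, ...).
The packaged default covers the vocabulary commonly seen in archaeal
two-component proteins, including the provisional lineage-specific output
domains (HalOD/MetOD/NitrOD/TackOD/AcidOD families).
"""

from __future__ import annotations

import re
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

ROLES = (
    "phosphotransfer_dimerization",
    "phosphotransfer_atpase",
    "hpt",
    "chew",
    "receiver",
    "sensor",
    "output_dna_binding",
    "output_enzymatic",
    "output_other",
)

UNKNOWN_ROLE = "unknown"

# Provisional lineage-specific output-domain families, named after the taxon
# of origin plus "OD" (output domain).
_NOVEL_OD_RE = re.compile(r"^(hal|met|nitr|tack|acid)od\d*$", re.IGNORECASE)

_CHEB_NAMES = frozenset({"cheb", "cheb_methylest"})
_CHEB_ACCESSIONS = frozenset({"PF01339"})
_HALX_NAMES = frozenset({"halx"})


def is_novel_output_name(name: str) -> bool:
    """True for provisional taxon-OD family names (HalOD1, MetOD3, ...)."""
    return bool(_NOVEL_OD_RE.match(name.strip()))


class DomainRoleDictionary:
    """Case-insensitive name -> role lookup with exact accession overrides.

    Unknown domains map to :data:`UNKNOWN_ROLE` rather than raising: the
    pipeline treats unrecognised segments as candidate novel domains, not
    as errors.
    """

    def __init__(self, mapping: dict[str, list[dict]]):
        self._by_name: dict[str, str] = {}
        self._by_accession: dict[str, str] = {}
        for role, entries in mapping.items():
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r} in dictionary")
            for entry in entries or []:
                name = str(entry["name"]).strip()
                key = name.lower()
                if key in self._by_name and self._by_name[key] != role:
                    raise ValueError(f"domain {name!r} mapped to two roles")
                self._by_name[key] = role
                acc = str(entry.get("accession", "") or "").strip()
                if acc:
                    self._by_accession[acc] = role

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DomainRoleDictionary":
        with open(path) as fh:
            mapping = yaml.safe_load(fh) or {}
        return cls(mapping)

    @classmethod
    def default(cls) -> "DomainRoleDictionary":
        ref = resources.files("tcscensus.data") / "domain_roles.yaml"
        mapping = yaml.safe_load(ref.read_text())
        return cls(mapping)

    def role(self, name: str, accession: str = "") -> str:
        acc = _strip_version(accession)
        if acc and acc in self._by_accession:
            return self._by_accession[acc]
        got = self._by_name.get(name.strip().lower())
        if got is not None:
            return got
        # Unlisted taxon-OD names still classify as novel output domains.
        if is_novel_output_name(name):
            return "output_other"
        return UNKNOWN_ROLE

    def is_cheb(self, name: str, accession: str = "") -> bool:
        return (
            name.strip().lower() in _CHEB_NAMES
            or _strip_version(accession) in _CHEB_ACCESSIONS
        )

    def is_halx(self, name: str) -> bool:
        return name.strip().lower() in _HALX_NAMES

    def known_names(self) -> list[str]:
        return sorted(self._by_name)


def _strip_version(accession: Optional[str]) -> str:
    """PF00072.24 -> PF00072 (Pfam accessions often carry a version)."""
    if not accession:
        return ""
    return accession.split(".", 1)[0].strip()
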