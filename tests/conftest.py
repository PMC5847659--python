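import pytest

from tcscensus.model import DomainHit, ProteinRecord
from tcscensus.roles import DomainRoleDictionary

#: plausible domain lengths used when synthesising architectures by name
_LENGTHS = {
    "REC": 120, "PAS": 100, "GAF": 95, "HisKA": 65, "HATPase": 110,
    "HATPase_c": 110, "Hpt": 95, "CheW": 140, "CheB": 190, "HalX": 120,
    "BAT": 130, "HTH_10": 50, "HTH": 60, "wHTH": 60, "MEDS": 95,
    "DUF835": 120, "iKaiC": 230, "BcsA": 170, "MCPsignal": 180, "HAMP": 55,
    "TPR": 34, "ArsR": 90,
}
_DEFAULT_LEN = 90


@pytest.fixture(scope="session")
def roles() -> DomainRoleDictionary:
    return DomainRoleDictionary.default()


def make_hits(names, protein_id="p1", linker=12, start=8):
    """Non-overlapping sequential hits for the named domains."""
    hits = []
    pos = start
    for i, name in enumerate(names):
        length = _LENGTHS.get(name, _DEFAULT_LEN)
        hits.append(
            DomainHit(
                protein_id=protein_id,
                domain_name=name,
                domain_accession="",
                start=pos,
                end=pos + length - 1,
                score=100.0 - i,
                evalue=1e-20 * (i + 1),
            )
        )
        pos += length + linker
    return hits, pos - linker + 10  # hits, protein length with a short tail


def make_protein(protein_id="p1", length=500, genome_id="g1", sequence=None):
    return ProteinRecord(
        protein_id=protein_id, genome_id=genome_id, length=length, sequence=sequence
    )


@pytest.fixture(scope="session")
def arch_factory(roles):
    """Build a resolved Architecture from a list of domain names."""
    from tcscensus.architecture import resolve_hits

    def build(names, protein_id="p1", length=None):
        hits, min_len = make_hits(names, protein_id=protein_id)
        prot = make_protein(protein_id=protein_id, length=length or min_len)
        return resolve_hits(hits, prot, roles=roles)

    return build
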