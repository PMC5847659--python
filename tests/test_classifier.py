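"""Classification of canonical archaeal regulator/kinase architectures."""

import pytest
from hypothesis import given, settings, strategies as st

from tcscensus.classify import classify, mark_divergent_rec
from tcscensus.model import RecSiteReport

# (domain names, expected category, expected RR subclass)
CANONICAL_CASES = [
    # regulators with described output domains
    (["REC", "CheB"], "RR", "CheB"),
    (["REC", "PAS"], "RR", "REC_PAS_GAF"),
    (["REC", "PAS", "PAS"], "RR", "REC_PAS_GAF"),
    (["REC", "PAS", "GAF"], "RR", "REC_PAS_GAF"),
    (["REC", "GAF"], "RR", "REC_PAS_GAF"),
    (["REC", "MEDS"], "RR", "REC_PAS_GAF"),
    (["REC", "PAS", "GAF", "BAT", "HTH_10"], "RR", "transcriptional_HTH"),
    (["HTH", "REC"], "RR", "transcriptional_HTH"),
    (["REC", "HalX"], "RR", "REC_HalX"),
    (["HxlR", "REC", "HalX"], "RR", "REC_HalX"),
    (["REC", "BcsA"], "RR", "REC_enzymatic"),
    (["REC", "REC", "BcsA"], "RR", "REC_enzymatic"),
    (["iKaiC", "REC"], "RR", "REC_enzymatic"),
    (["REC", "DUF835"], "RR", "REC_enzymatic"),
    (["REC", "PAS", "PAS", "DUF835"], "RR", "REC_enzymatic"),
    (["REC", "PAS", "PAS", "HAMP", "MCPsignal"], "RR", "other"),
    (["REC", "PAS", "TPR"], "RR", "other"),
    (["TPR", "TPR", "TPR", "REC"], "RR", "other"),
    # stand-alone receiver domain (CheY-like)
    (["REC"], "RR", "REC_only"),
    # novel lineage-specific output domains
    (["REC", "HalOD1"], "RR", "REC_novel_OD"),
    (["REC", "HalOD2"], "RR", "REC_novel_OD"),
    (["REC", "MetOD1"], "RR", "REC_novel_OD"),
    (["REC", "PAS", "MetOD1"], "RR", "REC_novel_OD"),
    (["MetOD3", "REC", "MetOD2"], "RR", "REC_novel_OD"),
    (["REC", "MetOD4"], "RR", "REC_novel_OD"),
    (["MetOD5", "REC"], "RR", "REC_novel_OD"),
    (["REC", "NitrOD1"], "RR", "REC_novel_OD"),
    (["NitrOD2", "REC"], "RR", "REC_novel_OD"),
    (["NitrOD3", "REC"], "RR", "REC_novel_OD"),
    (["NitrOD4", "REC"], "RR", "REC_novel_OD"),
    (["REC", "NitrOD5"], "RR", "REC_novel_OD"),
    (["REC", "TackOD1"], "RR", "REC_novel_OD"),
    (["REC", "AcidOD1"], "RR", "REC_novel_OD"),
    # regulators with both HTH and a novel domain keep the HTH subclass
    (["REC", "wHTH", "TackOD1"], "RR", "transcriptional_HTH"),
    # receiver + kinase combinations
    (["REC", "PAS", "PAS", "HisKA"], "RR", "REC_HisK"),
    (["REC", "PAS", "HisKA", "HATPase"], "RR", "REC_HisK"),
    (["HisKA", "HATPase", "REC"], "hybrid_HK", "n/a"),
    (["PAS", "HisKA", "HATPase", "REC", "Hpt"], "hybrid_HK", "n/a"),
    # kinases
    (["HisKA", "HATPase"], "HK", "n/a"),
    (["PAS", "GAF", "HisKA", "HATPase"], "HK", "n/a"),
    (["MEDS", "HisKA", "HATPase"], "HK", "n/a"),
    (["PAS", "GAF", "HisKA"], "HisKA_no_HATPase", "n/a"),
    # stand-alone output domains are not two-component proteins
    (["HalX"], "not_TCS", "n/a"),
    (["HalOD1"], "not_TCS", "n/a"),
    (["MEDS"], "not_TCS", "n/a"),
    (["ArsR"], "not_TCS", "n/a"),
]


@pytest.mark.parametrize(
    "names,category,subclass",
    CANONICAL_CASES,
    ids=["-".join(c[0]) for c in CANONICAL_CASES],
)
def test_canonical_architectures(arch_factory, roles, names, category, subclass):
    call = classify(arch_factory(names), roles)
    assert call.category == category
    assert call.rr_subclass == subclass


class TestCheATypeKinases:
    def test_hatpase_with_hpt_and_chew_is_cheA_like(self, arch_factory, roles):
        call = classify(arch_factory(["Hpt", "CheW", "HATPase"]), roles)
        assert call.category == "HK"
        assert "cheA_like" in call.flags

    def test_bare_hatpase_is_plain_hk(self, arch_factory, roles):
        call = classify(arch_factory(["HATPase"]), roles)
        assert call.category == "HK"
        assert "cheA_like" not in call.flags


class TestAmbiguousRecPlacement:
    def test_rec_on_both_sides_counts_as_rr_with_warning(self, arch_factory, roles):
        call = classify(arch_factory(["REC", "HisKA", "HATPase", "REC"]), roles)
        assert call.category == "RR"
        assert call.rr_subclass == "REC_HisK"
        assert call.warnings

    def test_rec_between_kinase_domains_warns(self, arch_factory, roles):
        call = classify(arch_factory(["HisKA", "REC", "HATPase"]), roles)
        assert call.category == "hybrid_HK"
        assert call.warnings


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.permutations(["REC", "HisKA", "HATPase"]),
    st.sampled_from(["PAS", "GAF", None]),
)
def test_rec_hiska_hatpase_footnote_identity(arch_factory, roles, order, extra):
    """Every REC+HisKA+HATPase protein is a hybrid HK or a REC-HisK RR."""
    names = list(order)
    if extra:
        names.insert(1, extra)
    call = classify(arch_factory(names), roles)
    assert (call.category == "hybrid_HK") or (
        call.category == "RR" and call.rr_subclass == "REC_HisK"
    )


class TestTotality:
    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.sampled_from(
                ["REC", "PAS", "GAF", "HisKA", "HATPase", "CheB", "HalX",
                 "HTH_10", "HalOD1", "Hpt", "CheW", "UnheardOfDomain"]
            ),
            min_size=0,
            max_size=6,
        )
    )
    def test_every_architecture_gets_one_category(self, arch_factory, roles, names):
        call = classify(arch_factory(names) if names else arch_factory(["REC"]), roles)
        assert call.category in {"HK", "hybrid_HK", "HisKA_no_HATPase", "RR", "not_TCS"}
        assert (call.category == "RR") == (call.rr_subclass != "n/a")


class TestDivergentReceiverExclusion:
    def test_short_rec_segment_excluded(self, roles):
        from tcscensus.architecture import resolve_hits
        from tcscensus.model import DomainHit

        from conftest import make_protein

        hits = [DomainHit("p1", "REC", "", 10, 54, 60.0, 1e-12)]  # 45 aa
        arch = resolve_hits(hits, make_protein(length=80), roles=roles)
        call = mark_divergent_rec(classify(arch, roles), arch)
        assert call.excluded
        assert call.category == "RR"  # the call itself is kept

    def test_full_length_rec_not_excluded(self, arch_factory, roles):
        arch = arch_factory(["REC"])
        report = RecSiteReport("p1", 1, {57: "D"}, reference_coverage=0.95,
                               identity=0.8, phosphorylatable=True)
        call = mark_divergent_rec(classify(arch, roles), arch, [report])
        assert not call.excluded

    def test_low_reference_coverage_excluded(self, arch_factory, roles):
        arch = arch_factory(["REC"])
        report = RecSiteReport("p1", 1, {57: "-"}, reference_coverage=0.50,
                               identity=0.7, phosphorylatable=False)
        call = mark_divergent_rec(classify(arch, roles), arch, [report])
        assert call.excluded
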