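"""Generator determinism, planted-label recovery, distributional fidelity."""

import numpy as np
import pandas as pd
import pytest

from tcscensus.pipeline import classify_proteins
from tcscensus.synthetic import (
    LineageProfile,
    fixture_table1,
    generate,
    haloarchaea_like,
    merge_datasets,
    methanogen_like,
    thaumarchaea_like,
)


def small(profile_fn, **kw):
    defaults = dict(n_genomes=2, proteins_per_genome=(60, 90), seed=5)
    defaults.update(kw)
    return profile_fn(**defaults)


class TestDeterminism:
    def test_same_seed_identical_output(self):
        a = generate(small(haloarchaea_like))
        b = generate(small(haloarchaea_like))
        assert a.hits == b.hits
        assert [p.sequence for p in a.proteins] == [p.sequence for p in b.proteins]
        assert a.features == b.features
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_different_seed_differs(self):
        a = generate(small(haloarchaea_like))
        b = generate(small(haloarchaea_like, seed=6))
        assert a.hits != b.hits


class TestProfileValidation:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            LineageProfile(
                name="bad", n_genomes=1, proteins_per_genome=(10, 20),
                tcs_per_genome=(2, 4), template_weights={"rec_only": 0.5},
            ).validate()

    def test_unknown_template_rejected(self):
        with pytest.raises(ValueError, match="unknown templates"):
            LineageProfile(
                name="bad", n_genomes=1, proteins_per_genome=(10, 20),
                tcs_per_genome=(2, 4), template_weights={"no_such": 1.0},
            ).validate()


class TestPureProfile:
    def test_all_rec_profile_yields_rec_only_truth(self):
        profile = LineageProfile(
            name="pure", n_genomes=1, proteins_per_genome=(10, 10),
            tcs_per_genome=(10, 10), template_weights={"rec_only": 1.0},
            chemotaxis_operon_rate=0.0, tandem_duplication_rate=0.0,
            nonphospho_rate=0.0, seed=1,
        )
        ds = generate(profile)
        assert len(ds.truth) == 10
        assert (ds.truth.category == "RR").all()
        assert (ds.truth.rr_subclass == "REC_only").all()


class TestEndToEndRecovery:
    @pytest.mark.parametrize(
        "profile_fn", [haloarchaea_like, methanogen_like, thaumarchaea_like]
    )
    def test_clean_emission_recovers_all_labels(self, profile_fn):
        ds = generate(small(profile_fn, rec_truncation_rate=0.05))
        _, calls = classify_proteins(ds.hits, ds.proteins)
        truth = ds.truth.set_index("protein_id")
        for pid, call in calls.items():
            row = truth.loc[pid]
            assert call.category == row.category, pid
            assert call.rr_subclass == row.rr_subclass, pid
            assert call.excluded == bool(row.excluded_divergent), pid

    def test_excluded_count_matches_planted_truncations(self):
        ds = generate(small(methanogen_like, rec_truncation_rate=0.15, seed=9))
        _, calls = classify_proteins(ds.hits, ds.proteins)
        planted = int(ds.truth.excluded_divergent.sum())
        found = sum(1 for c in calls.values() if c.excluded)
        assert planted > 0
        assert found == planted

    def test_census_conservation_on_synthetic_data(self):
        datasets = [generate(small(fn)) for fn in
                    (haloarchaea_like, methanogen_like, thaumarchaea_like)]
        ds = merge_datasets(datasets)
        _, calls = classify_proteins(ds.hits, ds.proteins)
        from tcscensus.census import build_census

        census = build_census(calls.values(), ds.proteins, ds.taxonomy)
        body = census[census.taxon != "Total"]
        totals = census[census.taxon == "Total"].iloc[0]
        for col in ("n_genomes", "n_proteins", "n_HK", "n_RR", "n_REC_only", "n_HTH"):
            assert totals[col] == body[col].sum()
        # every protein is accounted for: HK + RR + other categories
        n_hk_rr = totals.n_HK + totals.n_RR
        others = sum(
            1 for c in calls.values()
            if c.excluded or c.category in ("not_TCS", "HisKA_no_HATPase")
        )
        assert n_hk_rr + others == len(ds.proteins)


class TestDistributionalFidelity:
    def test_rec_only_fraction_tracks_profile_weight(self):
        profile = thaumarchaea_like(
            n_genomes=4, proteins_per_genome=(220, 280), tcs_per_genome=(30, 40),
            chemotaxis_operon_rate=0.0, tandem_duplication_rate=0.0,
            novel_domain_plants=[], seed=31,
        )
        ds = generate(profile)
        _, calls = classify_proteins(ds.hits, ds.proteins)
        rrs = [c for c in calls.values() if c.is_rr and not c.excluded]
        rec_only = [c for c in rrs if c.rr_subclass == "REC_only"]
        w = profile.template_weights
        expected = w["rec_only"] / sum(
            w[k] for k in w if k.startswith(("rec_", "cheB", "bat", "ltrR",
                                            "ikaic", "nitrod"))
        )
        n = len(rrs)
        p_hat = len(rec_only) / n
        sigma = (expected * (1 - expected) / n) ** 0.5
        assert abs(p_hat - expected) < 3 * sigma + 1e-9

    def test_membrane_plant_rate_recovered(self):
        ds = generate(small(methanogen_like, membrane_hk_rate=0.38, seed=77,
                            n_genomes=4, proteins_per_genome=(100, 140)))
        truth = ds.truth
        hks = truth[truth.category.isin(["HK", "hybrid_HK"])]
        n = len(hks)
        p_hat = hks.tm_present.mean()
        sigma = (0.38 * 0.62 / n) ** 0.5
        assert abs(p_hat - 0.38) < 3 * sigma + 1e-9

    def test_chemotaxis_flags_match_truth_exactly(self):
        ds = generate(small(haloarchaea_like, chemotaxis_operon_rate=1.0, seed=13))
        from tcscensus.census import find_neighbors

        _, calls = classify_proteins(ds.hits, ds.proteins)
        _, flagged = find_neighbors(ds.features, calls)
        truth_flagged = set(
            ds.truth[ds.truth.chemotaxis_associated].protein_id
        )
        assert truth_flagged
        assert flagged == truth_flagged


class TestTable1Fixture:
    def test_row_values(self):
        t = fixture_table1().set_index("taxon")
        arch = t.loc["Archaeoglobi"]
        assert (arch.n_genomes, arch.n_proteins) == (7, 15162)
        assert (arch.n_HK, arch.n_RR, arch.n_REC_only) == (37, 42, 32)
        methanopyri = t.loc["Methanopyri"]
        assert methanopyri.n_HK == 0 and methanopyri.n_RR == 0

    def test_column_sums_match_published_totals(self):
        t = fixture_table1()
        assert t.n_proteins.sum() == 511588
        assert t.n_HK.sum() == 2139
        assert t.n_RR.sum() == 1875
        assert t.n_REC_only.sum() == 740
        assert t.n_HTH.sum() == 116
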