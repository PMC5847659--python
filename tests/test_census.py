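"""Census aggregation, per-genome stats, membrane prediction, neighborhoods."""

import math

import numpy as np
import pytest

from tcscensus.census import (
    build_census,
    build_census_from_rows,
    find_neighbors,
    format_census,
    genome_stats,
    intergenic_distance,
    membrane_fraction,
    predict_tm,
    round_half_away,
    sensor_tally,
)
from tcscensus.model import GeneFeature, ProteinRecord, TCSCall
from tcscensus.synthetic import fixture_table1


class TestRounding:
    @pytest.mark.parametrize(
        "x,expected", [(0.5, 1), (1.4, 1), (1.5, 2), (2.5, 3), (-0.5, -1), (22.9, 23)]
    )
    def test_half_away_from_zero(self, x, expected):
        assert round_half_away(x) == expected


class TestCensusFromRows:
    def test_published_totals_reproduced(self):
        census = build_census_from_rows(fixture_table1())
        totals = census[census.taxon == "Total"].iloc[0]
        assert totals.n_proteins == 511588
        assert totals.n_HK == 2139
        assert totals.n_RR == 1875
        assert totals.n_REC_only == 740
        assert totals.n_HTH == 116

    @pytest.mark.parametrize(
        "taxon,pct",
        [
            ("Archaeoglobi", 76),
            ("Halobacteria", 23),
            ("Methanomicrobia", 43),
            ("Thaumarchaeota", 77),
            ("Methanococci", 65),
            ("Thermococci", 55),
        ],
    )
    def test_published_rec_only_percentages(self, taxon, pct):
        census = build_census_from_rows(fixture_table1())
        row = census[census.taxon == taxon].iloc[0]
        assert row.pct_REC_only == pct

    def test_zero_rr_taxon_renders_dash_not_error(self):
        census = build_census_from_rows(fixture_table1())
        row = census[census.taxon == "Nanoarchaeota"].iloc[0]
        assert math.isnan(row.pct_REC_only)
        formatted = format_census(census)
        frow = formatted[formatted.taxon == "Nanoarchaeota"].iloc[0]
        assert frow.pct_REC_only == "—"
        assert frow.n_HK == "—"

    def test_totals_row_is_columnwise_sum(self):
        census = build_census_from_rows(fixture_table1())
        body = census[census.taxon != "Total"]
        totals = census[census.taxon == "Total"].iloc[0]
        for col in ("n_genomes", "n_proteins", "n_HK", "n_RR", "n_REC_only", "n_HTH"):
            assert totals[col] == body[col].sum()


def _mini_world():
    proteins = [
        ProteinRecord("a1", "gA", 300), ProteinRecord("a2", "gA", 300),
        ProteinRecord("a3", "gA", 300), ProteinRecord("b1", "gB", 300),
        ProteinRecord("b2", "gB", 300),
    ]
    calls = [
        TCSCall("a1", "HK", "n/a", set(), "HisKA-HATPase_c"),
        TCSCall("a2", "RR", "REC_only", set(), "REC"),
        TCSCall("a3", "RR", "REC_only", {"excluded_divergent"}, "REC"),
        TCSCall("b1", "hybrid_HK", "n/a", set(), "HisKA-HATPase_c-REC"),
        TCSCall("b2", "RR", "transcriptional_HTH", set(), "REC-BAT-HTH_10"),
    ]
    return calls, proteins


class TestBuildCensusFromCalls:
    def test_counts_and_exclusion(self):
        calls, proteins = _mini_world()
        census = build_census(calls, proteins, {"gA": "taxA", "gB": "taxB"})
        a = census[census.taxon == "taxA"].iloc[0]
        assert (a.n_HK, a.n_RR, a.n_REC_only) == (1, 1, 1)  # a3 excluded
        b = census[census.taxon == "taxB"].iloc[0]
        assert (b.n_HK, b.n_RR, b.n_HTH) == (1, 1, 1)  # hybrid counted as HK

    def test_unmapped_genome_grouped_as_unclassified(self):
        calls, proteins = _mini_world()
        census = build_census(calls, proteins, {"gA": "taxA"})
        assert "unclassified" in set(census.taxon)


class TestGenomeStats:
    def test_ratio_and_fraction(self):
        proteins = [ProteinRecord(f"p{i}", "g1", 200) for i in range(1000)]
        calls = [
            TCSCall(f"p{i}", "HK", "n/a", set(), "") for i in range(5)
        ] + [
            TCSCall(f"p{i}", "RR", "REC_only", set(), "") for i in range(5, 15)
        ]
        table, _ = genome_stats(calls, proteins)
        row = table.iloc[0]
        assert row.rr_hk_ratio == pytest.approx(2.0)
        # 15 TCS proteins in 1,000 ORFs
        assert row.tcs_pct_of_orfs == pytest.approx(1.5)

    def test_zero_hk_ratio_is_nan(self):
        proteins = [ProteinRecord("p1", "g1", 200)]
        calls = [TCSCall("p1", "RR", "REC_only", set(), "")]
        table, _ = genome_stats(calls, proteins)
        assert math.isnan(table.iloc[0].rr_hk_ratio)

    def test_size_independent_tcs_count_gives_weak_correlation(self):
        from tcscensus.synthetic import generate, thaumarchaea_like

        profile = thaumarchaea_like(
            n_genomes=50,
            proteins_per_genome=(400, 1600),
            tcs_per_genome=(12, 16),
            realize_sequences=False,
            seed=123,
        )
        ds = generate(profile)
        from tcscensus.pipeline import classify_proteins

        _, calls = classify_proteins(ds.hits, ds.proteins)
        table, summary = genome_stats(calls.values(), ds.proteins)
        assert len(table) == 50
        assert abs(summary["pearson_r"]) < 0.3


class TestPredictTm:
    def test_hydrophobic_island_called_once(self):
        seq = "D" * 40 + "L" * 25 + "D" * 40
        segments = predict_tm(seq)
        assert len(segments) == 1
        start, end = segments[0]
        assert start <= 45 and end >= 60  # covers the poly-Leu island

    def test_hydrophilic_chain_has_no_segments(self):
        assert predict_tm("D" * 120) == []

    def test_short_sequence_returns_empty(self):
        assert predict_tm("LLLL") == []


class TestMembraneFraction:
    def test_counting_from_tm_tables(self):
        proteins = {}
        calls = []
        for i in range(10):
            pid = f"hk{i}"
            tm = [(10, 30)] if i < 4 else []
            proteins[pid] = ProteinRecord(pid, "g1", 300, tm_segments=tm)
            calls.append(TCSCall(pid, "HK", "n/a", set(), ""))
        fraction, table = membrane_fraction(calls, proteins)
        assert fraction == pytest.approx(0.6)
        assert len(table) == 10

    def test_kinase_dead_proteins_not_in_denominator(self):
        proteins = {
            "hk1": ProteinRecord("hk1", "g1", 300),
            "x1": ProteinRecord("x1", "g1", 300),
        }
        calls = [
            TCSCall("hk1", "HK", "n/a", set(), ""),
            TCSCall("x1", "HisKA_no_HATPase", "n/a", set(), ""),
        ]
        fraction, table = membrane_fraction(calls, proteins, use_prediction_fallback=False)
        assert len(table) == 1

    def test_strict_mode_excludes_unknowable_proteins(self, caplog):
        proteins = {"hk1": ProteinRecord("hk1", "g1", 300)}
        calls = [TCSCall("hk1", "HK", "n/a", set(), "")]
        fraction, table = membrane_fraction(calls, proteins, strict=True)
        assert len(table) == 0
        assert math.isnan(fraction)


class TestSensorTally:
    def test_pas_gaf_and_named_sensors(self, arch_factory):
        archs = {
            "h1": arch_factory(["PAS", "GAF", "HisKA", "HATPase"], protein_id="h1"),
            "h2": arch_factory(["MEDS", "HisKA", "HATPase"], protein_id="h2"),
            "h3": arch_factory(["HisKA", "HATPase"], protein_id="h3"),
        }
        calls = [TCSCall(p, "HK", "n/a", set(), "") for p in archs]
        tally = sensor_tally(calls, archs)
        assert tally.set_index("protein_id").loc["h1", "has_both"]
        assert tally.set_index("protein_id").loc["h2", "has_MEDS"]
        assert int(tally.has_PAS.sum()) == 1
        assert not tally.set_index("protein_id").loc["h3", "has_GAF"]


def _gene(pid, start, end, strand, contig="c1"):
    return GeneFeature("g1", contig, pid, start, end, strand)


class TestNeighborhoods:
    def test_co_oriented_adjacent_within_gap(self):
        feats = [_gene("A", 100, 1000, "+"), _gene("B", 1100, 2000, "+")]
        relations, _ = find_neighbors(feats, {})
        assert len(relations) == 1
        assert relations[0].relation == "same_operon_adjacent"
        assert relations[0].intergenic_distance == 99

    def test_head_to_head_pair_is_divergent(self):
        feats = [_gene("A", 100, 1000, "-"), _gene("B", 1200, 2000, "+")]
        relations, _ = find_neighbors(feats, {})
        assert relations[0].relation == "divergent"

    def test_large_gap_breaks_operon(self):
        feats = [_gene("A", 100, 1000, "+"), _gene("B", 1500, 2000, "+")]
        relations, _ = find_neighbors(feats, {})
        assert relations == []

    def test_different_contigs_never_pair(self):
        feats = [_gene("A", 100, 1000, "+"), _gene("B", 1100, 2000, "+", contig="c2")]
        relations, _ = find_neighbors(feats, {})
        assert relations == []

    def test_relation_symmetric_under_input_order(self):
        feats = [_gene("A", 100, 1000, "-"), _gene("B", 1200, 2000, "+"),
                 _gene("C", 2100, 2900, "+")]
        fwd, _ = find_neighbors(feats, {})
        rev, _ = find_neighbors(list(reversed(feats)), {})
        key = lambda r: (tuple(sorted((r.protein_a, r.protein_b))), r.relation)
        assert sorted(map(key, fwd)) == sorted(map(key, rev))

    def test_rec_only_near_cheA_in_operon_flagged(self):
        feats = [
            _gene("cheA", 100, 3000, "+"),
            _gene("cheB", 3100, 4500, "+"),
            _gene("cheY", 4600, 5000, "+"),
            _gene("lone", 9000, 9400, "+"),  # far away: separate run
        ]
        calls = {
            "cheA": TCSCall("cheA", "HK", "n/a", {"cheA_like"}, ""),
            "cheB": TCSCall("cheB", "RR", "CheB", set(), ""),
            "cheY": TCSCall("cheY", "RR", "REC_only", set(), ""),
            "lone": TCSCall("lone", "RR", "REC_only", set(), ""),
        }
        _, flagged = find_neighbors(feats, calls)
        assert flagged == {"cheY"}
        assert "chemotaxis_associated" in calls["cheY"].flags
        assert "chemotaxis_associated" not in calls["lone"].flags


def test_intergenic_distance_is_non_negative():
    a = _gene("A", 100, 1000, "+")
    b = _gene("B", 990, 2000, "+")  # slight overlap
    assert intergenic_distance(a, b) == 0
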