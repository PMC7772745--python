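"""The hypergeometric engine, p-value adjustment and the enrichment pipeline."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from qtlannot.enrich import (
    adjust_pvalues,
    enrich_from_counts,
    enrichment_bubble_data,
    hypergeom_upper_tail,
    permutation_pvalue,
    qtl_enrich,
    ENRICH_COLUMNS,
)
from qtlannot.annotate import annotate_loci
from qtlannot.fixtures import FixtureSpec, build_databases, simulate_records
from qtlannot.io import read_table


def enumerate_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """Exhaustive oracle: count n-subsets of an N-population with >= k successes."""
    population = [1] * K + [0] * (N - K)
    hits = total = 0
    for draw in combinations(range(N), n):
        total += 1
        hits += sum(population[i] for i in draw) >= k
    return hits / total if total else 1.0


# count quadruples with published chromosome-wide p-values (trait, chromosome
# label kept for readability only)
PUBLISHED = [
    (132, 134, 347, 5942, 1.56e-171),
    (11, 13, 41, 2147, 2.20e-18),
    (11, 14, 30, 1395, 2.04e-17),
    (71, 1607, 204, 12158, 1.86e-15),
    (47, 285, 347, 5942, 3.38e-11),
    (4, 5, 12, 3606, 3.51e-10),
    (76, 2637, 204, 12158, 2.39e-07),
    (6, 7, 347, 5942, 2.53e-07),
    (7, 44, 21, 1440, 1.29e-06),
    (4, 8, 19, 1159, 3.48e-06),
]


class TestHypergeomUpperTail:
    @pytest.mark.parametrize("k,K,n,N,expected", PUBLISHED)
    def test_published_chromosome_wide_pvalues(self, k, K, n, N, expected):
        assert hypergeom_upper_tail(k, K, n, N) == pytest.approx(expected, rel=5e-3)

    def test_zero_successes_is_certain(self):
        assert hypergeom_upper_tail(0, 5, 12, 100) == 1.0

    def test_small_case_against_enumeration(self):
        # population 6 with 3 successes, 3 draws: 10 of the 20 subsets have >= 2
        assert enumerate_upper_tail(2, 3, 3, 6) == 0.5
        assert hypergeom_upper_tail(2, 3, 3, 6) == pytest.approx(0.5, abs=1e-12)

    def test_exhaustive_grid_small_populations(self):
        """Agrees with subset enumeration for every parameter set with N <= 12."""
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        assert hypergeom_upper_tail(k, K, n, N) == pytest.approx(
                            enumerate_upper_tail(k, K, n, N), abs=1e-10
                        ), (k, K, n, N)

    def test_against_independent_library_tail(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            N = int(rng.integers(10, 5000))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            expected = hypergeom.sf(k - 1, N, K, n)
            assert hypergeom_upper_tail(k, K, n, N) == pytest.approx(expected, rel=1e-9)

    def test_pmf_normalization(self):
        """Point masses over the full support sum to 1 within 1e-12."""
        from qtlannot.enrich import hypergeom_pmf

        rng = np.random.default_rng(9)
        for _ in range(100):
            N = int(rng.integers(2, 2000))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            total = sum(
                hypergeom_pmf(i, K, n, N)
                for i in range(max(0, n + K - N), min(K, n) + 1)
            )
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_tail_monotone_in_k(self):
        K, n, N = 30, 50, 200
        tails = [hypergeom_upper_tail(k, K, n, N) for k in range(min(K, n) + 1)]
        assert all(a >= b for a, b in zip(tails, tails[1:]))

    @pytest.mark.parametrize("bad", [(5, 4, 10, 20), (1, 2, 30, 20), (-1, 2, 3, 9), (4, 5, 3, 20)])
    def test_invalid_parameters_fatal(self, bad):
        with pytest.raises(ValueError, match="k="):
            hypergeom_upper_tail(*bad)

    def test_permutation_cross_check(self):
        k, K, n, N = 5, 20, 30, 100
        exact = hypergeom_upper_tail(k, K, n, N)
        approx = permutation_pvalue(k, K, n, N, n_perm=20_000, rng=1)
        assert approx == pytest.approx(exact, abs=0.02)


class TestAdjustPvalues:
    def test_bh_hand_computed(self):
        # BH: p_(i) * m / i, monotonized from the largest: all become 0.03
        assert adjust_pvalues([0.01, 0.02, 0.03], "BH") == pytest.approx([0.03, 0.03, 0.03])

    def test_holm_hand_computed(self):
        # Holm: max cumulative of p_(i) * (m - i + 1)
        assert adjust_pvalues([0.01, 0.04], "holm") == pytest.approx([0.02, 0.04])

    def test_bonferroni_caps_at_one(self):
        assert adjust_pvalues([0.5, 0.5], "bonferroni") == [1.0, 1.0]

    def test_none_is_identity_and_order_preserved(self):
        vals = [0.9, 0.1, 0.5]
        assert adjust_pvalues(vals, "none") == vals

    def test_out_of_range_fatal(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            adjust_pvalues([0.5, 1.5], "BH")


def _annotated(seed=7, **kw):
    spec = FixtureSpec(seed=seed, **kw)
    candidates, _, qtls = simulate_records(spec)
    _, qtl_db = build_databases([], qtls)
    return annotate_loci(candidates, qtl_db, spec.window_w), qtl_db


class TestQtlEnrich:
    def test_record_hit_by_several_markers_counts_once(self):
        ann = pd.DataFrame(
            {
                "CHR": ["1"] * 3 + ["1"],
                "qtl_id": ["q1", "q1", "q1", "q2"],
                "trait_name": ["T", "T", "T", "U"],
                "qtl_class": ["Milk"] * 4,
            }
        )
        from qtlannot.io import FeatureDatabase, QTLRecord

        db = FeatureDatabase(
            [
                QTLRecord("1", 1, 10, "q1", "T", "Milk"),
                QTLRecord("1", 20, 30, "q2", "U", "Milk"),
                QTLRecord("1", 40, 50, "q3", "T", "Milk"),
            ],
            kind="qtls",
        )
        res = qtl_enrich(ann, db, enrich_type="genome", by="trait")
        row = res[res["QTL"] == "T"].iloc[0]
        assert (row["N_QTLs"], row["N_QTLs_db"]) == (1, 2)
        assert (row["Total_annotated_QTLs"], row["Total_QTLs_db"]) == (2, 3)

    def test_single_trait_database_is_degenerate(self):
        ann, db = _annotated(trait_catalog=(("only", "Milk", 1.0),))
        res = qtl_enrich(ann, db, enrich_type="genome", by="trait")
        assert len(res) == 1
        row = res.iloc[0]
        assert row["N_QTLs"] == row["Total_annotated_QTLs"]
        assert row["N_QTLs_db"] == row["Total_QTLs_db"]
        assert row["pvalue"] == 1.0

    def test_annotated_trait_missing_from_db_is_fatal(self):
        ann, db = _annotated()
        bad = ann.rows.copy()
        bad.loc[bad.index[0], "trait_name"] = "ghost trait"
        bad.loc[bad.index[0], "qtl_id"] = "ghost-id"
        with pytest.raises(ValueError, match="ghost trait"):
            qtl_enrich(bad, db, enrich_type="genome", by="trait")

    def test_empty_annotation_warns_and_returns_empty(self, caplog):
        ann, db = _annotated()
        res = qtl_enrich(ann.rows.iloc[0:0], db)
        assert res.empty and list(res.columns) == ENRICH_COLUMNS

    def test_trait_counts_partition_scope_counts(self):
        """Per chromosome, sum of k over traits equals n (one trait per record)."""
        ann, db = _annotated(seed=3)
        res = qtl_enrich(ann, db, enrich_type="chromosome", by="trait")
        for chrom, sub in res.groupby("CHR"):
            assert sub["N_QTLs"].sum() == sub["Total_annotated_QTLs"].iloc[0]
            assert sub["N_QTLs_db"].sum() <= sub["Total_QTLs_db"].iloc[0]

    def test_chromosome_scope_and_subset(self):
        ann, db = _annotated(seed=3)
        res = qtl_enrich(ann, db, enrich_type="chromosome", by="trait", chr_subset=["2"])
        assert set(res["CHR"]) == {"2"}
        # counts restricted to the chromosome
        n2 = len(ann.rows[ann.rows["CHR"] == "2"].drop_duplicates("qtl_id"))
        assert (res["Total_annotated_QTLs"] == n2).all()
        N2 = sum(r.chrom == "2" for r in db.records)
        assert (res["Total_QTLs_db"] == N2).all()

    def test_by_class_grouping(self):
        ann, db = _annotated(seed=3)
        res = qtl_enrich(ann, db, enrich_type="genome", by="class")
        assert set(res["QTL"]) <= {"Milk", "Reproduction", "Meat and Carcass", "Health", "Production", "Exterior"}
        assert (res["QTL_type"] == res["QTL"]).all()

    def test_sorted_by_pvalue_then_trait(self):
        ann, db = _annotated(seed=3)
        res = qtl_enrich(ann, db, enrich_type="chromosome", by="trait")
        keys = list(zip(res["pvalue"], res["QTL"]))
        assert keys == sorted(keys)
        assert (res["adj.pval"] >= res["pvalue"] - 1e-15).all()
        assert ((res["richness"] > 0) & (res["richness"] <= 1)).all()
        assert res.attrs["n_tests"] == len(res)

    def test_planted_trait_ranks_first(self):
        ann, db = _annotated(seed=0, planted_enrichment=("Stature", 10))
        res = qtl_enrich(ann, db, enrich_type="genome", by="trait")
        assert res.iloc[0]["QTL"] == "Stature"


def test_enrich_from_counts_matches_direct_test(toy):
    counts = read_table(toy["enrichment_counts"])
    res = enrich_from_counts(counts)
    assert list(res.columns) == ENRICH_COLUMNS
    for row in res.itertuples():
        direct = hypergeom_upper_tail(
            row.N_QTLs, row.N_QTLs_db, row.Total_annotated_QTLs, row.Total_QTLs_db
        )
        assert row.pvalue == direct
    assert res["pvalue"].is_monotonic_increasing


class TestBubbleData:
    def test_top_row_richness_and_size(self, toy):
        res = enrich_from_counts(read_table(toy["enrichment_counts"]))
        bubble = enrichment_bubble_data(res, top=5)
        assert len(bubble) == 5
        assert bubble.iloc[0]["richness"] == pytest.approx(132 / 134)
        assert bubble.iloc[0]["size"] == 132
        assert bubble["neg_log10_p"].is_monotonic_decreasing

    def test_top_exceeding_rows_warns_and_uses_all(self, toy, caplog):
        res = enrich_from_counts(read_table(toy["enrichment_counts"])).head(1)
        bubble = enrichment_bubble_data(res, top=5)
        assert len(bubble) == 1
        assert any("using all rows" in r.message for r in caplog.records)
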