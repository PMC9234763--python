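"""Shared statistics: chi-squared, ANOVA/Tukey, hypergeometric enrichment,
ddCt fold changes and variant filtering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import durameth as dm
from durameth.core_io import GeneSetCollection


def chi2_textbook(table):
    """Independent direct computation of the Pearson statistic."""
    obs = np.asarray(table, dtype=float)
    total = obs.sum()
    stat = 0.0
    for i in range(obs.shape[0]):
        for j in range(obs.shape[1]):
            e = obs[i].sum() * obs[:, j].sum() / total
            stat += (obs[i, j] - e) ** 2 / e
    return stat


class TestPearsonChi2:
    def test_sex_by_grade_reconstruction(self):
        # unique 2x2 completion of marginals 6/25 (M/F) x 10/21 (high/low)
        res = dm.pearson_chi2([[4, 2], [6, 19]])
        assert res.statistic == pytest.approx(4.03, abs=0.005)
        assert res.df == 1
        assert res.p_value == pytest.approx(0.045, abs=0.002)

    def test_flat_table_is_null(self):
        res = dm.pearson_chi2([[5, 5], [5, 5]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_matches_textbook_formula_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            table = rng.integers(1, 40, size=(3, 4))
            res = dm.pearson_chi2(table)
            assert res.statistic == pytest.approx(chi2_textbook(table),
                                                  abs=1e-10)
            assert res.df == 6

    def test_no_continuity_correction_by_default(self):
        table = [[4, 2], [6, 19]]
        corrected = dm.pearson_chi2(table, correction=True)
        assert corrected.statistic < dm.pearson_chi2(table).statistic

    def test_zero_margins_dropped_then_degenerate_errors(self):
        with pytest.warns(UserWarning, match="zero-margin"):
            res = dm.pearson_chi2([[3, 0, 4], [5, 0, 1]])
        assert res.df == 1
        with pytest.raises(ValueError, match="degenerate"):
            with pytest.warns(UserWarning):
                dm.pearson_chi2([[3, 0], [5, 0]])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 5))
    def test_invariant_to_permutation(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(1, 30, size=(3, 3))
        base = dm.pearson_chi2(table).statistic
        perm = rng.permutation(3)
        assert dm.pearson_chi2(table[perm][:, perm]).statistic \
            == pytest.approx(base, abs=1e-12)


def anova_textbook(values, groups):
    """Direct one-way ANOVA F from sums of squares."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    grand = values.mean()
    levels = np.unique(groups)
    ss_between = sum(len(values[groups == g])
                     * (values[groups == g].mean() - grand) ** 2
                     for g in levels)
    ss_within = sum(((values[groups == g] - values[groups == g].mean()) ** 2).sum()
                    for g in levels)
    df_b, df_w = len(levels) - 1, len(values) - len(levels)
    return (ss_between / df_b) / (ss_within / df_w)


class TestAnovaTukey:
    def test_identical_groups_are_null(self):
        values = [1, 2, 3] * 3
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = dm.anova_tukey(values, groups)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_separated_groups_approach_zero_p(self):
        values = [0, 0, 0, 10, 10, 10]
        groups = ["a"] * 3 + ["b"] * 3
        res = dm.anova_tukey(values, groups)
        assert res.p_value < 1e-10

    def test_matches_textbook_f_on_random_data(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            values = rng.normal(size=24)
            groups = np.repeat(["a", "b", "c"], 8)
            res = dm.anova_tukey(values, groups)
            assert res.f_statistic == pytest.approx(
                anova_textbook(values, groups), abs=1e-10)

    def test_tukey_table_covers_all_pairs(self):
        rng = np.random.default_rng(2)
        values = np.concatenate([rng.normal(m, 1, 6) for m in (0, 0, 5)])
        groups = np.repeat(["a", "b", "c"], 6)
        res = dm.anova_tukey(values, groups)
        assert len(res.tukey) == 3
        table = res.tukey.set_index(["group_a", "group_b"])["p_adj"]
        assert table[("a", "c")] < 0.05 and table[("a", "b")] > 0.05

    def test_singleton_group_excluded_from_hsd(self):
        values = [1.0, 2.0, 3.0, 8.0, 9.0, 5.0]
        groups = ["a", "a", "a", "b", "b", "c"]
        with pytest.warns(UserWarning, match="n=1"):
            res = dm.anova_tukey(values, groups)
        assert set(res.tukey["group_a"]) | set(res.tukey["group_b"]) == {"a", "b"}

    def test_all_identical_values(self):
        res = dm.anova_tukey([3.0] * 9, ["a", "b", "c"] * 3)
        assert res.f_statistic == 0.0 and res.p_value == 1.0


def hypergeom_enumeration(N, K, n, k):
    """Exhaustive oracle: enumerate all C(N, n) draws, count overlap >= k."""
    hits = 0
    total = 0
    in_set = set(range(K))
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(in_set.intersection(draw)) >= k:
            hits += 1
    return hits / total


class TestHypergeometricEnrichment:
    def _collection(self, sets):
        return GeneSetCollection(sets={k: frozenset(v) for k, v in sets.items()})

    def test_closed_form_example(self):
        # N=10, K=5, n=3, k=3 -> C(5,3)/C(10,3) = 10/120
        universe = [f"g{i}" for i in range(10)]
        sets = self._collection({"S": universe[:5]})
        out = dm.hypergeometric_enrichment(universe[:3], universe, sets,
                                           dm.EnrichmentParams(min_set_size=1))
        assert out["p_value"].iloc[0] == pytest.approx(10 / 120, abs=1e-12)

    def test_zero_overlap_has_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        sets = self._collection({"S": universe[5:]})
        out = dm.hypergeometric_enrichment(universe[:3], universe, sets,
                                           dm.EnrichmentParams(min_set_size=1))
        assert out["p_value"].iloc[0] == pytest.approx(1.0)
        assert not out["enriched"].iloc[0]

    def test_matches_enumeration_oracle_small_universes(self):
        from scipy import stats as sps
        rng = np.random.default_rng(3)
        for _ in range(30):
            N = int(rng.integers(4, 13))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            expected = hypergeom_enumeration(N, K, n, k)
            assert sps.hypergeom.sf(k - 1, N, K, n) == pytest.approx(
                expected, abs=1e-12)

    def test_p_monotone_in_overlap(self):
        from scipy import stats as sps
        N, K, n = 40, 12, 15
        ps = [sps.hypergeom.sf(k - 1, N, K, n) for k in range(0, 13)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_stray_query_genes_dropped_with_warning(self):
        universe = [f"g{i}" for i in range(10)]
        sets = self._collection({"S": universe[:5]})
        with pytest.warns(UserWarning, match="outside the universe"):
            out = dm.hypergeometric_enrichment(
                universe[:3] + ["alien"], universe, sets,
                dm.EnrichmentParams(min_set_size=1))
        assert out["n"].iloc[0] == 3

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError, match="universe"):
            dm.hypergeometric_enrichment(["a"], [], self._collection({"S": {"a"}}))

    def test_q_values_and_flags(self):
        universe = [f"g{i}" for i in range(30)]
        sets = self._collection({
            "hit": universe[:6], "miss": universe[20:26]})
        out = dm.hypergeometric_enrichment(universe[:6], universe, sets)
        out = out.set_index("set")
        assert out.loc["hit", "enriched"]
        assert not out.loc["miss", "enriched"]


class TestDdctFoldChange:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["sample_id", "condition",
                                           "target_ct", "reference_ct"])

    def test_power_of_two_example(self):
        # case dCt 10, control dCt 18 -> ddCt -8 -> fold 256
        t = self._table([("case1", "case", 20.0, 10.0),
                         ("ctrl1", "control", 30.0, 12.0)])
        res = dm.ddct_fold_change(t)
        assert res.loc["case1", "fold_change"] == pytest.approx(256.0)

    def test_case_identical_to_control_is_one(self):
        t = self._table([("case1", "case", 21.0, 11.0),
                         ("ctrl1", "control", 25.0, 15.0)])
        res = dm.ddct_fold_change(t)
        assert res.loc["case1", "fold_change"] == pytest.approx(1.0)
        assert res.loc["ctrl1", "fold_change"] == pytest.approx(1.0)

    def test_replicates_averaged_before_differencing(self):
        t_rep = self._table([("c", "case", 19.9, 10.0),
                             ("c", "case", 20.1, 10.0),
                             ("k", "control", 30.0, 12.0)])
        t_single = self._table([("c", "case", 20.0, 10.0),
                                ("k", "control", 30.0, 12.0)])
        assert dm.ddct_fold_change(t_rep).loc["c", "fold_change"] == \
            pytest.approx(dm.ddct_fold_change(t_single).loc["c", "fold_change"])

    def test_missing_control_errors(self):
        t = self._table([("c", "case", 20.0, 10.0)])
        with pytest.raises(ValueError, match="control"):
            dm.ddct_fold_change(t)


class TestVariantFilter:
    def _table(self):
        rows = [
            # kept: all rules pass, alt_reads boundary = 5 inclusive
            ("v_keep", "NF2", "exonic", 0.0, 0.10, 5),
            ("v_keep2", "TRAF7", "exonic", np.nan, 0.30, 12),
            # dropped: each violates exactly one rule
            ("v_vaf_edge", "NF2", "exonic", 0.0, 0.05, 10),     # vaf strict
            ("v_af_edge", "NF2", "exonic", 0.0001, 0.10, 10),   # af strict
            ("v_alt", "NF2", "exonic", 0.0, 0.10, 4),
            ("v_func", "NF2", "intronic", 0.0, 0.10, 10),
            ("v_gene", "NOTAGENE", "exonic", 0.0, 0.10, 10),
            ("v_af_hi", "AKT1", "exonic", 0.01, 0.10, 10),
            ("v_vaf_lo", "SMO", "exonic", 0.0, 0.01, 10),
            ("v_keep3", "KLF4", "exonic", 0.00009, 0.051, 7),
        ]
        return pd.DataFrame(rows, columns=["variant_id", "gene", "func",
                                           "gnomad_af", "vaf", "alt_reads"])

    def test_boundary_behavior_on_fixture(self):
        kept = dm.filter_somatic_variants(self._table())
        assert sorted(kept["variant_id"]) == ["v_keep", "v_keep2", "v_keep3"]

    def test_missing_gnomad_af_treated_as_absent(self):
        kept = dm.filter_somatic_variants(self._table())
        assert "v_keep2" in set(kept["variant_id"])

    def test_idempotent(self):
        once = dm.filter_somatic_variants(self._table())
        twice = dm.filter_somatic_variants(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_missing_column_errors(self):
        with pytest.raises(ValueError, match="missing columns"):
            dm.filter_somatic_variants(pd.DataFrame({"gene": ["NF2"]}))

    def test_allowlist_has_73_genes(self):
        assert len(dm.DEFAULT_GENE_ALLOWLIST) == 73

    def test_custom_allowlist_loader(self, tmp_path):
        p = tmp_path / "genes.txt"
        p.write_text("# comment\nGENEA\nGENEB\n")
        assert dm.load_allowlist(p) == {"GENEA", "GENEB"}
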