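"""Probe-level differential methylation: transforms, filtering, the
empirical-Bayes moderated t-test, BH adjustment and delta-beta calls."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import durameth as dm
from durameth.core_io import build_cohort
from durameth.diffmeth import estimate_variance_prior


def brute_force_bh(p):
    """Independent step-up oracle: q_i = min_{j: p_j >= p_i} p_j * n / rank_j."""
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    running = np.inf
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        q[i] = min(running, 1.0)
    return q


class TestBetaToM:
    @pytest.mark.parametrize("beta,expected", [
        (0.5, 0.0),
        (0.8, 2.0),
        (0.3, np.log2(3 / 7)),
    ])
    def test_closed_forms(self, beta, expected):
        assert dm.beta_to_m(np.array([beta]))[0] == pytest.approx(expected, abs=1e-12)

    def test_missing_propagates_and_epsilon_validated(self):
        out = dm.beta_to_m(np.array([np.nan, 0.0, 1.0]))
        assert np.isnan(out[0]) and np.isfinite(out[1]) and np.isfinite(out[2])
        with pytest.raises(ValueError):
            dm.beta_to_m(np.array([0.5]), epsilon=0.0)


class TestVariabilityFilter:
    def _cohort(self, dura_mean, tumor_values):
        """1 informative probe, 31 tumors, 4 dura."""
        n_t = len(tumor_values)
        samples = [f"D{i}" for i in range(4)] + [f"T{i}" for i in range(n_t)]
        beta = pd.DataFrame(
            [[dura_mean] * 4 + list(tumor_values),
             [0.5] * (4 + n_t)],  # always-dropped companion probe
            index=["cgA", "cgB"], columns=samples)
        intensity = beta * 0 + 1000.0
        sheet = pd.DataFrame({
            "sample_id": samples,
            "patient_id": samples,
            "tissue": ["dura"] * 4 + ["tumor"] * n_t,
            "grade": ["unknown"] * 4 + ["I"] * n_t,
            "nf2_status": "unknown", "sex": "F", "recurrent": False,
            "batch": "b", "excluded": False,
        }).set_index("sample_id", drop=False)
        manifest = pd.DataFrame({
            "probe_id": ["cgA", "cgB"], "chrom": "chr1", "pos": [100, 200],
            "masked": False}).set_index("probe_id", drop=False)
        ann = pd.DataFrame({"gene_id": ["G"], "gene_name": ["G"],
                            "chrom": ["chr1"], "strand": ["+"], "start": [1],
                            "end": [10], "gene_type": ["x"]}
                           ).set_index("gene_id", drop=False)
        return build_cohort(beta, intensity, sheet, manifest, ann)

    def test_low_branch_retains_at_4_of_31_tumors(self):
        tumors = [0.25] * 4 + [0.1] * 27  # 12.9% above 0.2
        cohort = self._cohort(0.1, tumors)
        assert "cgA" in dm.select_analysis_probes(cohort)

    def test_low_branch_drops_at_3_of_31_tumors(self):
        tumors = [0.25] * 3 + [0.1] * 28  # 9.7% < 10%, ceil rule fails
        cohort = self._cohort(0.1, tumors)
        assert "cgA" not in dm.select_analysis_probes(cohort)

    def test_intermediate_dura_mean_dropped(self):
        cohort = self._cohort(0.5, [0.9] * 31)
        assert dm.select_analysis_probes(cohort) == []

    def test_high_branch_uses_asymmetric_07_bound(self):
        tumors = [0.65] * 4 + [0.85] * 27
        cohort = self._cohort(0.85, tumors)
        assert "cgA" in dm.select_analysis_probes(cohort)
        tumors = [0.65] * 2 + [0.85] * 29  # 6.5% below 0.7
        cohort = self._cohort(0.85, tumors)
        assert "cgA" not in dm.select_analysis_probes(cohort)

    def test_masked_probes_removed_first(self):
        cohort = self._cohort(0.1, [0.25] * 4 + [0.1] * 27)
        cohort.manifest.loc["cgA", "masked"] = True
        assert dm.select_analysis_probes(cohort) == []

    def test_requires_dura(self):
        cohort = self._cohort(0.1, [0.3] * 31)
        cohort.samples["tissue"] = "tumor"
        cohort.samples["grade"] = "I"
        with pytest.raises(ValueError, match="dura"):
            dm.select_analysis_probes(cohort)


class TestModeratedTTest:
    def test_single_feature_falls_back_to_ordinary_t(self):
        values = np.array([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
        design = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
        with pytest.warns(UserWarning, match="ordinary t"):
            res = dm.moderated_ttest(values, design, [0.0, 1.0])
        assert res["effect"].iloc[0] == pytest.approx(3.0)
        assert res["t"].iloc[0] == pytest.approx(3.674, abs=1e-3)
        assert res["residual_df"].iloc[0] == 4

    def test_equal_residual_variances_reduce_to_ordinary_t(self):
        # identical residual layout per feature -> trigamma equation has no
        # excess dispersion -> d0 capped, s0^2 = s^2, moderated t == plain t
        rng = np.random.default_rng(1)
        base = rng.normal(size=8)
        shifts = rng.normal(size=50)
        values = base[None, :] + shifts[:, None]
        design = np.column_stack([np.ones(8), [0] * 4 + [1] * 4])
        res = dm.moderated_ttest(values, design, [0.0, 1.0])
        assert (res["prior_df"] >= dm.diffmeth.D0_CAP).all() \
            or res["prior_df"].iloc[0] > 1e6
        resid = base - np.concatenate([
            np.repeat(base[:4].mean(), 4), np.repeat(base[4:].mean(), 4)])
        s = np.sqrt((resid ** 2).sum() / 6)
        expected_t = (base[4:].mean() - base[:4].mean()) / (s * np.sqrt(0.5))
        np.testing.assert_allclose(res["t"], expected_t, atol=1e-8)

    def test_prior_df_zero_reproduces_ordinary_t(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(40, 10))
        design = np.column_stack([np.ones(10), [0] * 5 + [1] * 5])
        res = dm.moderated_ttest(values, design, [0.0, 1.0], prior_df=0)
        a, b = values[:, 5:], values[:, :5]
        sp = np.sqrt(((a - a.mean(1, keepdims=True)) ** 2).sum(1)
                     + ((b - b.mean(1, keepdims=True)) ** 2).sum(1)) / np.sqrt(8)
        t_plain = (a.mean(1) - b.mean(1)) / (sp * np.sqrt(2 / 5))
        np.testing.assert_allclose(res["t"], t_plain, atol=1e-9)

    def test_null_type_one_error_near_nominal(self):
        # Monte-Carlo: 500 independent N(0,1) features, two groups of 6
        rng = np.random.default_rng(7)
        values = rng.normal(size=(500, 12))
        design = np.column_stack([np.ones(12), [0] * 6 + [1] * 6])
        res = dm.moderated_ttest(values, design, [0.0, 1.0])
        rate = float((res["p_value"] < 0.05).mean())
        assert 0.03 <= rate <= 0.07

    def test_rank_deficient_design_names_columns(self):
        values = np.random.default_rng(0).normal(size=(5, 6))
        design = pd.DataFrame({"a": np.ones(6), "b": np.ones(6)})
        with pytest.raises(dm.diffmeth.DesignError, match="collinear"):
            dm.moderated_ttest(values, design, [1.0, 0.0])

    def test_variance_prior_recovers_known_hierarchy(self):
        # s2 ~ s0^2 * d0/chi2(d0) scaled F hierarchy, method of moments
        rng = np.random.default_rng(3)
        d0_true, s0_true, d = 8.0, 2.0, 6
        g = 20000
        true_var = s0_true * d0_true / rng.chisquare(d0_true, size=g)
        s2 = true_var * rng.chisquare(d, size=g) / d
        d0, s0 = estimate_variance_prior(s2, d)
        assert d0 == pytest.approx(d0_true, rel=0.15)
        assert s0 == pytest.approx(s0_true, rel=0.1)


class TestBhAdjust:
    @pytest.mark.parametrize("p,expected", [
        ((0.01, 0.02, 0.03, 0.04), (0.04, 0.04, 0.04, 0.04)),
        ((0.005, 0.5), (0.01, 0.5)),
    ])
    def test_hand_examples(self, p, expected):
        np.testing.assert_allclose(dm.bh_adjust(np.array(p)), expected)

    def test_matches_brute_force_on_all_permutations_of_six(self):
        base = np.array([0.001, 0.02, 0.02, 0.4, 0.7, 1.0])
        for perm in itertools.permutations(range(6)):
            p = base[list(perm)]
            np.testing.assert_allclose(dm.bh_adjust(p), brute_force_bh(p),
                                       atol=1e-15)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=12))
    def test_matches_brute_force_on_random_lists(self, p):
        p = np.array(p)
        np.testing.assert_allclose(dm.bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_uniform_nulls_rarely_pass(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=1000)
        q = dm.bh_adjust(p)
        assert (q < 0.05).mean() <= 0.01

    def test_missing_propagates_and_out_of_range_errors(self):
        q = dm.bh_adjust(np.array([0.01, np.nan, 0.5]))
        assert np.isnan(q[1]) and np.isfinite(q[0])
        with pytest.raises(ValueError):
            dm.bh_adjust(np.array([1.5]))


class TestCallDmps:
    def test_recovers_planted_effects(self, default_cohort):
        cohort, truth = default_cohort
        table, dmps = dm.call_dmps(cohort)
        called = set(dmps)
        cls = truth.probe_class
        true_eff = set(cls.index[cls.isin(["hyper", "hypo"])])
        nulls = set(cls.index[cls == "null"])
        sensitivity = len(called & true_eff) / len(true_eff)
        fdr = len(called & nulls) / max(1, len(called))
        assert sensitivity >= 0.9
        assert fdr <= 0.1

    def test_null_simulation_controls_dmps(self):
        cfg = dm.SimConfig(
            n_probes=4000, n_genes=400, seed=5, delta_beta=0.0,
            cluster_shift=0.0, cluster_block_size=0, diffuse_hypo_probes=0,
            diffuse_hypo_shift=0.0, n_promoter_hyper=0, n_promoter_hypo=0,
            nf2_promoter_effects={}, contaminated_dura=False,
            frac_dmp_hyper=0.005, frac_dmp_hypo=0.002)
        cohort, truth = dm.generate_cohort(cfg)
        assert (truth.probe_class != "null").sum() \
            == (truth.probe_class.isin(["hyper", "hypo"])).sum()
        table, dmps = dm.call_dmps(cohort)
        # with no real shifts, nothing informative passes the variability
        # filter, and whatever is tested stays mostly insignificant
        assert len(dmps) <= max(2, 2 * 0.05 * max(1, len(table)))

    def test_fdr_cutoff_zero_gives_no_dmps(self, default_cohort):
        cohort, _ = default_cohort
        _, dmps = dm.call_dmps(cohort, fdr_cutoff=0.0)
        assert dmps == []


class TestClassifyProbeShifts:
    def _mini_cohort(self, tumor_beta, dura_betas):
        samples = ["D1", "D2", "T1"]
        beta = pd.DataFrame([list(dura_betas) + [tumor_beta]],
                            index=["cgA"], columns=samples)
        intensity = beta * 0 + 100.0
        sheet = pd.DataFrame({
            "sample_id": samples, "patient_id": samples,
            "tissue": ["dura", "dura", "tumor"],
            "grade": ["unknown", "unknown", "I"],
            "nf2_status": "unknown", "sex": "F", "recurrent": False,
            "batch": "b", "excluded": False}).set_index("sample_id", drop=False)
        manifest = pd.DataFrame({"probe_id": ["cgA"], "chrom": "chr1",
                                 "pos": [5], "masked": False}
                                ).set_index("probe_id", drop=False)
        ann = pd.DataFrame({"gene_id": ["G"], "gene_name": ["G"],
                            "chrom": ["chr1"], "strand": ["+"], "start": [1],
                            "end": [2], "gene_type": ["x"]}
                           ).set_index("gene_id", drop=False)
        return build_cohort(beta, intensity, sheet, manifest, ann)

    @pytest.mark.parametrize("tumor,dura,expected", [
        (0.75, (0.5, 0.5), "hyper"),    # delta 0.25
        (0.70, (0.5, 0.5), "hyper"),    # delta exactly +0.2, inclusive
        (0.30, (0.5, 0.5), "hypo"),     # delta exactly -0.2, inclusive
        (0.31, (0.5, 0.5), "neutral"),  # delta -0.19
    ])
    def test_thresholds(self, tumor, dura, expected):
        cohort = self._mini_cohort(tumor, dura)
        counts, classes = dm.classify_probe_shifts(cohort)
        assert classes.loc["cgA", "T1"] == expected

    def test_counts_invariant_to_tumor_order(self, small_cohort):
        cohort, _ = small_cohort
        counts, _ = dm.classify_probe_shifts(cohort)
        flipped = dm.Cohort(
            beta=cohort.beta.iloc[:, ::-1], intensity=cohort.intensity.iloc[:, ::-1],
            samples=cohort.samples, manifest=cohort.manifest,
            annotation=cohort.annotation)
        counts2, _ = dm.classify_probe_shifts(flipped)
        pd.testing.assert_frame_equal(counts.sort_index(), counts2.sort_index())

    def test_diffuse_hypo_cluster_has_more_hypo_probes(self, default_cohort):
        cohort, truth = default_cohort
        counts, _ = dm.classify_probe_shifts(cohort)
        labels = truth.cluster_labels
        hypo_by_cluster = counts["hypo_count"].groupby(labels).mean()
        assert hypo_by_cluster[4] > 2 * hypo_by_cluster[1]
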