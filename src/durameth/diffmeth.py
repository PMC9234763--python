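"""Probe-level differential methylation.

Pipeline: variability filtering of probes, logit transform of beta values to
M-values, empirical-Bayes moderated t-tests of tumor vs dura, Benjamini-
Hochberg FDR, DMP calling, and per-tumor delta-beta probe classification.

The moderated t-test follows the empirical-Bayes treatment standard in
microarray analysis: per-feature least-squares fits give residual variances
``s_g^2`` with ``d_g`` residual degrees of freedom, assumed to follow a scaled
F/chi-squared hierarchy with prior ``(d0, s0^2)``.  The prior is estimated by
method of moments on ``log s_g^2`` (digamma/trigamma moment equations, Newton
inversion of the trigamma function), and the posterior variance

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

replaces ``s_g^2`` in the t statistic, which is referred to a t distribution
with ``d0 + d_g`` degrees of freedom.  When residual variances carry no excess
dispersion beyond sampling noise the trigamma equation drives ``d0`` to
infinity (capped at 1e7) and the moderated t degenerates to a z test against
``s0``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .core_io import Cohort

D0_CAP = 1e7  # prior df above this is treated as infinite


class DesignError(ValueError):
    """The design matrix cannot support the requested fit."""


@dataclass
class VariableProbeFilterParams:
    """Inclusion rules for the between-sample variability filter.

    A probe is kept iff (baseline mean beta < ``low_mean`` and at least
    ``low_tumor_frac`` of tumors have beta > ``low_tumor_beta``) or (baseline
    mean beta > ``high_mean`` and at least ``high_tumor_frac`` of tumors have
    beta < ``high_tumor_beta``).  The asymmetric 0.7 bound in the high branch
    is deliberate.  "At least 10%" is a count >= ceil(frac * n_tumors).
    """

    low_mean: float = 0.2
    low_tumor_frac: float = 0.10
    low_tumor_beta: float = 0.2
    high_mean: float = 0.8
    high_tumor_frac: float = 0.10
    high_tumor_beta: float = 0.7
    # samples over which "mean beta-value" is computed: dura (stable normal
    # baseline), tumor, or all
    mean_over: str = "dura"

    def __post_init__(self):
        for name in ("low_mean", "low_tumor_frac", "low_tumor_beta",
                     "high_mean", "high_tumor_frac", "high_tumor_beta"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.mean_over not in {"dura", "tumor", "all"}:
            raise ValueError("mean_over must be 'dura', 'tumor' or 'all'")


@dataclass
class ProbeShiftParams:
    """Delta-beta threshold for per-tumor hyper/hypomethylated probe calls."""

    delta: float = 0.2

    def __post_init__(self):
        if not 0.0 < self.delta < 1.0:
            raise ValueError("delta must be in (0,1)")


def beta_to_m(beta, epsilon: float = 1e-6):
    """logit2 transform: M = log2(beta' / (1 - beta')), beta' clipped to
    [epsilon, 1 - epsilon].  Missing values stay missing."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if isinstance(beta, pd.DataFrame) or isinstance(beta, pd.Series):
        values = beta.to_numpy(dtype=float)
    else:
        values = np.asarray(beta, dtype=float)
    clipped = np.clip(values, epsilon, 1.0 - epsilon)
    with np.errstate(invalid="ignore"):
        m = np.log2(clipped / (1.0 - clipped))
    m = np.where(np.isfinite(values), m, np.nan)
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(m, index=beta.index)
    return m


def select_analysis_probes(cohort: Cohort,
                           params: VariableProbeFilterParams | None = None,
                           ) -> list[str]:
    """Masked-probe removal followed by the variability filter.

    Returns the retained probe ids in cohort order.
    """
    params = params or VariableProbeFilterParams()
    dura = cohort.dura_ids()
    tumors = cohort.tumor_ids()
    if not dura:
        raise ValueError("variability filter requires >=1 dura sample")
    if not tumors:
        raise ValueError("variability filter requires >=1 tumor sample")

    unmasked = ~cohort.manifest["masked"].astype(bool)
    beta = cohort.beta.loc[unmasked.values]

    baseline_cols = {"dura": dura, "tumor": tumors,
                     "all": dura + tumors}[params.mean_over]
    base_mean = beta[baseline_cols].mean(axis=1, skipna=True)
    tb = beta[tumors].to_numpy(dtype=float)
    n_tumors = len(tumors)
    low_need = int(np.ceil(params.low_tumor_frac * n_tumors))
    high_need = int(np.ceil(params.high_tumor_frac * n_tumors))
    with np.errstate(invalid="ignore"):
        n_above = np.nansum(tb > params.low_tumor_beta, axis=1)
        n_below = np.nansum(tb < params.high_tumor_beta, axis=1)
    low_branch = (base_mean.to_numpy() < params.low_mean) & (n_above >= low_need)
    high_branch = (base_mean.to_numpy() > params.high_mean) & (n_below >= high_need)
    return list(beta.index[low_branch | high_branch])


# ---------------------------------------------------------------------------
# empirical-Bayes moderated t


def _trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Uses the asymptotic starting value x ~ 0.5 + 1/y and the update
    x <- x + trigamma(x) * (1 - trigamma(x)/y) / psi''(x), which is a Newton
    step on 1/trigamma (approximately linear in x).  Large y maps to small x
    and vice versa.
    """
    y = np.asarray(y, dtype=float)
    x = np.where(y > 1e7, 1.0 / np.sqrt(y), 0.5 + 1.0 / y)
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif) < 1e-10 * np.maximum(x, 1e-10)):
            break
    return x


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the (d0, s0^2) variance prior.

    Under the hierarchy, ``log s_g^2`` has mean ``log s0^2 + digamma(d/2)
    - log(d/2) - digamma(d0/2) + log(d0/2)`` and excess variance
    ``trigamma(d0/2)`` beyond the sampling term ``trigamma(d/2)``.  Inverting
    the variance equation with the trigamma inverse gives d0; plugging back
    gives s0^2.  Non-positive excess variance means no dispersion beyond
    chance: d0 is capped at D0_CAP (effectively infinite).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        raise ValueError("need >=2 positive residual variances to fit the prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = float(2.0 * _trigamma_inverse(np.array(evar)))
        if d0 > D0_CAP:
            d0 = D0_CAP
        s0_sq = float(np.exp(
            emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # no dispersion beyond chance: infinite prior df.  Exactly equal
        # variances are a degenerate input where the only sensible scale is
        # that common variance (the moderated t then collapses to the
        # ordinary statistic); variances that do fluctuate are treated as
        # pure chi-squared sampling noise around s0^2, whose log-scale
        # estimate carries the digamma/log correction.
        d0 = D0_CAP
        if z.var() < 1e-12:
            s0_sq = float(np.exp(z.mean()))
        else:
            s0_sq = float(np.exp(emean))
    return d0, s0_sq


def moderated_ttest(values, design, contrast,
                    feature_ids=None, prior_df=None,
                    prior_var=None) -> pd.DataFrame:
    """Empirical-Bayes moderated t-test of one contrast across features.

    Parameters
    ----------
    values : (features, samples) array or DataFrame
        Response matrix; must be finite (drop incomplete features upstream).
    design : (samples, coefficients) array or DataFrame
        Full-rank design matrix.
    contrast : (coefficients,) weights
        The tested linear combination of coefficients.

    Returns a DataFrame with one row per feature: ``effect`` (the contrast
    estimate), ``t``, ``p_value``, ``fdr`` (BH), ``direction`` (up/down by
    sign of effect), ``residual_df``, ``prior_df``, ``prior_var``.
    With fewer than 2 features the variance prior is not estimable and the
    ordinary t-test is returned with a warning.
    """
    if isinstance(values, pd.DataFrame):
        if feature_ids is None:
            feature_ids = values.index
        values = values.to_numpy(dtype=float)
    else:
        values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[None, :]
    X = np.asarray(design, dtype=float)
    if isinstance(design, pd.DataFrame):
        colnames = list(design.columns)
    else:
        colnames = [f"x{i}" for i in range(X.shape[1])]
    c = np.asarray(contrast, dtype=float)
    n, p = X.shape
    if values.shape[1] != n:
        raise DesignError(
            f"values have {values.shape[1]} samples but design has {n} rows")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite (apply complete-case filtering first)")

    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the collinear columns: those whose removal restores full rank
        collinear = [colnames[j] for j in range(p)
                     if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank]
        raise DesignError(f"design matrix is rank-deficient; "
                          f"collinear columns: {collinear}")
    df_resid = n - p
    if df_resid < 1:
        raise DesignError("need >=1 residual degree of freedom")

    xtx_inv = np.linalg.inv(X.T @ X)
    coef = values @ X @ xtx_inv.T          # (features, p)
    resid = values - coef @ X.T
    s2 = (resid ** 2).sum(axis=1) / df_resid
    v_c = float(c @ xtx_inv @ c)
    effect = coef @ c

    # features that are numerically constant leave rounding dust in the
    # residuals; snap variances and effects below the floating-point floor
    # to exact zero so the variance prior is fit on genuine variances only
    scale = np.maximum(np.abs(values).max(axis=1), 1.0)
    s2 = np.where(s2 < (scale * 1e-9) ** 2, 0.0, s2)
    effect = np.where(np.abs(effect) < scale * 1e-9, 0.0, effect)

    n_features = values.shape[0]
    if prior_df is not None:
        # explicit prior (e.g. prior_df=0 reproduces the ordinary t-test)
        d0 = float(prior_df)
        s0_sq = float(prior_var) if prior_var is not None else np.nan
        if d0 == 0:
            post_var = s2
        else:
            post_var = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        total_df = d0 + df_resid
    elif n_features < 2:
        warnings.warn("fewer than 2 features: variance prior not estimable, "
                      "falling back to the ordinary t-test")
        d0, s0_sq = 0.0, np.nan
        post_var = s2
        total_df = float(df_resid)
    elif np.count_nonzero(s2 > 0) < 2:
        warnings.warn("fewer than 2 features with positive residual variance; "
                      "variance prior not estimable")
        d0, s0_sq = 0.0, np.nan
        post_var = s2
        total_df = float(df_resid)
    else:
        d0, s0_sq = estimate_variance_prior(s2, df_resid)
        post_var = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        total_df = d0 + df_resid

    denom = np.sqrt(post_var * v_c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, effect / np.where(denom > 0, denom, 1.0),
                     np.where(effect == 0, 0.0, np.sign(effect) * np.inf))
    if total_df >= D0_CAP:
        p_values = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p_values = 2.0 * stats.t.sf(np.abs(t), total_df)

    result = pd.DataFrame({
        "effect": effect,
        "t": t,
        "p_value": p_values,
        "fdr": bh_adjust(p_values),
        "direction": np.where(effect >= 0, "up", "down"),
        "residual_df": float(df_resid),
        "prior_df": d0,
        "prior_var": s0_sq,
    })
    if feature_ids is not None:
        result.index = pd.Index(feature_ids, name="feature_id")
    return result


def bh_adjust(p_values):
    """Benjamini-Hochberg step-up adjusted p-values.

    q_i = min_{j >= i} (p_(j) * n / j), clipped at 1, returned in the original
    order.  Missing values are propagated and do not count toward n.
    """
    p = np.asarray(p_values, dtype=float)
    shape = p.shape
    p = p.ravel()
    ok = np.isfinite(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0,1]")
    q = np.full_like(p, np.nan)
    pv = p[ok]
    n = pv.size
    if n:
        order = np.argsort(pv, kind="mergesort")
        ranked = pv[order] * n / np.arange(1, n + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.empty(n)
        adj[order] = np.minimum(ranked, 1.0)
        q[ok] = adj
    out = q.reshape(shape)
    if isinstance(p_values, pd.Series):
        return pd.Series(out, index=p_values.index)
    return out


# ---------------------------------------------------------------------------
# composite operations


def call_dmps(cohort: Cohort,
              filter_params: VariableProbeFilterParams | None = None,
              fdr_cutoff: float = 0.05) -> tuple[pd.DataFrame, list[str]]:
    """Tumor-vs-dura DMP calling.

    Composes probe filtering -> M-value transform -> two-group moderated
    t-test (unpaired, contrast tumor - dura) -> BH adjustment.  Probes with
    any missing value among the tested samples are dropped (complete case).
    Returns the per-probe statistics table and the DMP id list (fdr < cutoff).
    """
    probes = select_analysis_probes(cohort, filter_params)
    dura = cohort.dura_ids()
    tumors = cohort.tumor_ids()
    samples = dura + tumors
    beta = cohort.beta.loc[probes, samples]
    complete = beta.notna().all(axis=1)
    beta = beta.loc[complete]
    if len(beta) == 0:
        empty = pd.DataFrame(columns=["effect", "t", "p_value", "fdr",
                                      "direction", "residual_df",
                                      "prior_df", "prior_var"])
        empty.index.name = "feature_id"
        return empty, []
    m = beta_to_m(beta)
    design = pd.DataFrame({
        "intercept": 1.0,
        "tumor": [0.0] * len(dura) + [1.0] * len(tumors),
    }, index=samples)
    res = moderated_ttest(m, design, contrast=[0.0, 1.0], feature_ids=beta.index)
    dmps = list(res.index[res["fdr"] < fdr_cutoff])
    return res, dmps


def classify_probe_shifts(cohort: Cohort,
                          params: ProbeShiftParams | None = None,
                          probe_ids=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-tumor delta-beta probe classification against the dura baseline.

    For tumor t and probe g: hyper iff beta_tg - mean_dura(beta_g) >= delta,
    hypo iff <= -delta, else neutral; thresholds inclusive.  Returns
    (per-tumor count table with columns hyper_count/hypo_count, per-probe
    per-tumor class matrix with values {hyper, hypo, neutral}).
    """
    params = params or ProbeShiftParams()
    dura = cohort.dura_ids()
    if not dura:
        raise ValueError("probe-shift classification requires >=1 dura sample")
    tumors = cohort.tumor_ids()
    beta = cohort.beta if probe_ids is None else cohort.beta.loc[probe_ids]
    dura_mean = beta[dura].mean(axis=1, skipna=True)
    delta = beta[tumors].sub(dura_mean, axis=0)
    arr = delta.to_numpy(dtype=float)
    classes = np.full(arr.shape, "neutral", dtype=object)
    # inclusive thresholds, with a hair of slack so decimal inputs that land
    # exactly on the printed boundary are not lost to binary rounding
    with np.errstate(invalid="ignore"):
        classes[arr >= params.delta - 1e-12] = "hyper"
        classes[arr <= -(params.delta - 1e-12)] = "hypo"
    classes[~np.isfinite(arr)] = "missing"
    class_df = pd.DataFrame(classes, index=delta.index, columns=tumors)
    counts = pd.DataFrame({
        "hyper_count": (class_df == "hyper").sum(axis=0),
        "hypo_count": (class_df == "hypo").sum(axis=0),
    })
    counts.index.name = "sample_id"
    return counts, class_df
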