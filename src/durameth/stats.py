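"""Shared statistics: chi-squared association, one-way ANOVA with Tukey HSD,
hypergeometric gene-set over-representation, qPCR delta-delta-Ct fold change,
and somatic-variant filtering."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .allowlist_synthetic import DEFAULT_GENE_ALLOWLIST
from .core_io import GeneSetCollection


@dataclass
class Chi2Result:
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray


def pearson_chi2(table, correction: bool = False) -> Chi2Result:
    """Pearson chi-squared test of independence on an r x c count table.

    No continuity correction by default (``correction=True`` applies the
    Yates correction for 2x2 tables only).  Rows/columns with zero margins
    are dropped with a warning; a resulting degenerate table is an error.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if (obs < 0).any() or not np.allclose(obs, np.round(obs)):
        raise ValueError("table must contain non-negative integer counts")
    row_ok = obs.sum(axis=1) > 0
    col_ok = obs.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        warnings.warn("dropping zero-margin rows/columns")
        obs = obs[np.ix_(row_ok, col_ok)]
    r, c = obs.shape
    df = (r - 1) * (c - 1)
    if df < 1:
        raise ValueError("degenerate table: zero degrees of freedom")
    total = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    diff = np.abs(obs - expected)
    if correction and r == 2 and c == 2:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float(np.sum(diff ** 2 / expected))
    p = float(sps.chi2.sf(stat, df))
    return Chi2Result(statistic=stat, df=df, p_value=p, expected=expected)


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    tukey: pd.DataFrame  # columns: group_a, group_b, diff, p_adj


def anova_tukey(values, groups) -> AnovaResult:
    """One-way ANOVA with Tukey HSD post-hoc pairwise comparisons.

    Groups of size 1 enter the ANOVA but are excluded from the HSD table
    with a warning.  All-identical values give F=0, p=1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must align")
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need >=2 groups")
    arrays = {lev: values[groups == lev] for lev in levels}
    if sum(len(a) for a in arrays.values()) - len(levels) < 2:
        raise ValueError("need >=2 residual degrees of freedom")
    if np.ptp(values) == 0:
        f, p = 0.0, 1.0
    else:
        f, p = sps.f_oneway(*arrays.values())
        f, p = float(f), float(p)
        if not np.isfinite(f):  # zero within-group variance
            f, p = np.inf, 0.0
    hsd_levels = [lev for lev in levels if len(arrays[lev]) >= 2]
    if len(hsd_levels) < len(levels):
        warnings.warn("groups with n=1 excluded from Tukey HSD")
    rows = []
    if len(hsd_levels) >= 2 and np.ptp(values) > 0:
        res = sps.tukey_hsd(*[arrays[lev] for lev in hsd_levels])
        for i, a in enumerate(hsd_levels):
            for j, b in enumerate(hsd_levels):
                if j <= i:
                    continue
                rows.append({
                    "group_a": a, "group_b": b,
                    "diff": float(arrays[a].mean() - arrays[b].mean()),
                    "p_adj": float(res.pvalue[i, j]),
                })
    tukey = pd.DataFrame(rows, columns=["group_a", "group_b", "diff", "p_adj"])
    return AnovaResult(f_statistic=f, p_value=p, tukey=tukey)


# ---------------------------------------------------------------------------
# gene-set over-representation


@dataclass
class EnrichmentParams:
    p_cutoff: float = 0.05
    q_cutoff: float = 0.2
    min_set_size: int = 3
    max_set_size: int = 2000

    def __post_init__(self):
        for name in ("p_cutoff", "q_cutoff"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1)")


def hypergeometric_enrichment(query, universe, sets: GeneSetCollection,
                              params: EnrichmentParams | None = None,
                              ) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` genes in each set.

    For a universe of N genes of which K are in the set and a query of n
    genes with k in the set, p = P(X >= k) under the hypergeometric null.
    q-values are BH-adjusted p over the tested sets; a set is enriched iff
    p < p_cutoff and q < q_cutoff.  Query genes outside the universe are
    dropped with a warning; sets are intersected with the universe and then
    size-filtered.
    """
    from .diffmeth import bh_adjust

    params = params or EnrichmentParams()
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    stray = query - universe
    if stray:
        warnings.warn(f"{len(stray)} query genes outside the universe dropped")
        query &= universe
    N, n = len(universe), len(query)
    rows = []
    for name, members in sets.items():
        members = members & universe
        K = len(members)
        if not params.min_set_size <= K <= params.max_set_size:
            continue
        k = len(query & members)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set": name, "k": k, "K": K, "n": n, "N": N,
                     "p_value": p,
                     "overlap": ",".join(sorted(query & members))})
    out = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N",
                                      "p_value", "overlap"])
    if len(out):
        out["q_value"] = bh_adjust(out["p_value"].to_numpy())
        out["enriched"] = (out["p_value"] < params.p_cutoff) & \
                          (out["q_value"] < params.q_cutoff)
        out = out.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    else:
        out["q_value"] = []
        out["enriched"] = []
    return out


# ---------------------------------------------------------------------------
# qPCR delta-delta-Ct


def ddct_fold_change(table: pd.DataFrame) -> pd.DataFrame:
    """Relative expression by the mean 2^-(ddCt) method.

    Input rows: sample_id, condition ({case, control}), target_ct,
    reference_ct, replicate.  Per sample, replicate (target - reference)
    differences are averaged into dCt; ddCt subtracts the control-group mean
    dCt; fold change is 2^-ddCt.  Control samples against their own mean are
    reported too (their geometric-mean fold is 1 by construction only when a
    single control sample exists).
    """
    required = {"sample_id", "condition", "target_ct", "reference_ct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    t = table.copy()
    for col in ("target_ct", "reference_ct"):
        t[col] = pd.to_numeric(t[col])
        if (t[col] <= 0).any():
            raise ValueError("Ct values must be positive")
    if not set(t["condition"]) <= {"case", "control"}:
        raise ValueError("condition must be 'case' or 'control'")
    if "control" not in set(t["condition"]):
        raise ValueError("no control samples present")
    t["dct"] = t["target_ct"] - t["reference_ct"]
    per_sample = t.groupby(["sample_id", "condition"], as_index=False)["dct"].mean()
    control_mean = per_sample.loc[per_sample["condition"] == "control", "dct"].mean()
    per_sample["ddct"] = per_sample["dct"] - control_mean
    per_sample["fold_change"] = 2.0 ** (-per_sample["ddct"])
    return per_sample.set_index("sample_id")


# ---------------------------------------------------------------------------
# somatic-variant filtering


@dataclass
class VariantFilterParams:
    """Inclusion rules for annotated somatic variants.

    Strictness follows the stated rules exactly: gnomAD allele frequency
    strictly below the cutoff (missing = absent from the population database,
    treated as 0), variant allele fraction strictly above, supporting reads
    at least the minimum, exonic only, gene on the cancer-gene allowlist.
    """

    max_gnomad_af: float = 0.0001
    min_vaf: float = 0.05
    min_alt_reads: int = 5
    gene_allowlist: frozenset[str] = field(
        default_factory=lambda: frozenset(DEFAULT_GENE_ALLOWLIST))
    require_exonic: bool = True


VARIANT_COLUMNS = ["gene", "func", "gnomad_af", "vaf", "alt_reads"]


def filter_somatic_variants(variants: pd.DataFrame,
                            params: VariantFilterParams | None = None,
                            ) -> pd.DataFrame:
    """Apply the somatic-variant inclusion rules; idempotent."""
    params = params or VariantFilterParams()
    missing = set(VARIANT_COLUMNS) - set(variants.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    if len(variants) == 0:
        return variants.copy()
    af = pd.to_numeric(variants["gnomad_af"], errors="coerce").fillna(0.0)
    vaf = pd.to_numeric(variants["vaf"])
    alt = pd.to_numeric(variants["alt_reads"])
    keep = (af < params.max_gnomad_af) & (vaf > params.min_vaf) & \
           (alt >= params.min_alt_reads) & \
           variants["gene"].isin(params.gene_allowlist)
    if params.require_exonic:
        keep &= variants["func"] == "exonic"
    return variants.loc[keep].copy()
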