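"""Consensus k-means subtype discovery, k selection, and PCA screening.

Consensus clustering repeatedly subsamples items, clusters each subsample
with k-means under the Euclidean metric, and records for every item pair how
often the two items land in the same cluster among the repetitions in which
both were drawn.  The resulting consensus matrix is clustered hierarchically
to yield final labels per k, and the number of clusters is chosen by the
relative change in area under the consensus CDF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .stats import pearson_chi2


@dataclass
class ConsensusParams:
    max_k: int = 20
    reps: int = 1000
    item_subsample: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.max_k < 2:
            raise ValueError("max_k must be >= 2")
        if not 0.0 < self.item_subsample <= 1.0:
            raise ValueError("item_subsample must be in (0,1]")


@dataclass
class ConsensusResult:
    """Per-k consensus matrices and labels, plus the CDF-area k selection."""

    item_ids: list
    consensus: dict[int, np.ndarray]       # k -> items x items matrix in [0,1]
    labels: dict[int, np.ndarray]          # k -> integer labels (1-based)
    cdf_areas: dict[int, float] = field(default_factory=dict)
    delta_areas: dict[int, float] = field(default_factory=dict)
    selected_k: int | None = None

    def labels_series(self, k: int | None = None) -> pd.Series:
        k = k if k is not None else self.selected_k
        return pd.Series(self.labels[k], index=self.item_ids, name=f"k{k}")


def consensus_cluster(data, params: ConsensusParams | None = None,
                      item_ids=None) -> ConsensusResult:
    """Consensus k-means over subsampled items for k = 2..max_k.

    ``data`` is items x features.  Each repetition draws
    ``floor(item_subsample * n)`` items without replacement, runs k-means
    (k-means++ init, n_init=10) for every k, and accumulates co-clustering
    and co-sampling counts.  Consensus entries are the ratio of the two; item
    pairs never co-sampled get 0 with a warning.  Final labels per k come
    from average-linkage hierarchical clustering of 1 - consensus.
    """
    params = params or ConsensusParams()
    if isinstance(data, pd.DataFrame):
        if item_ids is None:
            item_ids = list(data.index)
        data = data.to_numpy(dtype=float)
    else:
        data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if item_ids is None:
        item_ids = list(range(n))
    if n < 3:
        raise ValueError("need at least 3 items")
    if params.max_k >= n:
        raise ValueError(f"max_k ({params.max_k}) must be < n_items ({n})")
    if not np.all(np.isfinite(data)):
        raise ValueError("features must be finite")

    rng = np.random.default_rng(params.seed)
    n_sub = max(2, int(np.floor(params.item_subsample * n)))
    ks = range(2, params.max_k + 1)
    together = {k: np.zeros((n, n)) for k in ks}
    cosampled = np.zeros((n, n))

    for _ in range(params.reps):
        idx = np.sort(rng.choice(n, size=n_sub, replace=False))
        sub = data[idx]
        m = np.zeros((n, n))
        m[np.ix_(idx, idx)] = 1.0
        cosampled += m
        for k in ks:
            if k >= n_sub:
                continue
            km = KMeans(n_clusters=k, init="k-means++", n_init=10,
                        random_state=int(rng.integers(2 ** 31)))
            lab = km.fit_predict(sub)
            same = (lab[:, None] == lab[None, :]).astype(float)
            together[k][np.ix_(idx, idx)] += same

    if np.any(cosampled[np.triu_indices(n, 1)] == 0):
        warnings.warn("some item pairs were never co-sampled; "
                      "their consensus is imputed as 0")
    consensus, labels = {}, {}
    for k in ks:
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.where(cosampled > 0, together[k] / np.maximum(cosampled, 1), 0.0)
        np.fill_diagonal(c, 1.0)
        c = (c + c.T) / 2.0
        consensus[k] = c
        d = 1.0 - c
        np.fill_diagonal(d, 0.0)
        link = hierarchy.linkage(squareform(d, checks=False), method="average")
        labels[k] = hierarchy.fcluster(link, t=k, criterion="maxclust")

    result = ConsensusResult(item_ids=list(item_ids),
                             consensus=consensus, labels=labels)
    select_k(result)
    return result


def _cdf_area(entries: np.ndarray) -> float:
    """Area under the empirical CDF of consensus entries over [0,1]."""
    x = np.sort(entries)
    n = x.size
    # right-continuous step CDF: integral = sum over steps of width * height
    xs = np.concatenate([x, [1.0]])
    heights = np.arange(1, n + 1) / n
    widths = np.diff(xs)
    return float(np.sum(widths * heights))


def select_k(result: ConsensusResult, delta_threshold: float = 0.05,
             pac_bounds: tuple[float, float] = (0.1, 0.9)) -> int:
    """Choose k from the consensus-CDF delta areas and consensus ambiguity.

    A(k) is the area under the empirical CDF of the off-diagonal consensus
    entries (equivalently 1 - mean consensus); Delta(2) = A(2) and
    Delta(k) = (A(k) - A(k-1)) / A(k-1) for k > 2.  Candidate values of k
    are those whose CDF area still gains at least ``delta_threshold``
    relative area.  Splitting a true cluster one step too far keeps adding
    area (the arbitrary split of a coherent cluster flips between
    subsamples), so the relative delta alone over-segments; among the
    candidates the selected k is therefore the one whose consensus matrix
    is least ambiguous — minimal PAC, the fraction of off-diagonal entries
    inside ``pac_bounds`` — with ties resolved toward the largest candidate
    (the finest stable partition).  Degenerate structure (no candidate)
    returns 2 with a warning.
    """
    ks = sorted(result.consensus)
    iu = np.triu_indices(len(result.item_ids), 1)
    areas = {k: _cdf_area(result.consensus[k][iu]) for k in ks}
    deltas: dict[int, float] = {}
    prev = None
    for k in ks:
        if prev is None:
            deltas[k] = areas[k]
        else:
            deltas[k] = (areas[k] - areas[prev]) / areas[prev] if areas[prev] > 0 else 0.0
        prev = k
    result.cdf_areas = areas
    result.delta_areas = deltas
    candidates = [k for k in ks if deltas[k] >= delta_threshold]
    if not candidates:
        warnings.warn("no k shows a consensus-CDF area gain above the "
                      "threshold; structure is degenerate, returning k=2")
        result.selected_k = ks[0]
        return ks[0]
    lo, hi = pac_bounds
    pac = {k: float(np.mean((result.consensus[k][iu] > lo)
                            & (result.consensus[k][iu] < hi)))
           for k in candidates}
    best = min(pac.values())
    selected = max(k for k in candidates if pac[k] == best)
    result.selected_k = selected
    return selected


def pca_explained_variance(values) -> np.ndarray:
    """Fraction of variance per principal component of a samples x features
    matrix (column-centered SVD); fractions sum to 1."""
    x = np.asarray(values, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need >=2 samples")
    x = x - x.mean(axis=0, keepdims=True)
    s = np.linalg.svd(x, compute_uv=False)
    total = np.sum(s ** 2)
    if total == 0:
        raise ValueError("no variance: constant matrix")
    return s ** 2 / total


def pca_components(values, n_components: int | None = None) -> np.ndarray:
    """Sample scores on the principal components (column-centered SVD)."""
    x = np.asarray(values, dtype=float)
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u * s
    if n_components is not None:
        scores = scores[:, :n_components]
    return scores


def covariate_component_screen(components, sample_sheet: pd.DataFrame,
                               covariates: list[str]) -> pd.DataFrame:
    """p-values relating each principal component to each sample covariate.

    Categorical covariates (non-numeric) use Kruskal-Wallis across levels;
    numeric covariates use the p-value of the slope in a simple linear
    regression.  Missing covariate values are dropped pairwise; a covariate
    with a single observed level yields a missing p with a warning.
    """
    comp = np.asarray(components, dtype=float)
    if comp.ndim == 1:
        comp = comp[:, None]
    missing = [c for c in covariates if c not in sample_sheet.columns]
    if missing:
        raise KeyError(f"covariates not in sample sheet: {missing}")
    out = pd.DataFrame(
        np.nan, index=[f"PC{i+1}" for i in range(comp.shape[1])],
        columns=covariates)
    for cov in covariates:
        raw = sample_sheet[cov]
        numeric = pd.to_numeric(raw, errors="coerce")
        treat_numeric = (numeric.notna() | raw.isna()).all() and numeric.notna().any()
        for i in range(comp.shape[1]):
            pc = comp[:, i]
            if treat_numeric:
                ok = numeric.notna().to_numpy()
                if ok.sum() < 3 or numeric[ok].nunique() < 2:
                    warnings.warn(f"covariate {cov!r} has <2 levels; p set missing")
                    continue
                res = stats.linregress(numeric.to_numpy(dtype=float)[ok], pc[ok])
                out.iloc[i, out.columns.get_loc(cov)] = res.pvalue
            else:
                vals = raw.astype(object)
                ok = vals.notna().to_numpy() & (vals != "unknown").to_numpy()
                levels = pd.unique(vals[ok])
                if len(levels) < 2:
                    warnings.warn(f"covariate {cov!r} has <2 levels; p set missing")
                    continue
                groups = [pc[ok & (vals == lev).to_numpy()] for lev in levels]
                stat = stats.kruskal(*groups)
                out.iloc[i, out.columns.get_loc(cov)] = stat.pvalue
    return out


def cluster_grade_association(labels, grades):
    """Chi-squared test of the cluster x grade contingency table."""
    labels = pd.Series(list(labels))
    grades = pd.Series(list(grades))
    if len(labels) == 0 or len(labels) != len(grades):
        raise ValueError("labels and grades must be non-empty and aligned")
    table = pd.crosstab(labels, grades)
    return pearson_chi2(table.to_numpy())
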