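"""Copy-number analysis from combined array intensities.

The combined (methylated + unmethylated) signal of each probe carries copy
number: per sample, log2 intensities are median-centered, subtracted from a
pooled-control (dura) reference, averaged within genomic bins of 50-5000 kb,
re-centered so the genome-wide median ratio is zero, segmented with circular
binary segmentation (CBS), and thresholded at +/-0.25 into
amplified / neutral / deleted calls.  An independent branch calls locus
status from externally produced integer-copy-number intervals.

CBS here is the classical recursive changepoint scheme: on each segment the
maximal standardized arc statistic over all circular arcs is referred to a
permutation null; a significant arc splits the segment and recursion
continues on the parts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import Cohort


@dataclass
class CnvParams:
    min_bin_size: int = 50_000
    max_bin_size: int = 5_000_000
    min_probes_per_bin: int = 15
    call_cutoff: float = 0.25      # |log2 ratio| at/above which a bin is altered
    cbs_alpha: float = 0.01
    cbs_nperm: int = 1000
    cbs_min_width: int = 3         # bins per arm
    seed: int = 0

    def __post_init__(self):
        if self.min_bin_size > self.max_bin_size:
            raise ValueError("min_bin_size must be <= max_bin_size")
        if self.call_cutoff <= 0:
            raise ValueError("call_cutoff must be positive")


@dataclass
class LocusDetailList:
    """Named loci (gene or cytoband) to report individually."""

    loci: pd.DataFrame  # columns: name, chrom, start, end (1-based inclusive)

    def __post_init__(self):
        req = {"name", "chrom", "start", "end"}
        missing = req - set(self.loci.columns)
        if missing:
            raise ValueError(f"locus list missing columns: {sorted(missing)}")
        if (self.loci["start"] > self.loci["end"]).any():
            raise ValueError("locus start > end")


# ---------------------------------------------------------------------------
# binning


def build_bins(manifest: pd.DataFrame, params: CnvParams | None = None,
               ) -> pd.DataFrame:
    """Tile each chromosome into probe-backed bins of 50-5000 kb.

    The probe-covered span of each chromosome is tiled in ``min_bin_size``
    windows; adjacent windows are merged greedily until a bin holds at least
    ``min_probes_per_bin`` probes, without exceeding ``max_bin_size``; a
    trailing underfilled window merges backward into the previous bin.
    Masked probes are excluded.  Returns a DataFrame with columns
    bin_id, chrom, start, end, n_probes, probes (list of probe ids).
    """
    params = params or CnvParams()
    probes = manifest[~manifest["masked"].astype(bool)]
    if len(probes) == 0:
        raise ValueError("manifest has no unmasked probes")
    records = []
    for chrom, sub in probes.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy(dtype=np.int64)
        ids = sub["probe_id"].to_numpy()
        order = np.argsort(pos, kind="mergesort")
        pos, ids = pos[order], ids[order]
        span_lo, span_hi = int(pos[0]), int(pos[-1])
        if len(pos) < params.min_probes_per_bin:
            warnings.warn(f"chromosome {chrom} has only {len(pos)} probes; "
                          "emitting a single bin")
            records.append((chrom, span_lo, span_hi, list(ids)))
            continue
        edges = np.arange(span_lo, span_hi + params.min_bin_size,
                          params.min_bin_size, dtype=np.int64)
        # window w covers [edges[w], edges[w+1]-1], 1-based inclusive
        cur_start, cur_probes = None, []
        for w in range(len(edges) - 1):
            lo, hi = int(edges[w]), int(edges[w + 1] - 1)
            sel = (pos >= lo) & (pos <= hi)
            if cur_start is None:
                cur_start, cur_probes = lo, list(ids[sel])
            else:
                cur_probes.extend(ids[sel])
            width = hi - cur_start + 1
            if len(cur_probes) >= params.min_probes_per_bin or \
                    width + params.min_bin_size > params.max_bin_size:
                records.append((chrom, cur_start, hi, cur_probes))
                cur_start, cur_probes = None, []
        if cur_start is not None:
            # trailing underfilled window merges backward
            if records and records[-1][0] == chrom:
                prev = records.pop()
                records.append((chrom, prev[1], int(edges[-1] - 1),
                                prev[3] + cur_probes))
            else:
                records.append((chrom, cur_start, int(edges[-1] - 1), cur_probes))
    bins = pd.DataFrame(records, columns=["chrom", "start", "end", "probes"])
    bins["n_probes"] = bins["probes"].map(len)
    bins.insert(0, "bin_id", [f"{c}:{s}-{e}" for c, s, e in
                              zip(bins["chrom"], bins["start"], bins["end"])])
    return bins[["bin_id", "chrom", "start", "end", "n_probes", "probes"]]


# ---------------------------------------------------------------------------
# log2 ratios


def bin_log2_ratios(cohort: Cohort, bins: pd.DataFrame,
                    control_ids: list[str] | None = None,
                    sample_ids: list[str] | None = None) -> pd.DataFrame:
    """Per-sample bin log2 ratios against a pooled control reference.

    Per sample, probe log2 intensities are median-centered; the reference is
    the mean centered log-intensity over the controls; each bin's ratio is
    the mean over its probes of (sample - reference); finally each sample is
    shifted so its genome-wide median bin ratio is zero.  Probes with
    non-positive intensity are dropped for that sample with a count warning.
    """
    control_ids = control_ids if control_ids is not None else cohort.dura_ids()
    if not control_ids:
        raise ValueError("need >=1 control sample")
    if sample_ids is None:
        sample_ids = cohort.tumor_ids()
    cols = list(dict.fromkeys(list(control_ids) + list(sample_ids)))
    inten = cohort.intensity[cols].to_numpy(dtype=float)
    bad = ~(np.isfinite(inten) & (inten > 0))
    if bad.any():
        warnings.warn(f"{int(bad.sum())} non-positive/missing intensity values "
                      "dropped")
    with np.errstate(divide="ignore", invalid="ignore"):
        logi = np.where(bad, np.nan, np.log2(np.where(bad, 1.0, inten)))
    logi = logi - np.nanmedian(logi, axis=0, keepdims=True)
    logi_df = pd.DataFrame(logi, index=cohort.intensity.index, columns=cols)
    reference = logi_df[list(control_ids)].mean(axis=1, skipna=True)
    diff = logi_df[sample_ids].sub(reference, axis=0)

    probe_loc = {p: i for i, p in enumerate(diff.index)}
    dvals = diff.to_numpy()
    ratio_rows = []
    for probes in bins["probes"]:
        idx = [probe_loc[p] for p in probes if p in probe_loc]
        if idx:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                ratio_rows.append(np.nanmean(dvals[idx], axis=0))
        else:
            ratio_rows.append(np.full(len(sample_ids), np.nan))
    ratios = pd.DataFrame(ratio_rows, index=bins["bin_id"].to_numpy(),
                          columns=sample_ids)
    ratios -= ratios.median(axis=0, skipna=True)
    ratios.index.name = "bin_id"
    return ratios


# ---------------------------------------------------------------------------
# circular binary segmentation


def _max_arc_stat(x: np.ndarray, min_width: int) -> tuple[float, int, int]:
    """Maximal standardized circular-arc mean-shift statistic.

    For arc (i, j] of length m out of n, the statistic is
    |S_j - S_i - m * xbar| / (sigma * sqrt(m (n - m) / n)), the z form of the
    two-sample comparison of arc vs complement with the global variance.
    Returns (max statistic, i, j).
    """
    n = x.size
    sigma = x.std()
    if sigma == 0 or n < 2 * min_width:
        return 0.0, 0, n
    s = np.concatenate([[0.0], np.cumsum(x - x.mean())])
    best, bi, bj = 0.0, 0, n
    for m in range(min_width, n - min_width + 1):
        d = s[m:] - s[:-m]                     # arc sums, all starts
        scale = sigma * np.sqrt(m * (n - m) / n)
        z = np.abs(d) / scale
        k = int(np.argmax(z))
        if z[k] > best:
            best, bi, bj = float(z[k]), k, k + m
    return best, bi, bj


def _perm_pvalue(x: np.ndarray, observed: float, min_width: int,
                 nperm: int, rng: np.random.Generator) -> float:
    """Permutation p-value of the max arc statistic (vectorized over m)."""
    n = x.size
    sigma = x.std()
    if sigma == 0:
        return 1.0
    perms = np.array([rng.permutation(x) for _ in range(nperm)])
    centered = perms - perms.mean(axis=1, keepdims=True)
    s = np.concatenate([np.zeros((nperm, 1)), np.cumsum(centered, axis=1)],
                       axis=1)
    sigmas = perms.std(axis=1)
    best = np.zeros(nperm)
    for m in range(min_width, n - min_width + 1):
        d = np.abs(s[:, m:] - s[:, :-m]).max(axis=1)
        scale = sigmas * np.sqrt(m * (n - m) / n)
        np.maximum(best, d / scale, out=best)
    exceed = int(np.sum(best >= observed))
    return (1 + exceed) / (1 + nperm)


def _segment_one(x: np.ndarray, offset: int, params: CnvParams,
                 rng: np.random.Generator, out: list[tuple[int, int]]) -> None:
    n = x.size
    if n < 2 * params.cbs_min_width:
        out.append((offset, offset + n))
        return
    stat, i, j = _max_arc_stat(x, params.cbs_min_width)
    if stat == 0.0:
        out.append((offset, offset + n))
        return
    p = _perm_pvalue(x, stat, params.cbs_min_width, params.cbs_nperm, rng)
    if p > params.cbs_alpha:
        out.append((offset, offset + n))
        return
    pieces = [(0, i), (i, j), (j, n)]
    for lo, hi in pieces:
        if hi > lo:
            _segment_one(x[lo:hi], offset + lo, params, rng, out)


def cbs_segment(bin_ratios: pd.DataFrame, bins: pd.DataFrame,
                params: CnvParams | None = None) -> pd.DataFrame:
    """Circular binary segmentation of each sample's bin ratios per chromosome.

    Returns a SEG-style table: sample, chrom, start, end, n_bins, seg_mean.
    Segments partition each chromosome's bins for each sample.
    """
    params = params or CnvParams()
    bins = bins.set_index("bin_id").loc[bin_ratios.index]
    rows = []
    for sample in bin_ratios.columns:
        rng = np.random.default_rng(
            np.random.SeedSequence([params.seed, _stable_hash(sample)]))
        for chrom, sub in bins.groupby("chrom", sort=True):
            x = bin_ratios.loc[sub.index, sample].to_numpy(dtype=float)
            keep = np.isfinite(x)
            xs = x[keep]
            sub_kept = sub[keep]
            if xs.size == 0:
                continue
            pieces: list[tuple[int, int]] = []
            _segment_one(xs, 0, params, rng, pieces)
            for lo, hi in sorted(pieces):
                seg_bins = sub_kept.iloc[lo:hi]
                rows.append({
                    "sample": sample, "chrom": chrom,
                    "start": int(seg_bins["start"].iloc[0]),
                    "end": int(seg_bins["end"].iloc[-1]),
                    "n_bins": hi - lo,
                    "seg_mean": float(xs[lo:hi].mean()),
                })
    return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end",
                                       "n_bins", "seg_mean"])


def _stable_hash(text: str) -> int:
    h = 0
    for ch in str(text):
        h = (h * 131 + ord(ch)) % (2 ** 31 - 1)
    return h


# ---------------------------------------------------------------------------
# calls


def classify_ratio(values, cutoff: float = 0.25):
    """amplified iff >= +cutoff, deleted iff <= -cutoff, else neutral
    (boundaries inclusive to the altered classes)."""
    arr = np.asarray(values, dtype=float)
    out = np.full(arr.shape, "neutral", dtype=object)
    with np.errstate(invalid="ignore"):
        out[arr >= cutoff] = "amplified"
        out[arr <= -cutoff] = "deleted"
    out[~np.isfinite(arr)] = "missing"
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index)
    if np.isscalar(values):
        return out.item()
    return out


def locus_detail_report(bin_ratios: pd.DataFrame, bins: pd.DataFrame,
                        loci: LocusDetailList, cutoff: float = 0.25,
                        ) -> pd.DataFrame:
    """Per-locus, per-sample mean bin ratio and amplified/neutral/deleted call.

    A locus's value is the mean ratio of the bins it overlaps (1-based
    inclusive interval overlap); loci overlapping no bin get a missing call
    with a warning.  Returns a long table: locus, sample, ratio, call.
    """
    bins = bins.set_index("bin_id").loc[bin_ratios.index]
    rows = []
    for _, locus in loci.loci.iterrows():
        sel = (bins["chrom"] == locus["chrom"]) & \
              (bins["start"] <= int(locus["end"])) & \
              (bins["end"] >= int(locus["start"]))
        if not sel.any():
            warnings.warn(f"locus {locus['name']} overlaps no bins; call missing")
            for sample in bin_ratios.columns:
                rows.append({"locus": locus["name"], "sample": sample,
                             "ratio": np.nan, "call": "missing"})
            continue
        means = bin_ratios.loc[sel.to_numpy()].mean(axis=0, skipna=True)
        for sample in bin_ratios.columns:
            v = float(means[sample])
            rows.append({"locus": locus["name"], "sample": sample,
                         "ratio": v, "call": classify_ratio(v, cutoff)})
    return pd.DataFrame(rows, columns=["locus", "sample", "ratio", "call"])


def call_loci_from_cn_intervals(cnv_intervals: pd.DataFrame,
                                loci: LocusDetailList) -> pd.DataFrame:
    """Locus status from externally called integer-copy-number intervals.

    A locus is deleted iff it overlaps any interval with copy number < 2 for
    that sample, amplified iff it overlaps any with copy number > 2, both ->
    "conflict", neither -> neutral.  Intervals are 1-based inclusive.
    """
    req = {"sample", "chrom", "start", "end", "copy_number"}
    missing = req - set(cnv_intervals.columns)
    if missing:
        raise ValueError(f"interval table missing columns: {sorted(missing)}")
    if len(cnv_intervals) and \
            (cnv_intervals["start"] > cnv_intervals["end"]).any():
        raise ValueError("malformed interval: start > end")
    if len(cnv_intervals) and (
            (cnv_intervals["copy_number"] < 0).any()
            or (cnv_intervals["copy_number"] !=
                cnv_intervals["copy_number"].astype(int)).any()):
        raise ValueError("copy numbers must be non-negative integers")
    samples = sorted(cnv_intervals["sample"].unique()) if len(cnv_intervals) else []
    rows = []
    for sample in samples:
        ivals = cnv_intervals[cnv_intervals["sample"] == sample]
        for _, locus in loci.loci.iterrows():
            hit = ivals[(ivals["chrom"] == locus["chrom"]) &
                        (ivals["start"] <= int(locus["end"])) &
                        (ivals["end"] >= int(locus["start"]))]
            deleted = (hit["copy_number"] < 2).any()
            amplified = (hit["copy_number"] > 2).any()
            if deleted and amplified:
                call = "conflict"
            elif deleted:
                call = "deleted"
            elif amplified:
                call = "amplified"
            else:
                call = "neutral"
            rows.append({"locus": locus["name"], "sample": sample, "call": call})
    return pd.DataFrame(rows, columns=["locus", "sample", "call"])


def cnv_burden(bin_calls: pd.DataFrame) -> pd.Series:
    """Count of non-neutral bins per sample (columns = samples)."""
    altered = bin_calls.isin(["amplified", "deleted"])
    counts = altered.sum(axis=0)
    counts.name = "altered_bins"
    return counts


def write_seg(segments: pd.DataFrame, path) -> None:
    """Write segments in SEG format (ID, chrom, loc.start, loc.end,
    num.mark, seg.mean)."""
    out = segments.rename(columns={
        "sample": "ID", "start": "loc.start", "end": "loc.end",
        "n_bins": "num.mark", "seg_mean": "seg.mean"})
    out.to_csv(path, sep="\t", index=False)
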