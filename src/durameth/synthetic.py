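"""Synthetic 450K-style cohort generator with ground truth.

Emulates the statistical structure the analysis assumes — matched dura/tumor
pairs plus unpaired tumors, four planted methylation clusters (one with
diffuse hypomethylation), planted hyper-/hypomethylated probes and promoters
with beta-distributed noise, NF2-group-specific promoter effects in the
paired subcohort, planted copy-number segments in the intensity channel, and
an optional tumor-contaminated dura sample — so every downstream stage can
be tested against known truth without any external download.

Genome model: ``n_chromosomes`` synthetic chromosomes of ``chrom_length`` bp.
Probes are promoter-enriched: each gene carries ``probes_per_promoter``
probes inside its TSS +/- 2 kb window (so promoter percent-methylation has a
non-trivial denominator), and the remaining probes are uniformly spaced
background.  Beta noise is drawn from a beta distribution parameterized by
mean and concentration, keeping support in (0,1) and reproducing the
heteroskedasticity that motivates M-value testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import Cohort, build_cohort

# per-probe truth classes
PROBE_HYPER = "hyper"
PROBE_HYPO = "hypo"
PROBE_NULL = "null"
PROBE_DIFFUSE = "diffuse_hypo"       # shifted only in the diffuse-hypo cluster
PROBE_GROUP = "group_specific"       # shifted only in an NF2 group / promoters


@dataclass
class SimConfig:
    """Study-scale defaults: 12 dura/tumor pairs plus 19 unpaired tumors,
    four clusters of sizes 12/7/8/4, planted probe shifts of 0.3 on the beta
    scale with concentration-50 beta noise."""

    n_patients_paired: int = 12
    n_tumor_unpaired: int = 19
    n_probes: int = 20_000
    n_genes: int = 2_000
    cluster_sizes: tuple[int, ...] = (12, 7, 8, 4)
    frac_dmp_hyper: float = 0.02      # 4:1 hyper:hypo split of planted DMPs
    frac_dmp_hypo: float = 0.005
    delta_beta: float = 0.3
    beta_noise_concentration: float = 50.0
    cluster_shift: float = 0.25
    cluster_block_size: int = 100     # probes per cluster-specific block
    nf2_cluster: int = 1              # cluster whose tumors are NF2-altered
    global_hypo_cluster: int = 4      # 1-based cluster with diffuse hypomethylation
    diffuse_hypo_probes: int = 600
    diffuse_hypo_shift: float = 0.25
    cnv_segments: list[tuple] = field(default_factory=lambda: [
        # (group, chrom, start, end, log2 effect); group = "clusterN" or sample id
        ("cluster4", "chr1", 1, 5_000_000, -1.0),
        ("cluster4", "chr2", 20_000_001, 45_000_000, -1.0),
        ("cluster3", "chr2", 1, 12_000_000, -1.0),
        ("cluster2", "chr1", 30_000_001, 40_000_000, 0.58),
    ])
    nf2_altered_fraction: float = 5 / 12
    nf2_promoter_effects: dict[str, int] = field(default_factory=lambda: {
        "shared_hyper": 40, "altered_hyper": 30, "wildtype_hyper": 30,
        "shared_hypo": 20, "altered_hypo": 15, "wildtype_hypo": 15,
    })
    n_promoter_hyper: int = 60        # tumor-wide promoter effects
    n_promoter_hypo: int = 40
    promoter_hyper_delta: float = 0.5
    promoter_hypo_delta: float = 0.6
    probe_masked_fraction: float = 0.02
    contaminated_dura: bool = True    # plant one tumor-contaminated dura
    contamination_leak: float = 0.3
    # genome / baseline
    n_chromosomes: int = 2
    chrom_length: int = 50_000_000
    probes_per_promoter: int = 3
    methylated_fraction: float = 0.45
    unmeth_mode: float = 0.08
    meth_mode: float = 0.85
    # intensity channel
    intensity_log2_mean: float = np.log2(3000.0)
    intensity_probe_sd: float = 0.5
    intensity_sample_sd: float = 0.1
    intensity_noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self):
        for name in ("frac_dmp_hyper", "frac_dmp_hypo", "probe_masked_fraction",
                     "nf2_altered_fraction", "contamination_leak"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if sum(self.cluster_sizes) != self.n_tumors:
            raise ValueError(
                f"cluster_sizes sum {sum(self.cluster_sizes)} != total tumors "
                f"{self.n_tumors}")
        if not 1 <= self.global_hypo_cluster <= len(self.cluster_sizes):
            raise ValueError("global_hypo_cluster out of range")

    @property
    def n_tumors(self) -> int:
        return self.n_patients_paired + self.n_tumor_unpaired


@dataclass
class Truth:
    """Ground-truth labels produced alongside a synthetic cohort."""

    probe_class: pd.Series                 # probe -> hyper/hypo/null/...
    promoter_class: pd.DataFrame           # genes x contrasts, hyper/hypo/null
    cluster_labels: pd.Series              # tumor -> 1..n_clusters
    nf2_group: pd.Series                   # sample -> altered/wildtype/unknown
    cnv_segments: pd.DataFrame             # sample, chrom, start, end, log2_effect
    contaminated_dura: str | None = None

    def cnv_state(self, bins: pd.DataFrame, sample: str) -> np.ndarray:
        """True per-bin log2 effect for one sample, given a bin table."""
        state = np.zeros(len(bins))
        segs = self.cnv_segments[self.cnv_segments["sample"] == sample]
        for _, seg in segs.iterrows():
            hit = (bins["chrom"] == seg["chrom"]) & \
                  (bins["start"] <= seg["end"]) & (bins["end"] >= seg["start"])
            state[hit.to_numpy()] += seg["log2_effect"]
        return state


def _beta_noise(rng: np.random.Generator, mean: np.ndarray,
                concentration: float) -> np.ndarray:
    mean = np.clip(mean, 0.001, 0.999)
    draw = rng.beta(mean * concentration, (1.0 - mean) * concentration)
    return np.clip(draw, 1e-6, 1.0 - 1e-6)


def generate_cohort(config: SimConfig | None = None) -> tuple[Cohort, Truth]:
    """Generate a cohort plus its Truth; same config + seed is bit-identical."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    chroms = [f"chr{i+1}" for i in range(cfg.n_chromosomes)]

    # ---- gene layout: TSS grid, alternating strands, 10 kb bodies --------
    genes_per_chrom = cfg.n_genes // cfg.n_chromosomes
    gene_rows = []
    for ci, chrom in enumerate(chroms):
        n = genes_per_chrom + (cfg.n_genes % cfg.n_chromosomes if ci == 0 else 0)
        spacing = cfg.chrom_length // (n + 1)
        for gi in range(n):
            idx = len(gene_rows)
            tss = spacing * (gi + 1)
            strand = "+" if idx % 2 == 0 else "-"
            if strand == "+":
                start, end = tss, min(tss + 9_999, cfg.chrom_length)
            else:
                start, end = max(tss - 9_999, 1), tss
            gene_rows.append({
                "gene_id": f"G{idx:05d}", "gene_name": f"G{idx:05d}",
                "chrom": chrom, "strand": strand, "start": start, "end": end,
                "gene_type": "protein_coding",
            })
    annotation = pd.DataFrame(gene_rows).set_index("gene_id", drop=False)
    tss = np.where(annotation["strand"] == "+",
                   annotation["start"], annotation["end"])

    # ---- probe layout: promoter-enriched + uniform background -----------
    n_promoter_probes = cfg.n_genes * cfg.probes_per_promoter
    if n_promoter_probes >= cfg.n_probes:
        raise ValueError("n_probes too small for the promoter probe layout")
    offsets = np.linspace(-1500, 1500, cfg.probes_per_promoter).astype(int)
    rows = []
    for g in range(cfg.n_genes):
        for off in offsets:
            rows.append((annotation["chrom"].iloc[g],
                         max(1, int(tss[g]) + int(off)), g))
    n_background = cfg.n_probes - n_promoter_probes
    bg_per_chrom = n_background // cfg.n_chromosomes
    for ci, chrom in enumerate(chroms):
        n = bg_per_chrom + (n_background % cfg.n_chromosomes if ci == 0 else 0)
        pos = np.linspace(1, cfg.chrom_length, n + 2)[1:-1].astype(np.int64)
        rows.extend((chrom, int(p), -1) for p in pos)
    probe_df = pd.DataFrame(rows, columns=["chrom", "pos", "gene_idx"])
    probe_df = probe_df.sort_values(["chrom", "pos"], kind="mergesort"
                                    ).reset_index(drop=True)
    probe_df["probe_id"] = [f"cg{i:07d}" for i in range(len(probe_df))]

    # ---- samples ---------------------------------------------------------
    n_tumors = cfg.n_tumors
    dura_ids = [f"D{i+1:02d}" for i in range(cfg.n_patients_paired)]
    tumor_ids = [f"T{i+1:02d}" for i in range(n_tumors)]
    patients = ([f"P{i+1:02d}" for i in range(cfg.n_patients_paired)]
                + [f"P{i+1:02d}" for i in range(cfg.n_patients_paired, n_tumors)])

    # NF2-altered tumors form one methylation cluster (the altered state
    # drives a subtype); the cluster assignment is constrained so that the
    # paired subcohort holds the configured altered fraction exactly
    cluster_labels = np.zeros(n_tumors, dtype=int)
    n_altered = int(round(cfg.nf2_altered_fraction * cfg.n_patients_paired))
    nf2_size = cfg.cluster_sizes[cfg.nf2_cluster - 1]
    if n_altered > nf2_size or n_altered > cfg.n_patients_paired:
        raise ValueError("nf2_altered_fraction inconsistent with cluster sizes")
    paired_alt = rng.choice(cfg.n_patients_paired, size=n_altered, replace=False)
    unpaired_pool = np.arange(cfg.n_patients_paired, n_tumors)
    unpaired_alt = rng.choice(unpaired_pool, size=nf2_size - n_altered,
                              replace=False)
    cluster_labels[np.concatenate([paired_alt, unpaired_alt])] = cfg.nf2_cluster
    rest = np.flatnonzero(cluster_labels == 0)
    rest = rest[rng.permutation(len(rest))]
    pos0 = 0
    for ci, size in enumerate(cfg.cluster_sizes, start=1):
        if ci == cfg.nf2_cluster:
            continue
        cluster_labels[rest[pos0:pos0 + size]] = ci
        pos0 += size
    grades = _grades_from_clusters(cluster_labels, cfg)
    nf2 = np.where(cluster_labels == cfg.nf2_cluster, "altered",
                   "wildtype").astype(object)

    sheet = pd.DataFrame({
        "sample_id": dura_ids + tumor_ids,
        "patient_id": patients[:cfg.n_patients_paired] + patients,
        "tissue": ["dura"] * cfg.n_patients_paired + ["tumor"] * n_tumors,
        "grade": ["unknown"] * cfg.n_patients_paired + list(grades),
        "nf2_status": list(nf2[:cfg.n_patients_paired]) + list(nf2),
        "sex": list(rng.choice(["F", "M"], size=cfg.n_patients_paired + n_tumors,
                               p=[0.8, 0.2])),
        "recurrent": False,
        "batch": "b1",
        "excluded": False,
    }).set_index("sample_id", drop=False)

    # ---- baseline methylation means --------------------------------------
    n_probes = len(probe_df)
    gene_state = rng.random(cfg.n_genes) < cfg.methylated_fraction
    baseline = np.empty(n_probes)
    is_promoter = probe_df["gene_idx"].to_numpy() >= 0
    gi = probe_df["gene_idx"].to_numpy()
    baseline[is_promoter] = np.where(gene_state[gi[is_promoter]],
                                     cfg.meth_mode, cfg.unmeth_mode)
    n_bg = int((~is_promoter).sum())
    baseline[~is_promoter] = np.where(rng.random(n_bg) < cfg.methylated_fraction,
                                      cfg.meth_mode, cfg.unmeth_mode)

    # ---- masking: background probes only, never planted-effect probes ----
    masked = np.zeros(n_probes, dtype=bool)
    n_masked = int(round(cfg.probe_masked_fraction * n_probes))
    bg_idx = np.flatnonzero(~is_promoter)
    masked[rng.choice(bg_idx, size=min(n_masked, len(bg_idx)), replace=False)] = True

    # ---- planted probe effects ------------------------------------------
    # effect probes are drawn outside every promoter window so planted
    # probe-level shifts never leak into promoter percent scores
    in_window = np.zeros(n_probes, dtype=bool)
    flank = 2000
    for chrom in chroms:
        gene_sel = (annotation["chrom"] == chrom).to_numpy()
        starts = np.sort(tss[gene_sel] - flank)
        probe_sel = (probe_df["chrom"] == chrom).to_numpy()
        ppos = probe_df.loc[probe_sel, "pos"].to_numpy()
        k = np.searchsorted(starts, ppos, side="right") - 1
        gtss = np.sort(tss[gene_sel])
        hit = (k >= 0) & (np.abs(ppos - gtss[np.clip(k, 0, None)]) <= flank)
        in_window[probe_sel] = hit
    probe_class = np.array([PROBE_NULL] * n_probes, dtype=object)
    free_bg = np.flatnonzero(~is_promoter & ~masked & ~in_window)
    unmeth_bg = free_bg[baseline[free_bg] < 0.5]
    meth_bg = free_bg[baseline[free_bg] >= 0.5]
    n_hyper = int(round(cfg.frac_dmp_hyper * cfg.n_probes))
    n_hypo = int(round(cfg.frac_dmp_hypo * cfg.n_probes))
    hyper_idx = rng.choice(unmeth_bg, size=n_hyper, replace=False)
    hypo_idx = rng.choice(meth_bg, size=n_hypo, replace=False)
    probe_class[hyper_idx] = PROBE_HYPER
    probe_class[hypo_idx] = PROBE_HYPO

    # cluster blocks: disjoint sub-blocks of the hyper probes, so the DMP
    # matrix carries the cluster structure (clustering runs on DMPs)
    n_clusters = len(cfg.cluster_sizes)
    if cfg.cluster_shift == 0 or cfg.cluster_block_size == 0:
        block_probes = {ci + 1: np.array([], dtype=int)
                        for ci in range(n_clusters)}
    else:
        need = n_clusters * cfg.cluster_block_size
        if need > n_hyper:
            raise ValueError(
                "cluster blocks need more probes than planted hyper DMPs")
        block_probes = {ci + 1: hyper_idx[ci * cfg.cluster_block_size:
                                          (ci + 1) * cfg.cluster_block_size]
                        for ci in range(n_clusters)}

    remaining_meth = np.setdiff1d(meth_bg, hypo_idx, assume_unique=False)
    diffuse_idx = rng.choice(remaining_meth,
                             size=min(cfg.diffuse_hypo_probes, len(remaining_meth)),
                             replace=False)
    probe_class[diffuse_idx] = PROBE_DIFFUSE

    # ---- planted promoter effects ---------------------------------------
    unmeth_genes = np.flatnonzero(~gene_state)
    meth_genes = np.flatnonzero(gene_state)
    rng.shuffle(unmeth_genes)
    rng.shuffle(meth_genes)
    eff = cfg.nf2_promoter_effects
    take_u = iter(unmeth_genes.tolist())
    take_m = iter(meth_genes.tolist())

    def _take(it, n):
        return [next(it) for _ in range(n)]

    gene_groups = {
        "tumor_hyper": _take(take_u, cfg.n_promoter_hyper),
        "tumor_hypo": _take(take_m, cfg.n_promoter_hypo),
        "shared_hyper": _take(take_u, eff.get("shared_hyper", 0)),
        "altered_hyper": _take(take_u, eff.get("altered_hyper", 0)),
        "wildtype_hyper": _take(take_u, eff.get("wildtype_hyper", 0)),
        "shared_hypo": _take(take_m, eff.get("shared_hypo", 0)),
        "altered_hypo": _take(take_m, eff.get("altered_hypo", 0)),
        "wildtype_hypo": _take(take_m, eff.get("wildtype_hypo", 0)),
    }
    promoter_probe_idx = {
        name: np.flatnonzero(np.isin(gi, idxs) & is_promoter)
        for name, idxs in gene_groups.items()
    }
    for name in ("tumor_hyper", "tumor_hypo"):
        probe_class[promoter_probe_idx[name]] = (
            PROBE_HYPER if name.endswith("hyper") else PROBE_HYPO)
    for name in ("shared_hyper", "altered_hyper", "wildtype_hyper",
                 "shared_hypo", "altered_hypo", "wildtype_hypo"):
        probe_class[promoter_probe_idx[name]] = PROBE_GROUP

    # ---- per-sample methylation means, then beta noise -------------------
    sample_ids = dura_ids + tumor_ids
    mu = np.tile(baseline[:, None], (1, len(sample_ids)))
    tumor_cols = {t: cfg.n_patients_paired + j for j, t in enumerate(tumor_ids)}
    t_slice = slice(cfg.n_patients_paired, None)
    mu[hyper_idx, t_slice] += cfg.delta_beta
    mu[hypo_idx, t_slice] -= cfg.delta_beta
    mu[promoter_probe_idx["tumor_hyper"], t_slice] += cfg.promoter_hyper_delta
    mu[promoter_probe_idx["tumor_hypo"], t_slice] -= cfg.promoter_hypo_delta
    for ci in range(1, n_clusters + 1):
        cols = [tumor_cols[t] for j, t in enumerate(tumor_ids)
                if cluster_labels[j] == ci]
        mu[np.ix_(block_probes[ci], cols)] += cfg.cluster_shift
        if ci == cfg.global_hypo_cluster:
            mu[np.ix_(diffuse_idx, cols)] -= cfg.diffuse_hypo_shift
    altered_cols = [tumor_cols[t] for j, t in enumerate(tumor_ids)
                    if nf2[j] == "altered"]
    wildtype_cols = [tumor_cols[t] for j, t in enumerate(tumor_ids)
                     if nf2[j] == "wildtype"]
    for name, cols in (("shared_hyper", altered_cols + wildtype_cols),
                       ("altered_hyper", altered_cols),
                       ("wildtype_hyper", wildtype_cols)):
        mu[np.ix_(promoter_probe_idx[name], cols)] += cfg.promoter_hyper_delta
    for name, cols in (("shared_hypo", altered_cols + wildtype_cols),
                       ("altered_hypo", altered_cols),
                       ("wildtype_hypo", wildtype_cols)):
        mu[np.ix_(promoter_probe_idx[name], cols)] -= cfg.promoter_hypo_delta
    mu = np.clip(mu, 0.001, 0.999)
    beta = _beta_noise(rng, mu, cfg.beta_noise_concentration)

    contaminated = None
    if cfg.contaminated_dura and cfg.n_patients_paired >= 1:
        # pick a wildtype paired patient so both NF2 groups stay analyzable
        wt_paired = [i for i in range(cfg.n_patients_paired)
                     if nf2[i] == "wildtype"]
        di = wt_paired[0] if wt_paired else 0
        contaminated = dura_ids[di]
        leak = cfg.contamination_leak
        beta[:, di] = (1 - leak) * beta[:, di] + leak * beta[:, tumor_cols[tumor_ids[di]]]

    # ---- intensity channel with planted CNV segments ---------------------
    affinity = rng.normal(cfg.intensity_log2_mean, cfg.intensity_probe_sd,
                          size=n_probes)
    sample_scale = rng.normal(0.0, cfg.intensity_sample_sd, size=len(sample_ids))
    log2_int = (affinity[:, None] + sample_scale[None, :]
                + rng.normal(0.0, cfg.intensity_noise_sd,
                             size=(n_probes, len(sample_ids))))
    chrom_arr = probe_df["chrom"].to_numpy()
    pos_arr = probe_df["pos"].to_numpy()
    seg_rows = []
    for group, chrom, start, end, effect in cfg.cnv_segments:
        if str(group).startswith("cluster"):
            ci = int(str(group)[len("cluster"):])
            targets = [tumor_ids[j] for j in range(n_tumors)
                       if cluster_labels[j] == ci]
        else:
            targets = [str(group)]
        in_seg = (chrom_arr == chrom) & (pos_arr >= start) & (pos_arr <= end)
        for t in targets:
            log2_int[in_seg, tumor_cols[t]] += effect
            seg_rows.append({"sample": t, "chrom": chrom, "start": start,
                             "end": end, "log2_effect": effect})
    intensity = 2.0 ** log2_int

    # ---- assemble --------------------------------------------------------
    probe_index = probe_df["probe_id"].to_numpy()
    beta_df = pd.DataFrame(beta, index=probe_index, columns=sample_ids)
    beta_df.index.name = "probe_id"
    intensity_df = pd.DataFrame(intensity, index=probe_index, columns=sample_ids)
    intensity_df.index.name = "probe_id"
    manifest = pd.DataFrame({
        "probe_id": probe_index,
        "chrom": chrom_arr,
        "pos": pos_arr,
        "masked": masked,
    }).set_index("probe_id", drop=False)

    cohort = build_cohort(beta_df, intensity_df, sheet, manifest, annotation)

    gene_ids = annotation["gene_id"].to_numpy()
    promoter_class = pd.DataFrame(
        PROBE_NULL, index=gene_ids,
        columns=["tumor_vs_dura", "nf2_altered_vs_dura", "nf2_wildtype_vs_dura"])
    for name, idxs in gene_groups.items():
        direction = PROBE_HYPER if name.endswith("hyper") else PROBE_HYPO
        ids = gene_ids[idxs]
        if name.startswith("tumor"):
            promoter_class.loc[ids, :] = direction
        else:
            # NF2-group plants affect only a subset of tumors: they are
            # neither null nor cohort-wide effects in the tumor-vs-dura view
            promoter_class.loc[ids, "tumor_vs_dura"] = PROBE_GROUP
            if name.startswith("shared"):
                promoter_class.loc[ids, ["nf2_altered_vs_dura",
                                         "nf2_wildtype_vs_dura"]] = direction
            elif name.startswith("altered"):
                promoter_class.loc[ids, "nf2_altered_vs_dura"] = direction
            elif name.startswith("wildtype"):
                promoter_class.loc[ids, "nf2_wildtype_vs_dura"] = direction

    truth = Truth(
        probe_class=pd.Series(probe_class, index=probe_index).sort_index(),
        promoter_class=promoter_class.sort_index(),
        cluster_labels=pd.Series(cluster_labels, index=tumor_ids),
        nf2_group=pd.Series(
            list(nf2[:cfg.n_patients_paired]) + list(nf2),
            index=dura_ids + tumor_ids),
        cnv_segments=pd.DataFrame(
            seg_rows, columns=["sample", "chrom", "start", "end", "log2_effect"]),
        contaminated_dura=contaminated,
    )
    return cohort, truth


def _grades_from_clusters(cluster_labels: np.ndarray, cfg: SimConfig) -> list[str]:
    """Histopathologic grade per tumor, tied to cluster: the diffuse-hypo
    cluster is all grade III, one cluster is mostly grade II, the rest grade I
    (roughly 21 I / 6 II / 4 III at the default cohort size)."""
    n_clusters = len(cfg.cluster_sizes)
    hypo = cfg.global_hypo_cluster
    # the largest non-hypo cluster other than cluster 1 is the grade-II-rich
    # one; cluster 1 stays grade-I enriched
    candidates = [c for c in range(2, n_clusters + 1) if c != hypo] or [1]
    grade2_cluster = max(candidates, key=lambda c: (cfg.cluster_sizes[c - 1], c))
    grades = []
    seen2 = 0
    for lab in cluster_labels:
        if lab == hypo:
            grades.append("III")
        elif lab == grade2_cluster and seen2 < max(
                1, cfg.cluster_sizes[grade2_cluster - 1] - 2):
            grades.append("II")
            seen2 += 1
        else:
            grades.append("I")
    return grades


# ---------------------------------------------------------------------------
# small focused generators


def make_cluster_matrix(cluster_sizes=(12, 7, 8, 4), n_probes: int = 1600,
                        shift: float = 0.25, concentration: float = 50.0,
                        seed: int = 0,
                        ) -> tuple[pd.DataFrame, pd.Series]:
    """Items x probes beta matrix with planted clusters on disjoint blocks.

    Each cluster's block (``n_probes / n_clusters`` probes) is shifted by
    ``shift`` on the beta scale for that cluster's items; noise is
    beta-distributed at the given concentration.  Returns (matrix, labels).
    """
    rng = np.random.default_rng(seed)
    n_items = int(sum(cluster_sizes))
    n_clusters = len(cluster_sizes)
    block = n_probes // n_clusters
    baseline = np.where(rng.random(n_probes) < 0.45, 0.85, 0.08)
    labels = np.concatenate([
        np.full(size, ci + 1) for ci, size in enumerate(cluster_sizes)])
    mu = np.tile(baseline, (n_items, 1))
    for ci in range(n_clusters):
        sel = labels == ci + 1
        cols = slice(ci * block, (ci + 1) * block)
        mu[np.ix_(sel, np.arange(n_probes)[cols])] += np.where(
            baseline[cols] < 0.5, shift, -shift)
    beta = _beta_noise(rng, mu, concentration)
    items = [f"T{i+1:02d}" for i in range(n_items)]
    df = pd.DataFrame(beta, index=items,
                      columns=[f"cg{i:07d}" for i in range(n_probes)])
    return df, pd.Series(labels, index=items)


def generate_variants(n_variants: int = 100, n_pass: int = 20,
                      seed: int = 0,
                      allowlist: tuple[str, ...] | None = None,
                      ) -> tuple[pd.DataFrame, set[str]]:
    """Annotated somatic-variant table with a known set of filter passes.

    Passing rows satisfy every inclusion rule; each failing row violates at
    least one (non-exonic, common in gnomAD, low allele fraction, few
    supporting reads, or gene off the allowlist), drawn at random.  Returns
    (table, set of passing variant ids).
    """
    from .allowlist_synthetic import DEFAULT_GENE_ALLOWLIST
    if n_pass > n_variants:
        raise ValueError("n_pass cannot exceed n_variants")
    allowlist = tuple(allowlist or DEFAULT_GENE_ALLOWLIST)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_variants):
        vid = f"v{i:04d}"
        passing = i < n_pass
        row = {
            "variant_id": vid,
            "sample": f"T{int(rng.integers(1, 32)):02d}",
            "gene": str(rng.choice(allowlist)),
            "func": "exonic",
            "gnomad_af": 0.0,
            "vaf": float(rng.uniform(0.1, 0.5)),
            "alt_reads": int(rng.integers(5, 60)),
        }
        if not passing:
            failures = rng.choice(5, size=int(rng.integers(1, 3)), replace=False)
            for mode in failures:
                if mode == 0:
                    row["func"] = "intronic"
                elif mode == 1:
                    row["gnomad_af"] = float(rng.choice([0.0001, 0.001, 0.01]))
                elif mode == 2:
                    row["vaf"] = float(rng.choice([0.01, 0.03, 0.05]))
                elif mode == 3:
                    row["alt_reads"] = int(rng.integers(0, 5))
                else:
                    row["gene"] = "ZZZNOTCANCER"
        rows.append(row)
    order = rng.permutation(n_variants)
    table = pd.DataFrame([rows[i] for i in order]).reset_index(drop=True)
    if n_variants == 0:
        table = pd.DataFrame(columns=["variant_id", "sample", "gene", "func",
                                      "gnomad_af", "vaf", "alt_reads"])
    return table, {f"v{i:04d}" for i in range(n_pass)}
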