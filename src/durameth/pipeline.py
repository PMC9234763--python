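"""End-to-end orchestration: simulate/load -> DMPs -> clustering -> probe
shifts -> promoters -> CNV -> enrichment -> summary report.

Every stage is a pure function of (inputs, parameters, seed); one global seed
is expanded into fixed per-stage child seeds so reducing repetitions in one
stochastic stage does not shift another stage's random stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, cnv, core_io, diffmeth, promoters, stats, synthetic

logger = logging.getLogger("durameth")

STAGE_SEEDS = {"simulate": 1, "cluster": 2, "cnv": 3, "variants": 4}


@dataclass
class PipelineConfig:
    """Paths, stage parameters and the global seed for one pipeline run."""

    # either simulate a cohort ...
    simulate: bool = True
    sim: synthetic.SimConfig | None = None
    # ... or load one from disk
    beta_path: str | None = None
    intensity_path: str | None = None
    sample_sheet_path: str | None = None
    manifest_path: str | None = None
    annotation_path: str | None = None
    gene_sets_path: str | None = None
    variants_path: str | None = None

    out_dir: str = "durameth_out"
    seed: int = 0
    fdr_cutoff: float = 0.05
    consensus: clustering.ConsensusParams | None = None
    cnv_params: cnv.CnvParams | None = None
    filter_params: diffmeth.VariableProbeFilterParams | None = None
    shift_params: diffmeth.ProbeShiftParams | None = None
    promoter_params: promoters.PromoterParams | None = None
    enrichment_params: stats.EnrichmentParams | None = None
    exclusions: list[str] = field(default_factory=list)
    max_k: int = 8
    consensus_reps: int = 200

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.sim = synthetic.SimConfig(**sim)
        return cfg

    def child_seed(self, stage: str) -> int:
        return int(np.random.SeedSequence(
            [self.seed, STAGE_SEEDS[stage]]).generate_state(1)[0] % (2 ** 31))


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)
    fields = dataclasses.asdict(config)
    fields.pop("out_dir", None)  # a location, not a parameter
    blob = json.dumps(fields, sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in dependency order; returns the report bundle and
    writes TSV/JSON outputs under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": _config_hash(config), "seed": config.seed}

    # ---- cohort ----------------------------------------------------------
    truth = None
    if config.simulate:
        sim = config.sim or synthetic.SimConfig(seed=config.child_seed("simulate"))
        logger.info("simulating cohort: %d probes, %d samples",
                    sim.n_probes, sim.n_tumors + sim.n_patients_paired)
        cohort, truth = synthetic.generate_cohort(sim)
        core_io.write_cohort(cohort, out, prefix="simulated")
        truth.probe_class.rename("class").to_csv(out / "truth.probe_class.tsv",
                                                 sep="\t")
        truth.cluster_labels.rename("cluster").to_csv(
            out / "truth.clusters.tsv", sep="\t")
        truth.promoter_class.to_csv(out / "truth.promoters.tsv", sep="\t")
    else:
        cohort = core_io.load_cohort(
            config.beta_path, config.intensity_path, config.sample_sheet_path,
            config.manifest_path, config.annotation_path)
    report["n_samples"] = len(cohort.sample_ids)
    report["n_probes"] = len(cohort.probe_ids)

    # ---- probe-level differential methylation ----------------------------
    try:
        dmp_table, dmp_ids = diffmeth.call_dmps(
            cohort, config.filter_params, config.fdr_cutoff)
    except ValueError as exc:
        raise RuntimeError(f"dmp stage failed: {exc}") from exc
    dmp_table.to_csv(out / "dmp.stats.tsv", sep="\t")
    pd.Series(dmp_ids, name="probe_id").to_csv(out / "dmp.list.tsv", sep="\t",
                                               index=False)
    report["n_tested_probes"] = len(dmp_table)
    report["n_dmps"] = len(dmp_ids)
    report["n_dmps_hyper"] = int((dmp_table.loc[dmp_ids, "direction"] == "up").sum())
    report["n_dmps_hypo"] = int((dmp_table.loc[dmp_ids, "direction"] == "down").sum())
    logger.info("dmp: %d tested, %d DMPs (%d hyper / %d hypo)",
                report["n_tested_probes"], report["n_dmps"],
                report["n_dmps_hyper"], report["n_dmps_hypo"])

    shift_counts, _ = diffmeth.classify_probe_shifts(cohort, config.shift_params)
    shift_counts.to_csv(out / "probe_shift_counts.tsv", sep="\t")

    # ---- clustering + PCA ------------------------------------------------
    labels = None
    if len(dmp_ids) >= 2:
        dmp_beta = cohort.beta.loc[dmp_ids, cohort.tumor_ids()].T
        params = config.consensus or clustering.ConsensusParams(
            max_k=min(config.max_k, len(dmp_beta) - 1),
            reps=config.consensus_reps, seed=config.child_seed("cluster"))
        cc = clustering.consensus_cluster(dmp_beta, params)
        labels = cc.labels_series()
        labels.rename("cluster").to_csv(out / "cluster_labels.tsv", sep="\t")
        pd.DataFrame({"k": list(cc.cdf_areas), "cdf_area": list(cc.cdf_areas.values()),
                      "delta_area": [cc.delta_areas[k] for k in cc.cdf_areas]}
                     ).to_csv(out / "consensus_areas.tsv", sep="\t", index=False)
        report["selected_k"] = cc.selected_k
        logger.info("clustering: selected k=%d", cc.selected_k)

        fractions = clustering.pca_explained_variance(dmp_beta.to_numpy())
        pd.Series(fractions, name="variance_fraction").to_csv(
            out / "pca_fractions.tsv", sep="\t")
        report["pc1_variance_pct"] = float(100 * fractions[0])
        comps = clustering.pca_components(dmp_beta.to_numpy(), n_components=3)
        sheet = cohort.samples.loc[dmp_beta.index].copy()
        sheet["cluster"] = labels.astype(str)
        screen = clustering.covariate_component_screen(
            comps, sheet, ["cluster", "grade", "sex", "nf2_status"])
        screen.to_csv(out / "pc_covariate_pvalues.tsv", sep="\t")

        grades = cohort.samples.loc[labels.index, "grade"]
        try:
            chi = clustering.cluster_grade_association(labels, grades)
            report["cluster_grade_chi2"] = chi.statistic
            report["cluster_grade_p"] = chi.p_value
        except ValueError as exc:
            logger.warning("cluster-grade association not computable: %s", exc)

    # ---- promoter analysis ----------------------------------------------
    pparams = config.promoter_params or promoters.PromoterParams()
    pm, gene_map = promoters.score_promoters(cohort, pparams)
    pm.to_csv(out / "promoter_percent.tsv", sep="\t")
    report["n_promoter_genes"] = len(pm)
    contrasts = [promoters.ContrastSpec(
        name="tumor_vs_dura", case={"tissue": "tumor"},
        control={"tissue": "dura"})]
    if labels is not None:
        for k in sorted(labels.unique()):
            members = list(labels.index[labels == k])
            contrasts.append(promoters.ContrastSpec(
                name=f"cluster{k}_vs_dura", case={"sample_id": members},
                control={"tissue": "dura"}))
    paired_patients = cohort.paired_patients()
    exclusions = list(config.exclusions)
    if truth is not None and truth.contaminated_dura:
        # a tumor-contaminated dura invalidates its whole pair for the
        # patient-blocked design; the tumor stays in unpaired contrasts
        pat = cohort.samples.loc[truth.contaminated_dura, "patient_id"]
        exclusions.extend(
            cohort.samples.index[cohort.samples["patient_id"] == pat])
    if len(paired_patients) >= 4:
        contrasts.extend(promoters.nf2_paired_contrasts(
            exclusions, patients=paired_patients))
    sheet_for_contrasts = cohort.samples.copy()
    results = promoters.differential_promoters(
        pm, sheet_for_contrasts, contrasts, config.fdr_cutoff)
    hyper_sets, hypo_sets = {}, {}
    for name, res in results.items():
        res.table.to_csv(out / f"promoters.{name}.tsv", sep="\t")
        hyper_sets[name], hypo_sets[name] = res.hyper, res.hypo
        report[f"n_hyper_{name}"] = len(res.hyper)
        report[f"n_hypo_{name}"] = len(res.hypo)
    nf2_names = [n for n in results if n.startswith("nf2_")]
    if len(nf2_names) == 2:
        venn = promoters.intersect_promoter_sets(
            {n: hyper_sets[n] for n in nf2_names})
        report["n_shared_nf2_hyper"] = len(venn["shared"])
        venn = promoters.intersect_promoter_sets(
            {n: hypo_sets[n] for n in nf2_names})
        report["n_shared_nf2_hypo"] = len(venn["shared"])

    # ---- CNV -------------------------------------------------------------
    cparams = config.cnv_params or cnv.CnvParams(seed=config.child_seed("cnv"))
    bins = cnv.build_bins(cohort.manifest, cparams)
    ratios = cnv.bin_log2_ratios(cohort, bins)
    segments = cnv.cbs_segment(ratios, bins, cparams)
    cnv.write_seg(segments, out / "segments.seg")
    bin_calls = cnv.classify_ratio(ratios, cparams.call_cutoff)
    burden = cnv.cnv_burden(bin_calls)
    burden.to_csv(out / "cnv_burden.tsv", sep="\t")
    report["n_bins"] = len(bins)
    report["mean_cnv_burden"] = float(burden.mean())
    grades = cohort.samples.loc[burden.index, "grade"]
    known = grades != "unknown"
    if known.any() and grades[known].nunique() >= 2:
        an = stats.anova_tukey(burden[known].to_numpy(),
                               grades[known].to_numpy())
        report["cnv_burden_anova_p"] = an.p_value
        an.tukey.to_csv(out / "cnv_burden_tukey.tsv", sep="\t", index=False)

    # ---- enrichment ------------------------------------------------------
    if config.gene_sets_path:
        sets = core_io.read_gmt(config.gene_sets_path)
        universe = set(gene_map)
        enr = stats.hypergeometric_enrichment(
            hyper_sets["tumor_vs_dura"], universe, sets,
            config.enrichment_params)
        enr.to_csv(out / "enrichment.hyper.tsv", sep="\t", index=False)
        report["n_enriched_hyper"] = int(enr["enriched"].sum()) if len(enr) else 0

    # ---- variants --------------------------------------------------------
    if config.variants_path:
        variants = pd.read_csv(config.variants_path, sep="\t")
        kept = stats.filter_somatic_variants(variants)
        kept.to_csv(out / "variants.filtered.tsv", sep="\t", index=False)
        report["n_variants_kept"] = len(kept)

    manifest = {"config_hash": report["config_hash"], "seed": config.seed,
                "stages": sorted(k for k in report if k.startswith("n_"))}
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
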