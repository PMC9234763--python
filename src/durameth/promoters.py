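"""Promoter percent-methylation scoring and contrast-based differential
promoter analysis.

A probe is called methylated at beta >= 0.3 (inclusive) and unmethylated
below.  Probes are mapped to strand-aware promoter windows of +/-2 kb around
each gene's TSS (4001 bp, 1-based inclusive on both ends), and each gene x
sample cell scores 100 x methylated / overlapping probes.  Differential
analysis of the percent scores reuses the empirical-Bayes moderated t
machinery, with contrast specifications that support unpaired group
comparisons, per-cluster contrasts against dura, and a paired design that
blocks on patient (used for NF2-altered vs wildtype tumor/dura pairs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import Cohort
from .diffmeth import beta_to_m, bh_adjust, moderated_ttest


@dataclass
class PromoterParams:
    methylated_beta: float = 0.3   # inclusive lower bound for "methylated"
    flank: int = 2000              # bp each side of the TSS

    def __post_init__(self):
        if not 0.0 < self.methylated_beta < 1.0:
            raise ValueError("methylated_beta must be in (0,1)")
        if self.flank <= 0:
            raise ValueError("flank must be positive")


@dataclass
class ContrastSpec:
    """One differential contrast over the sample sheet.

    ``case``/``control`` are {column: allowed values} selectors; a sample
    belongs to an arm iff every selector column matches.  ``paired`` blocks
    on ``patient_id`` (each patient must appear in both arms).  ``exclusions``
    are sample ids removed before the fit (e.g. a contaminated dura).
    """

    name: str
    case: dict[str, object]
    control: dict[str, object]
    paired: bool = False
    exclusions: list[str] = field(default_factory=list)


def binarize_beta(beta, params: PromoterParams | None = None):
    """1 iff beta >= threshold, 0 below, missing stays missing."""
    params = params or PromoterParams()
    if isinstance(beta, pd.DataFrame):
        vals = beta.to_numpy(dtype=float)
    else:
        vals = np.asarray(beta, dtype=float)
    out = np.where(vals >= params.methylated_beta, 1.0, 0.0)
    out = np.where(np.isfinite(vals), out, np.nan)
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(out, index=beta.index, columns=beta.columns)
    return out


def map_probes_to_promoters(manifest: pd.DataFrame, annotation: pd.DataFrame,
                            params: PromoterParams | None = None,
                            ) -> dict[str, list[str]]:
    """Map unmasked probes into strand-aware TSS windows.

    TSS is ``start`` for + genes and ``end`` for - genes; the window is
    [TSS - flank, TSS + flank], 1-based inclusive on both ends.  A probe may
    map to several genes; genes with no overlapping probe are absent from
    the result.  Genes with unknown strand are skipped with a warning.
    """
    params = params or PromoterParams()
    probes = manifest[~manifest["masked"].astype(bool)]
    gene_map: dict[str, list[str]] = {}
    skipped = []
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in probes.groupby("chrom"):
        pos = sub["pos"].to_numpy(dtype=np.int64)
        order = np.argsort(pos, kind="mergesort")
        by_chrom[chrom] = (pos[order], sub["probe_id"].to_numpy()[order])
    for gene_id, row in annotation.iterrows():
        strand = row["strand"]
        if strand == "+":
            tss = int(row["start"])
        elif strand == "-":
            tss = int(row["end"])
        else:
            skipped.append(gene_id)
            continue
        entry = by_chrom.get(row["chrom"])
        if entry is None:
            continue
        pos, ids = entry
        lo = np.searchsorted(pos, tss - params.flank, side="left")
        hi = np.searchsorted(pos, tss + params.flank, side="right")
        if hi > lo:
            gene_map[str(gene_id)] = list(ids[lo:hi])
    if skipped:
        warnings.warn(f"{len(skipped)} genes skipped for unknown strand")
    return gene_map


def promoter_percent_methylation(binary: pd.DataFrame,
                                 gene_map: dict[str, list[str]],
                                 ) -> pd.DataFrame:
    """Genes x samples percent-methylation matrix.

    Cell = 100 x (methylated probes) / (non-missing overlapping probes);
    a cell whose probes are all missing is missing.
    """
    if not gene_map:
        raise ValueError("empty gene->probe map")
    rows = {}
    for gene, probe_ids in gene_map.items():
        sub = binary.loc[probe_ids]
        n = sub.notna().sum(axis=0)
        with np.errstate(invalid="ignore"):
            rows[gene] = 100.0 * sub.sum(axis=0, skipna=True) / n.where(n > 0)
    pm = pd.DataFrame(rows).T
    pm.index.name = "gene_id"
    pm.columns = binary.columns
    return pm.sort_index()


def score_promoters(cohort: Cohort, params: PromoterParams | None = None,
                    ) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Convenience: binarize the cohort's beta matrix and score promoters."""
    params = params or PromoterParams()
    gene_map = map_probes_to_promoters(cohort.manifest, cohort.annotation, params)
    binary = binarize_beta(cohort.beta, params)
    return promoter_percent_methylation(binary, gene_map), gene_map


# ---------------------------------------------------------------------------
# contrast-based differential analysis


def _select_arm(samples: pd.DataFrame, selector: dict[str, object]) -> list[str]:
    mask = pd.Series(True, index=samples.index)
    for col, allowed in selector.items():
        if col not in samples.columns:
            raise KeyError(f"selector column {col!r} not in sample sheet")
        if isinstance(allowed, (list, tuple, set, frozenset)):
            mask &= samples[col].isin(list(allowed))
        else:
            mask &= samples[col] == allowed
    return list(samples.index[mask])


@dataclass
class PromoterContrastResult:
    name: str
    table: pd.DataFrame          # DiffTestResult fields per gene
    hyper: set[str]              # fdr < cutoff, effect > 0 (case vs control)
    hypo: set[str]


def differential_promoters(pm: pd.DataFrame, sample_sheet: pd.DataFrame,
                           contrasts: list[ContrastSpec],
                           fdr_cutoff: float = 0.05,
                           logit_scale: bool = False,
                           ) -> dict[str, PromoterContrastResult]:
    """Moderated-t differential promoter methylation for each contrast.

    Operates on the percent values directly (``logit_scale=True`` switches to
    a logit of percent/100, off by default).  Paired contrasts add patient
    indicator columns to the design; excluded samples and the sheet-level
    ``excluded`` flag are honored.  Genes with any missing value among the
    tested samples are dropped from that contrast.
    """
    results: dict[str, PromoterContrastResult] = {}
    sheet = sample_sheet
    if "excluded" in sheet.columns:
        sheet = sheet[~sheet["excluded"].astype(bool)]
    for spec in contrasts:
        sub_sheet = sheet.drop(index=[s for s in spec.exclusions
                                      if s in sheet.index])
        case = [s for s in _select_arm(sub_sheet, spec.case) if s in pm.columns]
        control = [s for s in _select_arm(sub_sheet, spec.control)
                   if s in pm.columns]
        overlap = set(case) & set(control)
        if overlap:
            raise ValueError(f"contrast {spec.name!r}: arms overlap: "
                             f"{sorted(overlap)[:5]}")
        if len(case) < 2 or len(control) < 2:
            raise ValueError(f"contrast {spec.name!r}: each arm needs >=2 samples "
                             f"(case {len(case)}, control {len(control)})")
        samples = control + case
        design = pd.DataFrame(index=samples)
        if spec.paired:
            patients = sub_sheet.loc[samples, "patient_id"]
            case_p = set(patients[case]); ctrl_p = set(patients[control])
            unmatched = sorted(case_p ^ ctrl_p)
            if unmatched:
                raise ValueError(
                    f"contrast {spec.name!r}: paired design has unmatched "
                    f"patients: {unmatched}")
            for pat in sorted(case_p):
                design[f"patient_{pat}"] = (patients == pat).astype(float)
        else:
            design["intercept"] = 1.0
        design["case"] = [0.0] * len(control) + [1.0] * len(case)
        contrast = np.zeros(design.shape[1])
        contrast[design.columns.get_loc("case")] = 1.0

        values = pm[samples]
        values = values.loc[values.notna().all(axis=1)]
        if logit_scale:
            values = beta_to_m(values / 100.0)
        table = moderated_ttest(values, design, contrast,
                                feature_ids=values.index)
        sig = table["fdr"] < fdr_cutoff
        results[spec.name] = PromoterContrastResult(
            name=spec.name,
            table=table,
            hyper=set(table.index[sig & (table["effect"] > 0)]),
            hypo=set(table.index[sig & (table["effect"] < 0)]),
        )
    return results


def nf2_paired_contrasts(exclusions: list[str] | None = None,
                         patients: list[str] | None = None,
                         ) -> list[ContrastSpec]:
    """The two paired tumor-vs-dura contrasts split by NF2 status.

    ``patients`` restricts both arms to the listed patient ids (normally the
    patients that actually have a dura/tumor pair); unpaired tumors carry an
    NF2 status too but cannot enter a patient-blocked design.
    """
    exclusions = exclusions or []
    specs = []
    for status in ("altered", "wildtype"):
        case = {"tissue": "tumor", "nf2_status": status}
        control = {"tissue": "dura", "nf2_status": status}
        if patients is not None:
            case["patient_id"] = list(patients)
            control["patient_id"] = list(patients)
        specs.append(ContrastSpec(
            name=f"nf2_{status}_vs_dura", case=case, control=control,
            paired=True, exclusions=list(exclusions)))
    return specs


def intersect_promoter_sets(sets: dict[str, set[str]]) -> dict:
    """Venn decomposition of >=2 named gene sets.

    Returns ``regions`` mapping each membership pattern (tuple of set names
    the genes belong to) to its member list, ``counts`` with the region
    cardinalities, and ``shared`` — the genes present in every set.
    """
    if len(sets) < 2:
        raise ValueError("need >=2 sets to intersect")
    names = list(sets)
    universe = set().union(*sets.values())
    regions: dict[tuple[str, ...], list[str]] = {}
    for gene in sorted(universe):
        pattern = tuple(n for n in names if gene in sets[n])
        regions.setdefault(pattern, []).append(gene)
    shared = set.intersection(*[set(s) for s in sets.values()])
    return {
        "regions": regions,
        "counts": {pattern: len(members) for pattern, members in regions.items()},
        "shared": shared,
    }
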