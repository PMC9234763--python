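"""Readers/writers for the external formats and assembly of a validated cohort.

The central container is :class:`Cohort`: a probes x samples beta-value matrix
(methylation fraction in [0,1]), the matching combined-intensity matrix
(methylated + unmethylated signal per probe), a sample sheet, a probe manifest
and a gene annotation.  All identifiers are aligned and sorted
lexicographically at load time so downstream stages can rely on positional
agreement between matrices and metadata.

Coordinates are 1-based inclusive throughout (array-manifest convention);
BED export converts to 0-based half-open at the boundary.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TISSUES = frozenset({"tumor", "dura"})
GRADES = frozenset({"I", "II", "III", "unknown"})
NF2_STATUSES = frozenset({"altered", "wildtype", "unknown"})
SEXES = frozenset({"M", "F", "unknown"})

SAMPLE_SHEET_COLUMNS = [
    "sample_id", "patient_id", "tissue", "grade", "nf2_status",
    "sex", "recurrent", "batch", "excluded",
]
MANIFEST_COLUMNS = ["probe_id", "chrom", "pos", "masked"]
ANNOTATION_COLUMNS = [
    "gene_id", "gene_name", "chrom", "strand", "start", "end", "gene_type",
]


class CohortError(ValueError):
    """Base class for cohort construction problems."""


class AlignmentError(CohortError):
    """Identifiers disagree between two inputs that must align."""


class ValidationError(CohortError):
    """A value violates its domain contract (e.g. beta outside [0,1])."""


class FormatError(CohortError):
    """A file does not follow its declared format."""


# ---------------------------------------------------------------------------
# domain types


@dataclass
class Cohort:
    """Aligned bundle of methylation data and metadata for one study.

    Invariants (enforced by :func:`validate_cohort`):

    * sample ids unique and identical across ``beta``, ``intensity`` and
      ``samples``; probe ids unique and identical across ``beta``,
      ``intensity`` and ``manifest``;
    * beta values in [0,1] or missing; intensities non-negative;
    * every dura sample shares its patient id with at most one tumor.
    """

    beta: pd.DataFrame
    intensity: pd.DataFrame
    samples: pd.DataFrame
    manifest: pd.DataFrame
    annotation: pd.DataFrame

    # -- convenience views -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.columns)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.beta.index)

    def tumor_ids(self, include_excluded: bool = False) -> list[str]:
        return self._tissue_ids("tumor", include_excluded)

    def dura_ids(self, include_excluded: bool = False) -> list[str]:
        return self._tissue_ids("dura", include_excluded)

    def _tissue_ids(self, tissue: str, include_excluded: bool) -> list[str]:
        sel = self.samples["tissue"] == tissue
        if not include_excluded:
            sel &= ~self.samples["excluded"].astype(bool)
        return list(self.samples.index[sel])

    def paired_patients(self) -> list[str]:
        """Patients with both a dura and a tumor sample."""
        by_tissue = self.samples.groupby("patient_id")["tissue"].agg(set)
        return sorted(p for p, t in by_tissue.items() if {"tumor", "dura"} <= t)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT contents); set names unique, sets non-empty."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()


# ---------------------------------------------------------------------------
# readers


def _read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "probe_id"
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate probe ids in {path}: {dups[:5]}")
    if df.columns.has_duplicates:
        raise FormatError(f"duplicate sample ids in {path}")
    return df.apply(pd.to_numeric, errors="coerce")


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    missing = set(SAMPLE_SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
    df = df[SAMPLE_SHEET_COLUMNS].copy()
    for col in ("recurrent", "excluded"):
        df[col] = df[col].map(_parse_flag)
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        raise FormatError("duplicate sample ids in sample sheet")
    return df.set_index("sample_id", drop=False).sort_index()


def _parse_flag(value) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in {"true", "1", "yes", "t"}:
        return True
    if s in {"false", "0", "no", "f", "", "nan", "none"}:
        return False
    raise FormatError(f"cannot parse flag value {value!r}")


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"manifest missing columns: {sorted(missing)}")
    df = df[MANIFEST_COLUMNS].copy()
    df["pos"] = pd.to_numeric(df["pos"]).astype(np.int64)
    df["masked"] = df["masked"].map(_parse_flag)
    if (df["pos"] <= 0).any():
        raise ValidationError("manifest positions must be positive (1-based)")
    if df["probe_id"].duplicated().any():
        raise FormatError("duplicate probe ids in manifest")
    return df.set_index("probe_id", drop=False).sort_index()


def read_annotation(path) -> pd.DataFrame:
    """Read a gene annotation table (headered TSV, or BED6).

    BED6 input (detected by the absence of the declared header) is converted
    from 0-based half-open to 1-based inclusive; ``gene_id`` comes from the
    BED name field.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if "gene_id" in first.split("\t") or "gene_id" in first.split(","):
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = set(ANNOTATION_COLUMNS) - set(df.columns)
        if missing:
            raise FormatError(f"annotation missing columns: {sorted(missing)}")
        df = df[ANNOTATION_COLUMNS].copy()
    else:  # BED6
        df = pd.read_csv(
            path, sep="\t", header=None, dtype=str,
            names=["chrom", "start", "end", "name", "score", "strand"],
        )
        df = pd.DataFrame({
            "gene_id": df["name"], "gene_name": df["name"],
            "chrom": df["chrom"],
            "strand": df["strand"],
            "start": pd.to_numeric(df["start"]) + 1,  # 0-based -> 1-based
            "end": pd.to_numeric(df["end"]),          # half-open -> inclusive
            "gene_type": "unknown",
        })
    df["start"] = pd.to_numeric(df["start"]).astype(np.int64)
    df["end"] = pd.to_numeric(df["end"]).astype(np.int64)
    if (df["start"] > df["end"]).any():
        bad = df.loc[df["start"] > df["end"], "gene_id"].tolist()
        raise ValidationError(f"annotation start > end for genes {bad[:5]}")
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        raise ValidationError(
            "strand must be '+' or '-' for every record; offenders: "
            f"{df.loc[bad_strand, 'gene_id'].tolist()[:5]}")
    if df["gene_id"].duplicated().any():
        raise FormatError("duplicate gene ids in annotation")
    return df.set_index("gene_id", drop=False).sort_index()


def read_gmt(path) -> GeneSetCollection:
    """Read gene sets in GMT format (name, description, tab-separated members).

    Duplicate members within a set are collapsed; duplicate set names are an
    error; an empty file yields an empty collection.
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields")
            name, desc, *members = fields
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = frozenset(m for m in members if m)
            if not members:
                raise FormatError(f"{path}:{lineno}: set {name!r} is empty")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


# ---------------------------------------------------------------------------
# cohort assembly


def validate_cohort(cohort: Cohort) -> Cohort:
    beta, intensity = cohort.beta, cohort.intensity
    samples, manifest = cohort.samples, cohort.manifest

    def _check_ids(kind, a, b, name_a, name_b):
        sa, sb = set(a), set(b)
        if sa != sb:
            only_a = sorted(sa - sb)[:5]
            only_b = sorted(sb - sa)[:5]
            raise AlignmentError(
                f"{kind} ids differ between {name_a} and {name_b}: "
                f"only in {name_a}: {only_a}; only in {name_b}: {only_b}")

    _check_ids("sample", beta.columns, intensity.columns, "beta", "intensity")
    _check_ids("sample", beta.columns, samples.index, "beta", "sample sheet")
    _check_ids("probe", beta.index, intensity.index, "beta", "intensity")
    _check_ids("probe", beta.index, manifest.index, "beta", "manifest")

    vals = beta.to_numpy(dtype=float)
    finite = np.isfinite(vals)
    if ((vals < 0) | (vals > 1))[finite].any():
        bad = beta.index[np.nanmax(np.where(finite, vals, 0.5), axis=1) > 1]
        if len(bad) == 0:
            bad = beta.index[np.nanmin(np.where(finite, vals, 0.5), axis=1) < 0]
        raise ValidationError(
            f"beta values outside [0,1]; offending probes include {list(bad[:5])}")
    ivals = intensity.to_numpy(dtype=float)
    if (ivals[np.isfinite(ivals)] < 0).any():
        raise ValidationError("negative intensities")

    bad_tissue = ~samples["tissue"].isin(TISSUES)
    if bad_tissue.any():
        raise ValidationError(
            f"unknown tissue for samples {list(samples.index[bad_tissue][:5])}")
    dura = samples[samples["tissue"] == "dura"]
    if (dura["grade"] != "unknown").any():
        bad = dura.index[dura["grade"] != "unknown"]
        raise ValidationError(f"dura samples must have grade 'unknown': {list(bad[:5])}")
    # every dura patient pairs with at most one tumor
    tumor_counts = samples[samples["tissue"] == "tumor"]["patient_id"].value_counts()
    multi = tumor_counts[tumor_counts > 1].index
    offenders = sorted(set(dura["patient_id"]) & set(multi))
    if offenders:
        raise ValidationError(
            f"dura patients paired with >1 tumor: {offenders[:5]}")
    return cohort


def _canonicalize(cohort: Cohort) -> Cohort:
    order = sorted(cohort.beta.columns)
    probes = sorted(cohort.beta.index)
    return Cohort(
        beta=cohort.beta.loc[probes, order],
        intensity=cohort.intensity.loc[probes, order],
        samples=cohort.samples.loc[sorted(cohort.samples.index)],
        manifest=cohort.manifest.loc[probes],
        annotation=cohort.annotation,
    )


def build_cohort(beta, intensity, samples, manifest, annotation) -> Cohort:
    """Assemble, canonically sort and validate a Cohort from in-memory parts."""
    cohort = _canonicalize(
        validate_cohort(Cohort(beta, intensity, samples, manifest, annotation)))
    return cohort


def load_cohort(beta_path, intensity_path, sample_sheet_path,
                manifest_path, annotation_path) -> Cohort:
    """Load and validate a cohort from its five on-disk files."""
    return build_cohort(
        beta=_read_matrix(beta_path),
        intensity=_read_matrix(intensity_path),
        samples=read_sample_sheet(sample_sheet_path),
        manifest=read_manifest(manifest_path),
        annotation=read_annotation(annotation_path),
    )


# ---------------------------------------------------------------------------
# writers


def write_cohort(cohort: Cohort, outdir, prefix: str = "cohort") -> dict[str, Path]:
    """Write all cohort files; returns the path of each written file.

    Round-trips bit-identically through :func:`load_cohort` for finite values
    (matrices use repr-exact float formatting).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": outdir / f"{prefix}.beta.tsv",
        "intensity": outdir / f"{prefix}.intensity.tsv",
        "samples": outdir / f"{prefix}.samples.csv",
        "manifest": outdir / f"{prefix}.manifest.tsv",
        "annotation": outdir / f"{prefix}.annotation.tsv",
    }
    _write_matrix(cohort.beta, paths["beta"])
    _write_matrix(cohort.intensity, paths["intensity"])
    cohort.samples.to_csv(paths["samples"], index=False)
    cohort.manifest.to_csv(paths["manifest"], sep="\t", index=False)
    cohort.annotation.to_csv(paths["annotation"], sep="\t", index=False)
    return paths


def _write_matrix(df: pd.DataFrame, path) -> None:
    buf = io.StringIO()
    buf.write("probe_id\t" + "\t".join(map(str, df.columns)) + "\n")
    vals = df.to_numpy(dtype=float)
    for pid, row in zip(df.index, vals):
        cells = ("" if not np.isfinite(v) else repr(float(v)) for v in row)
        buf.write(str(pid) + "\t" + "\t".join(cells) + "\n")
    Path(path).write_text(buf.getvalue())
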