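"""Shared fixtures: a hand-built toy cohort and a default synthetic cohort."""

import numpy as np
import pandas as pd
import pytest

import durameth as dm


@pytest.fixture()
def toy_cohort_frames():
    """Three probes x two samples, one dura / one tumor, hand-checkable."""
    beta = pd.DataFrame(
        {"S1": [0.1, 0.5, 0.9], "S2": [0.2, 0.6, 0.8]},
        index=["cg01", "cg02", "cg03"])
    beta.index.name = "probe_id"
    intensity = pd.DataFrame(
        {"S1": [1000.0, 2000.0, 1500.0], "S2": [1100.0, 1900.0, 1600.0]},
        index=beta.index)
    samples = pd.DataFrame({
        "sample_id": ["S1", "S2"],
        "patient_id": ["P1", "P1"],
        "tissue": ["dura", "tumor"],
        "grade": ["unknown", "II"],
        "nf2_status": ["wildtype", "wildtype"],
        "sex": ["F", "F"],
        "recurrent": [False, False],
        "batch": ["b1", "b1"],
        "excluded": [False, False],
    }).set_index("sample_id", drop=False)
    manifest = pd.DataFrame({
        "probe_id": ["cg01", "cg02", "cg03"],
        "chrom": ["chr1", "chr1", "chr2"],
        "pos": [100, 5000, 100],
        "masked": [False, False, False],
    }).set_index("probe_id", drop=False)
    annotation = pd.DataFrame({
        "gene_id": ["G1"], "gene_name": ["G1"], "chrom": ["chr1"],
        "strand": ["+"], "start": [1000], "end": [4000],
        "gene_type": ["protein_coding"],
    }).set_index("gene_id", drop=False)
    return beta, intensity, samples, manifest, annotation


@pytest.fixture()
def toy_cohort(toy_cohort_frames):
    return dm.build_cohort(*toy_cohort_frames)


@pytest.fixture(scope="session")
def default_cohort():
    """Default-scale synthetic cohort (31 tumors vs 12 dura) with truth."""
    return dm.generate_cohort(dm.SimConfig(seed=20123))


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced cohort for fast end-to-end checks."""
    cfg = dm.SimConfig(
        n_probes=4000, n_genes=400, seed=77,
        cluster_block_size=20, diffuse_hypo_probes=100,
        n_promoter_hyper=20, n_promoter_hypo=12,
        nf2_promoter_effects={"shared_hyper": 10, "altered_hyper": 8,
                              "wildtype_hyper": 8, "shared_hypo": 6,
                              "altered_hypo": 5, "wildtype_hypo": 5})
    return dm.generate_cohort(cfg)


def rng(seed=0):
    return np.random.default_rng(seed)
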