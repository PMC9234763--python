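"""Synthetic default cancer-gene allowlist for somatic-variant filtering.

This is a stand-in list of 73 genes assembled from loci recurrently
implicated in meningioma (NF2, TRAF7, KLF4, AKT1, SMO, PIK3CA, ...), the
BAF/SWI-SNF chromatin-remodeling complex, and broadly cancer-associated
genes.  It is a replaceable default, not a curated reference: supply your
own list via :func:`load_allowlist` or
``VariantFilterParams(gene_allowlist=...)`` for real analyses.
"""

from __future__ import annotations

DEFAULT_GENE_ALLOWLIST: tuple[str, ...] = (
    # meningioma drivers
    "NF2", "TRAF7", "KLF4", "AKT1", "SMO", "PIK3CA", "POLR2A", "SUFU",
    "SMARCB1", "SMARCE1", "BAP1", "TERT", "CDKN2A", "CDKN2B",
    # BAF (SWI/SNF) complex
    "SMARCA2", "SMARCA4", "SMARCC1", "SMARCC2", "SMARCD1", "SMARCD2",
    "SMARCD3", "ARID1A", "ARID1B", "ARID2", "PBRM1", "BRD7", "BRD9",
    "PHF10", "DPF1", "DPF2", "DPF3", "ACTL6A", "ACTL6B", "BCL7A", "BCL7B",
    "BCL7C", "SS18", "SS18L1", "BICRA", "BICRAL", "ACTB",
    # broadly cancer-associated
    "TP53", "RB1", "PTEN", "NF1", "CHEK2", "ATM", "ATR", "BRCA1", "BRCA2",
    "MEN1", "VHL", "PRKAR1A", "AKT2", "AKT3", "PIK3R1", "MTOR", "TSC1",
    "TSC2", "CREBBP", "EP300", "KDM5C", "KDM6A", "SETD2", "EZH2", "EED",
    "SUZ12", "DNMT3A", "TET2", "IDH1", "IDH2", "FOXM1", "GAB1",
)

assert len(DEFAULT_GENE_ALLOWLIST) == 73
assert len(set(DEFAULT_GENE_ALLOWLIST)) == 73


def load_allowlist(path) -> frozenset[str]:
    """Read a user-supplied allowlist: one gene symbol per line, '#' comments."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line.split("\t")[0])
    return frozenset(genes)
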