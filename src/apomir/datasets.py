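"""Packaged reference tables from a published paired colorectal-cancer cohort.

Three small TSVs ship with the package and serve as fixtures for the
table-level arithmetic the pipeline reproduces:

* ``crc_apoptosis_de.tsv`` — per-gene summary statistics (tumor/normal mean
  RPMPCG, fold change, raw and adjusted p) for the 133 apoptosis-pathway
  genes with sufficient expression in a 217-subject paired tumor/normal
  colorectal cohort;
* ``crc_apoptosis_mirna_assoc.tsv`` — the 48 significant gene:miRNA
  associations from the same cohort (betas, bootstrap p, FDR p, and whether
  a seed-region match exists);
* ``crc_cohort_counts.tsv`` — cohort composition counts (site, sex, race,
  stage, tumor phenotype, vital status).

Raw p-values printed as "<0.0001" in the association table are kept as
strings in ``raw_p``; ``raw_p_upper`` gives a numeric upper bound.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_de_reference",
    "load_association_reference",
    "load_cohort_counts",
]


def _path(name: str):
    return resources.files("apomir.data").joinpath(name)


def load_de_reference() -> pd.DataFrame:
    """Differential-expression summary for the 133 apoptosis-pathway genes."""
    with resources.as_file(_path("crc_apoptosis_de.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_association_reference() -> pd.DataFrame:
    """The 48 significant gene:miRNA association rows."""
    with resources.as_file(_path("crc_apoptosis_mirna_assoc.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype={"raw_p": str})
    df["seed_match"] = df["seed_match"].astype(bool)
    df["raw_p_upper"] = [
        float(s.lstrip("<")) for s in df["raw_p"]
    ]
    return df


def load_cohort_counts() -> pd.DataFrame:
    """Cohort composition counts (category, level, count)."""
    with resources.as_file(_path("crc_cohort_counts.tsv")) as p:
        return pd.read_csv(p, sep="\t")
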