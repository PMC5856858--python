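import numpy as np
import pytest

from apomir.io import (
    ExpressionMatrix,
    MatrixKind,
    Phenotype,
    SampleMeta,
    Sex,
    Site,
    Tissue,
    Vital,
)
from apomir.simulate import SimulationConfig, simulate_paired_counts


def make_meta(subject_id, tissue, **kw):
    defaults = dict(
        age=64.8,
        sex=Sex.MALE,
        site=Site.COLON,
        stage=2,
        phenotype=Phenotype.MSS,
        vital=Vital.ALIVE,
        survival_months=60.0,
        crc_death=False,
    )
    defaults.update(kw)
    return SampleMeta(subject_id=subject_id, tissue=Tissue(tissue), **defaults)


@pytest.fixture
def paired_meta():
    """Six subjects, one tumor + one normal record each."""
    meta = []
    for i in range(6):
        sex = Sex.MALE if i % 2 else Sex.FEMALE
        pheno = Phenotype.MSI if i < 2 else Phenotype.MSS
        for t in ("tumor", "normal"):
            meta.append(
                make_meta(f"s{i}", t, sex=sex, phenotype=pheno, age=55.0 + 3 * i)
            )
    return meta


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-subject simulated cohort shared by read-only tests."""
    cfg = SimulationConfig(
        n_subjects=40,
        n_genes=15,
        n_mirnas=6,
        rng_seed=12345,
        true_log_fc=np.r_[np.log(2.0), -np.log(2.0), np.zeros(13)],
    )
    counts, meta, truth = simulate_paired_counts(cfg)
    return cfg, counts, meta, truth


def as_matrix(arr, features=None, samples=None, kind=MatrixKind.RPMPCG):
    import pandas as pd

    arr = np.asarray(arr)
    features = features or [f"f{i}" for i in range(arr.shape[0])]
    samples = samples or [f"c{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=features, columns=samples), kind)
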