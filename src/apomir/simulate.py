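"""Synthetic paired-cohort data with the structure every pipeline stage assumes.

The generator emulates a paired tumor/normal colorectal cohort:

* **mRNA counts** — negative-binomial counts with a per-subject random
  intercept on the log scale, planted log fold changes for chosen genes,
  lognormal library sizes, and the NB2 mean/dispersion parameterization
  (Var = mu + dispersion * mu^2) that the analysis model tests;
* **miRNA intensities** — lognormal tumor/normal array intensities with
  planted miRNA fold changes, per-sample multiplicative scale distortions
  (so the upper-quartile normalization has real work to do), and planted
  linear gene~miRNA association effects written into the gene differential
  matrix (some inverse, as expected of repressive targeting);
* **3'UTR sequences** — random-background DNA with reverse-complement
  seed sites of chosen miRNAs inserted at recorded positions;
* **survival** — exponential event times under a proportional-hazards
  model on age, sex, stage, and one miRNA's differential expression, with
  administrative censoring tuned to a target censored fraction.

Cohort composition defaults mirror a real 217-subject study population:
77.9% colon, 54.4% male, 86.6% MSS, mean (SD) age 64.8 (10.1), 57.4%
alive at end of follow-up. Every generator is a pure function of its
configuration including the seed. Everything planted is recorded exactly
once in :class:`SyntheticTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    MatrixKind,
    Phenotype,
    SampleMeta,
    SequenceRecord,
    Sex,
    Site,
    Tissue,
    ValidationError,
    Vital,
    subjects_of,
)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_paired_counts",
    "simulate_mirna_with_associations",
    "simulate_utrs_with_seed_sites",
    "simulate_survival",
]

_STAGE_PROBS = np.array([58, 61, 72, 23]) / 214.0  # observed stage mix


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults are the emulated study conditions."""

    n_subjects: int = 217
    n_genes: int = 133
    n_mirnas: int = 50
    true_log_fc: np.ndarray | None = None  # per-gene; None = all zero
    nb_dispersion: float = 0.3
    subject_effect_sd: float = 0.3  # log scale
    library_size_mean: float = 1e6
    library_size_sd: float = 0.25  # lognormal sigma of library sizes
    pathway_mass_fraction: float = 0.02  # share of transcriptome in pathway genes
    mirna_true_log_fc: np.ndarray | None = None  # per-miRNA; None = all zero
    assoc_effects: list[tuple[str, str, float]] = field(default_factory=list)
    assoc_noise_sd: float = 1.0  # relative to the sd of the miRNA differential
    assoc_age_beta: float = 0.0
    assoc_sex_beta: float = 0.0
    mirna_scale_distortion_sd: float = 0.2
    mirna_intensity_sd: float = 0.25  # lognormal sigma within tissue
    cox_betas: dict[str, float] = field(
        default_factory=lambda: {"age": 0.0, "sex": 0.0, "stage": 0.0, "exposure": 0.0}
    )
    baseline_hazard: float = 0.02  # events per month at the covariate mean
    censor_fraction_target: float = 0.574
    frac_colon: float = 0.779
    frac_mss: float = 0.866
    frac_male: float = 0.544
    age_mean: float = 64.8
    age_sd: float = 10.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("censor_fraction_target", "frac_colon", "frac_mss", "frac_male"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.subject_effect_sd < 0 or self.mirna_scale_distortion_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_subjects < 1 or self.n_genes < 1 or self.n_mirnas < 1:
            raise ValueError("n_subjects, n_genes, n_mirnas must be positive")

    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    def mirna_ids(self) -> list[str]:
        return [f"mir-{i:03d}" for i in range(self.n_mirnas)]


@dataclass
class SyntheticTruth:
    """Everything planted, recorded exactly once."""

    true_log_fc: dict[str, float] = field(default_factory=dict)
    mirna_true_log_fc: dict[str, float] = field(default_factory=dict)
    assoc_betas: dict[tuple[str, str], float] = field(default_factory=dict)
    seed_sites: list[tuple[str, str, int, int]] = field(default_factory=list)
    # (mirna, target, 1-based position, seed length)
    seed_collisions: list[tuple[str, str, int, int]] = field(default_factory=list)
    cox_betas: dict[str, float] = field(default_factory=dict)
    survival_mirna: str | None = None
    censor_time: float | None = None
    mirna_differential: pd.DataFrame | None = None  # realized, pre-distortion


def _simulate_meta(config: SimulationConfig, rng: np.random.Generator) -> list[SampleMeta]:
    meta = []
    for i in range(config.n_subjects):
        sid = f"S{i:04d}"
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 30, 95))
        sex = Sex.MALE if rng.random() < config.frac_male else Sex.FEMALE
        site = Site.COLON if rng.random() < config.frac_colon else Site.RECTAL
        stage = int(rng.choice([1, 2, 3, 4], p=_STAGE_PROBS))
        pheno = Phenotype.MSS if rng.random() < config.frac_mss else Phenotype.MSI
        for tissue in (Tissue.TUMOR, Tissue.NORMAL):
            meta.append(
                SampleMeta(
                    subject_id=sid,
                    tissue=tissue,
                    age=age,
                    sex=sex,
                    site=site,
                    stage=stage,
                    phenotype=pheno,
                    vital=Vital.ALIVE,
                    survival_months=0.0,
                    crc_death=False,
                )
            )
    return meta


def simulate_paired_counts(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, list[SampleMeta], SyntheticTruth]:
    """Paired NB mRNA counts with subject effects and planted fold changes.

    count(i, g, t) ~ NB(mean = s_it * exp(a_g + u_ig + fc_g * 1[t=tumor]),
    dispersion), with u_ig ~ N(0, subject_effect_sd) and s_it lognormal
    library-size factors. Dispersion 0 gives the Poisson limit.

    Pathway genes carry ``pathway_mass_fraction`` of each library; the
    rest of the protein-coding transcriptome is represented by one
    aggregated ``PC_BACKGROUND`` row (Poisson — the summed dispersion of
    thousands of independent genes is negligible), so RPMPCG values and
    offsets behave like those of a genome-wide count matrix without
    simulating one.
    """
    rng = np.random.default_rng(config.rng_seed)
    S, G = config.n_subjects, config.n_genes
    fc = (
        np.zeros(G)
        if config.true_log_fc is None
        else np.asarray(config.true_log_fc, dtype=float)
    )
    if fc.shape != (G,):
        raise ValueError(f"true_log_fc must have length n_genes={G}")
    meta = _simulate_meta(config, rng)
    genes = config.gene_ids()
    # relative abundances: lognormal spread, scaled to the pathway mass share
    a = rng.normal(0.0, 1.0, size=G)
    a += np.log(config.pathway_mass_fraction) - np.log(np.exp(a).sum())
    u = rng.normal(0.0, config.subject_effect_sd, size=(S, G))
    libs = rng.lognormal(
        np.log(config.library_size_mean), config.library_size_sd, size=(S, 2)
    )
    log_mu_base = a[None, :] + u  # S x G
    bg_mass = 1.0 - config.pathway_mass_fraction
    cols = {}
    subjects = subjects_of(meta)
    for j, tissue in enumerate(("T", "N")):
        shift = fc if tissue == "T" else 0.0
        mu = libs[:, j][:, None] * np.exp(log_mu_base + shift)
        if config.nb_dispersion < 1e-12:
            draw = rng.poisson(mu)
        else:
            r = 1.0 / config.nb_dispersion
            p = r / (r + mu)
            draw = rng.negative_binomial(r, p)
        bg = rng.poisson(libs[:, j] * bg_mass)
        for i, s in enumerate(subjects):
            cols[f"{s}_{tissue}"] = np.append(draw[i], bg[i])
    order = [m.sample_id for m in meta]
    df = pd.DataFrame(cols, index=genes + ["PC_BACKGROUND"])[order]
    truth = SyntheticTruth(true_log_fc={g: float(v) for g, v in zip(genes, fc)})
    return ExpressionMatrix(df, MatrixKind.MRNA_COUNTS), meta, truth


def simulate_mirna_with_associations(
    config: SimulationConfig,
    truth: SyntheticTruth,
    meta: Sequence[SampleMeta],
    gene_diff: ExpressionMatrix | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix | None]:
    """miRNA intensities with planted fold changes, scale distortions, and
    planted linear gene~miRNA effects.

    Per-subject miRNA differential values are drawn first (lognormal
    tumor/normal intensities around planted fold changes). When
    ``gene_diff`` is given, each planted gene's differential column is
    rebuilt from the linear model the screen estimates — the sum of
    ``beta * miRNA differential`` over that gene's planted effects, plus
    age and sex effects and Gaussian noise whose sd is
    ``assoc_noise_sd`` times the sd of the (first) planted miRNA
    differential, so planted slopes are recoverable at a signal-to-noise
    that does not depend on intensity units. Unplanted genes keep their
    count-derived differential (true null associations). The adjusted
    gene differential matrix is returned alongside. Finally each sample
    is hit with a lognormal multiplicative scale distortion, which the
    upper-quartile normalization is expected to undo.

    The realized (pre-distortion) miRNA differential is recorded in
    ``truth.mirna_differential``; planted betas in ``truth.assoc_betas``.
    """
    rng = np.random.default_rng(config.rng_seed + 1_000_003)
    S, M = config.n_subjects, config.n_mirnas
    mirnas = config.mirna_ids()
    genes = set(config.gene_ids())
    for g, m, _ in config.assoc_effects:
        if m not in set(mirnas):
            raise ValidationError(f"assoc_effects references unknown miRNA {m!r}")
        if g not in genes:
            raise ValidationError(f"assoc_effects references unknown gene {g!r}")
    mfc = (
        np.zeros(M)
        if config.mirna_true_log_fc is None
        else np.asarray(config.mirna_true_log_fc, dtype=float)
    )
    if mfc.shape != (M,):
        raise ValueError(f"mirna_true_log_fc must have length n_mirnas={M}")
    subjects = subjects_of(meta)
    if len(subjects) != S:
        raise ValidationError("metadata subject count does not match config")
    base = rng.lognormal(np.log(50.0), 0.8, size=M)  # per-miRNA baseline intensity
    normal = base[:, None] * rng.lognormal(
        0.0, config.mirna_intensity_sd, size=(M, S)
    )
    tumor = base[:, None] * np.exp(mfc)[:, None] * rng.lognormal(
        0.0, config.mirna_intensity_sd, size=(M, S)
    )
    diff = pd.DataFrame(tumor - normal, index=mirnas, columns=subjects)
    truth.mirna_true_log_fc = {m: float(v) for m, v in zip(mirnas, mfc)}
    truth.mirna_differential = diff.copy()

    adjusted = None
    if gene_diff is not None and config.assoc_effects:
        values = gene_diff.values.copy()
        tumor_rec = {m.subject_id: m for m in meta if m.tissue is Tissue.TUMOR}
        age = np.array([tumor_rec[s].age for s in subjects])
        sexf = np.array(
            [1.0 if tumor_rec[s].sex is Sex.FEMALE else 0.0 for s in subjects]
        )
        by_gene: dict[str, list[tuple[str, float]]] = {}
        for g, m, beta in config.assoc_effects:
            by_gene.setdefault(g, []).append((m, beta))
        for g, effects in by_gene.items():
            if g not in values.index:
                raise ValidationError(f"gene {g!r} missing from gene differential")
            signal = np.zeros(S)
            for m, beta in effects:
                signal += beta * diff.loc[m].to_numpy()
                truth.assoc_betas[(g, m)] = float(beta)
            noise_scale = config.assoc_noise_sd * float(diff.loc[effects[0][0]].std())
            values.loc[g] = (
                signal
                + config.assoc_age_beta * (age - age.mean())
                + config.assoc_sex_beta * sexf
                + rng.normal(0.0, noise_scale, size=S)
            )
        adjusted = ExpressionMatrix(values, MatrixKind.DIFFERENTIAL)

    distort = rng.lognormal(0.0, config.mirna_scale_distortion_sd, size=2 * S)
    cols = {}
    for i, s in enumerate(subjects):
        cols[f"{s}_T"] = np.maximum(tumor[:, i], 1e-6) * distort[2 * i]
        cols[f"{s}_N"] = np.maximum(normal[:, i], 1e-6) * distort[2 * i + 1]
    order = [m.sample_id for m in meta]
    intens = pd.DataFrame(cols, index=mirnas)[order]
    return ExpressionMatrix(intens, MatrixKind.MIRNA_INTENSITY), adjusted


_DNA_ALPHA = np.array(list("ACGT"))
_RC = {"A": "T", "C": "G", "G": "C", "U": "A", "T": "A"}


def _site_of(mirna_seq: str, length: int) -> str:
    seed = {6: mirna_seq[1:7], 7: mirna_seq[1:8], 8: mirna_seq[0:8]}[length]
    return "".join(_RC[c] for c in reversed(seed))


def simulate_utrs_with_seed_sites(
    mirnas: Sequence[SequenceRecord],
    plants: Sequence[tuple[str, str, int]],
    background_length: int = 500,
    rng_seed: int = 0,
) -> tuple[list[SequenceRecord], SyntheticTruth]:
    """Random-background UTRs with reverse-complement seed sites planted.

    ``plants`` rows are (miRNA id, target id, seed length in {6,7,8}).
    Backgrounds are redrawn a few times to avoid accidental occurrences of
    any planted miRNA's site strings; remaining accidental occurrences are
    recorded in ``truth.seed_collisions`` rather than forbidden.
    """
    rng = np.random.default_rng(rng_seed)
    by_id = {m.id: m for m in mirnas}
    for mid, _, L in plants:
        if mid not in by_id:
            raise ValidationError(f"unknown miRNA id {mid!r}")
        if L not in (6, 7, 8):
            raise ValidationError(f"seed length must be 6, 7 or 8, got {L}")
        if len(by_id[mid]) < 8:
            raise ValidationError(f"miRNA {mid!r} shorter than 8 nt")
    targets: dict[str, list[tuple[str, int]]] = {}
    for mid, tid, L in plants:
        targets.setdefault(tid, []).append((mid, L))
    all_sites = {
        _site_of(by_id[mid].seq, L)
        for mid, _, L in plants
    }
    truth = SyntheticTruth()
    utrs = []
    for tid, wants in sorted(targets.items()):
        total_site_len = sum(L for _, L in wants)
        if background_length < total_site_len:
            raise ValidationError(
                f"background_length {background_length} too short for planted sites"
            )
        background = None
        for _ in range(50):  # redraw to dodge accidental site occurrences
            cand = "".join(rng.choice(_DNA_ALPHA, size=background_length))
            if not any(s in cand for s in all_sites):
                background = cand
                break
        if background is None:
            background = cand
        seq = list(background)
        # insert sites by overwriting non-overlapping stretches (one spare
        # base on each side so flank fixes below cannot collide)
        occupied: list[tuple[int, int]] = []
        for mid, L in wants:
            site = _site_of(by_id[mid].seq, L)
            site8 = _site_of(by_id[mid].seq, 8)
            for _ in range(200):
                start = int(rng.integers(0, background_length - L + 1))
                if all(start + L + 1 <= lo or start - 1 >= hi for lo, hi in occupied):
                    break
            else:
                raise ValidationError(f"could not place site for {mid!r} on {tid!r}")
            occupied.append((start, start + L))
            seq[start : start + L] = site
            # a flanking base can silently extend the planted site into a
            # longer one (the 6/7/8-mer sites nest); break such extensions
            if L == 6 and start > 0 and seq[start - 1] == site8[0]:
                seq[start - 1] = str(rng.choice([c for c in "ACGT" if c != site8[0]]))
            if L == 7 and start + 7 < background_length and seq[start + 7] == site8[7]:
                seq[start + 7] = str(rng.choice([c for c in "ACGT" if c != site8[7]]))
            truth.seed_sites.append((mid, tid, start + 1, L))
        seq = "".join(seq)
        # record accidental extra occurrences of any planted site
        planted_pos = {(m, p) for m, _, p, _ in truth.seed_sites}
        for mid, L in wants:
            site = _site_of(by_id[mid].seq, L)
            start = 0
            while True:
                i = seq.find(site, start)
                if i == -1:
                    break
                if (mid, i + 1) not in planted_pos:
                    truth.seed_collisions.append((mid, tid, i + 1, L))
                start = i + 1
        utrs.append(SequenceRecord(tid, seq, "dna"))
    return utrs, truth


def simulate_survival(
    meta: Sequence[SampleMeta],
    mirna_diff: ExpressionMatrix,
    config: SimulationConfig,
    survival_mirna: str | None = None,
    truth: SyntheticTruth | None = None,
) -> list[SampleMeta]:
    """Fill survival fields from a proportional-hazards model.

    Event times are exponential with rate baseline_hazard *
    exp(lp), lp = cox_betas over (centered age, sex, centered stage,
    exposure); administrative censoring at a single time tuned so the
    expected censored fraction equals ``censor_fraction_target``.
    ``crc_death`` is true exactly for simulated events.
    """
    rng = np.random.default_rng(config.rng_seed + 2_000_003)
    subjects = subjects_of(meta)
    rec = {m.subject_id: m for m in meta if m.tissue is Tissue.TUMOR}
    if survival_mirna is None:
        survival_mirna = mirna_diff.feature_ids[0]
    if survival_mirna not in mirna_diff.values.index:
        raise ValidationError(f"miRNA {survival_mirna!r} not in differential matrix")
    expo = mirna_diff.values.loc[survival_mirna, subjects].to_numpy(dtype=float)
    age = np.array([rec[s].age for s in subjects])
    sexf = np.array([1.0 if rec[s].sex is Sex.FEMALE else 0.0 for s in subjects])
    stage = np.array([float(rec[s].stage) for s in subjects])
    b = config.cox_betas
    lp = (
        b.get("age", 0.0) * (age - age.mean())
        + b.get("sex", 0.0) * (sexf - sexf.mean())
        + b.get("stage", 0.0) * (stage - stage.mean())
        + b.get("exposure", 0.0) * (expo - expo.mean())
    )
    rate = config.baseline_hazard * np.exp(lp)
    times = rng.exponential(1.0 / rate)

    def censored_frac(c: float) -> float:
        return float(np.mean(np.exp(-rate * c)))

    lo, hi = 1e-9, 1e9
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if censored_frac(mid) > config.censor_fraction_target:
            lo = mid
        else:
            hi = mid
    censor_time = np.sqrt(lo * hi)
    event = times <= censor_time
    obs = np.minimum(times, censor_time)
    if truth is not None:
        truth.cox_betas = dict(b)
        truth.survival_mirna = survival_mirna
        truth.censor_time = float(censor_time)
    info = {
        s: (float(t), bool(e)) for s, t, e in zip(subjects, obs, event)
    }
    out = []
    for m in meta:
        t, e = info[m.subject_id]
        out.append(
            replace(
                m,
                survival_months=t,
                vital=Vital.DEAD if e else Vital.ALIVE,
                crc_death=e,
            )
        )
    return out
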