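"""Gene:miRNA association screen with a residual-resampling bootstrap F-null.

For each candidate (gene, miRNA) pair, per-subject differential expression
of the gene (tumor minus normal, RPMPCG scale) is regressed by ordinary
least squares on the per-subject miRNA differential, adjusting for age and
sex:

    gene_diff_i = b0 + beta * mirna_diff_i + b_age * age_i + b_sex * sex_i + e_i.

The test statistic is the extra-sum-of-squares F comparing this model to
the covariates-only null (intercept + age + sex). Its reference
distribution is built empirically: residuals of the *null* fit are
resampled with replacement, added back to the null fitted values, both
models are refit to each bootstrap response, and the bootstrap p-value is
(1 + #{F* >= F_obs}) / (n_boot + 1) — the add-one Monte-Carlo convention,
which can never return zero. With Gaussian errors this converges to the
classical F-test p-value.

Candidates are the genes and miRNAs whose tumor/normal fold change falls
outside [0.67, 1.50]; Benjamini-Hochberg adjustment is applied jointly
across all pairs tested in a run. Pairs with a negative slope (miRNA up,
gene down, or vice versa) are flagged ``inverse`` — the direction expected
of direct seed-mediated repression.

Per-pair bootstrap streams are derived by hashing the pair ids together
with the root seed, so results do not depend on pair enumeration order.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .diffexp import DEResult, bh_adjust
from .io import ExpressionMatrix, SampleMeta, Tissue, ValidationError

__all__ = [
    "LinearFit",
    "AssociationResult",
    "ScreenConfig",
    "fit_adjusted_linear",
    "bootstrap_f_pvalue",
    "run_association_screen",
]


@dataclass
class LinearFit:
    """OLS fit of gene differential on (miRNA differential, age, sex)."""

    beta: float
    f_stat: float
    x_full: np.ndarray  # n x 4 design: intercept, mirna, age, sex
    x_null: np.ndarray  # n x 3 design: intercept, age, sex
    null_fitted: np.ndarray
    null_residuals: np.ndarray
    full_residuals: np.ndarray
    df_resid: int


@dataclass
class AssociationResult:
    gene: str
    mirna: str
    beta: float
    f_stat: float
    boot_p: float
    fdr_p: float
    n_boot: int
    direction: str  # "inverse" | "positive"
    significant: bool = False


@dataclass
class ScreenConfig:
    fc_lower: float = 0.67
    fc_upper: float = 1.50
    alpha: float = 0.05
    n_boot: int = 10_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.fc_lower <= 0 or self.fc_upper <= 0:
            raise ValueError("fold-change thresholds must be positive")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")


def _check_rank(x: np.ndarray, names: Sequence[str]) -> None:
    if np.linalg.matrix_rank(x) < x.shape[1]:
        # identify offending columns by dropping each in turn
        bad = [
            names[j]
            for j in range(1, x.shape[1])
            if np.linalg.matrix_rank(np.delete(x, j, axis=1)) == np.linalg.matrix_rank(x)
        ]
        raise ValidationError(f"collinear design columns: {bad or 'unknown'}")


def _rss(q: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of y (vector or matrix of columns) given an
    orthonormal basis q of the design column space."""
    total = np.sum(y * y, axis=0)
    proj = q.T @ y
    return total - np.sum(proj * proj, axis=0)


def fit_adjusted_linear(
    gene_diff: Sequence[float] | np.ndarray,
    mirna_diff: Sequence[float] | np.ndarray,
    age: Sequence[float] | np.ndarray,
    sex: Sequence[str] | np.ndarray,
) -> LinearFit:
    """OLS of gene differential on miRNA differential with age/sex adjustment.

    ``sex`` may be strings ("male"/"female") or a numeric indicator;
    females are coded 1. Returns the slope, the extra-sum-of-squares F for
    the miRNA term, and the residual sets of both models.
    """
    y = np.asarray(gene_diff, dtype=float)
    x = np.asarray(mirna_diff, dtype=float)
    a = np.asarray(age, dtype=float)
    s = np.asarray(
        [1.0 if str(v).lower() in ("female", "f", "1", "1.0") else 0.0 for v in sex]
    )
    n = y.size
    if not (x.size == a.size == s.size == n):
        raise ValidationError("all inputs must have the same length")
    if np.ptp(x) == 0:
        raise ValidationError("miRNA differential has zero variance")
    # constant covariates are absorbed by the intercept
    covars = [(name, c) for name, c in (("age", a), ("sex", s)) if np.ptp(c) > 0]
    x_full = np.column_stack([np.ones(n), x] + [c for _, c in covars])
    x_null = np.delete(x_full, 1, axis=1)
    if n <= x_full.shape[1]:
        raise ValidationError(
            f"need more subjects than coefficients (n={n}, p={x_full.shape[1]})"
        )
    _check_rank(x_full, ["intercept", "mirna_diff"] + [name for name, _ in covars])
    coef, _, _, _ = np.linalg.lstsq(x_full, y, rcond=None)
    coef0, _, _, _ = np.linalg.lstsq(x_null, y, rcond=None)
    fitted = x_full @ coef
    fitted0 = x_null @ coef0
    res = y - fitted
    res0 = y - fitted0
    df_resid = n - x_full.shape[1]
    rss1 = float(res @ res)
    rss0 = float(res0 @ res0)
    num = max(rss0 - rss1, 0.0)
    f_stat = 0.0 if rss1 <= 0 and num <= 1e-300 else num / (rss1 / df_resid) if rss1 > 0 else np.inf
    if num == 0.0:
        f_stat = 0.0
    return LinearFit(
        beta=float(coef[1]),
        f_stat=float(f_stat),
        x_full=x_full,
        x_null=x_null,
        null_fitted=fitted0,
        null_residuals=res0,
        full_residuals=res,
        df_resid=df_resid,
    )


def bootstrap_f_pvalue(
    fit: LinearFit, n_boot: int = 10_000, rng_seed: int = 0
) -> float:
    """Bootstrap p-value for the miRNA F statistic under the no-association null.

    Null-model residuals are resampled with replacement and added to the
    null fitted values; both models are refit to each bootstrap response
    (all refits vectorized through fixed orthonormal bases of the two
    design spaces). p = (1 + #{F* >= F_obs}) / (n_boot + 1).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(rng_seed)
    n = fit.null_residuals.size
    q_full, _ = np.linalg.qr(fit.x_full)
    q_null, _ = np.linalg.qr(fit.x_null)
    exceed = 0
    chunk = max(1, min(n_boot, int(5e6) // max(n, 1)))
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(n, b))
        ystar = fit.null_fitted[:, None] + fit.null_residuals[idx]
        rss1 = _rss(q_full, ystar)
        rss0 = _rss(q_null, ystar)
        with np.errstate(divide="ignore", invalid="ignore"):
            fstar = np.maximum(rss0 - rss1, 0.0) / (rss1 / fit.df_resid)
        fstar = np.nan_to_num(fstar, nan=0.0, posinf=np.inf)
        exceed += int(np.sum(fstar >= fit.f_stat))
        done += b
    return (1 + exceed) / (n_boot + 1)


def _pair_seed(root: int, gene: str, mirna: str) -> int:
    h = hashlib.sha256(f"{root}:{gene}:{mirna}".encode()).digest()
    return int.from_bytes(h[:4], "big")


def _subject_covariates(
    meta: Sequence[SampleMeta], subjects: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    rec = {m.subject_id: m for m in meta if m.tissue is Tissue.TUMOR}
    missing = [s for s in subjects if s not in rec]
    if missing:
        raise ValidationError(f"subjects without metadata: {missing}")
    age = np.array([rec[s].age for s in subjects])
    sex = np.array([rec[s].sex.value for s in subjects])
    return age, sex


def run_association_screen(
    gene_de: Sequence[DEResult],
    mirna_de: Sequence[DEResult],
    gene_diff: ExpressionMatrix,
    mirna_diff: ExpressionMatrix,
    meta: Sequence[SampleMeta],
    config: ScreenConfig | None = None,
) -> list[AssociationResult]:
    """Test every dysregulated gene x dysregulated miRNA pair.

    Genes and miRNAs whose fold change lies outside [fc_lower, fc_upper]
    enter the screen; every pair is tested with the bootstrap F, and BH
    adjustment is applied once across all tested pairs. Deterministic for
    a given ``config.rng_seed`` regardless of pair order.
    """
    config = config or ScreenConfig()
    genes = sorted(
        r.gene
        for r in gene_de
        if np.isfinite(r.fold_change)
        and (r.fold_change < config.fc_lower or r.fold_change > config.fc_upper)
        and r.gene in gene_diff.values.index
    )
    mirnas = sorted(
        r.gene
        for r in mirna_de
        if np.isfinite(r.fold_change)
        and (r.fold_change < config.fc_lower or r.fold_change > config.fc_upper)
        and r.gene in mirna_diff.values.index
    )
    if not genes or not mirnas:
        raise ValidationError("no genes or no miRNAs pass the fold-change filter")
    subjects = gene_diff.sample_ids
    if mirna_diff.sample_ids != subjects:
        raise ValidationError("gene and miRNA differential matrices must share subjects")
    age, sex = _subject_covariates(meta, subjects)
    results: list[AssociationResult] = []
    for g in genes:
        gvec = gene_diff.values.loc[g].to_numpy(dtype=float)
        for m in mirnas:
            mvec = mirna_diff.values.loc[m].to_numpy(dtype=float)
            fit = fit_adjusted_linear(gvec, mvec, age, sex)
            bp = bootstrap_f_pvalue(fit, config.n_boot, _pair_seed(config.rng_seed, g, m))
            results.append(
                AssociationResult(
                    gene=g,
                    mirna=m,
                    beta=fit.beta,
                    f_stat=fit.f_stat,
                    boot_p=bp,
                    fdr_p=np.nan,
                    n_boot=config.n_boot,
                    direction="inverse" if fit.beta < 0 else "positive",
                )
            )
    adj = bh_adjust([r.boot_p for r in results])
    for r, ap in zip(results, adj):
        r.fdr_p = float(ap)
        r.significant = bool(ap < config.alpha)
    return results
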