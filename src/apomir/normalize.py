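"""Expression normalization and the per-subject differential transform.

Two bespoke normalizations feed everything downstream:

* **RPMPCG** (reads per million protein-coding genes): each gene's count in
  a sample divided by that sample's total count over protein-coding genes,
  times 1e6. The protein-coding total also provides the log offset for the
  paired negative-binomial model.
* **Upper-quartile scaling** for miRNA array intensities: each sample is
  multiplied by (median over samples of the 75th percentile) / (that
  sample's 75th percentile), so every sample's upper quartile is brought to
  the common median value.

The **paired differential transform** collapses each feature's tumor and
normal values per subject to a single number — tumor minus normal
(default; keeps zeros legal and linear models well-posed) or tumor/normal
(per-subject fold change; requires a zero-handling rule).

Percentiles use linear interpolation between order statistics throughout
(numpy's default, the "type 7" rule); the rule is a parameter so an
alternative convention can be swapped in.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    MatrixKind,
    PathwayGeneList,
    SampleMeta,
    Tissue,
    ValidationError,
    check_pairing,
    subjects_of,
)

__all__ = [
    "rpmpcg_normalize",
    "protein_coding_totals",
    "mirna_quantile_scale",
    "quantile_scale_factors",
    "paired_differential",
]


def protein_coding_totals(
    counts: ExpressionMatrix, protein_coding_ids: PathwayGeneList | Sequence[str]
) -> pd.Series:
    """Per-sample total count over the protein-coding gene set."""
    ids = [g for g in protein_coding_ids if g in counts.values.index]
    if not ids:
        raise ValidationError("no protein-coding gene ids present in the count matrix")
    totals = counts.values.loc[ids].sum(axis=0).astype(float)
    zero = totals.index[totals <= 0].tolist()
    if zero:
        raise ValidationError(f"samples with zero protein-coding total: {zero}")
    return totals


def rpmpcg_normalize(
    counts: ExpressionMatrix, protein_coding_ids: PathwayGeneList | Sequence[str]
) -> ExpressionMatrix:
    """Scale counts to reads per million protein-coding transcripts.

    value(g, s) = count(g, s) / sum over protein-coding g' of count(g', s) * 1e6.
    The per-sample protein-coding sums of the output equal 1e6 by
    construction, and the transform is invariant to rescaling any single
    sample's counts.
    """
    if counts.kind is not MatrixKind.MRNA_COUNTS:
        raise ValidationError(f"expected mrna_counts matrix, got {counts.kind.value}")
    totals = protein_coding_totals(counts, protein_coding_ids)
    values = counts.values.astype(float).div(totals, axis=1) * 1e6
    return ExpressionMatrix(values, MatrixKind.RPMPCG)


def quantile_scale_factors(
    intensities: ExpressionMatrix, q: float = 0.75
) -> pd.DataFrame:
    """Per-sample upper-quartile scaling report: sample, P75, factor."""
    arr = intensities.values.to_numpy(dtype=float)
    p75 = np.quantile(arr, q, axis=0)  # linear-interpolation percentile
    zero = [s for s, v in zip(intensities.sample_ids, p75) if v <= 0]
    if zero:
        raise ValidationError(f"samples with nonpositive 75th percentile: {zero}")
    med = float(np.median(p75))
    return pd.DataFrame(
        {"sample": intensities.sample_ids, "p75": p75, "factor": med / p75}
    )


def mirna_quantile_scale(
    intensities: ExpressionMatrix, q: float = 0.75
) -> ExpressionMatrix:
    """Scale each sample so its 75th percentile equals the across-sample median P75.

    Idempotent: after one application every sample's P75 equals the common
    median, so a second application multiplies by 1.
    """
    if intensities.kind is not MatrixKind.MIRNA_INTENSITY:
        raise ValidationError(
            f"expected mirna_intensity matrix, got {intensities.kind.value}"
        )
    report = quantile_scale_factors(intensities, q)
    values = intensities.values.mul(
        pd.Series(report["factor"].to_numpy(), index=intensities.sample_ids), axis=1
    )
    return ExpressionMatrix(values, MatrixKind.MIRNA_INTENSITY)


def paired_differential(
    matrix: ExpressionMatrix,
    meta: Sequence[SampleMeta],
    mode: str = "difference",
    pseudocount: float | None = None,
) -> ExpressionMatrix:
    """Collapse tumor/normal sample pairs to one per-subject column.

    Parameters
    ----------
    mode
        ``"difference"`` — tumor minus normal (default). ``"ratio"`` —
        tumor / normal; a normal value of zero is an error unless
        ``pseudocount`` is given, in which case it is added to both members.
    """
    if mode not in ("difference", "ratio"):
        raise ValueError(f"mode must be 'difference' or 'ratio', got {mode!r}")
    check_pairing(meta)
    subjects = subjects_of(meta)
    have = set(matrix.sample_ids)
    missing = [
        s for s in subjects if f"{s}_T" not in have or f"{s}_N" not in have
    ]
    if missing:
        raise ValidationError(f"subjects missing matrix columns: {missing}")
    tumor = matrix.values[[f"{s}_T" for s in subjects]].to_numpy(dtype=float)
    normal = matrix.values[[f"{s}_N" for s in subjects]].to_numpy(dtype=float)
    if mode == "difference":
        out = tumor - normal
    else:
        if pseudocount is not None:
            tumor = tumor + pseudocount
            normal = normal + pseudocount
        if (normal == 0).any():
            i, j = np.argwhere(normal == 0)[0]
            raise ValidationError(
                f"ratio undefined: normal value 0 for feature "
                f"{matrix.feature_ids[i]!r}, subject {subjects[j]!r} "
                "(enable a pseudocount to permit zeros)"
            )
        out = tumor / normal
    values = pd.DataFrame(out, index=matrix.feature_ids, columns=subjects)
    return ExpressionMatrix(values, MatrixKind.DIFFERENTIAL)
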