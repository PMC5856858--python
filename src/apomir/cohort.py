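"""Study-population summary tables (counts, percentages, mean age)."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .io import SampleMeta, Phenotype, Tissue

__all__ = ["cohort_percentages", "make_cohort_report"]


def cohort_percentages(counts: pd.DataFrame) -> pd.DataFrame:
    """Attach percentages to a (category, level, count) table.

    Percentages are computed over the non-missing denominator of each
    category — the sum of that category's counts — and rounded to 1 dp,
    matching how clinical descriptive tables are printed.
    """
    out = counts.copy()
    totals = out.groupby("category")["count"].transform("sum")
    out["percent"] = np.round(100.0 * out["count"] / totals, 1)
    return out


def make_cohort_report(meta: Sequence[SampleMeta]) -> pd.DataFrame:
    """Counts and percentages by site, sex, stage, phenotype and vital status,
    plus mean (SD) age, from subject-level metadata.

    Subjects with unknown phenotype are excluded from the phenotype
    denominator (percentages are per non-missing category).
    """
    if not meta:
        raise ValueError("metadata is empty")
    seen = set()
    subjects = []
    for m in meta:
        if m.subject_id not in seen:
            seen.add(m.subject_id)
            subjects.append(m)
    rows = []

    def tally(category: str, values) -> None:
        vc = pd.Series(values).value_counts()
        for level, n in vc.items():
            rows.append({"category": category, "level": str(level), "count": int(n)})

    tally("site", [s.site.value for s in subjects])
    tally("sex", [s.sex.value for s in subjects])
    tally("stage", [s.stage for s in subjects])
    tally(
        "phenotype",
        [s.phenotype.value for s in subjects if s.phenotype is not Phenotype.UNKNOWN],
    )
    tally("vital", [s.vital.value for s in subjects])
    report = cohort_percentages(pd.DataFrame(rows))
    ages = np.array([s.age for s in subjects])
    age_row = pd.DataFrame(
        [
            {
                "category": "age",
                "level": f"mean (SD) {ages.mean():.1f} ({ages.std(ddof=1):.1f})"
                if len(ages) > 1
                else f"mean {ages.mean():.1f}",
                "count": len(ages),
                "percent": 100.0,
            }
        ]
    )
    return pd.concat([report, age_row], ignore_index=True)
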