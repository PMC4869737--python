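"""Group-level statistics: secretion normalisation, two-sample t tests and
spider-plot normalisation across disease stages.

Secretion is expressed as a percentage of islet insulin content; two-group
comparisons use the classical pooled-variance (Student's) two-tailed unpaired
t test with significance at p < 0.05, matching how the stage comparisons were
analysed; Welch's correction is available behind a flag.  The spider summary
rescales each variable to [0, 1] by a stated reference maximum, with the GTT
AUC inverted and expressed as a fraction of 5,000 mmol/l x min so that a
healthier (lower) AUC plots larger.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SecretionRecord", "GroupComparison", "normalize_secretion",
           "compare_groups", "spider_normalise", "AUC_SPIDER_REFERENCE"]

AUC_SPIDER_REFERENCE = 5000.0  # mmol/l x min, the spider-plot AUC scale
ALPHA = 0.05


@dataclass
class SecretionRecord:
    """One secretion measurement at one glucose condition."""

    group: str
    glucose_condition_mmol_l: float
    secreted_ng: float
    content_ng: float

    @property
    def percent_content(self) -> float:
        return normalize_secretion(self.secreted_ng, self.content_ng)


@dataclass
class GroupComparison:
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    t_statistic: float
    df: float
    p_value: float
    significant: bool


def normalize_secretion(secreted_ng: float, content_ng: float) -> float:
    """Secretion as a percentage of insulin content: 100 * secreted/content."""
    if content_ng <= 0:
        raise ValueError("insulin content must be positive")
    if secreted_ng < 0:
        raise ValueError("secreted amount must be non-negative")
    return 100.0 * secreted_ng / content_ng


def compare_groups(a: Sequence[float], b: Sequence[float],
                   welch: bool = False) -> GroupComparison:
    """Two-tailed unpaired t test between two samples.

    Default is the classical pooled-variance Student's test with
    df = n_a + n_b - 2; ``welch=True`` uses the unequal-variance form.
    Two identical constant samples give t = 0, p = 1; constant samples with
    unequal means have no sampling variability to test against and raise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    na, nb = a.size, b.size
    mean_a, mean_b = a.mean(), b.mean()
    var_a, var_b = a.var(ddof=1), b.var(ddof=1)

    if welch:
        se2 = var_a / na + var_b / nb
        if se2 == 0:
            return _degenerate(mean_a, mean_b, na, nb, var_a, var_b,
                               df=float(na + nb - 2))
        t = (mean_a - mean_b) / np.sqrt(se2)
        df = se2 ** 2 / ((var_a / na) ** 2 / (na - 1) + (var_b / nb) ** 2 / (nb - 1))
    else:
        df = float(na + nb - 2)
        pooled = ((na - 1) * var_a + (nb - 1) * var_b) / df
        if pooled == 0:
            return _degenerate(mean_a, mean_b, na, nb, var_a, var_b, df=df)
        t = (mean_a - mean_b) / np.sqrt(pooled * (1.0 / na + 1.0 / nb))

    p = 2.0 * stats.t.sf(abs(t), df)
    return GroupComparison(
        mean_a=float(mean_a), sem_a=float(np.sqrt(var_a / na)),
        mean_b=float(mean_b), sem_b=float(np.sqrt(var_b / nb)),
        t_statistic=float(t), df=float(df), p_value=float(p),
        significant=bool(p < ALPHA),
    )


def _degenerate(mean_a, mean_b, na, nb, var_a, var_b, df) -> GroupComparison:
    if mean_a != mean_b:
        raise ValueError("zero variance with unequal means: t test undefined")
    return GroupComparison(mean_a=float(mean_a), sem_a=0.0,
                           mean_b=float(mean_b), sem_b=0.0,
                           t_statistic=0.0, df=df, p_value=1.0,
                           significant=False)


def spider_normalise(table: pd.DataFrame,
                     reference: dict[str, float],
                     inverted: Optional[set[str]] = None) -> pd.DataFrame:
    """Rescale per-group means and SEMs to [0, 1] by per-variable references.

    ``table`` needs columns variable, group, mean, sem.  ``reference`` maps
    each variable to its positive reference maximum.  Variables in
    ``inverted`` (default: any variable named 'auc') are flipped to
    1 - mean/reference so that smaller raw values plot larger; the ribbon
    width (sem/reference) is unaffected by the flip.
    """
    if inverted is None:
        inverted = {"auc"}
    required = {"variable", "group", "mean", "sem"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table is missing columns: {sorted(missing)}")
    rows = []
    for row in table.itertuples(index=False):
        if row.variable not in reference:
            raise ValueError(f"no reference scale for variable '{row.variable}'")
        ref = reference[row.variable]
        if ref <= 0:
            raise ValueError(f"reference for '{row.variable}' must be positive")
        norm_mean = row.mean / ref
        if row.variable in inverted:
            norm_mean = 1.0 - norm_mean
        rows.append({"variable": row.variable, "group": row.group,
                     "norm_mean": norm_mean, "norm_sem": row.sem / ref})
    return pd.DataFrame(rows)
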