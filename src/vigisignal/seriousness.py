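"""Seriousness and demographic profile comparison across compounds.

Reports are cross-tabulated as drugs x categories (seriousness outcome or
age band), tested for independence with a Pearson chi-square, and followed
up with post hoc adjusted standardized residuals

    r_ij = (O_ij - E_ij) / sqrt(E_ij (1 - n_i./N) (1 - n_.j/N))

which are approximately standard normal under independence; their two-sided
p-values are Bonferroni-corrected over all tested cells.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import VigisignalError
from .ingest import subset
from .schema import AGE_GROUPS, SERIOUS_CATEGORIES, SERIOUSNESS_CATEGORIES

logger = logging.getLogger("vigisignal")

_AXES = {"seriousness": SERIOUSNESS_CATEGORIES, "age_group": AGE_GROUPS}


def tabulate(collection: pd.DataFrame, drugs: Sequence[str],
             axis: str = "seriousness") -> pd.DataFrame:
    """Counts of reports per drug x category.

    A report suspecting several of the listed drugs contributes to each of
    their rows, as it would in per-substance line-listing exports.
    """
    if axis not in _AXES:
        raise VigisignalError(f"unknown axis {axis!r}; use 'seriousness' or 'age_group'")
    categories = _AXES[axis]
    rows = {}
    for drug in drugs:
        sub = subset(collection, drug=drug)
        counts = sub[axis].value_counts()
        rows[drug] = [int(counts.get(cat, 0)) for cat in categories]
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(categories))


def row_percentages(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise percentages of a category matrix, at full precision."""
    totals = matrix.sum(axis=1)
    return 100 * matrix.div(totals, axis=0)


def serious_fraction(row: pd.Series) -> float:
    """Percentage of serious cases in one seriousness-matrix row.

    Serious means fatal, life-threatening, disabling, or having caused or
    prolonged hospitalization.  Returned at two decimals.
    """
    total = row.sum()
    if total == 0:
        raise VigisignalError("zero row total")
    serious = sum(row.get(cat, 0) for cat in SERIOUS_CATEGORIES)
    return round(100 * serious / total, 2)


def _drop_degenerate(matrix: pd.DataFrame) -> pd.DataFrame:
    m = matrix.loc[matrix.sum(axis=1) > 0, matrix.sum(axis=0) > 0]
    if m.shape != matrix.shape:
        warnings.warn("zero row/column dropped before the independence test")
    return m


def independence_test(matrix: pd.DataFrame) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on the full matrix.

    Returns ``(chi2, dof, p)``.  All-zero rows or columns are dropped with
    a warning before testing.
    """
    m = _drop_degenerate(matrix)
    if m.shape[0] < 2 or m.shape[1] < 2 or m.to_numpy().sum() == 0:
        raise VigisignalError("independence test needs at least a 2x2 matrix")
    chi2, p, dof, _ = stats.chi2_contingency(m.to_numpy(), correction=False)
    return float(chi2), int(dof), float(p)


def adjusted_residuals(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Adjusted standardized residuals and their two-sided normal p-values.

    Cells whose variance term degenerates (a margin equal to the grand
    total) are returned as NaN.
    """
    counts = matrix.to_numpy(dtype=float)
    n = counts.sum()
    if n == 0:
        raise VigisignalError("empty matrix")
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    expected = np.outer(row, col) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        var = expected * (1 - row[:, None] / n) * (1 - col[None, :] / n)
        resid = np.where(var > 0, (counts - expected) / np.sqrt(var), np.nan)
    pvals = 2 * stats.norm.sf(np.abs(resid))
    index, columns = matrix.index, matrix.columns
    return (pd.DataFrame(resid, index=index, columns=columns),
            pd.DataFrame(pvals, index=index, columns=columns))


def bonferroni_flags(p_matrix: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Significance flags at the Bonferroni-corrected level alpha / (R*C)."""
    values = p_matrix.to_numpy(dtype=float)
    if np.nanmin(values) < 0 or np.nanmax(values) > 1:
        raise VigisignalError("p-values must lie in [0, 1]")
    m = values.size
    return p_matrix < alpha / m
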