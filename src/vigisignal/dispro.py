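"""Disproportionality analysis on 2x2 contingency tables.

Each suspected drug-event pair is tabulated against the full-database
comparator:

=============  ==================  =====================
               event reported      event not reported
=============  ==================  =====================
drug suspect   a                   b
other reports  c                   d
=============  ==================  =====================

with ``a + b`` the drug margin, ``a + c`` the event margin and ``N`` the
size of the whole de-duplicated database (the index drug's reports stay in
the margins).  On that table

* PRR = [a/(a+b)] / [c/(c+d)]  (proportional reporting ratio),
* ROR = (a.d)/(b.c)            (reporting odds ratio), with a Wald
  confidence interval exp(ln ROR +- z * sqrt(1/a + 1/b + 1/c + 1/d)),
* Pearson chi-square on one degree of freedom, optionally with the Yates
  continuity correction, and
* the EMA signal-of-disproportionate-reporting (SDR) rule:
  a >= 3, chi-square >= 4 and PRR >= 2, all thresholds inclusive.

Counting is at report level: a preferred term contributes at most once per
report, and a report contributes once per system organ class in SOC-level
scans.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import VigisignalError
from .ingest import TermMaps, subset

logger = logging.getLogger("vigisignal")

#: Default SDR thresholds: minimum cases, chi-square, PRR.
SDR_THRESHOLDS = (3, 4.0, 2.0)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts for one drug-event pair against the full database."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise VigisignalError(f"negative cell in {self}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def drug_margin(self) -> int:
        return self.a + self.b

    @property
    def event_margin(self) -> int:
        return self.a + self.c

    @classmethod
    def from_margins(cls, a: int, drug_margin: int, event_margin: int,
                     n: int) -> "ContingencyTable":
        """Build the table from the counts a study typically publishes:
        joint count, drug margin, event margin and database size."""
        return cls(a, drug_margin - a, event_margin - a,
                   n - drug_margin - (event_margin - a))


@dataclass
class SignalResult:
    """Disproportionality statistics for one drug-event (or drug-SOC) pair.

    ``chi2`` is the Yates-corrected statistic used by the SDR rule;
    ``chi2_uncorrected`` is also kept.  ``p_value`` is the two-sided normal
    test on ln ROR with the Wald standard error.  ``zero_cell_corrected``
    marks pairs where 0.5 was added to every cell before the odds ratio.
    """

    drug: str
    event: str
    table: ContingencyTable
    prr: float
    ror: float
    ror_ci: tuple
    chi2: float
    chi2_uncorrected: float
    p_value: float
    is_sdr: bool
    stratum: str = "all"
    zero_cell_corrected: bool = False


def _policy_cells(table: ContingencyTable) -> tuple[tuple, bool]:
    """Haldane-Anscombe correction, applied only when b or c is zero."""
    if table.b == 0 or table.c == 0:
        return (table.a + 0.5, table.b + 0.5, table.c + 0.5, table.d + 0.5), True
    return (float(table.a), float(table.b), float(table.c), float(table.d)), False


def compute_prr(table: ContingencyTable) -> float:
    """Proportional reporting ratio [a/(a+b)] / [c/(c+d)]."""
    if table.drug_margin == 0:
        raise VigisignalError("PRR undefined: drug margin is zero")
    if table.c == 0:
        warnings.warn("no comparator events: PRR reported as +inf")
        return math.inf
    return (table.a / table.drug_margin) / (table.c / (table.c + table.d))


def compute_ror(table: ContingencyTable) -> float:
    """Reporting odds ratio (a.d)/(b.c), with the zero-cell policy."""
    (a, b, c, d), _ = _policy_cells(table)
    return (a * d) / (b * c)


def ror_confidence_interval(table: ContingencyTable,
                            level: float = 0.95) -> tuple[float, float]:
    """Wald interval for the ROR on the log scale."""
    if not 0 < level < 1:
        raise VigisignalError(f"confidence level must be in (0,1), got {level}")
    (a, b, c, d), _ = _policy_cells(table)
    if min(a, b, c, d) == 0:
        raise VigisignalError("ROR interval undefined with an empty cell")
    z = stats.norm.ppf(0.5 + level / 2)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ror = (a * d) / (b * c)
    return ror * math.exp(-z * se), ror * math.exp(z * se)


def ror_p_value(table: ContingencyTable) -> float:
    """Two-sided normal test of ln ROR = 0 with the Wald standard error."""
    (a, b, c, d), _ = _policy_cells(table)
    if min(a, b, c, d) == 0:
        return float("nan")
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = math.log((a * d) / (b * c)) / se
    return 2 * stats.norm.sf(abs(z))


def chi_square(table: ContingencyTable,
               continuity_correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square (1 dof) with optional Yates correction."""
    n = table.n
    m1, m0 = table.drug_margin, table.c + table.d
    e1, e0 = table.event_margin, table.b + table.d
    if n == 0 or 0 in (m1, m0, e1, e0):
        warnings.warn("degenerate 2x2 margin: chi-square reported as 0")
        return 0.0, 1.0
    diff = abs(table.a * table.d - table.b * table.c)
    if continuity_correction:
        diff = max(0.0, diff - n / 2)
    statistic = n * diff * diff / (m1 * m0 * e1 * e0)
    return statistic, float(stats.chi2.sf(statistic, df=1))


def evaluate_sdr(a: int, chi2: float, prr: float,
                 thresholds: Sequence[float] = SDR_THRESHOLDS) -> bool:
    """EMA signal-of-disproportionate-reporting rule (inclusive thresholds)."""
    t_a, t_chi2, t_prr = thresholds
    return a >= t_a and chi2 >= t_chi2 and prr >= t_prr


def membership_matrix(sets: pd.Series, universe: Sequence[str]) -> np.ndarray:
    """Boolean reports x terms matrix of set membership."""
    index = {name: j for j, name in enumerate(universe)}
    m = np.zeros((len(sets), len(universe)), dtype=bool)
    for i, items in enumerate(sets):
        for name in items:
            j = index.get(name)
            if j is not None:
                m[i, j] = True
    return m


def build_contingency(
    collection: pd.DataFrame,
    drug: str,
    event: Union[str, Callable[[frozenset], bool]],
) -> ContingencyTable:
    """Count the 2x2 table for one drug against one event predicate.

    ``event`` is a preferred-term name, or any predicate over a report's
    reaction set.  The collection is assumed de-duplicated and normalized.
    """
    if len(collection) == 0:
        raise VigisignalError("empty collection")
    has_drug = collection["suspect_drugs"].map(lambda s: drug in s).to_numpy()
    if callable(event):
        has_event = collection["reactions"].map(event).to_numpy(dtype=bool)
    else:
        has_event = collection["reactions"].map(lambda s: event in s).to_numpy()
    a = int((has_drug & has_event).sum())
    b = int((has_drug & ~has_event).sum())
    c = int((~has_drug & has_event).sum())
    d = int((~has_drug & ~has_event).sum())
    return ContingencyTable(a, b, c, d)


def _result_for(drug: str, event: str, table: ContingencyTable, stratum: str,
                thresholds: Sequence[float]) -> SignalResult:
    prr = compute_prr(table)
    chi2_y, _ = chi_square(table, continuity_correction=True)
    chi2_u, _ = chi_square(table, continuity_correction=False)
    cells, corrected = _policy_cells(table)
    if table.a == 0:
        ror, ci, p = 0.0, (float("nan"), float("nan")), float("nan")
    else:
        ror = compute_ror(table)
        ci = ror_confidence_interval(table) if min(cells) > 0 else (float("nan"),) * 2
        p = ror_p_value(table)
    return SignalResult(
        drug=drug, event=event, table=table, prr=prr, ror=ror, ror_ci=ci,
        chi2=chi2_y, chi2_uncorrected=chi2_u, p_value=p,
        is_sdr=evaluate_sdr(table.a, chi2_y, prr, thresholds),
        stratum=stratum, zero_cell_corrected=corrected,
    )


def signal_scan(
    collection: pd.DataFrame,
    drugs: Sequence[str],
    level: str = "pt",
    stratum: str = "all",
    term_maps: Optional[TermMaps] = None,
    thresholds: Sequence[float] = SDR_THRESHOLDS,
) -> list[SignalResult]:
    """Scan every drug x event pair with at least one joint report.

    ``level="soc"`` groups preferred terms by primary system organ class
    before counting (one count per report per SOC; ``term_maps`` required).
    ``stratum="serious_only"`` restricts numerator and comparator alike to
    serious reports, so the 2x2 tables stay internally consistent.
    Pairs with fewer than three cases are reported but can never be flagged
    as signals, which the case-count threshold enforces by itself.
    """
    if not drugs:
        raise VigisignalError("empty drug list")
    if stratum not in ("all", "serious_only"):
        raise VigisignalError(f"unknown stratum {stratum!r}")
    df = subset(collection, serious_only=(stratum == "serious_only"))
    if len(df) == 0:
        raise VigisignalError("no reports left in stratum")
    if level == "pt":
        event_sets = df["reactions"]
    elif level == "soc":
        if term_maps is None:
            raise VigisignalError("SOC-level scan requires term maps")
        event_sets = df["reactions"].map(
            lambda s: frozenset(term_maps.soc(pt) for pt in s))
    else:
        raise VigisignalError(f"unknown level {level!r}")
    events = sorted(set().union(*event_sets)) if len(event_sets) else []
    drug_m = membership_matrix(df["suspect_drugs"], drugs)
    event_m = membership_matrix(event_sets, events)
    n = len(df)
    joint = drug_m.T.astype(np.int64) @ event_m.astype(np.int64)
    drug_margins = drug_m.sum(axis=0)
    event_margins = event_m.sum(axis=0)
    results = []
    for i, drug in enumerate(drugs):
        if drug_margins[i] == 0:
            continue
        for j, event in enumerate(events):
            a = int(joint[i, j])
            if a < 1:
                continue
            table = ContingencyTable.from_margins(
                a, int(drug_margins[i]), int(event_margins[j]), n)
            results.append(_result_for(drug, event, table, stratum, thresholds))
    return results


def descriptive_tables(
    collection: pd.DataFrame, drugs: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-drug PT frequency tables and reporting-intensity summaries.

    Returns ``(pt_table, summary)``: ``pt_table`` has one row per drug and
    preferred term with the report count and its share of the drug's total
    ADR mentions; ``summary`` has the report count, total mentions and mean
    mentions per report for each drug.  A mention is one PT in one report.
    """
    pt_rows, summary_rows = [], []
    for drug in drugs:
        sub = subset(collection, drug=drug)
        n_reports = len(sub)
        counts = pd.Series(
            [pt for s in sub["reactions"] for pt in s], dtype=object
        ).value_counts()
        n_mentions = int(counts.sum())
        for pt, count in counts.items():
            pt_rows.append({
                "drug": drug, "pt": pt, "count": int(count),
                "pct_of_mentions": 100 * count / n_mentions if n_mentions else 0.0,
            })
        summary_rows.append({
            "drug": drug, "n_reports": n_reports, "n_mentions": n_mentions,
            "mean_adrs_per_report": n_mentions / n_reports if n_reports else 0.0,
        })
    return pd.DataFrame(pt_rows), pd.DataFrame(summary_rows)
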