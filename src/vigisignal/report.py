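"""Rendering result tables as TSV or markdown at the conventional precision
(ROR to 1 decimal, PRR to 2, percentages to 2)."""

from __future__ import annotations

from typing import Sequence, Union

import pandas as pd

from .dispro import SignalResult
from .errors import VigisignalError

#: Column order of the signal table contract.
SIGNAL_COLUMNS = ("drug", "event", "a", "b", "c", "d", "prr", "ror",
                  "ci_low", "ci_high", "chi2", "p", "is_sdr", "stratum")


def signals_frame(results: Sequence[SignalResult]) -> pd.DataFrame:
    """Flatten signal results into the canonical output table."""
    rows = [{
        "drug": r.drug, "event": r.event,
        "a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d,
        "prr": r.prr, "ror": r.ror,
        "ci_low": r.ror_ci[0], "ci_high": r.ror_ci[1],
        "chi2": r.chi2, "p": r.p_value,
        "is_sdr": r.is_sdr, "stratum": r.stratum,
    } for r in results]
    return pd.DataFrame(rows, columns=list(SIGNAL_COLUMNS))


_FORMATS = {
    "prr": "{:.2f}", "ror": "{:.1f}", "ci_low": "{:.1f}", "ci_high": "{:.1f}",
    "chi2": "{:.2f}", "p": "{:.3g}", "pct_of_mentions": "{:.2f}",
    "mean_adrs_per_report": "{:.2f}", "pseudo_r2": "{:.5f}", "llr_p": "{:.3g}",
    "loglik": "{:.3f}", "aic": "{:.2f}", "coef": "{:.4f}", "se": "{:.3f}",
    "z": "{:.3f}", "or": "{:.2f}",
}


def _format_cell(column: str, value) -> str:
    if isinstance(value, bool):
        return str(value)
    fmt = _FORMATS.get(column)
    if fmt is not None and isinstance(value, float):
        return fmt.format(value)
    return str(value)


def render_table(result: Union[pd.DataFrame, Sequence[SignalResult]],
                 style: str = "tsv") -> str:
    """Render a result table (or list of signal results) as text.

    ``style`` is ``"tsv"`` (tab-separated, one header line) or
    ``"markdown"`` (pipe table).  Column order is stable and numbers are
    printed at the conventional display precision.
    """
    if not isinstance(result, pd.DataFrame):
        result = signals_frame(list(result))
    if style not in ("tsv", "markdown"):
        raise VigisignalError(f"unknown style {style!r}")
    columns = [str(c) for c in result.columns]
    body = [[_format_cell(col, row[col]) for col in result.columns]
            for _, row in result.iterrows()]
    if style == "tsv":
        lines = ["\t".join(columns)] + ["\t".join(cells) for cells in body]
    else:
        lines = ["| " + " | ".join(columns) + " |",
                 "| " + " | ".join("---" for _ in columns) + " |"]
        lines += ["| " + " | ".join(cells) + " |" for cells in body]
    return "\n".join(lines) + "\n"
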