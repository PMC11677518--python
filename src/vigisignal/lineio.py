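"""Reading and writing ICSR line listings.

The on-disk dialect mirrors EudraVigilance-style "line listings" exports:
one row per report, UTF-8, mandatory header, and multi-valued fields joined
with ``;``.  A literal semicolon or backslash inside an item is escaped with
a backslash, so arbitrary substance or reaction names survive a round trip.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import FormatError
from .schema import COLUMNS, SET_COLUMNS, parse_enum

logger = logging.getLogger("vigisignal")

_SEPS = {"csv": ",", "tsv": "\t"}


def _escape(item: str) -> str:
    return item.replace("\\", "\\\\").replace(";", "\\;")


def join_list(values: Iterable[str]) -> str:
    """Serialize a set of items into one semicolon-separated field."""
    return ";".join(_escape(v) for v in sorted(values))


def split_list(field: str) -> frozenset:
    """Parse a semicolon-separated field back into a set of items."""
    if field == "":
        return frozenset()
    items, buf, esc = [], [], False
    for ch in field:
        if esc:
            buf.append(ch)
            esc = False
        elif ch == "\\":
            esc = True
        elif ch == ";":
            items.append("".join(buf))
            buf = []
        else:
            buf.append(ch)
    if esc:  # lone trailing backslash kept literal
        buf.append("\\")
    items.append("".join(buf))
    return frozenset(i for i in items if i != "")


def write_line_listing(collection: pd.DataFrame, path, dialect: str = "csv") -> Path:
    """Write a report collection to ``path`` in the given dialect.

    Only the canonical schema columns are written; helper columns (such as
    the duplicate marker added by the synthetic generator) are dropped.
    """
    if dialect not in _SEPS:
        raise FormatError(f"unknown dialect {dialect!r}; use 'csv' or 'tsv'")
    if len(collection) == 0:
        raise FormatError("refusing to write an empty line listing")
    out = pd.DataFrame(index=collection.index)
    for col in COLUMNS:
        if col in SET_COLUMNS:
            out[col] = collection[col].map(join_list)
        else:
            out[col] = collection[col].astype(str)
    path = Path(path)
    out.to_csv(path, sep=_SEPS[dialect], index=False, lineterminator="\n")
    return path


def read_line_listing(path, dialect: str = "csv") -> pd.DataFrame:
    """Read a line listing into the canonical DataFrame schema.

    Multi-valued fields are split on unescaped semicolons; enum fields are
    mapped to the controlled vocabularies, with unknown tokens logged and
    set to ``"unspecified"``.
    """
    if dialect not in _SEPS:
        raise FormatError(f"unknown dialect {dialect!r}; use 'csv' or 'tsv'")
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        raw = pd.read_csv(path, sep=_SEPS[dialect], dtype=str,
                          keep_default_na=False, encoding="utf-8")
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty line listing: {path}") from None
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")
    if len(raw) == 0:
        raise FormatError(f"line listing has a header but no reports: {path}")
    df = pd.DataFrame(index=raw.index)
    df["case_key"] = raw["case_key"]
    if (df["case_key"] == "").any():
        raise FormatError("empty case_key encountered")
    for col in ("reporter_type", "region", "sex", "age_group", "seriousness"):
        df[col] = raw[col].map(lambda tok, c=col: parse_enum(c, tok))
    for col in SET_COLUMNS:
        df[col] = raw[col].map(split_list)
    return df
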