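"""Ingestion of ICSR line listings: de-duplication, term normalization,
preferred-term to system-organ-class mapping, and stratified subsetting.

MedDRA itself is licensed, so the PT -> SOC mapping and the synonym table
are supplied as plain two-column TSV files; a small default covering the
terms emitted by the synthetic generator ships with the package.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd

from .errors import ConfigError, FormatError
from .lineio import read_line_listing, write_line_listing  # noqa: F401 (module surface)
from .schema import SERIOUS_CATEGORIES

logger = logging.getLogger("vigisignal")

#: Sentinel returned for preferred terms absent from the mapping table.
UNMAPPED = "UNMAPPED"


def _read_two_column_tsv(path, names) -> dict:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such mapping file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns[:2]) != list(names):
        raise FormatError(
            f"{path} must have columns {names!r}, found {list(df.columns)!r}")
    return dict(zip(df[names[0]], df[names[1]]))


def _resolve_synonyms(raw: dict) -> dict:
    """Follow synonym chains to their canonical term; reject cycles."""
    resolved = {}
    for start in raw:
        seen = [start]
        term = start
        while term in raw:
            term = raw[term]
            if term in seen:
                raise ConfigError(
                    "cyclic synonym chain: " + " -> ".join(seen + [term]))
            seen.append(term)
        resolved[start] = term
    return resolved


@dataclass
class TermMaps:
    """PT -> primary SOC mapping plus a PT synonym table.

    ``synonyms`` is stored fully resolved (every variant maps straight to
    its canonical preferred term).  PTs looked up but absent from
    ``pt_to_soc`` are tallied in ``unmapped``.
    """

    pt_to_soc: dict
    synonyms: dict
    unmapped: Counter = field(default_factory=Counter)

    def __post_init__(self):
        self.synonyms = _resolve_synonyms(dict(self.synonyms))

    @classmethod
    def load(cls, pt_soc_path, synonyms_path) -> "TermMaps":
        return cls(
            pt_to_soc=_read_two_column_tsv(pt_soc_path, ("pt", "soc")),
            synonyms=_read_two_column_tsv(synonyms_path, ("variant", "canonical")),
        )

    def canonical(self, pt: str) -> str:
        return self.synonyms.get(pt, pt)

    def soc(self, pt: str) -> str:
        soc = self.pt_to_soc.get(self.canonical(pt))
        if soc is None:
            self.unmapped[pt] += 1
            return UNMAPPED
        return soc


def default_term_maps() -> TermMaps:
    """Term maps bundled with the package (covers the generator vocabulary)."""
    data = resources.files("vigisignal") / "data"
    return TermMaps.load(data / "pt_soc.tsv", data / "synonyms.tsv")


def deduplicate(collection: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop repeated case keys, keeping the first occurrence.

    Returns the cleaned collection and the number of rows removed.  Exact
    key matching mirrors how duplicate transmissions share the worldwide
    case identifier; probabilistic record linkage is out of scope.
    """
    keep = ~collection["case_key"].duplicated(keep="first")
    removed = int((~keep).sum())
    return collection.loc[keep].reset_index(drop=True), removed


def normalize_events(collection: pd.DataFrame, maps: TermMaps) -> pd.DataFrame:
    """Replace every reaction PT by its canonical synonym.

    A report listing both a variant and its canonical term ends up with the
    single canonical PT, because reactions are sets.
    """
    out = collection.copy()
    syn = maps.synonyms
    if syn:
        out["reactions"] = out["reactions"].map(
            lambda s: frozenset(syn.get(pt, pt) for pt in s))
    return out


def map_pt_to_soc(pt: str, maps: TermMaps) -> str:
    """Primary SOC for a preferred term; ``"UNMAPPED"`` if unknown."""
    return maps.soc(pt)


def subset(
    collection: pd.DataFrame,
    drug: Optional[str] = None,
    serious_only: bool = False,
    age_group: Optional[str] = None,
    sex: Optional[str] = None,
) -> pd.DataFrame:
    """Reports satisfying all the given filters (composition is order-free).

    ``drug`` filters on membership in ``suspect_drugs``: disproportionality
    counts a report for a substance only when that substance is suspected,
    matching line-listing semantics.
    """
    mask = pd.Series(True, index=collection.index)
    if drug is not None:
        mask &= collection["suspect_drugs"].map(lambda s: drug in s)
    if serious_only:
        mask &= collection["seriousness"].isin(SERIOUS_CATEGORIES)
    if age_group is not None:
        mask &= collection["age_group"] == age_group
    if sex is not None:
        mask &= collection["sex"] == sex
    return collection.loc[mask]
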