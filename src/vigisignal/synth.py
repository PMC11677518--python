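"""Synthetic spontaneous-report databases with known ground truth.

The generator emulates a EudraVigilance-style database scaled down to a
configurable number of reports: per-drug exposure probabilities, a
background event distribution, planted drug-event effects expressed as
log reporting odds ratios, demographic and seriousness strata, injected
duplicate transmissions, and a known logistic risk structure for
hypercalcemia.

Sampling model, per report:

* each drug is an independent Bernoulli suspect exposure;
* each reaction preferred term is an independent Bernoulli given the
  exposures, with logit(p) = logit(background) + sum of planted log-ROR
  effects of the suspected drugs (so the population reporting odds ratio of
  a planted pair equals exp(effect) against the full-database comparator);
* when a logistic risk structure is configured, the hypercalcemia PT is
  instead drawn from logit(p) = intercept + beta'x (+ any planted drug
  effects), where the covariate vector x is sampled from configured
  prevalences and the report's demographics, and every active covariate
  leaves a recoverable footprint in the report (an "Overdose" PT, a
  "calcium carbonate" concomitant, at least five concomitants for
  polypharmacy, and so on);
* sex, age band and a single mutually exclusive seriousness category are
  drawn from configured probability vectors.

Identical configuration (including the seed) yields a byte-identical
database.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from .dispro import ContingencyTable, compute_ror
from .errors import ConfigError
from .lineio import write_line_listing  # noqa: F401 (module surface)
from .schema import (AGE_GROUPS, COLUMNS, HYPERCALCEMIA_PT,
                     SERIOUSNESS_CATEGORIES, SEXES)

logger = logging.getLogger("vigisignal")

#: Seriousness distribution of the study cohort (order of
#: SERIOUSNESS_CATEGORIES).
STUDY_SERIOUSNESS_DIST = (0.0594, 0.0408, 0.0165, 0.2102, 0.0023, 0.3037, 0.3671)

#: Age-band distribution of the study cohort (order of AGE_GROUPS).
STUDY_AGE_DIST = (0.2429, 0.0344, 0.0276, 0.0154, 0.0105, 0.3247, 0.2973, 0.0472)

#: Sex distribution of the study cohort (female, male, unspecified).
STUDY_SEX_DIST = (0.2603, 0.7026, 0.0371)

#: Best-fit coefficient vector of the 12-covariate hypercalcemia model.
TABLE4_INTERCEPT = -2.6774
TABLE4_COEFFICIENTS = {
    "age_vulnerable": 0.1810,
    "sex_female": -0.2026,
    "overdose": 1.2878,
    "calcium_supplements": 0.7763,
    "cancer": -0.8620,
    "thiazide": 0.3753,
    "lithium": 0.9759,
    "dehydration": 1.6194,
    "polypharmacy": -0.7028,
    "age_vulnerable:calcium_supplements": -0.6229,
    "age_vulnerable:dehydration": 0.6346,
    "age_vulnerable:polypharmacy": 0.8343,
}

#: Prevalence of the sampled (non-demographic) risk covariates.
DEFAULT_COVARIATE_PREVALENCE = {
    "overdose": 0.06,
    "calcium_supplements": 0.15,
    "cancer": 0.04,
    "thiazide": 0.05,
    "lithium": 0.01,
    "dehydration": 0.015,
    "polypharmacy": 0.25,
}

_FILLER_CONCOMITANTS = ("omeprazole", "metformin", "amlodipine", "atorvastatin",
                        "aspirin", "metoprolol", "simvastatin", "levothyroxine")
_BACKGROUND_SUSPECTS = ("paracetamol", "ibuprofen", "amoxicillin",
                        "sertraline", "ramipril")
_COVARIATE_FOOTPRINTS = {
    "overdose": ("reaction", "Overdose"),
    "dehydration": ("reaction", "Dehydration"),
    "cancer": ("indication", "neoplasm malignant"),
    "calcium_supplements": ("concomitant", "calcium carbonate"),
    "thiazide": ("concomitant", "hydrochlorothiazide"),
    "lithium": ("concomitant", "lithium carbonate"),
}

_HCP_FRACTION = 0.6559
_EEA_FRACTION = 0.5940


def _check_probability_vector(name, vec, length):
    vec = tuple(float(v) for v in vec)
    if len(vec) != length:
        raise ConfigError(f"{name} must have {length} entries, got {len(vec)}")
    if min(vec) < 0:
        raise ConfigError(f"{name} has negative entries")
    if abs(sum(vec) - 1.0) > 1e-9:
        raise ConfigError(f"{name} must sum to 1 within 1e-9 (got {sum(vec)!r})")
    return vec


@dataclass
class RiskStructure:
    """Known logistic structure for the hypercalcemia outcome."""

    intercept: float = TABLE4_INTERCEPT
    coefficients: dict = field(default_factory=lambda: dict(TABLE4_COEFFICIENTS))
    covariate_prevalence: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PREVALENCE))

    def __post_init__(self):
        for name, prev in self.covariate_prevalence.items():
            if not 0 < prev < 1:
                raise ConfigError(f"prevalence of {name!r} must be in (0,1)")
        sampled = set(self.covariate_prevalence) | {"age_vulnerable", "sex_female",
                                                    "multi_vdr"}
        for term in self.coefficients:
            parents = term.split(":")
            unknown = [p for p in parents if p not in sampled]
            if unknown:
                raise ConfigError(f"risk coefficient {term!r} uses unknown "
                                  f"covariate(s) {unknown}")


@dataclass
class SynthConfig:
    """Full specification of one synthetic database."""

    n_reports: int
    drugs: list  # [(substance, exposure_probability), ...]
    events: list  # [(pt_name, background_probability), ...]
    planted_signals: list = field(default_factory=list)  # [(drug, pt, log_ror)]
    seriousness_distribution: tuple = STUDY_SERIOUSNESS_DIST
    age_group_distribution: tuple = STUDY_AGE_DIST
    sex_distribution: tuple = STUDY_SEX_DIST
    risk_model: Optional[RiskStructure] = None
    duplicate_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_reports < 1:
            raise ConfigError("n_reports must be >= 1")
        for name, p in self.drugs:
            if not 0 < p < 1:
                raise ConfigError(f"exposure probability of {name!r} must be in (0,1)")
        for name, p in self.events:
            if not 0 < p < 1:
                raise ConfigError(f"background probability of {name!r} must be in (0,1)")
        drug_names = [d for d, _ in self.drugs]
        if len(set(drug_names)) != len(drug_names):
            raise ConfigError("duplicate drug names")
        event_names = [e for e, _ in self.events]
        if len(set(event_names)) != len(event_names):
            raise ConfigError("duplicate event names")
        for drug, event, _ in self.planted_signals:
            if drug not in drug_names:
                raise ConfigError(f"planted signal on unknown drug {drug!r}")
            if event not in event_names and not (
                    self.risk_model is not None and event == HYPERCALCEMIA_PT):
                raise ConfigError(f"planted signal on unknown event {event!r}")
        self.seriousness_distribution = _check_probability_vector(
            "seriousness_distribution", self.seriousness_distribution,
            len(SERIOUSNESS_CATEGORIES))
        self.age_group_distribution = _check_probability_vector(
            "age_group_distribution", self.age_group_distribution, len(AGE_GROUPS))
        self.sex_distribution = _check_probability_vector(
            "sex_distribution", self.sex_distribution, len(SEXES))
        if not 0 <= self.duplicate_fraction < 1:
            raise ConfigError("duplicate_fraction must be in [0, 1)")
        probs = [p for _, p in self.drugs] + [p for _, p in self.events]
        if probs and self.n_reports * max(probs) < 1:
            logger.warning("n_reports * max probability < 1: planted signals "
                           "are unverifiable at this size")

    @classmethod
    def from_dict(cls, raw: dict) -> "SynthConfig":
        raw = dict(raw)
        if raw.get("risk_model") is not None and not isinstance(
                raw["risk_model"], RiskStructure):
            raw["risk_model"] = RiskStructure(**raw["risk_model"])
        raw["drugs"] = [tuple(item) for item in raw.get("drugs", [])]
        raw["events"] = [tuple(item) for item in raw.get("events", [])]
        raw["planted_signals"] = [tuple(item)
                                  for item in raw.get("planted_signals", [])]
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from None

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(raw)


def generate_database(config: SynthConfig) -> pd.DataFrame:
    """Sample a report collection from a :class:`SynthConfig`.

    Returns ``round(n_reports * (1 + duplicate_fraction))`` rows; duplicate
    rows repeat an original case key and payload and are marked in the
    helper column ``_is_duplicate`` (dropped on write).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    drug_names = [d for d, _ in config.drugs]
    drug_probs = np.array([p for _, p in config.drugs])

    exposed = rng.random((n, len(drug_names))) < drug_probs[None, :]

    sex = rng.choice(len(SEXES), size=n, p=config.sex_distribution)
    age = rng.choice(len(AGE_GROUPS), size=n, p=config.age_group_distribution)
    serious = rng.choice(len(SERIOUSNESS_CATEGORIES), size=n,
                         p=config.seriousness_distribution)
    reporter = rng.random(n) < _HCP_FRACTION
    region = rng.random(n) < _EEA_FRACTION

    events = list(config.events)
    if config.risk_model is not None:
        dropped = [e for e, _ in events if e == HYPERCALCEMIA_PT]
        if dropped:
            warnings.warn(f"{HYPERCALCEMIA_PT!r} is governed by the risk model; "
                          "its configured background probability is ignored")
            events = [(e, p) for e, p in events if e != HYPERCALCEMIA_PT]
    event_names = [e for e, _ in events]
    event_logits = logit(np.array([p for _, p in events])) if events else np.empty(0)

    effects = np.zeros((len(drug_names), len(event_names)))
    hyper_effects = np.zeros(len(drug_names))
    for drug, event, log_ror in config.planted_signals:
        i = drug_names.index(drug)
        if event in event_names:
            effects[i, event_names.index(event)] += log_ror
        else:  # hypercalcemia effect feeding the risk-model logit
            hyper_effects[i] += log_ror

    if event_names:
        lp = event_logits[None, :] + exposed.astype(float) @ effects
        occurred = rng.random((n, len(event_names))) < expit(lp)
    else:
        occurred = np.zeros((n, 0), dtype=bool)

    covariates = {}
    hyper = np.zeros(n, dtype=bool)
    if config.risk_model is not None:
        rm = config.risk_model
        for name, prev in rm.covariate_prevalence.items():
            covariates[name] = rng.random(n) < prev
        covariates["age_vulnerable"] = np.array(
            [AGE_GROUPS[i] in ("0-1 month", "2 months-2 years", "3-11 years",
                               "12-17 years", "65-85 years", ">85 years")
             for i in age])
        covariates["sex_female"] = sex == SEXES.index("female")
        covariates["multi_vdr"] = exposed.sum(axis=1) >= 2
        lp = np.full(n, rm.intercept)
        for term, beta in rm.coefficients.items():
            x = np.ones(n, dtype=bool)
            for parent in term.split(":"):
                x = x & covariates[parent]
            lp += beta * x
        lp += exposed.astype(float) @ hyper_effects
        hyper = rng.random(n) < expit(lp)

    background_pick = rng.integers(0, len(_BACKGROUND_SUSPECTS), size=n)
    filler_count = rng.integers(0, 2, size=n)  # 0 or 1 incidental concomitant
    osteo = rng.random(n) < 0.3

    rows = []
    cov = {k: v for k, v in covariates.items()}
    for i in range(n):
        suspects = {drug_names[j] for j in np.flatnonzero(exposed[i])}
        if not suspects:
            suspects = {_BACKGROUND_SUSPECTS[background_pick[i]]}
        reactions = {event_names[j] for j in np.flatnonzero(occurred[i])}
        concomitant = set()
        indications = set()
        if osteo[i]:
            indications.add("osteoporosis")
        if cov:
            for name, (kind, token) in _COVARIATE_FOOTPRINTS.items():
                if name in cov and cov[name][i]:
                    if kind == "reaction":
                        reactions.add(token)
                    elif kind == "concomitant":
                        concomitant.add(token)
                    else:
                        indications.add(token)
            if "polypharmacy" in cov and cov["polypharmacy"][i]:
                for filler in _FILLER_CONCOMITANTS:
                    if len(concomitant) >= 5:
                        break
                    concomitant.add(filler)
            elif filler_count[i] and len(concomitant) < 4:
                concomitant.add(_FILLER_CONCOMITANTS[0])
            if hyper[i]:
                reactions.add(HYPERCALCEMIA_PT)
        elif filler_count[i]:
            concomitant.add(_FILLER_CONCOMITANTS[0])
        rows.append((
            f"EV{i:08d}",
            "healthcare_professional" if reporter[i] else "non_hcp",
            "EEA" if region[i] else "non_EEA",
            SEXES[sex[i]],
            AGE_GROUPS[age[i]],
            SERIOUSNESS_CATEGORIES[serious[i]],
            frozenset(suspects),
            frozenset(concomitant),
            frozenset(indications),
            frozenset(reactions),
        ))
    df = pd.DataFrame(rows, columns=list(COLUMNS))
    df["_is_duplicate"] = False
    if config.duplicate_fraction > 0:
        df = inject_duplicates(df, config.duplicate_fraction,
                               seed=int(rng.integers(0, 2**31)))
    return df


def inject_duplicates(collection: pd.DataFrame, fraction: float,
                      seed: int = 0) -> pd.DataFrame:
    """Append ``round(fraction * n)`` exact copies of randomly chosen rows.

    Copies share the original case key and payload (near-duplicates are out
    of scope) and carry ``_is_duplicate = True`` so test oracles can find
    them.  De-duplication of the result recovers the input.
    """
    if not 0 <= fraction < 1:
        raise ConfigError("duplicate fraction must be in [0, 1)")
    k = round(fraction * len(collection))
    if k == 0:
        return collection.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(collection), size=k, replace=False)
    base = collection.copy()
    if "_is_duplicate" not in base.columns:
        base["_is_duplicate"] = False
    copies = base.iloc[sorted(picks)].copy()
    copies["_is_duplicate"] = True
    return pd.concat([base, copies], ignore_index=True)


def _reconstructed_log_ror(a: int, drug_margin: int, event_margin: int,
                           n: int) -> float:
    table = ContingencyTable.from_margins(a, drug_margin, event_margin, n)
    return math.log(compute_ror(table))


def study_config(n_reports: int = 100_000, seed: int = 0) -> SynthConfig:
    """Scaled-down emulation of the full spontaneous-report database.

    Exposure probabilities are the study drugs' report fractions of the
    5,369,581-report database; the hypercalcemia background is the event's
    rate among reports without these drugs, and the planted log-ROR of each
    drug-hypercalcemia pair is reconstructed from the published joint
    counts and margins.  A handful of common PTs form the unassociated
    background event mix.
    """
    n_db = 5_369_581
    margins = {"cholecalciferol": 12_944, "calcitriol": 1_355,
               "alfacalcidol": 1_166, "ergocalciferol": 826,
               "paricalcitol": 651, "calcifediol": 564}
    hyper_counts = {"cholecalciferol": 722, "calcitriol": 304,
                    "alfacalcidol": 322, "ergocalciferol": 49,
                    "paricalcitol": 40, "calcifediol": 85}
    hyper_margin = 2_442
    non_vdr_hyper = hyper_margin - sum(hyper_counts.values())
    non_vdr_n = n_db - sum(margins.values())
    drugs = [(d, m / n_db) for d, m in margins.items()]
    events = [
        (HYPERCALCEMIA_PT, non_vdr_hyper / non_vdr_n),
        ("Nausea", 0.004),
        ("Fatigue", 0.003),
        ("Headache", 0.003),
        ("Rash", 0.002),
        ("Drug ineffective", 0.004),
    ]
    planted = [
        (drug, HYPERCALCEMIA_PT,
         _reconstructed_log_ror(hyper_counts[drug], margins[drug],
                                hyper_margin, n_db))
        for drug in margins
    ]
    return SynthConfig(n_reports=n_reports, drugs=drugs, events=events,
                       planted_signals=planted, seed=seed)


def risk_cohort_config(n_reports: int = 50_000, seed: int = 0,
                       risk_model: Optional[RiskStructure] = None) -> SynthConfig:
    """Emulation of the drug cohort on which the risk model is estimated.

    Every report belongs to the cohort; the hypercalcemia outcome follows
    the configured logistic structure (default: the published 12-covariate
    coefficient vector) and no disproportionality effect is planted.
    """
    drugs = [("cholecalciferol", 0.70), ("calcitriol", 0.08),
             ("alfacalcidol", 0.07), ("ergocalciferol", 0.05),
             ("paricalcitol", 0.04)]
    events = [("Nausea", 0.05), ("Abdominal pain", 0.04), ("Fatigue", 0.03),
              ("Headache", 0.03)]
    return SynthConfig(
        n_reports=n_reports, drugs=drugs, events=events,
        risk_model=risk_model if risk_model is not None else RiskStructure(),
        seed=seed)


def demo_config(n_reports: int = 5_000, seed: int = 0) -> SynthConfig:
    """Small end-to-end demo: visible planted signals, a risk structure and
    injected duplicates, sized to run in seconds."""
    drugs = [("cholecalciferol", 0.10), ("calcitriol", 0.03),
             ("alfacalcidol", 0.03), ("ergocalciferol", 0.02)]
    events = [("Nausea", 0.05), ("Abdominal pain", 0.04), ("Fatigue", 0.03),
              ("Headache", 0.03), ("Rash", 0.02), ("Nephrolithiasis", 0.005)]
    planted = [
        ("calcitriol", HYPERCALCEMIA_PT, math.log(20)),
        ("alfacalcidol", HYPERCALCEMIA_PT, math.log(15)),
        ("calcitriol", "Nephrolithiasis", math.log(4)),
    ]
    return SynthConfig(n_reports=n_reports, drugs=drugs, events=events,
                       planted_signals=planted, risk_model=RiskStructure(),
                       duplicate_fraction=0.05, seed=seed)
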