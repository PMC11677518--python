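"""Logistic risk-factor modelling of hypercalcemia.

Each report is reduced to a vector of boolean risk covariates — overdose,
concomitant calcium salts, lithium, thiazide or thiazide-like diuretics,
cancer comorbidity, dehydration, polypharmacy (five or more concomitant
drugs), vulnerable age (<18 or >65 years), female sex, and combined use of
two or more vitamin D receptor agonists — and the hypercalcemia outcome is
modelled by maximum-likelihood logistic regression.  Models are compared by
log-likelihood, McFadden pseudo-R-squared (1 - llf/llnull), the likelihood
ratio test and AIC (2k - 2 llf), and coefficients are translated into odds
ratios exp(beta) with Wald intervals exp(beta +- z * SE).

The covariate lexicons (which substance or term counts as a calcium salt,
an overdose PT, a cancer term, ...) are configuration with shipped
defaults: matching is case-insensitive substring containment, so
"calcium carbonate" is caught by the token "calcium".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml
from scipy import stats

from .errors import ConfigError, VigisignalError
from .schema import HYPERCALCEMIA_PT, VDR_AGONISTS, VULNERABLE_AGE_GROUPS

logger = logging.getLogger("vigisignal")

#: Recognized covariate names, in reporting order.
TERMS = (
    "age_vulnerable",
    "sex_female",
    "overdose",
    "calcium_supplements",
    "cancer",
    "thiazide",
    "lithium",
    "dehydration",
    "polypharmacy",
    "multi_vdr",
)

DEFAULT_LEXICONS: dict = {
    "vdr_agonists": list(VDR_AGONISTS),
    "calcium_substances": ["calcium"],
    "lithium_substances": ["lithium"],
    "thiazide_substances": [
        "thiazide", "chlorthalidone", "indapamide", "metolazone",
    ],
    "overdose_pts": [
        "overdose", "toxicity to various agents",
    ],
    "dehydration_pts": ["dehydration", "hypovolaemia", "hypovolemia"],
    "cancer_terms": [
        "neoplasm", "cancer", "carcinoma", "lymphoma", "leukaemia",
        "leukemia", "myeloma", "sarcoma",
    ],
    "hypercalcemia_pts": [HYPERCALCEMIA_PT],
}


def load_lexicons(path=None) -> dict:
    """Keyword lexicons, from a YAML file merged over the defaults."""
    lex = {k: list(v) for k, v in DEFAULT_LEXICONS.items()}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"lexicon file {path} must map names to term lists")
        lex.update({k: list(v) for k, v in user.items()})
    missing = set(DEFAULT_LEXICONS) - set(lex)
    if missing:
        raise ConfigError(f"missing lexicon(s): {sorted(missing)}")
    return lex


def _contains_any(names, tokens) -> bool:
    return any(tok in name.lower() for name in names for tok in tokens)


def extract_risk_flags(report: Mapping, lexicons: Optional[dict] = None) -> dict:
    """Boolean risk covariates plus the hypercalcemia outcome for one report.

    ``report`` is a row of the canonical collection (mapping-like access to
    the schema columns).  Extraction is deterministic: substances are
    matched in suspect and concomitant lists, PT lexicons in the normalized
    reaction set, and cancer terms in reactions and indications alike.
    """
    lex = lexicons if lexicons is not None else DEFAULT_LEXICONS
    try:
        vdr = [t.lower() for t in lex["vdr_agonists"]]
        calcium = [t.lower() for t in lex["calcium_substances"]]
        lithium = [t.lower() for t in lex["lithium_substances"]]
        thiazide = [t.lower() for t in lex["thiazide_substances"]]
        overdose = [t.lower() for t in lex["overdose_pts"]]
        dehydration = [t.lower() for t in lex["dehydration_pts"]]
        cancer = [t.lower() for t in lex["cancer_terms"]]
        hyper = set(lex["hypercalcemia_pts"])
    except KeyError as exc:
        raise ConfigError(f"missing lexicon: {exc}") from None
    suspects = report["suspect_drugs"]
    concomitant = report["concomitant_drugs"]
    reactions = report["reactions"]
    indications = report["indications"]
    all_drugs = set(suspects) | set(concomitant)
    n_vdr = sum(1 for name in all_drugs if _contains_any([name], vdr))
    return {
        "outcome_hypercalcemia": bool(hyper & set(reactions)),
        "age_vulnerable": report["age_group"] in VULNERABLE_AGE_GROUPS,
        "sex_female": report["sex"] == "female",
        "overdose": _contains_any(reactions, overdose),
        "calcium_supplements": _contains_any(concomitant, calcium),
        "cancer": _contains_any(reactions, cancer) or _contains_any(indications, cancer),
        "thiazide": _contains_any(concomitant, thiazide),
        "lithium": _contains_any(concomitant, lithium),
        "dehydration": _contains_any(reactions, dehydration),
        "polypharmacy": len(concomitant) >= 5,
        "multi_vdr": n_vdr >= 2,
    }


def build_risk_table(collection: pd.DataFrame,
                     lexicons: Optional[dict] = None) -> pd.DataFrame:
    """Risk-covariate table (one boolean row per report, plus the outcome)."""
    lex = lexicons if lexicons is not None else DEFAULT_LEXICONS
    rows = [extract_risk_flags(rec, lex) for rec in collection.to_dict("records")]
    return pd.DataFrame(rows, index=collection.index)


@dataclass(frozen=True)
class ModelSpec:
    """Covariate set of one logistic model: main terms plus interactions."""

    name: str
    terms: tuple
    interactions: tuple = ()

    def __post_init__(self):
        if len(set(self.terms)) != len(self.terms):
            raise ConfigError(f"duplicate terms in model {self.name!r}")
        for pair in self.interactions:
            for parent in pair:
                if parent not in self.terms:
                    raise ConfigError(
                        f"interaction parent {parent!r} not in terms of {self.name!r}")

    @property
    def columns(self) -> list:
        return list(self.terms) + [f"{a}:{b}" for a, b in self.interactions]


_CONDITION_TERMS = ("overdose", "calcium_supplements", "cancer", "thiazide",
                    "lithium", "dehydration")

#: The candidate model suite: main effects only, plus demographics, plus
#: polypharmacy, and the full 12-covariate model with age interactions.
MODEL_SPECS = {
    "model1": ModelSpec("model1", _CONDITION_TERMS),
    "model2": ModelSpec("model2", ("age_vulnerable", "sex_female") + _CONDITION_TERMS),
    "model3": ModelSpec(
        "model3",
        ("age_vulnerable", "sex_female") + _CONDITION_TERMS + ("polypharmacy",)),
    "model4": ModelSpec(
        "model4",
        ("age_vulnerable", "sex_female") + _CONDITION_TERMS + ("polypharmacy",),
        (("age_vulnerable", "calcium_supplements"),
         ("age_vulnerable", "dehydration"),
         ("age_vulnerable", "polypharmacy"))),
}


def build_design_matrix(flags: pd.DataFrame,
                        spec: ModelSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Design matrix (intercept first, then terms, then interaction products)
    and the outcome vector, from a risk-covariate table."""
    x = pd.DataFrame(index=flags.index)
    x["const"] = 1.0
    for term in spec.terms:
        if term not in flags.columns:
            raise ConfigError(f"unknown covariate {term!r}")
        x[term] = flags[term].astype(float)
    for a, b in spec.interactions:
        x[f"{a}:{b}"] = (flags[a] & flags[b]).astype(float)
    for col in x.columns[1:]:
        if x[col].nunique() < 2:
            logger.warning("covariate %r has no variation; column retained", col)
    y = flags["outcome_hypercalcemia"].astype(float)
    return x, y


class HypercalcemiaRiskResults:
    """Fitted logistic model: estimates, uncertainties and diagnostics.

    Thin results object in the statsmodels mould; ``summary()`` renders a
    coefficient table with odds ratios.
    """

    def __init__(self, sm_results, spec: Optional[ModelSpec] = None):
        self._sm = sm_results
        self.spec = spec
        self.params = sm_results.params
        self.bse = sm_results.bse
        self.zvalues = sm_results.tvalues
        self.pvalues = sm_results.pvalues
        self.loglik = float(sm_results.llf)
        self.null_loglik = float(sm_results.llnull)
        self.pseudo_r2 = float(sm_results.prsquared)
        self.llr_p = float(sm_results.llr_pvalue)
        self.aic = float(sm_results.aic)
        self.converged = bool(sm_results.mle_retvals.get("converged", False))
        self.n_obs = int(sm_results.nobs)
        self.k_params = len(self.params)

    def odds_ratios(self, level: float = 0.95) -> pd.DataFrame:
        rows = {
            term: wald_odds_ratio(self.params[term], self.bse[term], level)
            for term in self.params.index
        }
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=["or", "ci_low", "ci_high"])

    def summary(self) -> str:
        ors = self.odds_ratios()
        name = self.spec.name if self.spec is not None else "logit"
        lines = [
            f"Hypercalcemia risk model ({name}), maximum likelihood logit",
            f"n_obs = {self.n_obs}, converged = {self.converged}",
            (f"loglik = {self.loglik:.3f}, null loglik = {self.null_loglik:.3f}, "
             f"McFadden R2 = {self.pseudo_r2:.5f}"),
            f"LLR p = {self.llr_p:.4g}, AIC = {self.aic:.2f}",
            f"{'term':<34}{'coef':>9}{'se':>8}{'z':>8}{'p':>9}"
            f"{'OR':>8}{'ci_low':>8}{'ci_high':>9}",
        ]
        for term in self.params.index:
            orow = ors.loc[term]
            lines.append(
                f"{term:<34}{self.params[term]:>9.4f}{self.bse[term]:>8.3f}"
                f"{self.zvalues[term]:>8.3f}{self.pvalues[term]:>9.4f}"
                f"{orow['or']:>8.2f}{orow['ci_low']:>8.2f}{orow['ci_high']:>9.2f}")
        return "\n".join(lines)


class HypercalcemiaRiskModel:
    """Logistic model of hypercalcemia risk, built from a report collection
    (``from_reports``) or directly from a design matrix."""

    def __init__(self, X: pd.DataFrame, y: pd.Series,
                 spec: Optional[ModelSpec] = None):
        if len(X) != len(y):
            raise VigisignalError("X and y lengths differ")
        self.X = X
        self.y = y
        self.spec = spec

    @classmethod
    def from_reports(cls, collection: pd.DataFrame,
                     spec: ModelSpec = MODEL_SPECS["model4"],
                     lexicons: Optional[dict] = None) -> "HypercalcemiaRiskModel":
        flags = build_risk_table(collection, lexicons)
        X, y = build_design_matrix(flags, spec)
        return cls(X, y, spec)

    def fit(self, tol: float = 1e-8, max_iter: int = 100) -> HypercalcemiaRiskResults:
        if len(self.X) <= self.X.shape[1]:
            raise VigisignalError("more parameters than observations")
        if self.y.nunique() < 2:
            raise VigisignalError("outcome has no variation")
        x = self.X.astype(float)
        rank = np.linalg.matrix_rank(x.to_numpy())
        if rank < x.shape[1]:
            raise VigisignalError(
                "singular design matrix; collinear columns among "
                f"{list(x.columns)}")
        model = sm.Logit(self.y.astype(float), x)
        model.raise_on_perfect_prediction = False
        results = model.fit(method="newton", tol=tol, maxiter=max_iter,
                            disp=0, warn_convergence=False)
        if not results.mle_retvals.get("converged", False):
            logger.warning("logit did not converge (possible separation); "
                           "coefficients reported anyway")
        return HypercalcemiaRiskResults(results, self.spec)


def fit_logistic(X: pd.DataFrame, y: pd.Series, tol: float = 1e-8,
                 max_iter: int = 100) -> HypercalcemiaRiskResults:
    """Functional wrapper around :class:`HypercalcemiaRiskModel`."""
    return HypercalcemiaRiskModel(X, y).fit(tol=tol, max_iter=max_iter)


def wald_odds_ratio(coef: float, se: float,
                    level: float = 0.95) -> tuple[float, float, float]:
    """Odds ratio exp(coef) with the Wald interval exp(coef +- z * SE)."""
    z = stats.norm.ppf(0.5 + level / 2)
    return math.exp(coef), math.exp(coef - z * se), math.exp(coef + z * se)


def compare_models(fits: Sequence[HypercalcemiaRiskResults]) -> pd.DataFrame:
    """Rank fitted models by AIC (ascending; ties broken by fewer params).

    All fits must be on the same observations.
    """
    if not fits:
        raise VigisignalError("no fits to compare")
    n = {fit.n_obs for fit in fits}
    if len(n) > 1:
        raise VigisignalError(f"fits on differing numbers of observations: {sorted(n)}")
    rows = [{
        "model": fit.spec.name if fit.spec is not None else f"fit{i}",
        "k_params": fit.k_params,
        "loglik": fit.loglik,
        "pseudo_r2": fit.pseudo_r2,
        "llr_p": fit.llr_p,
        "aic": fit.aic,
    } for i, fit in enumerate(fits)]
    return (pd.DataFrame(rows)
            .sort_values(["aic", "k_params"], kind="mergesort")
            .reset_index(drop=True))
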