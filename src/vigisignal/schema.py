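"""Column schema and controlled vocabularies for ICSR line listings.

An individual case safety report (ICSR) is one spontaneous report of one
or more suspected adverse drug reactions.  A collection of reports is held
as a :class:`pandas.DataFrame` with one row per report and the columns in
:data:`COLUMNS`; multi-valued fields (substances, indications, reaction
preferred terms) are stored as ``frozenset`` objects so that a term is
counted at most once per report.
"""

from __future__ import annotations

import logging
import re

logger = logging.getLogger("vigisignal")

#: Column order of the canonical line-listing schema.
COLUMNS = (
    "case_key",
    "reporter_type",
    "region",
    "sex",
    "age_group",
    "seriousness",
    "suspect_drugs",
    "concomitant_drugs",
    "indications",
    "reactions",
)

#: Columns holding sets of strings.
SET_COLUMNS = ("suspect_drugs", "concomitant_drugs", "indications", "reactions")

REPORTER_TYPES = ("healthcare_professional", "non_hcp", "unspecified")
REGIONS = ("EEA", "non_EEA", "unspecified")
SEXES = ("female", "male", "unspecified")

#: Ordinal age bands used by EudraVigilance line listings.
AGE_GROUPS = (
    "unspecified",
    "0-1 month",
    "2 months-2 years",
    "3-11 years",
    "12-17 years",
    "18-64 years",
    "65-85 years",
    ">85 years",
)

#: Mutually exclusive seriousness categories (one per report).
SERIOUSNESS_CATEGORIES = (
    "death",
    "life_threatening",
    "disabling",
    "hospitalization",
    "congenital_anomaly",
    "other_medically_important",
    "unspecified",
)

#: Categories counting as "serious" for serious-case fractions and strata.
SERIOUS_CATEGORIES = ("death", "life_threatening", "disabling", "hospitalization")

#: Age bands regarded as vulnerable (<18 years or >65 years).
VULNERABLE_AGE_GROUPS = frozenset(
    ["0-1 month", "2 months-2 years", "3-11 years", "12-17 years",
     "65-85 years", ">85 years"]
)

#: The ten vitamin D receptor agonists licensed in the EU.
VDR_AGONISTS = (
    "cholecalciferol",
    "ergocalciferol",
    "calcifediol",
    "calcitriol",
    "alfacalcidol",
    "paricalcitol",
    "dihydrotachysterol",
    "doxercalciferol",
    "tacalcitol",
    "calcipotriol",
)

#: Canonical preferred term for elevated blood calcium; "blood calcium
#: increased" is folded into it by the default synonym table.
HYPERCALCEMIA_PT = "Hypercalcaemia"


def _norm(token: str) -> str:
    token = token.strip().lower().replace("–", "-").replace("—", "-")
    return re.sub(r"\s+", " ", token)


_SEX_TOKENS = {
    "female": "female", "f": "female",
    "male": "male", "m": "male",
    "": "unspecified", "not specified": "unspecified",
    "unspecified": "unspecified", "unknown": "unspecified",
}

_REPORTER_TOKENS = {
    "healthcare professional": "healthcare_professional",
    "healthcare_professional": "healthcare_professional",
    "hcp": "healthcare_professional",
    "physician": "healthcare_professional",
    "pharmacist": "healthcare_professional",
    "non healthcare professional": "non_hcp",
    "non-healthcare professional": "non_hcp",
    "non_hcp": "non_hcp",
    "consumer": "non_hcp",
    "lawyer": "non_hcp",
    "": "unspecified", "not specified": "unspecified", "unspecified": "unspecified",
}

_REGION_TOKENS = {
    "eea": "EEA", "european economic area": "EEA",
    "non eea": "non_EEA", "non-eea": "non_EEA", "non_eea": "non_EEA",
    "not specified": "unspecified", "": "unspecified", "unspecified": "unspecified",
}

_AGE_TOKENS = {
    "0-1 month": "0-1 month", "0-1 mo": "0-1 month",
    "2 months-2 years": "2 months-2 years", "2 months - 2 years": "2 months-2 years",
    "3-11 years": "3-11 years",
    "12-17 years": "12-17 years",
    "18-64 years": "18-64 years",
    "65-85 years": "65-85 years",
    ">85 years": ">85 years", "more than 85 years": ">85 years",
    "85+ years": ">85 years",
    "": "unspecified", "not specified": "unspecified", "unspecified": "unspecified",
}

_SERIOUSNESS_TOKENS = {
    "results in death": "death", "death": "death", "fatal": "death",
    "life threatening": "life_threatening", "life-threatening": "life_threatening",
    "life_threatening": "life_threatening",
    "disabling": "disabling", "caused disability": "disabling",
    "caused/prolonged hospitalisation": "hospitalization",
    "caused/prolonged hospitalization": "hospitalization",
    "hospitalisation": "hospitalization", "hospitalization": "hospitalization",
    "congenital anomaly": "congenital_anomaly", "congenital_anomaly": "congenital_anomaly",
    "other medically important condition": "other_medically_important",
    "other medically important": "other_medically_important",
    "other_medically_important": "other_medically_important",
    "not specified/unknown": "unspecified", "not specified": "unspecified",
    "unknown": "unspecified", "": "unspecified", "unspecified": "unspecified",
}

_ENUM_PARSERS = {
    "sex": _SEX_TOKENS,
    "reporter_type": _REPORTER_TOKENS,
    "region": _REGION_TOKENS,
    "age_group": _AGE_TOKENS,
    "seriousness": _SERIOUSNESS_TOKENS,
}


def parse_enum(field: str, token: str) -> str:
    """Map a raw token to the canonical vocabulary of ``field``.

    Unknown tokens map to ``"unspecified"`` and are logged, mirroring how
    line-listing exports leave fields blank or use free-text variants.
    """
    table = _ENUM_PARSERS[field]
    value = table.get(_norm(token))
    if value is None:
        logger.warning("unknown %s token %r mapped to 'unspecified'", field, token)
        return "unspecified"
    return value
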