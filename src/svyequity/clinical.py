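"""Clinical stratifiers: Charlson Comorbidity Index, HbA1c strata, T2DM age
bands, and Multum-style therapeutic drug classification.

The Charlson weight table here is a reconstruction: the survey's 15 self-
reported conditions are mapped onto the original Charlson components where
one exists (several respiratory conditions collapse onto the single chronic
pulmonary disease component; hypertension, arthritis and gout are not
Charlson components and carry weight 0).  Diabetes itself contributes weight
1, or 2 when retinopathy marks diabetes with end-organ complication.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import yaml

__all__ = [
    "CONDITIONS",
    "CciLevel",
    "CciResult",
    "CharlsonWeights",
    "DrugMap",
    "cci_score",
    "cci_level",
    "hba1c_stratum",
    "t2dm_age_band",
    "categorize_drugs",
    "ingredient_usage",
    "load_default_drug_map",
]

#: The 15 self-reported comorbid conditions available in the survey.
CONDITIONS = (
    "hypertension",
    "asthma",
    "arthritis",
    "gout",
    "congestive_heart_failure",
    "coronary_heart_disease",
    "heart_attack",
    "stroke",
    "emphysema",
    "chronic_bronchitis",
    "cancer",
    "liver_disease",
    "copd",
    "kidney_disease",
    "diabetic_retinopathy",
)

#: Conditions that all map to the single Charlson chronic-pulmonary component.
PULMONARY = ("asthma", "emphysema", "chronic_bronchitis", "copd")

_DEFAULT_WEIGHTS: dict[str, int] = {
    "hypertension": 0,
    "arthritis": 0,
    "gout": 0,
    "coronary_heart_disease": 0,
    "congestive_heart_failure": 1,
    "heart_attack": 1,
    "stroke": 1,
    "asthma": 1,
    "emphysema": 1,
    "chronic_bronchitis": 1,
    "copd": 1,
    "liver_disease": 1,
    "kidney_disease": 2,
    "cancer": 2,
    "diabetic_retinopathy": 0,  # handled through the diabetes component
}


class CciLevel(str, Enum):
    NONE = "none"
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


@dataclass(frozen=True)
class CharlsonWeights:
    """Condition -> integer Charlson weight over the 15 survey conditions."""

    weights: Mapping[str, int] = field(default_factory=lambda: dict(_DEFAULT_WEIGHTS))

    def __post_init__(self) -> None:
        missing = set(CONDITIONS) - set(self.weights)
        if missing:
            raise ValueError(f"weight table lacks conditions: {sorted(missing)}")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("Charlson weights must be non-negative")

    def __getitem__(self, condition: str) -> int:
        return self.weights[condition]


def cci_level(score: int) -> CciLevel:
    """Severity band: 0 none, 1-2 mild, 3-4 moderate, >=5 severe."""
    if score < 0:
        raise ValueError("CCI score cannot be negative")
    if score == 0:
        return CciLevel.NONE
    if score <= 2:
        return CciLevel.MILD
    if score <= 4:
        return CciLevel.MODERATE
    return CciLevel.SEVERE


@dataclass(frozen=True)
class CciResult:
    score: int
    level: CciLevel


def cci_score(
    flags: Mapping[str, bool],
    weights: CharlsonWeights | None = None,
    *,
    has_diabetes: bool = False,
    has_retinopathy: bool = False,
) -> CciResult:
    """Charlson Comorbidity Index from the 15 condition flags.

    Respiratory conditions count once through the chronic-pulmonary
    component regardless of how many are present.  Diabetes adds 1, or 2
    when retinopathy is present (diabetes with end-organ damage).

    Parameters
    ----------
    flags : mapping of condition name -> bool
        Must cover all 15 conditions (missingness is resolved upstream).
    """
    w = weights if weights is not None else CharlsonWeights()
    missing = set(CONDITIONS) - set(flags)
    if missing:
        raise ValueError(f"incomplete condition flags; missing {sorted(missing)}")
    score = 0
    pulmonary_used = False
    for cond in CONDITIONS:
        if not flags[cond]:
            continue
        if cond in PULMONARY:
            if not pulmonary_used:
                score += max(w[c] for c in PULMONARY)
                pulmonary_used = True
            continue
        score += w[cond]
    retino = has_retinopathy or bool(flags.get("diabetic_retinopathy"))
    if has_diabetes:
        score += 2 if retino else 1
    return CciResult(score=score, level=cci_level(score))


def hba1c_stratum(hba1c: float) -> str:
    """Glycemic-control band: <6%, 6-7%, 7-9%, >=9% (half-open intervals)."""
    if not hba1c > 0:
        raise ValueError(f"HbA1c must be positive; got {hba1c!r}")
    if hba1c < 6.0:
        return "lt6"
    if hba1c < 7.0:
        return "6to7"
    if hba1c < 9.0:
        return "7to9"
    return "ge9"


def t2dm_age_band(age: float) -> str:
    """Adult diabetic age bands 20-45, 46-64, >=65."""
    if age < 20:
        raise ValueError(f"age {age!r} below the adult cohort minimum of 20")
    if age < 46:
        return "20-45"
    if age < 65:
        return "46-64"
    return "ge65"


#: The 9 single-ingredient therapeutic categories plus combinations.
CATEGORIES = (
    "meglitinides",
    "SGLT2is",
    "SUs",
    "biguanides",
    "DPP-4is",
    "insulin",
    "TZDs",
    "GLP-1RAs",
    "AGIs",
    "combinations",
)


def _norm(name: str) -> str:
    return " ".join(name.strip().lower().split())


@dataclass
class DrugMap:
    """Antidiabetic formulary: drug -> therapeutic category, with
    combination products decomposable into their ingredients.

    Names are matched case-insensitively after whitespace normalization.
    """

    categories: dict[str, str]
    combinations: dict[str, list[str]]

    def __post_init__(self) -> None:
        self.categories = {_norm(k): v for k, v in self.categories.items()}
        self.combinations = {
            _norm(k): [_norm(i) for i in v] for k, v in self.combinations.items()
        }
        for drug, cat in self.categories.items():
            if cat not in CATEGORIES:
                raise ValueError(f"unknown category {cat!r} for drug {drug!r}")
        for combo, ingredients in self.combinations.items():
            if self.categories.get(combo) != "combinations":
                raise ValueError(f"{combo!r} listed as combination but not categorized so")
            for ing in ingredients:
                cat = self.categories.get(ing)
                if cat is None or cat == "combinations":
                    raise ValueError(
                        f"combination {combo!r} ingredient {ing!r} must map to a "
                        "single-ingredient category"
                    )

    def category(self, drug: str) -> str:
        key = _norm(drug)
        if key not in self.categories:
            raise KeyError(f"drug {drug!r} not in the configured formulary")
        return self.categories[key]

    def ingredients(self, drug: str) -> list[str]:
        key = _norm(drug)
        if self.categories.get(key) == "combinations":
            return list(self.combinations[key])
        if key not in self.categories:
            raise KeyError(f"drug {drug!r} not in the configured formulary")
        return [key]

    @classmethod
    def from_yaml(cls, path) -> "DrugMap":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(categories=raw["categories"], combinations=raw.get("combinations", {}))


def load_default_drug_map() -> DrugMap:
    """Bundled representative antidiabetic formulary."""
    ref = importlib.resources.files("svyequity.config").joinpath("drug_map.yaml")
    with importlib.resources.as_file(ref) as path:
        return DrugMap.from_yaml(path)


def categorize_drugs(
    prescriptions: Iterable[str], drug_map: DrugMap, *, decompose: bool = False
) -> dict[str, bool]:
    """Therapeutic-category indicators for a respondent's prescription list.

    With ``decompose=False`` combination products stay in their own
    "combinations" class (10 indicators); with ``decompose=True`` each
    combination contributes its ingredients' categories instead (9
    indicators).  An empty prescription list sets the "None" indicator.
    """
    cats = list(CATEGORIES) if not decompose else [c for c in CATEGORIES if c != "combinations"]
    out = {c: False for c in cats}
    out["None"] = False
    drugs = list(prescriptions)
    if not drugs:
        out["None"] = True
        return out
    for drug in drugs:
        cat = drug_map.category(drug)
        if decompose and cat == "combinations":
            for ing in drug_map.ingredients(drug):
                out[drug_map.category(ing)] = True
        else:
            out[cat] = True
    return out


def ingredient_usage(prescriptions: Iterable[str], drug_map: DrugMap) -> dict[str, bool]:
    """Per-ingredient indicators after decomposing combination products."""
    out: dict[str, bool] = {}
    for drug in prescriptions:
        for ing in drug_map.ingredients(drug):
            out[ing] = True
    return out
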