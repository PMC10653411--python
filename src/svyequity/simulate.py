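"""Synthetic NHANES-like survey microdata with known ground truth.

A finite census is generated over a stratified frame (strata containing
PSUs containing respondents), covariates are drawn from configurable
marginal distributions with mild PSU-level heterogeneity, clinical variables
follow mixture models (HbA1c by diabetes status), and binary outcomes come
from logistic models with configurable true odds ratios plus optional
subgroup odds multipliers that inject known disparities.  Surveys are drawn
by two-stage sampling with replacement at both stages — the design the
with-replacement variance approximation is exact for — with unequal
respondent inclusion probabilities (an oversampling factor) so weights are
genuinely informative.  Everything is driven by a NumPy Generator seeded by
the caller: the same seed reproduces the same bytes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from ._xport import write_xport
from .harmonize import SurveyDesign

__all__ = [
    "Scenario",
    "GroundTruth",
    "generate_population",
    "draw_survey",
    "write_fixture",
    "default_scenario",
]

RACE_LEVELS = ("NH White", "NH Black", "NH Asian", "Hispanic", "other/unknown")
EDU_LEVELS = (
    "less than 9th grade",
    "9-11th grade",
    "high school graduate",
    "some college or AA degree",
    "college graduate or above",
)
INSURANCE_FLAG_COLS = ("ins_priv", "ins_care", "ins_caid", "ins_oth")

COMORBIDITY_COLS = {
    "hypertension": "cm_htn",
    "asthma": "cm_asth",
    "arthritis": "cm_arth",
    "gout": "cm_gout",
    "congestive_heart_failure": "cm_chf",
    "coronary_heart_disease": "cm_chd",
    "heart_attack": "cm_mi",
    "stroke": "cm_strk",
    "emphysema": "cm_emph",
    "chronic_bronchitis": "cm_bronc",
    "cancer": "cm_canc",
    "liver_disease": "cm_liver",
    "copd": "cm_copd",
    "kidney_disease": "cm_kidn",
    "diabetic_retinopathy": "cm_retin",
}


@dataclass
class Scenario:
    """Study conditions for the synthetic survey.

    Sizes default to a desk-scale rendition of a 3-cycle national survey:
    15 design strata, 8 PSUs per stratum in the frame of which 2 are sampled,
    150 respondents sampled per PSU draw, 3 cycles — about 13,500 sampled
    rows from a census of 72,000.
    """

    n_strata: int = 15
    psus_per_stratum: int = 8
    psu_size: int = 600
    sampled_psus: int = 2
    sampled_per_psu: int = 150
    cycles: tuple[str, ...] = ("2013-2014", "2015-2016", "2017-2018")

    race_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "NH White": 0.62,
            "NH Black": 0.12,
            "NH Asian": 0.06,
            "Hispanic": 0.17,
            "other/unknown": 0.03,
        }
    )
    p_male: float = 0.49
    edu_probs: tuple[float, ...] = (0.08, 0.12, 0.24, 0.31, 0.25)
    insurance_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "private": 0.55,
            "medicare": 0.15,
            "medicaid": 0.12,
            "other": 0.08,
            "uninsured": 0.10,
        }
    )
    p_dual_plan: float = 0.03
    pir_mu: float = -0.15  # log-scale location of the income-to-poverty ratio
    pir_sigma: float = 0.70
    pir_cap: float = 5.0
    age_mean: float = 47.0
    age_sd: float = 17.0
    age_min: int = 18
    age_max: int = 85
    p_pregnant_fertile: float = 0.05
    p_diabetes: float = 0.12
    hba1c_nondiab: tuple[float, float] = (5.4, 0.35)
    hba1c_diab: tuple[float, float] = (7.4, 1.4)
    comorbidity_prev: Mapping[str, float] = field(
        default_factory=lambda: {
            "hypertension": 0.35,
            "asthma": 0.08,
            "arthritis": 0.24,
            "gout": 0.04,
            "congestive_heart_failure": 0.03,
            "coronary_heart_disease": 0.05,
            "heart_attack": 0.04,
            "stroke": 0.03,
            "emphysema": 0.02,
            "chronic_bronchitis": 0.04,
            "cancer": 0.09,
            "liver_disease": 0.03,
            "copd": 0.04,
            "kidney_disease": 0.03,
            "diabetic_retinopathy": 0.02,
        }
    )
    #: per-outcome logistic models: intercept on the logit scale plus
    #: {column: {level: log-odds-ratio}} for categorical effects and
    #: {column: slope} for continuous ones.
    outcome_models: Mapping[str, Mapping] = field(
        default_factory=lambda: {
            "vax_hav": {
                "intercept": -0.85,
                "race": {
                    "NH Black": np.log(1.09),
                    "NH Asian": np.log(1.17),
                    "Hispanic": np.log(1.13),
                },
                "age_slope": -0.004,
            },
            "vax_hbv": {
                "intercept": -0.75,
                "race": {"NH Asian": np.log(1.10)},
                "age_slope": -0.006,
            },
            "vax_hpv": {
                "intercept": -1.30,
                "race": {"NH Asian": np.log(0.94)},
                "age_slope": -0.010,
            },
        }
    )
    #: optional injected disparities: outcome -> {(column, level): odds multiplier}
    share_disparities: Mapping[str, Mapping[tuple[str, str], float]] = field(
        default_factory=dict
    )
    psu_effect_sd: float = 0.15
    #: respondent oversampling factors by race (unequal inclusion probabilities)
    oversample: Mapping[str, float] = field(
        default_factory=lambda: {
            "NH Black": 1.8,
            "NH Asian": 1.8,
            "Hispanic": 1.6,
        }
    )


def default_scenario(**overrides) -> Scenario:
    return Scenario(**overrides)


@dataclass
class GroundTruth:
    """Exact census-level truth recorded at generation time."""

    coefficients: dict
    subgroup_shares: dict
    utilization_rates: dict
    census_size: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "coefficients": self.coefficients,
                    "subgroup_shares": self.subgroup_shares,
                    "utilization_rates": self.utilization_rates,
                    "census_size": self.census_size,
                },
                fh,
                indent=2,
            )


def _linear_predictor(df: pd.DataFrame, model: Mapping, scenario: Scenario) -> np.ndarray:
    eta = np.full(len(df), float(model.get("intercept", 0.0)))
    for key, effect in model.items():
        if key in ("intercept",):
            continue
        if key.endswith("_slope"):
            col = key[: -len("_slope")]
            eta += float(effect) * (df[col].to_numpy(dtype=float) - df[col].mean())
            continue
        for level, logor in effect.items():
            eta += float(logor) * (df[key] == level).to_numpy(dtype=float)
    return eta


def generate_population(
    scenario: Scenario, rng: np.random.Generator
) -> tuple[pd.DataFrame, GroundTruth]:
    """Realize the finite census and record its exact ground truth.

    Returns the census table (one row per population member, with stratum
    and PSU labels) and a :class:`GroundTruth` holding the true logistic
    coefficients, the realized subgroup shares, and realized per-subgroup
    utilization rates.
    """
    sc = scenario
    n = sc.n_strata * sc.psus_per_stratum * sc.psu_size
    stratum = np.repeat(np.arange(sc.n_strata), sc.psus_per_stratum * sc.psu_size)
    psu = np.tile(np.repeat(np.arange(sc.psus_per_stratum), sc.psu_size), sc.n_strata)

    races = list(sc.race_probs)
    race = rng.choice(races, size=n, p=np.asarray(list(sc.race_probs.values())))
    gender = np.where(rng.random(n) < sc.p_male, "male", "female")
    edu = rng.choice(EDU_LEVELS, size=n, p=np.asarray(sc.edu_probs))
    age = np.clip(
        np.round(rng.normal(sc.age_mean, sc.age_sd, size=n)), sc.age_min, sc.age_max
    ).astype(int)

    # PSU-level heterogeneity: a random shift of the income location so that
    # respondents within a PSU resemble each other
    psu_key = stratum * sc.psus_per_stratum + psu
    n_psus = sc.n_strata * sc.psus_per_stratum
    psu_income_shift = rng.normal(0.0, 0.10, size=n_psus)
    pir = np.minimum(
        np.exp(rng.normal(sc.pir_mu + psu_income_shift[psu_key], sc.pir_sigma, size=n)),
        sc.pir_cap,
    )

    ins_class = rng.choice(
        list(sc.insurance_probs), size=n, p=np.asarray(list(sc.insurance_probs.values()))
    )
    flags = {c: np.zeros(n, dtype=bool) for c in INSURANCE_FLAG_COLS}
    flag_of = {
        "private": "ins_priv",
        "medicare": "ins_care",
        "medicaid": "ins_caid",
        "other": "ins_oth",
    }
    for cls, col in flag_of.items():
        flags[col] |= ins_class == cls
    # a few respondents report a second plan, exercising the priority rule
    dual = rng.random(n) < sc.p_dual_plan
    extra = rng.choice(list(flag_of.values()), size=n)
    for col in flag_of.values():
        flags[col] |= dual & (extra == col) & (ins_class != "uninsured")

    fertile = (gender == "female") & (age < 45)
    pregnant = fertile & (rng.random(n) < sc.p_pregnant_fertile)

    diabetes = rng.random(n) < (
        sc.p_diabetes * np.clip((age - 18) / 40.0, 0.3, 2.0)
    )
    hba1c = np.where(
        diabetes,
        rng.normal(*sc.hba1c_diab, size=n),
        rng.normal(*sc.hba1c_nondiab, size=n),
    )
    hba1c = np.clip(hba1c, 4.0, 15.0).round(1)

    df = pd.DataFrame(
        {
            "stratum": stratum,
            "psu": psu,
            "race": race,
            "gender": gender,
            "educ": edu,
            "age": age,
            "pir": pir.round(2),
            "pregnant": pregnant,
            "t2dm": diabetes,
            "hba1c": hba1c,
        }
    )
    for cond, col in COMORBIDITY_COLS.items():
        prev = sc.comorbidity_prev.get(cond, 0.0)
        if cond == "diabetic_retinopathy":
            # retinopathy only among diabetics
            df[col] = diabetes & (rng.random(n) < prev / max(sc.p_diabetes, 1e-9) * 0.5)
        else:
            df[col] = rng.random(n) < prev
    for col, arr in flags.items():
        df[col] = arr

    psu_effects = rng.normal(0.0, sc.psu_effect_sd, size=n_psus)
    utilization: dict[str, dict] = {}
    for outcome, model in sc.outcome_models.items():
        eta = _linear_predictor(df, model, sc) + psu_effects[psu_key]
        for (col, level), mult in sc.share_disparities.get(outcome, {}).items():
            if not mult > 0:
                raise ValueError(
                    f"infeasible disparity multiplier {mult!r} for {outcome!r}: "
                    "odds multipliers must be positive"
                )
            eta += np.log(mult) * (df[col] == level).to_numpy(dtype=float)
        p = 1.0 / (1.0 + np.exp(-eta))
        df[outcome] = rng.random(n) < p
        utilization[outcome] = {
            lvl: float(df.loc[df["race"] == lvl, outcome].mean()) for lvl in races
        }

    truth = GroundTruth(
        coefficients={
            out: {
                k: (dict(v) if isinstance(v, Mapping) else float(v))
                for k, v in model.items()
            }
            for out, model in sc.outcome_models.items()
        },
        subgroup_shares={
            "race": {lvl: float((df["race"] == lvl).mean()) for lvl in races}
        },
        utilization_rates=utilization,
        census_size=n,
    )
    return df, truth


def draw_survey(
    census: pd.DataFrame,
    scenario: Scenario,
    rng: np.random.Generator,
    *,
    cycle: str | None = None,
) -> tuple[pd.DataFrame, SurveyDesign]:
    """Draw one two-stage sample (one cycle) from the census.

    Within each stratum, ``sampled_psus`` PSU draws are made with
    replacement (equal probability); each draw then samples
    ``sampled_per_psu`` respondents with replacement, with probability
    proportional to the race-based oversampling factor.  The design weight
    is the reciprocal of the per-draw expected number of selections, so
    weighted sample totals are unbiased for census totals.
    """
    sc = scenario
    if census.empty:
        raise ValueError("census is empty")
    m = sc.sampled_per_psu
    label = cycle if cycle is not None else sc.cycles[0]
    over = np.ones(len(census))
    for lvl, factor in sc.oversample.items():
        over[(census["race"] == lvl).to_numpy()] = factor

    groups = census.groupby(["stratum", "psu"], sort=True).indices
    strata: dict = {}
    for (h, p), idx in groups.items():
        strata.setdefault(h, []).append((p, np.asarray(idx)))

    pick_rows: list[np.ndarray] = []
    weights: list[np.ndarray] = []
    psu_labels: list[np.ndarray] = []
    ids: list[str] = []
    for h, psu_list in strata.items():
        n_frame = len(psu_list)
        chosen = rng.integers(0, n_frame, size=sc.sampled_psus)
        for j, which in enumerate(chosen):
            p, members = psu_list[which]
            if m > len(members):
                raise ValueError(
                    f"requested {m} respondents from PSU of size {len(members)}"
                )
            o = over[members]
            o_total = o.sum()
            picks = members[
                rng.choice(len(members), size=m, replace=True, p=o / o_total)
            ]
            # Hansen-Hurwitz weight: inverse expected number of selections
            weights.append((n_frame / sc.sampled_psus) * o_total / (m * over[picks]))
            pick_rows.append(picks)
            psu_labels.append(np.full(m, j))
            ids.extend(f"{label}_{h}_{j}_{k}_{cid}" for k, cid in enumerate(picks))
    all_picks = np.concatenate(pick_rows)
    sample = census.iloc[all_picks].copy().reset_index(drop=True)
    sample["weight"] = np.concatenate(weights)
    sample["psu"] = np.concatenate(psu_labels)  # sampled-PSU draw identity
    sample["cycle"] = label
    sample["id"] = ids
    design = SurveyDesign(weight="weight", stratum="stratum", psu="psu")
    return sample, design


def draw_cycles(
    census: pd.DataFrame, scenario: Scenario, rng: np.random.Generator
) -> list[tuple[pd.DataFrame, SurveyDesign]]:
    """One independent survey draw per configured cycle."""
    return [
        draw_survey(census, scenario, rng, cycle=c) for c in scenario.cycles
    ]


def _default_codebooks_yaml() -> dict:
    """Codebooks for the coded fixture emitted by :func:`write_fixture`."""
    return {
        "gender": {"codes": {1: "male", 2: "female"}, "missing": [9]},
        "race": {
            "codes": {
                1: "NH White",
                2: "NH Black",
                3: "NH Asian",
                4: "Hispanic",
                5: "other/unknown",
            },
            "missing": [9],
        },
        "educ": {
            "codes": {
                1: "less than 9th grade",
                2: "9-11th grade",
                3: "12th grade no diploma",
                4: "high school graduate",
                5: "GED or equivalent",
                6: "some college or AA degree",
                7: "college graduate or above",
            },
            "missing": [9],
            "groups": {
                "less than 9th grade": "less than 9th grade",
                "9-11th grade": "9-11th grade",
                "12th grade no diploma": "9-11th grade",
                "high school graduate": "high school graduate",
                "GED or equivalent": "high school graduate",
                "some college or AA degree": "some college or AA degree",
                "college graduate or above": "college graduate or above",
            },
        },
        "pregnant": {"codes": {1: "yes", 2: "no"}, "missing": [9]},
    }


_EDU_CODE = {
    "less than 9th grade": 1,
    "9-11th grade": 2,
    "high school graduate": 4,
    "some college or AA degree": 6,
    "college graduate or above": 7,
}
_RACE_CODE = {lvl: i + 1 for i, lvl in enumerate(RACE_LEVELS)}


def encode_fixture(df: pd.DataFrame) -> pd.DataFrame:
    """Re-express labelled columns as survey-style integer codes."""
    out = df.copy()
    if "gender" in out:
        out["gender"] = out["gender"].map({"male": 1, "female": 2})
    if "race" in out:
        out["race"] = out["race"].map(_RACE_CODE)
    if "educ" in out:
        out["educ"] = out["educ"].map(_EDU_CODE)
    if "pregnant" in out:
        out["pregnant"] = out["pregnant"].map({True: 1, False: 2})
    for col in out.columns:
        if out[col].dtype == bool:
            out[col] = out[col].astype(int)
    return out


def write_fixture(
    df: pd.DataFrame,
    out_dir,
    *,
    format: str = "csv",
    name: str = "survey",
    coded: bool = True,
) -> dict[str, Path]:
    """Write a sample table (plus codebooks) as loadable fixture files.

    ``coded=True`` re-encodes labelled columns into integer codes matching
    the emitted codebook YAML, mirroring how real survey files arrive.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = encode_fixture(df) if coded else df.copy()
    paths: dict[str, Path] = {}
    if format == "csv":
        data_path = out_dir / f"{name}.csv"
        table.to_csv(data_path, index=False)
    elif format == "xpt":
        data_path = out_dir / f"{name}.xpt"
        write_xport(table, data_path, dataset_name="SVYDATA")
    else:
        raise ValueError(f"unknown fixture format {format!r}")
    paths["data"] = data_path
    if coded:
        cb_path = out_dir / "codebooks.yaml"
        with open(cb_path, "w") as fh:
            yaml.safe_dump(_default_codebooks_yaml(), fh, sort_keys=False)
        paths["codebooks"] = cb_path
    return paths
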