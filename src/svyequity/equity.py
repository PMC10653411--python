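"""Log-disparity equity metric, thresholds, and six-level classification.

The central question: did a subgroup receive a healthcare service (a vaccine,
a drug class) in proportion to its share of the population that needs the
service?  Writing ``p_obs`` for the subgroup's share among service recipients
and ``p_tgt`` for its share of the target (in-need) population, the metric is

    LogDisparity = log[ (p_obs / (1 - p_obs)) / (p_tgt / (1 - p_tgt)) ]

i.e. the log odds ratio of observed versus target composition.  Zero means
proportionate utilization; negative means the subgroup is under-served.

Scores are graded against two thresholds derived from disparate-impact rules,
tau = -log(1 - tau_rule): the 80% rule gives the lower threshold
tau_l = -log(0.8) and a 60% rule gives the upper threshold tau_u = -log(0.6).
A significance test gates the grading: a cell whose observed/target gap is
not statistically significant is always classified Adequate.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import ShareEstimate, subgroup_shares

__all__ = [
    "EquityLevel",
    "EquityThresholds",
    "EquityCell",
    "EquityTable",
    "threshold_from_rule",
    "log_disparity",
    "test_disparity",
    "classify_equity",
    "equity_table",
    "ABSENT",
]

#: Sentinel score for a subgroup present in the target population but entirely
#: absent among recipients (observed share exactly zero).
ABSENT = float("-inf")


class EquityLevel(str, Enum):
    """Six-level equity classification, ordered from worst to best supply."""

    ABSENT = "Absent"
    HIGHLY_INADEQUATE = "Highly Inadequate"
    INADEQUATE = "Inadequate"
    ADEQUATE = "Adequate"
    ABUNDANT = "Abundant"
    HIGHLY_ABUNDANT = "Highly Abundant"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def threshold_from_rule(tau_rule: float) -> float:
    """Convert a disparate-impact rule fraction into a log-disparity threshold.

    A rule fraction ``tau_rule`` (e.g. 0.2 for the 80% rule) maps to the
    threshold ``-log(1 - tau_rule)``; a subgroup whose observed odds fall
    below ``1 - tau_rule`` times its target odds crosses the threshold.

    Parameters
    ----------
    tau_rule : float in [0, 1)
        Rule fraction.  0.2 reproduces the classic 80% disparate-impact rule.

    Returns
    -------
    float
        Non-negative threshold on the log-disparity scale.
    """
    if not 0.0 <= tau_rule < 1.0:
        raise ValueError(
            f"tau_rule must lie in [0, 1); got {tau_rule!r} "
            "(tau_rule >= 1 would give an infinite threshold)"
        )
    return -math.log(1.0 - tau_rule)


@dataclass(frozen=True)
class EquityThresholds:
    """Threshold configuration for equity classification.

    Attributes
    ----------
    tau_rule_lower, tau_rule_upper : float
        Rule fractions; defaults 0.2 (the 80% rule) and 0.4.  The derived
        log-scale thresholds are ``tau_l = -log(1 - tau_rule_lower)`` and
        ``tau_u = -log(1 - tau_rule_upper)``.
    alpha : float
        Significance level for the disparity test gate; default 0.05.
    """

    tau_rule_lower: float = 0.2
    tau_rule_upper: float = 0.4
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau_rule_lower < self.tau_rule_upper < 1.0:
            raise ValueError(
                "require 0 <= tau_rule_lower < tau_rule_upper < 1; got "
                f"{self.tau_rule_lower!r}, {self.tau_rule_upper!r}"
            )
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1); got {self.alpha!r}")

    @property
    def tau_l(self) -> float:
        return threshold_from_rule(self.tau_rule_lower)

    @property
    def tau_u(self) -> float:
        return threshold_from_rule(self.tau_rule_upper)


def log_disparity(observed_share: float, target_share: float) -> float:
    """Log odds ratio of a subgroup's observed versus target share.

    Parameters
    ----------
    observed_share : float in [0, 1)
        Subgroup share among recipients of the service.
    target_share : float in (0, 1)
        Subgroup share of the target population.

    Returns
    -------
    float
        ``log[(p_obs/(1-p_obs)) / (p_tgt/(1-p_tgt))]`` (natural log), or the
        ``-inf`` Absent sentinel when the observed share is exactly zero.
    """
    if not 0.0 < target_share < 1.0:
        raise ValueError(
            f"target share must lie strictly in (0, 1); got {target_share!r} "
            "(odds undefined at 0 or 1)"
        )
    if not 0.0 <= observed_share < 1.0:
        raise ValueError(f"observed share must lie in [0, 1); got {observed_share!r}")
    if observed_share == 0.0:
        return ABSENT
    return math.log(observed_share / (1.0 - observed_share)) - math.log(
        target_share / (1.0 - target_share)
    )


def test_disparity(
    observed: ShareEstimate,
    target: ShareEstimate,
    *,
    method: str = "exact",
) -> float:
    """Two-sided p-value for H0: observed subgroup share equals target share.

    Two modes are provided because the original analysis does not pin down
    whether the survey design entered its test:

    ``"exact"`` (default)
        Exact binomial test on design-adjusted counts: successes are the
        observed share times the Kish effective number of recipients
        (rounded), trials the rounded effective n, and the null probability
        the target share point estimate.
    ``"normal"``
        Normal approximation using the linearized standard errors of both
        shares: z = (p_obs - p_tgt) / sqrt(se_obs^2 + se_tgt^2).
    """
    p_tgt = target.estimate
    if not 0.0 < p_tgt < 1.0:
        raise ValueError(f"degenerate target share {p_tgt!r}; test undefined")
    if method == "exact":
        n_eff = observed.effective_n
        if not n_eff > 0:
            raise ValueError("recipient effective n must be positive")
        trials = max(int(round(n_eff)), 1)
        successes = int(round(observed.estimate * n_eff))
        successes = min(max(successes, 0), trials)
        return stats.binomtest(successes, trials, p_tgt, alternative="two-sided").pvalue
    if method == "normal":
        se = math.hypot(observed.se, target.se)
        if se == 0.0:
            return 1.0 if observed.estimate == p_tgt else 0.0
        z = (observed.estimate - p_tgt) / se
        return 2.0 * stats.norm.sf(abs(z))
    raise ValueError(f"unknown test method {method!r}; use 'exact' or 'normal'")


def classify_equity(
    score: float, p_value: float, thresholds: EquityThresholds | None = None
) -> EquityLevel:
    """Map a (score, p-value) pair to one of the six equity levels.

    Rules, in order: the Absent sentinel (observed share zero) wins outright;
    a non-significant disparity (p > alpha) is Adequate regardless of score;
    otherwise the score is graded on half-open bands
    ``(-inf, -tau_u) | [-tau_u, -tau_l) | [-tau_l, tau_l) | [tau_l, tau_u) |
    [tau_u, inf)``.
    """
    th = thresholds if thresholds is not None else EquityThresholds()
    if score == ABSENT or (isinstance(score, float) and math.isinf(score) and score < 0):
        return EquityLevel.ABSENT
    if p_value > th.alpha:
        return EquityLevel.ADEQUATE
    tau_l, tau_u = th.tau_l, th.tau_u
    if score < -tau_u:
        return EquityLevel.HIGHLY_INADEQUATE
    if score < -tau_l:
        return EquityLevel.INADEQUATE
    if score < tau_l:
        return EquityLevel.ADEQUATE
    if score < tau_u:
        return EquityLevel.ABUNDANT
    return EquityLevel.HIGHLY_ABUNDANT


@dataclass(frozen=True)
class EquityCell:
    """One subgroup x outcome evaluation (optionally within a conditioning stratum)."""

    subgroup: str
    outcome: str
    conditioning: tuple[str, ...] = ()
    observed: ShareEstimate | None = None
    target: ShareEstimate | None = None
    p_value: float = float("nan")
    score: float = float("nan")
    level: EquityLevel | None = None
    structurally_missing: bool = False


@dataclass
class EquityTable:
    """Grid of equity cells plus the thresholds and target description used."""

    cells: list[EquityCell]
    thresholds: EquityThresholds
    target_description: str = ""

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-cell representation (the serialization format)."""
        rows = []
        for c in self.cells:
            rows.append(
                {
                    "subgroup": c.subgroup,
                    "conditioning": " | ".join(c.conditioning),
                    "outcome": c.outcome,
                    "observed_share": c.observed.estimate if c.observed else np.nan,
                    "observed_se": c.observed.se if c.observed else np.nan,
                    "target_share": c.target.estimate if c.target else np.nan,
                    "target_se": c.target.se if c.target else np.nan,
                    "effective_n": c.observed.effective_n if c.observed else np.nan,
                    "score": c.score,
                    "p_value": c.p_value,
                    "level": c.level.value if c.level is not None else "",
                    "structurally_missing": c.structurally_missing,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path) -> None:
        self.to_frame().to_json(path, orient="records", indent=2)


def _conditioning_strata(
    df: pd.DataFrame, conditioning: Sequence[str] | None
) -> Iterable[tuple[tuple[str, ...], pd.Series]]:
    """Yield (labels, row mask) per conditioning stratum; one trivial stratum if none."""
    if not conditioning:
        yield (), pd.Series(True, index=df.index)
        return
    level_sets = [sorted(df[c].dropna().unique(), key=str) for c in conditioning]
    for combo in itertools.product(*level_sets):
        mask = pd.Series(True, index=df.index)
        for col, val in zip(conditioning, combo):
            mask &= df[col] == val
        yield tuple(f"{c}={v}" for c, v in zip(conditioning, combo)), mask


def equity_table(
    df: pd.DataFrame,
    *,
    sensitive: str | Sequence[str],
    outcomes: Sequence[str],
    design,
    conditioning: Sequence[str] | None = None,
    target_mask: pd.Series | None = None,
    thresholds: EquityThresholds | None = None,
    test_method: str = "exact",
    bonferroni: bool = False,
) -> EquityTable:
    """Build the full equity grid over subgroup levels x outcomes.

    For each level of the sensitive covariate(s), each binary outcome column
    and each conditioning stratum, the pipeline is: survey-weighted observed
    and target shares -> significance test -> log-disparity score -> six-level
    classification.

    Parameters
    ----------
    df : pandas.DataFrame
        Harmonized analysis table (complete cases on the used columns).
    sensitive : str or sequence of str
        Sensitive covariate column(s); with several, subgroups are their
        cross-classification.
    outcomes : sequence of str
        Boolean outcome columns (service received).
    design : SurveyDesign
        Column bindings for weight / stratum / PSU.
    conditioning : sequence of str, optional
        Columns whose joint levels define subpopulations analyzed separately
        (e.g. an HbA1c stratum crossed with insurance type).
    target_mask : boolean Series, optional
        Rows forming the target (in-need) population; defaults to all rows.
    bonferroni : bool
        Divide alpha by the number of tested cells (off by default).

    Returns
    -------
    EquityTable
    """
    th = thresholds if thresholds is not None else EquityThresholds()
    sens_cols = [sensitive] if isinstance(sensitive, str) else list(sensitive)
    for col in sens_cols + list(outcomes):
        if col not in df.columns:
            raise KeyError(f"column {col!r} not present in analysis table")
    base_target = (
        pd.Series(True, index=df.index) if target_mask is None else target_mask.astype(bool)
    )

    level_sets = [sorted(df.loc[base_target, c].dropna().unique(), key=str) for c in sens_cols]
    subgroup_levels = list(itertools.product(*level_sets))

    cells: list[EquityCell] = []
    pending: list[tuple[int, ShareEstimate, ShareEstimate]] = []
    for cond_labels, cond_mask in _conditioning_strata(df, conditioning):
        stratum_target = base_target & cond_mask
        if conditioning and not stratum_target.any():
            raise ValueError(
                f"target population empty in conditioning stratum {cond_labels!r}"
            )
        for outcome in outcomes:
            recipients = stratum_target & df[outcome].eq(True)
            for combo in subgroup_levels:
                sub_mask = pd.Series(True, index=df.index)
                for col, val in zip(sens_cols, combo):
                    sub_mask &= df[col] == val
                label = " & ".join(f"{v}" for v in combo)
                in_target = (stratum_target & sub_mask).any()
                if not in_target:
                    cells.append(
                        EquityCell(
                            subgroup=label,
                            outcome=outcome,
                            conditioning=cond_labels,
                            structurally_missing=True,
                        )
                    )
                    continue
                obs, tgt = subgroup_shares(
                    df,
                    subgroup_mask=sub_mask,
                    target_mask=stratum_target,
                    recipient_mask=recipients,
                    design=design,
                )
                if obs is None:
                    # target subgroup exists but nobody at all received care
                    cells.append(
                        EquityCell(
                            subgroup=label,
                            outcome=outcome,
                            conditioning=cond_labels,
                            target=tgt,
                            score=ABSENT,
                            p_value=float("nan"),
                            level=EquityLevel.ABSENT,
                        )
                    )
                    continue
                pending.append((len(cells), obs, tgt))
                cells.append(
                    EquityCell(
                        subgroup=label,
                        outcome=outcome,
                        conditioning=cond_labels,
                        observed=obs,
                        target=tgt,
                    )
                )

    alpha = th.alpha / max(len(pending), 1) if bonferroni else th.alpha
    eff_th = EquityThresholds(th.tau_rule_lower, th.tau_rule_upper, alpha)
    for idx, obs, tgt in pending:
        cell = cells[idx]
        if not 0.0 < tgt.estimate < 1.0:
            # subgroup == whole target (or empty): no disparity is definable
            score, p = 0.0, 1.0
            level = EquityLevel.ADEQUATE
        else:
            score = log_disparity(obs.estimate, tgt.estimate)
            p = test_disparity(obs, tgt, method=test_method)
            level = classify_equity(score, p, eff_th)
        cells[idx] = EquityCell(
            subgroup=cell.subgroup,
            outcome=cell.outcome,
            conditioning=cell.conditioning,
            observed=obs,
            target=tgt,
            p_value=p,
            score=score,
            level=level,
        )
    return EquityTable(cells=cells, thresholds=th)
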