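"""Design-aware estimation for stratified multistage survey samples.

Point estimates are Horvitz-Thompson style weighted ratios; variances use
Taylor linearization under the with-replacement first-stage (ultimate
cluster) approximation standard for NHANES-like designs: per-row influence
values are summed to PSU totals, and the between-PSU variance within each
stratum, inflated by n_h/(n_h - 1), is summed over strata.  Finite-population
corrections are deliberately omitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ShareEstimate",
    "weighted_proportion",
    "kish_effective_n",
    "linearized_variance",
    "subgroup_shares",
]


@dataclass(frozen=True)
class ShareEstimate:
    """A weighted proportion with its design-based uncertainty.

    Attributes
    ----------
    estimate : float in [0, 1]
    se : float
        Taylor-linearized standard error.
    effective_n : float
        Kish effective sample size of the denominator rows.
    weighted_total : float
        Weighted size of the denominator population.
    n : int
        Raw number of denominator rows.
    """

    estimate: float
    se: float
    effective_n: float
    weighted_total: float
    n: int


def weighted_proportion(indicator, weights) -> float:
    """Weighted proportion sum(w*x) / sum(w).

    The estimator is invariant to uniform rescaling of the weights.
    """
    x = np.asarray(indicator, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.shape != w.shape:
        raise ValueError("indicator and weights must have equal length")
    total = w.sum()
    if not total > 0:
        raise ValueError("weights must include at least one positive value")
    return float((w * x).sum() / total)


def kish_effective_n(weights) -> float:
    """Kish effective sample size (sum w)^2 / sum(w^2).

    Equals the raw n under equal weights and approaches 1 as a single weight
    dominates; it is the equal-weight sample size with equivalent variance.
    """
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValueError("weights must be nonempty")
    return float(w.sum() ** 2 / (w**2).sum())


def linearized_variance(
    numerator,
    denominator,
    weights,
    strata,
    psus,
    *,
    lonely_psu: str = "center",
) -> float:
    """Taylor-linearized variance of the ratio estimator R = sum(w*y)/sum(w*x).

    Per-row influence values z_i = w_i (y_i - R x_i) / sum(w*x) are aggregated
    to PSU totals; within each stratum the between-PSU sum of squares around
    the stratum mean, times n_h/(n_h - 1), contributes to the variance.

    Parameters
    ----------
    numerator, denominator : array-like
        Row-level y and x of the ratio (for a domain proportion, x is the
        domain indicator and y the domain-and-trait indicator).
    weights, strata, psus : array-like
        Design columns, aligned with the rows.
    lonely_psu : {"center", "error"}
        Strata containing a single PSU either contribute their squared
        deviation from the grand mean of PSU totals ("center", default) or
        raise an error.
    """
    y = np.asarray(numerator, dtype=float)
    x = np.asarray(denominator, dtype=float)
    w = np.asarray(weights, dtype=float)
    strata = np.asarray(strata)
    psus = np.asarray(psus)
    xw = float((w * x).sum())
    if not xw > 0:
        raise ValueError("denominator weighted total must be positive")
    ratio = (w * y).sum() / xw
    z = w * (y - ratio * x) / xw

    frame = pd.DataFrame({"z": z, "stratum": strata, "psu": psus})
    psu_totals = frame.groupby(["stratum", "psu"], sort=False, observed=True)["z"].sum()
    counts = psu_totals.groupby(level=0, sort=False, observed=True).size()

    lonely = counts[counts < 2].index
    if len(lonely) and lonely_psu == "error":
        raise ValueError(f"strata with a single PSU: {list(lonely)!r}")

    variance = 0.0
    grand_mean = float(psu_totals.mean())
    for stratum, totals in psu_totals.groupby(level=0, sort=False, observed=True):
        t = totals.to_numpy()
        n_h = t.size
        if n_h >= 2:
            variance += n_h / (n_h - 1) * float(((t - t.mean()) ** 2).sum())
        else:
            # lonely PSU centered at the grand mean of PSU totals
            variance += float((t[0] - grand_mean) ** 2)
    return variance


def subgroup_shares(
    df: pd.DataFrame,
    *,
    subgroup_mask,
    target_mask,
    recipient_mask,
    design,
) -> tuple[ShareEstimate | None, ShareEstimate]:
    """Observed and target shares of a subgroup, with design-based SEs.

    The *target share* is the weighted proportion of subgroup members among
    the target (in-need) population; the *observed share* is the weighted
    proportion of subgroup members among target-population members who
    actually received the service.

    Returns
    -------
    (observed, target) : tuple of ShareEstimate
        ``observed`` is None when nobody in the target population received
        the service (the grid marks such cells for Absent handling).
    """
    sub = np.asarray(subgroup_mask, dtype=bool)
    tgt = np.asarray(target_mask, dtype=bool)
    rec = np.asarray(recipient_mask, dtype=bool) & tgt
    w = df[design.weight].to_numpy(dtype=float)
    strata = df[design.stratum].to_numpy()
    psus = df[design.psu].to_numpy()
    if not tgt.any():
        raise ValueError("target population is empty")

    def _share(denom_mask: np.ndarray) -> ShareEstimate:
        num = (denom_mask & sub).astype(float)
        den = denom_mask.astype(float)
        p = float((w * num).sum() / (w * den).sum())
        var = linearized_variance(num, den, w, strata, psus)
        return ShareEstimate(
            estimate=p,
            se=float(np.sqrt(max(var, 0.0))),
            effective_n=kish_effective_n(w[denom_mask]),
            weighted_total=float(w[denom_mask].sum()),
            n=int(denom_mask.sum()),
        )

    target_est = _share(tgt)
    if not rec.any():
        return None, target_est
    observed_est = _share(rec)
    return observed_est, target_est
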