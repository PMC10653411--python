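"""Survey-weighted logistic regression with design-based inference.

The model maximizes the weighted Bernoulli log-likelihood by iteratively
reweighted least squares (IRLS).  Because sample weights are not frequency
weights, the usual inverse-information variance is wrong; instead the
covariance is the Taylor-linearization sandwich: per-respondent score
contributions u_i = w_i (y_i - p_i) x_i are summed to PSU totals, their
between-PSU scatter within each stratum (inflated by n_h/(n_h-1)) forms the
meat G, and Cov(beta) = H^-1 G H^-1 with H the weighted information.
Confidence intervals use a t reference with the design degrees of freedom
(#PSUs - #strata), the standard convention for complex-survey inference.

The estimator follows scikit-learn conventions: constructor stores
parameters, `fit` learns `coef_`/`cov_` and friends, `get_params` /
`set_params` allow composition with model-selection tooling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.special import expit

from .harmonize import SurveyDesign

__all__ = [
    "Covariate",
    "ModelSpec",
    "SeparationError",
    "ConvergenceError",
    "SurveyLogisticRegression",
    "fit_weighted_logistic",
]


class SeparationError(RuntimeError):
    """(Quasi-)complete separation: a coefficient diverges while fitted
    probabilities pin to 0/1."""


class ConvergenceError(RuntimeError):
    """IRLS failed to converge within the iteration budget."""


@dataclass(frozen=True)
class Covariate:
    """One model covariate.

    kind: "categorical" (unordered, treatment-coded against `reference`),
    "ordered" (entered as per-level indicators against the lowest/declared
    reference so each level gets its own odds ratio), or "continuous".
    """

    name: str
    kind: str = "categorical"
    reference: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "ordered", "continuous"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Outcome + covariates of a regression model."""

    outcome: str
    covariates: tuple[Covariate, ...]

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        covs = tuple(
            Covariate(
                name=c["name"],
                kind=c.get("kind", "categorical"),
                reference=c.get("reference"),
            )
            for c in raw["covariates"]
        )
        return cls(outcome=raw["outcome"], covariates=covs)


def _design_matrix(df: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    """Intercept + treatment-coded categorical indicators + continuous columns."""
    cols: list[np.ndarray] = [np.ones(len(df))]
    names: list[str] = ["(Intercept)"]
    for cov in spec.covariates:
        if cov.name not in df.columns:
            raise KeyError(f"covariate {cov.name!r} missing from table")
        if cov.kind == "continuous":
            cols.append(df[cov.name].to_numpy(dtype=float))
            names.append(cov.name)
            continue
        values = df[cov.name]
        levels = sorted(values.dropna().unique(), key=str)
        ref = cov.reference if cov.reference is not None else levels[0]
        if ref not in levels:
            raise ValueError(
                f"reference level {ref!r} of {cov.name!r} absent from the data"
            )
        for level in levels:
            if level == ref:
                continue
            cols.append((values == level).to_numpy(dtype=float))
            names.append(f"{cov.name}[{level}]")
    return np.column_stack(cols), names


class SurveyLogisticRegression:
    """Design-based logistic regression estimator.

    Parameters
    ----------
    spec : ModelSpec
        Outcome and covariates with reference levels.
    design : SurveyDesign
        Weight / stratum / PSU column bindings.
    max_iter : int
        IRLS iteration cap (default 25).
    tol : float
        Relative deviance-change convergence tolerance (default 1e-8).

    Attributes (after fit)
    ----------------------
    coef_ : pandas.Series          log-odds coefficients by term
    cov_ : pandas.DataFrame        linearized sandwich covariance
    se_ : pandas.Series            design-based standard errors
    df_resid_ : int                design degrees of freedom (#PSUs - #strata)
    n_iter_, converged_, deviance_trace_ : convergence record
    """

    def __init__(
        self,
        spec: ModelSpec,
        design: SurveyDesign,
        *,
        max_iter: int = 25,
        tol: float = 1e-8,
    ) -> None:
        self.spec = spec
        self.design = design
        self.max_iter = max_iter
        self.tol = tol

    # -- sklearn-style parameter plumbing ---------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "spec": self.spec,
            "design": self.design,
            "max_iter": self.max_iter,
            "tol": self.tol,
        }

    def set_params(self, **params) -> "SurveyLogisticRegression":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    # ----------------------------------------------------------------------
    def fit(self, df: pd.DataFrame) -> "SurveyLogisticRegression":
        spec, design = self.spec, self.design
        design.validate(df)
        y = df[spec.outcome].to_numpy(dtype=float)
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError(f"outcome {spec.outcome!r} must be binary 0/1")
        X, names = _design_matrix(df, spec)
        w = df[design.weight].to_numpy(dtype=float)
        if np.isnan(X).any():
            raise ValueError("design matrix contains missing values; drop them first")

        beta = np.zeros(X.shape[1])
        deviances: list[float] = []
        converged = False
        for _ in range(self.max_iter):
            eta = X @ beta
            p = expit(eta)
            p = np.clip(p, 1e-12, 1 - 1e-12)
            irls_w = w * p * (1 - p)
            z = eta + (y - p) / (p * (1 - p))
            XtW = X.T * irls_w
            try:
                beta = np.linalg.solve(XtW @ X, XtW @ z)
            except np.linalg.LinAlgError as err:
                raise ConvergenceError(f"singular weighted information: {err}") from err
            dev = -2.0 * float(np.sum(w * (y * np.log(p) + (1 - y) * np.log(1 - p))))
            deviances.append(dev)
            if len(deviances) >= 2:
                rel = abs(deviances[-2] - dev) / (abs(dev) + 0.1)
                if rel < self.tol:
                    converged = True
                    break
        p = expit(np.clip(X @ beta, -700, 700))
        pinned = (p < 1e-10) | (p > 1 - 1e-10)
        if pinned.any() and np.abs(beta).max() > 15:
            worst = names[int(np.argmax(np.abs(beta)))]
            raise SeparationError(
                f"separation detected: coefficient of {worst!r} diverges with "
                f"{int(pinned.sum())} fitted probabilities pinned at 0/1"
            )
        if not converged:
            raise ConvergenceError(
                f"IRLS did not converge in {self.max_iter} iterations; "
                f"deviance trace {deviances!r}"
            )

        # Taylor-linearization sandwich over PSU score totals
        H = (X.T * (w * p * (1 - p))) @ X
        scores = X * (w * (y - p))[:, None]
        strata = df[self.design.stratum].to_numpy()
        psus = df[self.design.psu].to_numpy()
        G = np.zeros((X.shape[1], X.shape[1]))
        n_psu_total = 0
        n_strata = 0
        score_df = pd.DataFrame(scores)
        score_df["_stratum"] = strata
        score_df["_psu"] = psus
        psu_totals = score_df.groupby(["_stratum", "_psu"], sort=False, observed=True).sum()
        for _, totals in psu_totals.groupby(level=0, sort=False, observed=True):
            t = totals.to_numpy()
            n_h = t.shape[0]
            n_psu_total += n_h
            n_strata += 1
            if n_h < 2:
                continue
            centered = t - t.mean(axis=0)
            G += n_h / (n_h - 1) * centered.T @ centered
        Hinv = np.linalg.inv(H)
        cov = Hinv @ G @ Hinv
        cov = (cov + cov.T) / 2.0

        self.term_names_ = names
        self.coef_ = pd.Series(beta, index=names)
        self.cov_ = pd.DataFrame(cov, index=names, columns=names)
        self.se_ = pd.Series(np.sqrt(np.clip(np.diag(cov), 0.0, None)), index=names)
        self.df_resid_ = max(n_psu_total - n_strata, 1)
        self.n_iter_ = len(deviances)
        self.converged_ = converged
        self.deviance_trace_ = deviances
        self.deviance_ = deviances[-1]
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "coef_"):
            raise RuntimeError("estimator is not fitted; call fit() first")

    def predict_proba(self, df: pd.DataFrame) -> np.ndarray:
        """Fitted event probabilities for new rows."""
        self._check_fitted()
        X, names = _design_matrix(df, self.spec)
        if names != self.term_names_:
            raise ValueError("new data produced a different design matrix layout")
        return expit(X @ self.coef_.to_numpy())

    def odds_ratios(self, *, alpha: float = 0.05) -> pd.DataFrame:
        """Adjusted odds ratios with design-based t confidence intervals.

        One row per non-reference covariate level: OR = exp(beta),
        CI = exp(beta -+ t_{df,1-alpha/2} * SE), Wald p-value, significance
        flag at `alpha`, and the printed "OR (low, high)" string.
        """
        self._check_fitted()
        tcrit = stats.t.ppf(1 - alpha / 2, self.df_resid_)
        rows = []
        for term in self.term_names_:
            if term == "(Intercept)":
                continue
            b = self.coef_[term]
            se = self.se_[term]
            tval = b / se if se > 0 else np.inf * np.sign(b)
            pval = 2 * stats.t.sf(abs(tval), self.df_resid_)
            lo, hi = np.exp(b - tcrit * se), np.exp(b + tcrit * se)
            rows.append(
                {
                    "term": term,
                    "or": float(np.exp(b)),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                    "p_value": float(pval),
                    "significant": bool(pval <= alpha),
                    "formatted": f"{np.exp(b):.2f} ({lo:.2f}, {hi:.2f})",
                }
            )
        return pd.DataFrame(rows).set_index("term")

    def flag_outliers(self, df: pd.DataFrame, *, cutoff: float = 3.0) -> pd.Index:
        """Rows with |weighted standardized Pearson residual| above `cutoff`.

        Residuals are standardized with the weighted leverage; flagged rows
        are reported for inspection, never dropped.
        """
        self._check_fitted()
        X, _ = _design_matrix(df, self.spec)
        y = df[self.spec.outcome].to_numpy(dtype=float)
        w = df[self.design.weight].to_numpy(dtype=float)
        p = expit(X @ self.coef_.to_numpy())
        w_norm = w / w.mean()  # keep typical residuals on the unit scale
        irls_w = w * p * (1 - p)
        XtWX_inv = np.linalg.inv((X.T * irls_w) @ X)
        leverage = np.einsum("ij,jk,ik->i", X, XtWX_inv, X) * irls_w
        leverage = np.clip(leverage, 0.0, 1.0 - 1e-12)
        denom = np.sqrt(p * (1 - p) / w_norm * (1.0 - leverage))
        resid = (y - p) / denom
        return df.index[np.abs(resid) > cutoff]


def fit_weighted_logistic(
    df: pd.DataFrame, spec: ModelSpec, design: SurveyDesign, **kwargs
) -> SurveyLogisticRegression:
    """Functional wrapper: construct and fit a SurveyLogisticRegression."""
    return SurveyLogisticRegression(spec, design, **kwargs).fit(df)
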