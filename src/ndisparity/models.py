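"""Parametric outcome and mediator models the estimators simulate from.

Three families:

* ``binary_logistic`` — eligibility (access met / not met);
* ``gaussian_log_mediator`` — plan size, Gaussian on the log-dollar scale
  (so simulated plans are log-normal and positive);
* ``gaussian_dollar`` — annualised spending, Gaussian on the dollar scale,
  with an exposure-by-mediator interaction included by default in mediation
  analyses.

Fitting is maximum likelihood via statsmodels formula API; categorical
covariates enter as full dummy sets, with the reference level configurable
per covariate.  Models are always fit within a disability-group stratum,
never pooled with group indicators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from pandas.api.types import is_numeric_dtype

FAMILIES = ("binary_logistic", "gaussian_log_mediator", "gaussian_dollar")


class ModelFitError(RuntimeError):
    pass


class SeparationError(ModelFitError):
    pass


class DegenerateMediatorError(ModelFitError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Declaration of one nuisance model."""

    outcome: str
    family: str
    exposure: str
    confounders: tuple[str, ...] = ()
    mediator: str | None = None
    interaction: bool = True
    references: Mapping[str, str] = field(default_factory=dict)
    formula: str | None = None
    min_stratum_n: int = 50

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")

    def build_formula(self, data: pd.DataFrame, lhs: str) -> str:
        if self.formula is not None:
            return self.formula
        terms = [self.exposure]
        if self.mediator is not None:
            terms.append(self.mediator)
            if self.interaction:
                terms.append(f"{self.exposure}:{self.mediator}")
        for col in self.confounders:
            if col in self.references:
                terms.append(f"C({col}, Treatment('{self.references[col]}'))")
            elif is_numeric_dtype(data[col]):
                terms.append(col)
            else:
                terms.append(f"C({col})")
        return f"{lhs} ~ " + " + ".join(terms)


@dataclass
class FittedModel:
    """A fitted nuisance model plus what simulation needs from it."""

    spec: ModelSpec
    result: object
    n: int
    converged: bool
    sigma: float = math.nan  # residual SD (log scale for the mediator family)

    @property
    def params(self) -> pd.Series:
        return self.result.params

    def predict_linear(self, rows: pd.DataFrame) -> np.ndarray:
        """Linear predictor: log-dollars for the mediator family, dollars or
        log-odds-free probability handled by :meth:`predict_mean`."""
        if self.spec.family == "binary_logistic":
            return np.asarray(self.result.predict(rows, which="linear"))
        return np.asarray(self.result.predict(rows))

    def predict_mean(self, rows: pd.DataFrame) -> np.ndarray:
        """Expected outcome on its natural scale."""
        if self.spec.family == "binary_logistic":
            return np.asarray(self.result.predict(rows))
        eta = np.asarray(self.result.predict(rows))
        if self.spec.family == "gaussian_log_mediator":
            return np.exp(eta + 0.5 * self.sigma**2)
        return eta

    def simulate(
        self, rows: pd.DataFrame, rng: np.random.Generator, n_draws: int = 1
    ) -> np.ndarray:
        """Outcome draws, shape ``(len(rows), n_draws)``.

        Binary: Bernoulli at the predicted probability, via a shared uniform
        grid (so identical rng states across counterfactual arms yield
        coupled, exchangeable noise).  Gaussian families: predicted mean
        plus fitted residual noise, exponentiated for the mediator family.
        """
        n = len(rows)
        if self.spec.family == "binary_logistic":
            p = np.asarray(self.result.predict(rows))[:, None]
            u = rng.random((n, n_draws))
            return (u < p).astype(float)
        eta = np.asarray(self.result.predict(rows))[:, None]
        z = rng.standard_normal((n, n_draws))
        if self.spec.family == "gaussian_log_mediator":
            return np.exp(eta + self.sigma * z)
        return eta + self.sigma * z

    def to_text_dict(self) -> dict:
        """Audit-friendly serialisable summary."""
        return {
            "outcome": self.spec.outcome,
            "family": self.spec.family,
            "n": int(self.n),
            "converged": bool(self.converged),
            "sigma": None if math.isnan(self.sigma) else float(self.sigma),
            "coefficients": {k: float(v) for k, v in self.params.items()},
        }


def _check_terms(data: pd.DataFrame, spec: ModelSpec) -> None:
    needed = [spec.exposure, *spec.confounders]
    if spec.mediator:
        needed.append(spec.mediator)
    missing = [c for c in needed if c not in data.columns]
    if missing:
        raise ModelFitError(f"data is missing model terms: {missing}")
    if len(data) < spec.min_stratum_n:
        raise ModelFitError(
            f"stratum has n={len(data)} < minimum {spec.min_stratum_n}"
        )


def fit_outcome_model(data: pd.DataFrame, spec: ModelSpec) -> FittedModel:
    """Maximum-likelihood fit of the declared outcome family."""
    _check_terms(data, spec)
    if spec.family == "binary_logistic":
        y = data[spec.outcome].astype(float)
        if y.nunique() < 2:
            raise SeparationError(
                f"outcome {spec.outcome!r} is constant in this stratum"
            )
        formula = spec.build_formula(data, spec.outcome)
        try:
            res = smf.glm(formula, data, family=sm.families.Binomial()).fit()
        except Exception as exc:  # statsmodels raises PerfectSeparation etc.
            raise SeparationError(str(exc)) from exc
        if not np.isfinite(res.bse).all() or np.abs(res.params).max() > 30:
            raise SeparationError(
                f"apparent separation fitting {spec.outcome!r} "
                f"(diverging coefficients)"
            )
        return FittedModel(spec=spec, result=res, n=len(data), converged=bool(res.converged))
    if spec.family == "gaussian_dollar":
        formula = spec.build_formula(data, spec.outcome)
        res = smf.ols(formula, data).fit()
        return FittedModel(
            spec=spec,
            result=res,
            n=len(data),
            converged=True,
            sigma=float(np.sqrt(res.mse_resid)),
        )
    raise ValueError(f"fit_outcome_model does not handle family {spec.family!r}")


def fit_mediator_model(data: pd.DataFrame, spec: ModelSpec) -> FittedModel:
    """Gaussian fit of the mediator: on log plan dollars by default, or on
    the identity scale when the family is ``gaussian_dollar`` (useful when
    the generating process is itself linear-Gaussian)."""
    if spec.family not in ("gaussian_log_mediator", "gaussian_dollar"):
        raise ValueError(
            "mediator model family must be gaussian_log_mediator or gaussian_dollar"
        )
    _check_terms(data, spec)
    m = data[spec.outcome].astype(float)
    if float(m.std(ddof=1)) == 0.0 or m.nunique() < 2:
        raise DegenerateMediatorError("mediator has zero variance in this stratum")
    if spec.family == "gaussian_dollar":
        formula = spec.build_formula(data, spec.outcome)
        res = smf.ols(formula, data).fit()
        return FittedModel(
            spec=spec,
            result=res,
            n=len(data),
            converged=True,
            sigma=float(np.sqrt(res.mse_resid)),
        )
    if (m <= 0).any():
        raise DegenerateMediatorError("mediator values must be positive dollars")
    work = data.assign(_log_m=np.log(m))
    formula = spec.build_formula(data, "_log_m")
    res = smf.ols(formula, work).fit()
    return FittedModel(
        spec=spec,
        result=res,
        n=len(data),
        converged=True,
        sigma=float(np.sqrt(res.mse_resid)),
    )


def simulate_from_model(
    model: FittedModel,
    rows: pd.DataFrame,
    rng: np.random.Generator,
    n_draws: int = 1,
) -> np.ndarray:
    """Simulated outcome draws for the given covariate rows."""
    return model.simulate(rows, rng, n_draws=n_draws)
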