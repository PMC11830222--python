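"""Interventional direct/indirect decomposition of spending inequalities.

The estimand comes from a three-arm target trial with plan size as the
mediator:

* arm 1 — comparator exposure, mediator drawn from its own (comparator)
  conditional distribution given confounders;
* arm 2 — exposure group, mediator drawn at the exposure level;
* arm 3 — exposure group, but with the mediator drawn from the
  comparator-level conditional distribution given confounders (a random
  interventional shift of the plan-size distribution).

TCE = mean(arm2) - mean(arm1); the interventional indirect effect
IIE = mean(arm2) - mean(arm3) captures the part of the spending difference
attributable to plan-size allocation; the interventional direct effect is
the remainder, IDE = TCE - IIE.  All arms share mediator and outcome noise
draws, so the additivity TCE = IDE + IIE is exact.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .gcomp import _strata
from .models import (
    FittedModel,
    ModelFitError,
    ModelSpec,
    fit_mediator_model,
    fit_outcome_model,
)
from .types import CausalSpec, Decomposition, EffectEstimate

logger = logging.getLogger(__name__)


def _mediator_coefs(outcome_model: FittedModel, spec: CausalSpec) -> tuple[float, float]:
    params = outcome_model.params
    if spec.mediator not in params.index:
        raise ModelFitError(
            f"outcome model has no mediator term {spec.mediator!r}"
        )
    beta_m = float(params[spec.mediator])
    inter_name = f"{spec.exposure}:{spec.mediator}"
    beta_int = float(params[inter_name]) if inter_name in params.index else 0.0
    return beta_m, beta_int


def simulate_arm(
    outcome_model: FittedModel,
    mediator_model: FittedModel,
    spec: CausalSpec,
    population: pd.DataFrame,
    exposure_setting: int,
    mediator_setting: int,
    n_mc: int,
    seed: int = 0,
    clamp_to_mediator: bool = False,
) -> float:
    """Monte Carlo mean outcome for one trial arm.

    ``exposure_setting`` fixes the exposure in the outcome model;
    ``mediator_setting`` selects which exposure level's conditional mediator
    distribution (given confounders) the plan draws come from.  Mediator and
    outcome noise derive deterministically from ``seed`` alone, so arms
    called with the same seed share draws.
    """
    levels = {spec.comparator_level, spec.exposure_level}
    if exposure_setting not in levels or mediator_setting not in levels:
        raise ValueError(
            f"arm settings must be one of {sorted(levels)}; got "
            f"exposure={exposure_setting}, mediator={mediator_setting}"
        )
    n = len(population)
    seed_key = [int(s) for s in np.atleast_1d(seed)]
    rng_m = np.random.default_rng(seed_key + [0])
    rng_y = np.random.default_rng(seed_key + [1])

    m_rows = population.assign(**{spec.exposure: mediator_setting})
    m_draws = mediator_model.simulate(m_rows, rng_m, n_draws=n_mc)  # (n, n_mc)

    base = population.assign(**{spec.exposure: exposure_setting, spec.mediator: 0.0})
    eta0 = np.asarray(outcome_model.result.predict(base))[:, None]
    beta_m, beta_int = _mediator_coefs(outcome_model, spec)
    slope = beta_m + beta_int * float(exposure_setting)
    mu = eta0 + slope * m_draws
    y = mu + outcome_model.sigma * rng_y.standard_normal((n, n_mc))
    if clamp_to_mediator:
        y = np.minimum(y, m_draws)
    return float(y.mean())


def decompose(
    data: pd.DataFrame,
    spec: CausalSpec,
    n_mc: int = 200,
    seed: int = 0,
    outcome_model: FittedModel | None = None,
    mediator_model: FittedModel | None = None,
    references: dict | None = None,
    interaction: bool = True,
    min_stratum_n: int = 50,
    clamp_to_mediator: bool = False,
    mediator_family: str = "gaussian_log_mediator",
) -> list[Decomposition]:
    """Per-stratum decomposition of the spending TCE into IDE and IIE.

    Fits (or accepts) a Gaussian log-scale mediator model and a Gaussian
    dollar-scale outcome model with an exposure-by-mediator interaction,
    then simulates the three trial arms on the stratum's empirical
    confounder distribution with shared draws.
    """
    if spec.mediator is None:
        raise ValueError("CausalSpec.mediator is required for decomposition")
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    out: list[Decomposition] = []
    for idx, (name, stratum) in enumerate(_strata(data, spec)):
        if len(stratum) == 0 or stratum[spec.exposure].nunique() < 2:
            logger.info("stratum %s not estimable for decomposition", name)
            continue
        try:
            if mediator_model is None:
                med_spec = ModelSpec(
                    outcome=spec.mediator,
                    family=mediator_family,
                    exposure=spec.exposure,
                    confounders=spec.confounders,
                    references=references or {},
                    min_stratum_n=min_stratum_n,
                )
                med = fit_mediator_model(stratum, med_spec)
            else:
                med = mediator_model
            if outcome_model is None:
                out_spec = ModelSpec(
                    outcome=spec.outcome,
                    family="gaussian_dollar",
                    exposure=spec.exposure,
                    confounders=spec.confounders,
                    mediator=spec.mediator,
                    interaction=interaction,
                    references=references or {},
                    min_stratum_n=min_stratum_n,
                )
                ymod = fit_outcome_model(stratum, out_spec)
            else:
                ymod = outcome_model
        except ModelFitError as exc:
            logger.info("stratum %s skipped: %s", name, exc)
            continue

        arm_seed = [seed, idx]
        common = dict(
            outcome_model=ymod,
            mediator_model=med,
            spec=spec,
            population=stratum,
            n_mc=n_mc,
            seed=arm_seed,
            clamp_to_mediator=clamp_to_mediator,
        )
        m1 = simulate_arm(
            exposure_setting=spec.comparator_level,
            mediator_setting=spec.comparator_level,
            **common,
        )
        m2 = simulate_arm(
            exposure_setting=spec.exposure_level,
            mediator_setting=spec.exposure_level,
            **common,
        )
        m3 = simulate_arm(
            exposure_setting=spec.exposure_level,
            mediator_setting=spec.comparator_level,
            **common,
        )
        tce = m2 - m1
        iie = m2 - m3
        ide = tce - iie  # = m3 - m1 under shared draws; additivity exact

        def est(point: float) -> EffectEstimate:
            return EffectEstimate(
                stratum=name,
                point=point,
                scale="dollars",
                comparator_mean=m1,
                n=len(stratum),
                n_mc=n_mc,
                seed=seed,
            )

        out.append(
            Decomposition(
                stratum=name,
                tce=est(tce),
                ide=est(ide),
                iie=est(iie),
                clamped=clamp_to_mediator,
            )
        )
    return out
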