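"""Total causal effects by Monte Carlo simulation-based g-computation.

For each disability-group stratum, an outcome model is fit (or supplied),
the stratum's full empirical confounder distribution — both exposure groups
combined — serves as the standard population, and the exposure is set to
each level in turn.  Simulated outcomes are averaged over ``n_mc`` draws
per row; the contrast of arm means is the total causal effect (TCE),
multiplied by 1000 for binary outcomes reported per 1000 access requests.

The two arms reuse identical generator states, so the exchangeable noise is
shared: swapping comparator and exposure levels negates the estimate
exactly, and Monte Carlo error enters only through the contrast.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .models import FittedModel, ModelFitError, ModelSpec, fit_outcome_model
from .types import CausalSpec, EffectEstimate

logger = logging.getLogger(__name__)


def _infer_family(data: pd.DataFrame, spec: CausalSpec) -> str:
    values = data[spec.outcome].dropna().unique()
    if set(np.asarray(values).tolist()) <= {0, 1, True, False}:
        return "binary_logistic"
    return "gaussian_dollar"


def _model_spec(data: pd.DataFrame, spec: CausalSpec, references=None) -> ModelSpec:
    return ModelSpec(
        outcome=spec.outcome,
        family=_infer_family(data, spec),
        exposure=spec.exposure,
        confounders=spec.confounders,
        references=references or {},
    )


def _strata(data: pd.DataFrame, spec: CausalSpec):
    if spec.stratifier is None or spec.stratifier not in data.columns:
        yield "all", data
        return
    for name in sorted(data[spec.stratifier].dropna().unique()):
        yield str(name), data[data[spec.stratifier] == name]


def _arm_mean(
    model: FittedModel, pop: pd.DataFrame, spec: CausalSpec, level: int, n_mc: int, seed
) -> float:
    rows = pop.assign(**{spec.exposure: level})
    rng = np.random.default_rng(seed)
    draws = model.simulate(rows, rng, n_draws=n_mc)
    return float(draws.mean())


def estimate_tce(
    data: pd.DataFrame,
    spec: CausalSpec,
    n_mc: int = 200,
    seed: int = 0,
    model: FittedModel | None = None,
    references: dict | None = None,
    min_stratum_n: int = 50,
) -> list[EffectEstimate]:
    """Per-stratum total causal effect of the exposure on the outcome.

    Stratum seeds derive from the root seed and the stratum's position in
    sorted order, so strata are independent and runs reproducible.  Strata
    where the fit fails, both exposure levels are not observed, or n falls
    below ``min_stratum_n`` are reported as not estimable.
    """
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    scale_factor = 1000.0 if spec.scale == "per_1000" else 1.0
    out: list[EffectEstimate] = []
    for idx, (name, stratum) in enumerate(_strata(data, spec)):
        not_estimable = EffectEstimate(
            stratum=name,
            point=float("nan"),
            scale=spec.scale,
            n=len(stratum),
            n_mc=n_mc,
            seed=seed,
            estimable=False,
        )
        if len(stratum) == 0:
            logger.info("stratum %s empty; skipped", name)
            out.append(not_estimable)
            continue
        if stratum[spec.exposure].nunique() < 2:
            logger.info("stratum %s has a single exposure level; not estimable", name)
            out.append(not_estimable)
            continue
        if model is None:
            mspec = _model_spec(stratum, spec, references)
            mspec = ModelSpec(
                **{**mspec.__dict__, "min_stratum_n": min_stratum_n}
            )
            if spec.scale == "per_1000" and mspec.family != "binary_logistic":
                raise ValueError("per_1000 scale requires a binary outcome")
            try:
                fitted = fit_outcome_model(stratum, mspec)
            except ModelFitError as exc:
                logger.info("stratum %s skipped: %s", name, exc)
                out.append(not_estimable)
                continue
        else:
            fitted = model
        arm_seed = [seed, idx]
        m_comp = _arm_mean(fitted, stratum, spec, spec.comparator_level, n_mc, arm_seed)
        m_exp = _arm_mean(fitted, stratum, spec, spec.exposure_level, n_mc, arm_seed)
        crude = float(
            stratum.loc[stratum[spec.exposure] == spec.comparator_level, spec.outcome].mean()
        )
        out.append(
            EffectEstimate(
                stratum=name,
                point=(m_exp - m_comp) * scale_factor,
                scale=spec.scale,
                comparator_mean=m_comp * scale_factor,
                comparator_mean_crude=crude * scale_factor,
                n=len(stratum),
                n_mc=n_mc,
                seed=seed,
            )
        )
    return out


def standardize_analytic(
    data: pd.DataFrame,
    spec: CausalSpec,
    model: FittedModel | None = None,
    references: dict | None = None,
    min_stratum_n: int = 50,
) -> list[EffectEstimate]:
    """Deterministic plug-in standardization (no simulation).

    Replaces outcome draws by model-predicted means; the limit of
    :func:`estimate_tce` as ``n_mc`` grows.
    """
    scale_factor = 1000.0 if spec.scale == "per_1000" else 1.0
    out: list[EffectEstimate] = []
    for name, stratum in _strata(data, spec):
        if len(stratum) == 0 or stratum[spec.exposure].nunique() < 2:
            out.append(
                EffectEstimate(
                    stratum=name, point=float("nan"), scale=spec.scale,
                    n=len(stratum), estimable=False,
                )
            )
            continue
        if model is None:
            mspec = _model_spec(stratum, spec, references)
            mspec = ModelSpec(**{**mspec.__dict__, "min_stratum_n": min_stratum_n})
            try:
                fitted = fit_outcome_model(stratum, mspec)
            except ModelFitError as exc:
                logger.info("stratum %s skipped: %s", name, exc)
                out.append(
                    EffectEstimate(
                        stratum=name, point=float("nan"), scale=spec.scale,
                        n=len(stratum), estimable=False,
                    )
                )
                continue
        else:
            fitted = model
        m_comp = float(
            fitted.predict_mean(stratum.assign(**{spec.exposure: spec.comparator_level})).mean()
        )
        m_exp = float(
            fitted.predict_mean(stratum.assign(**{spec.exposure: spec.exposure_level})).mean()
        )
        out.append(
            EffectEstimate(
                stratum=name,
                point=(m_exp - m_comp) * scale_factor,
                scale=spec.scale,
                comparator_mean=m_comp * scale_factor,
                n=len(stratum),
            )
        )
    return out
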