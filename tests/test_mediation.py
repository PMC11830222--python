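"""Interventional mediation: additivity, closed-form linear oracle, sign
grid, arm behaviour."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

import ndisparity as nd
from ndisparity.models import ModelSpec, fit_mediator_model, fit_outcome_model


def _linear_data(make_linear_config, seed, n, **kw):
    cfg = make_linear_config(seed=seed, n_participants=n, **kw)
    return nd.prepare_participants(nd.generate_participants(cfg)), cfg


def test_additivity_exact_under_shared_draws(small_default_participants, linear_spec):
    spec = dataclasses.replace(
        linear_spec,
        confounders=("severity_band", "years_band", "sil", "sda", "prior_support"),
    )
    dec = nd.decompose(small_default_participants, spec, n_mc=100, seed=1)[0]
    assert dec.tce.point - (dec.ide.point + dec.iie.point) == 0.0


def test_no_mediator_path_gives_null_iie(make_linear_config, linear_spec):
    data, cfg = _linear_data(make_linear_config, seed=21, n=20_000, gA=0.0)
    dec = nd.decompose(
        data, linear_spec, n_mc=200, seed=2, mediator_family="gaussian_dollar"
    )[0]
    # IIE ~ slope * gA_hat; gA_hat noise sets the tolerance
    med_spec = ModelSpec(
        outcome="plan_annual",
        family="gaussian_dollar",
        exposure="women_girls",
        confounders=("severity_band",),
    )
    med = fit_mediator_model(data, med_spec)
    tol = 3 * med.result.bse["women_girls"] * abs(0.7)
    assert abs(dec.iie.point) < tol


def test_linear_gaussian_closed_form(make_linear_config, linear_spec):
    gA, sA, bM = -8000.0, -1500.0, 0.7
    data, cfg = _linear_data(make_linear_config, seed=22, n=50_000, gA=gA, sA=sA, bM=bM)
    dec = nd.decompose(
        data, linear_spec, n_mc=300, seed=3, mediator_family="gaussian_dollar"
    )[0]

    ymod = fit_outcome_model(
        data,
        ModelSpec(
            outcome="spend_annual",
            family="gaussian_dollar",
            exposure="women_girls",
            confounders=("severity_band",),
            mediator="plan_annual",
        ),
    )
    med = fit_mediator_model(
        data,
        ModelSpec(
            outcome="plan_annual",
            family="gaussian_dollar",
            exposure="women_girls",
            confounders=("severity_band",),
        ),
    )
    # delta-method SEs for the estimators' sampling noise
    cov = ymod.result.cov_params()
    m_bar = float(data["plan_annual"].mean())
    inter = "women_girls:plan_annual"
    se_ide = math.sqrt(
        cov.loc["women_girls", "women_girls"]
        + m_bar**2 * cov.loc[inter, inter]
        + 2 * m_bar * cov.loc["women_girls", inter]
    )
    se_gA = float(med.result.bse["women_girls"])
    se_iie = abs(bM) * se_gA + abs(gA) * float(ymod.result.bse["plan_annual"])

    assert abs(dec.ide.point - sA) < 3 * se_ide
    assert abs(dec.iie.point - bM * gA) < 3 * se_iie
    assert abs(dec.tce.point - (sA + bM * gA)) < 3 * (se_ide + se_iie)


@pytest.mark.parametrize("s_gA", [-1.0, 1.0])
@pytest.mark.parametrize("s_bM", [-1.0, 1.0])
@pytest.mark.parametrize("s_sA", [-1.0, 1.0])
def test_iie_sign_matches_product_of_coefficients(
    make_linear_config, linear_spec, s_gA, s_bM, s_sA
):
    gA, sA, bM = 12_000.0 * s_gA, 3_000.0 * s_sA, 0.8 * s_bM
    data, _ = _linear_data(make_linear_config, seed=23, n=8_000, gA=gA, sA=sA, bM=bM)
    dec = nd.decompose(
        data, linear_spec, n_mc=150, seed=4, mediator_family="gaussian_dollar"
    )[0]
    assert np.sign(dec.iie.point) == np.sign(bM * gA)


def test_arm3_mean_between_arms_in_monotone_linear_dgp(
    make_linear_config, linear_spec
):
    data, _ = _linear_data(
        make_linear_config, seed=24, n=10_000, gA=10_000.0, sA=4_000.0, bM=0.8
    )
    ymod = fit_outcome_model(
        data,
        ModelSpec(
            outcome="spend_annual",
            family="gaussian_dollar",
            exposure="women_girls",
            confounders=("severity_band",),
            mediator="plan_annual",
        ),
    )
    med = fit_mediator_model(
        data,
        ModelSpec(
            outcome="plan_annual",
            family="gaussian_dollar",
            exposure="women_girls",
            confounders=("severity_band",),
        ),
    )
    kw = dict(
        outcome_model=ymod, mediator_model=med, spec=linear_spec,
        population=data, n_mc=200, seed=6,
    )
    m1 = nd.simulate_arm(exposure_setting=0, mediator_setting=0, **kw)
    m2 = nd.simulate_arm(exposure_setting=1, mediator_setting=1, **kw)
    m3 = nd.simulate_arm(exposure_setting=1, mediator_setting=0, **kw)
    assert m1 < m3 < m2


def test_arm_mc_error_shrinks_with_sqrt_n_mc(make_linear_config, linear_spec):
    data, _ = _linear_data(make_linear_config, seed=25, n=400)
    ymod = fit_outcome_model(
        data,
        ModelSpec(
            outcome="spend_annual", family="gaussian_dollar",
            exposure="women_girls", confounders=("severity_band",),
            mediator="plan_annual",
        ),
    )
    med = fit_mediator_model(
        data,
        ModelSpec(
            outcome="plan_annual", family="gaussian_dollar",
            exposure="women_girls", confounders=("severity_band",),
        ),
    )

    def arm_means(n_mc):
        return [
            nd.simulate_arm(
                outcome_model=ymod, mediator_model=med, spec=linear_spec,
                population=data, exposure_setting=1, mediator_setting=1,
                n_mc=n_mc, seed=100 + r,
            )
            for r in range(20)
        ]

    sd_small = np.std(arm_means(100))
    sd_big = np.std(arm_means(10_000))
    assert sd_big < sd_small / 2


def test_unknown_arm_setting_rejected(make_linear_config, linear_spec):
    data, _ = _linear_data(make_linear_config, seed=26, n=500)
    ymod = fit_outcome_model(
        data,
        ModelSpec(
            outcome="spend_annual", family="gaussian_dollar",
            exposure="women_girls", confounders=("severity_band",),
            mediator="plan_annual",
        ),
    )
    med = fit_mediator_model(
        data,
        ModelSpec(
            outcome="plan_annual", family="gaussian_dollar",
            exposure="women_girls", confounders=("severity_band",),
        ),
    )
    with pytest.raises(ValueError):
        nd.simulate_arm(
            outcome_model=ymod, mediator_model=med, spec=linear_spec,
            population=data, exposure_setting=2, mediator_setting=0, n_mc=10,
        )


def test_missing_mediator_spec_rejected(small_default_participants):
    spec = nd.CausalSpec(
        exposure="women_girls", outcome="spend_annual",
        confounders=("severity_band",), scale="dollars", stratifier=None,
    )
    with pytest.raises(ValueError):
        nd.decompose(small_default_participants, spec, n_mc=10, seed=0)


def test_decomposition_tce_consistent_with_gcomp(small_default_participants):
    """The mediation TCE and the no-mediator g-computation TCE estimate the
    same contrast; they should agree within joint sampling noise."""
    confs = ("severity_band", "years_band", "sil", "sda", "prior_support")
    gspec = nd.CausalSpec(
        exposure="women_girls", outcome="spend_annual", confounders=confs,
        scale="dollars", stratifier=None,
    )
    mspec = dataclasses.replace(gspec, mediator="plan_annual")
    tce_g = nd.estimate_tce(small_default_participants, gspec, n_mc=300, seed=7)[0].point
    tce_m = nd.decompose(small_default_participants, mspec, n_mc=300, seed=7)[0].tce.point
    scale = small_default_participants["spend_annual"].std()
    n = len(small_default_participants)
    assert abs(tce_g - tce_m) < 6 * scale / math.sqrt(n)
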