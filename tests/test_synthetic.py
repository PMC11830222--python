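"""Synthetic-data generator: determinism, null DGPs, moment oracles,
calibration exactness and the DGP-truth oracle."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import ndisparity as nd
from ndisparity.synthetic import (
    ConfigurationError,
    largest_remainder,
    default_mediator_coefs,
    default_spend_coefs,
)
from ndisparity import marginals


def test_seed_reproducibility():
    cfg = nd.SynthConfig(n_applications=2000, n_participants=1500, seed=42)
    pd.testing.assert_frame_equal(
        nd.generate_applications(cfg), nd.generate_applications(cfg)
    )
    pd.testing.assert_frame_equal(
        nd.generate_participants(cfg), nd.generate_participants(cfg)
    )


def test_different_seeds_differ():
    a = nd.generate_applications(nd.SynthConfig(n_applications=2000, seed=1))
    b = nd.generate_applications(nd.SynthConfig(n_applications=2000, seed=2))
    assert not a.equals(b)


def test_null_exposure_effect_on_eligibility():
    """With bA = 0 the empirical eligibility gap is binomial noise."""
    cfg = nd.SynthConfig(n_applications=50_000, seed=7)
    cfg.coef_outcome = dataclasses.replace(cfg.coef_outcome, exposure=0.0)
    apps = nd.generate_applications(cfg)
    decided = apps[apps.decision_type.isin(["access_met", "access_not_met"])]
    decided = nd.derive_exposures(decided)
    decided["eligible"] = (decided.decision_type == "access_met").astype(int)
    g = decided.groupby("women_girls")["eligible"].agg(["mean", "count"])
    diff = g.loc[1, "mean"] - g.loc[0, "mean"]
    p = decided["eligible"].mean()
    se = math.sqrt(p * (1 - p) * (1 / g.loc[0, "count"] + 1 / g.loc[1, "count"]))
    assert abs(diff) < 3 * se


def test_eligibility_rate_matches_integrated_dgp():
    """Empirical eligibility agrees with exact integration of the logistic
    DGP over the finite confounder support (independent oracle)."""
    cfg = nd.SynthConfig(n_applications=100_000, seed=13)
    implied = nd.implied_eligibility_rate(cfg)
    apps = nd.generate_applications(cfg)
    decided = apps[apps.decision_type.isin(["access_met", "access_not_met"])]
    emp = (decided.decision_type == "access_met").mean()
    se = math.sqrt(implied * (1 - implied) / len(decided))
    assert abs(emp - implied) < 3 * se


def test_spend_never_exceeds_plan():
    cfg = nd.SynthConfig(n_participants=20_000, seed=5)
    parts = nd.generate_participants(cfg)
    assert (parts.spend_amount <= parts.plan_amount).all()
    assert (parts.plan_amount > 0).all()


def test_null_mediator_and_spend_effects():
    cfg = nd.SynthConfig(n_participants=40_000, seed=8)
    cfg.coef_mediator = dataclasses.replace(cfg.coef_mediator, exposure=0.0)
    cfg.coef_spend = dataclasses.replace(cfg.coef_spend, exposure=0.0)
    parts = nd.prepare_participants(nd.generate_participants(cfg))
    g = parts.groupby("women_girls")["spend_annual"].agg(["mean", "count", "std"])
    diff = g.loc[1, "mean"] - g.loc[0, "mean"]
    se = math.sqrt(
        g.loc[0, "std"] ** 2 / g.loc[0, "count"] + g.loc[1, "std"] ** 2 / g.loc[1, "count"]
    )
    assert abs(diff) < 3 * se


def test_plan_mean_matches_lognormal_closed_form():
    """Sample mean of annual plan vs E[exp(eta + sigma z)] summed over the
    finite covariate support (closed-form log-normal oracle)."""
    cfg = nd.SynthConfig(n_participants=60_000, seed=9)
    import itertools

    coefs = cfg.coef_mediator
    cols = list(coefs.terms)
    dists = []
    for col in cols:
        spec = coefs.terms[col]
        if isinstance(spec, dict):
            dists.append(list(cfg.confounder_dist[col].items()))
        else:
            dists.append(list(cfg.confounder_dist[col].items()))
    prev = cfg.exposure_prevalence
    expected = 0.0
    for combo in itertools.product(*dists):
        p = 1.0
        eta = coefs.intercept
        for (level, prob), col in zip(combo, cols):
            p *= prob
            spec = coefs.terms[col]
            eta += spec.get(level, 0.0) if isinstance(spec, dict) else spec * level
        for a, pa in ((0, 1 - prev), (1, prev)):
            expected += p * pa * math.exp(eta + coefs.exposure * a + coefs.sigma**2 / 2)

    parts = nd.prepare_participants(nd.generate_participants(cfg))
    emp = parts["plan_annual"].mean()
    se = parts["plan_annual"].std(ddof=1) / math.sqrt(len(parts))
    assert abs(emp - expected) < 3 * se


def test_invalid_configs_rejected():
    cfg = nd.SynthConfig(n_applications=-1)
    with pytest.raises(ConfigurationError):
        cfg.validate()
    cfg = nd.SynthConfig()
    cfg.decision_mix = {k: v * 2 for k, v in cfg.decision_mix.items()}
    with pytest.raises(ConfigurationError):
        cfg.validate()
    cfg = nd.SynthConfig()
    cfg.coef_mediator = dataclasses.replace(default_mediator_coefs(), sigma=-1.0)
    with pytest.raises(ConfigurationError):
        cfg.validate()


@given(
    counts=st.lists(st.integers(min_value=0, max_value=40), min_size=6, max_size=6)
)
def test_calibration_counts_exact(counts):
    from ndisparity.cohort import DECISION_TYPES

    targets = pd.DataFrame({"decision_type": DECISION_TYPES, "count": counts})
    out = nd.calibrate_counts(targets)
    assert len(out) == sum(counts)
    got = out["decision_type"].value_counts().to_dict()
    for dt, c in zip(DECISION_TYPES, counts):
        assert got.get(dt, 0) == c


def test_calibration_zero_targets_empty():
    targets = pd.DataFrame({"decision_type": ["access_met"], "count": [0]})
    assert len(nd.calibrate_counts(targets)) == 0


def test_calibration_negative_counts_error():
    targets = pd.DataFrame({"decision_type": ["access_met"], "count": [-3]})
    with pytest.raises(ConfigurationError):
        nd.calibrate_counts(targets)


def test_calibration_published_flow_row_total():
    tab = nd.calibrate_counts(marginals.results_flow_targets())
    assert len(tab) == marginals.TOTAL_APPLICATIONS
    assert tab["applicant_id"].is_unique


@given(n=st.integers(min_value=0, max_value=500))
def test_largest_remainder_allocates_exactly(n):
    probs = {"a": 0.31, "b": 0.29, "c": 0.25, "d": 0.15}
    alloc = largest_remainder(probs, n)
    assert sum(alloc.values()) == n
    for k, p in probs.items():
        assert abs(alloc[k] - p * n) < 1.0


def test_true_effects_null_config():
    cfg = nd.SynthConfig(seed=3)
    cfg.coef_mediator = dataclasses.replace(cfg.coef_mediator, exposure=0.0)
    cfg.coef_spend = dataclasses.replace(cfg.coef_spend, exposure=0.0)
    dec = nd.true_effects(cfg, n_oracle=150_000, seed=4)
    for est in (dec.tce, dec.ide, dec.iie):
        assert abs(est.point) < 3 * max(est.mc_se, 1e-9)


def test_true_effects_linear_closed_form(make_linear_config):
    gA, sA, bM = -8000.0, -1500.0, 0.7
    cfg = make_linear_config(seed=6, n_participants=1000, gA=gA, sA=sA, bM=bM)
    dec = nd.true_effects(cfg, n_oracle=200_000, seed=6)
    assert abs(dec.ide.point - sA) < 3 * max(dec.ide.mc_se, 1e-9)
    assert abs(dec.iie.point - bM * gA) < 3 * max(dec.iie.mc_se, 1e-9)
    assert abs(dec.tce.point - (sA + bM * gA)) < 3 * max(dec.tce.mc_se, 1e-9)


def test_true_effects_scales_linearly_with_dollar_coefficients(make_linear_config):
    cfg = make_linear_config(seed=12, n_participants=1000)
    doubled = make_linear_config(seed=12, n_participants=1000)
    doubled.coef_spend = nd.CoefSet(
        intercept=2 * cfg.coef_spend.intercept,
        exposure=2 * cfg.coef_spend.exposure,
        terms={
            k: ({kk: 2 * vv for kk, vv in v.items()} if isinstance(v, dict) else 2 * v)
            for k, v in cfg.coef_spend.terms.items()
        },
        sigma=cfg.coef_spend.sigma,
    )
    base = nd.true_effects(cfg, n_oracle=50_000, seed=12)
    twice = nd.true_effects(doubled, n_oracle=50_000, seed=12)
    assert twice.tce.point == pytest.approx(2 * base.tce.point, rel=1e-9)


def test_true_effects_small_oracle_warns():
    with pytest.warns(UserWarning):
        nd.true_effects(nd.SynthConfig(seed=1), n_oracle=500, seed=1)


def test_calibrated_participant_group_sizes():
    cfg = nd.SynthConfig(seed=11)
    parts = nd.generate_participants(cfg, group_sizes={0: 300, 1: 200})
    flags = nd.derive_exposures(parts)["women_girls"]
    assert len(parts) == 500
    assert flags.sum() == 200


def test_unmeasured_confounding_switch_biases_naive_contrast():
    """The optional shared latent term induces spurious spending differences
    even with all exposure coefficients at zero."""
    base = nd.SynthConfig(n_participants=40_000, seed=17)
    base.coef_mediator = dataclasses.replace(base.coef_mediator, exposure=0.0)
    base.coef_spend = dataclasses.replace(default_spend_coefs(), exposure=0.0)
    confounded = dataclasses.replace(base)
    confounded.unmeasured_strength = 0.8
    parts = nd.prepare_participants(nd.generate_participants(confounded))
    g = parts.groupby("women_girls")["spend_annual"].agg(["mean", "count", "std"])
    diff = g.loc[1, "mean"] - g.loc[0, "mean"]
    se = math.sqrt(
        g.loc[0, "std"] ** 2 / g.loc[0, "count"] + g.loc[1, "std"] ** 2 / g.loc[1, "count"]
    )
    assert diff > 3 * se
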