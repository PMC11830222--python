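"""Repeated-simulation studies of the estimators' statistical properties.

These run many synthetic replicates against the generator's known truth:

* parameter recovery — does the mean estimate over replicates recover the
  DGP-true TCE/IDE/IIE (and the eligibility TCE) with small bias?
* bootstrap coverage — does the 95% percentile interval cover the true
  effect at its nominal rate?

All replicate seeds derive from a single root seed via
``numpy.random.SeedSequence`` so runs are reproducible end to end.
"""

from __future__ import annotations

import numpy as np

from .cohort import (
    filter_eligibility_cohort,
    prepare_applications,
    prepare_participants,
)
from .gcomp import estimate_tce
from .inference import bootstrap_ci
from .mediation import decompose
from .synthetic import (
    CoefSet,
    SynthConfig,
    generate_applications,
    generate_participants,
    true_eligibility_effect,
)
from .types import BootstrapConfig, CausalSpec

LINEAR_SPEC = CausalSpec(
    exposure="women_girls",
    outcome="spend_annual",
    confounders=("severity_band",),
    mediator="plan_annual",
    scale="dollars",
    stratifier=None,
)


def linear_gaussian_config(
    seed: int,
    n_participants: int,
    gA: float = -8000.0,
    sA: float = -1500.0,
    bM: float = 0.7,
) -> SynthConfig:
    """Identity-link Gaussian DGP with a closed-form decomposition:
    IDE = sA (direct effect), IIE = bM * gA (mediated), TCE = sA + bM * gA."""
    mediator = CoefSet(
        intercept=90_000.0,
        exposure=gA,
        terms={"severity_band": {"6-10": 15_000.0, "11-15": 30_000.0}},
        sigma=20_000.0,
    )
    spend = CoefSet(
        intercept=5_000.0,
        exposure=sA,
        terms={
            "plan_annual": bM,
            "severity_band": {"6-10": 1_000.0, "11-15": 3_000.0},
        },
        sigma=8_000.0,
    )
    return SynthConfig(
        n_participants=n_participants,
        seed=seed,
        exposure_prevalence=0.5,
        coef_mediator=mediator,
        mediator_family="gaussian",
        coef_spend=spend,
        spend_family="gaussian",
    )


def _child_seed(root: int, index: int) -> int:
    return int(np.random.SeedSequence([root, index]).generate_state(1)[0] % (2**31))


def spend_recovery_study(
    n_reps: int = 200,
    n: int = 20_000,
    seed: int = 0,
    n_mc: int = 50,
    gA: float = -8000.0,
    sA: float = -1500.0,
    bM: float = 0.7,
) -> dict:
    """Mean decomposition estimates over replicates vs the DGP truth."""
    truth = {"tce": sA + bM * gA, "ide": sA, "iie": bM * gA}
    draws: dict[str, list[float]] = {k: [] for k in truth}
    for r in range(n_reps):
        rep = _child_seed(seed, r)
        cfg = linear_gaussian_config(seed=rep, n_participants=n, gA=gA, sA=sA, bM=bM)
        data = prepare_participants(generate_participants(cfg))
        dec = decompose(
            data, LINEAR_SPEC, n_mc=n_mc, seed=rep, mediator_family="gaussian_dollar"
        )[0]
        draws["tce"].append(dec.tce.point)
        draws["ide"].append(dec.ide.point)
        draws["iie"].append(dec.iie.point)
    out = {}
    for key, true_val in truth.items():
        arr = np.asarray(draws[key])
        out[key] = {
            "truth": true_val,
            "mean_estimate": float(arr.mean()),
            "bias": float(arr.mean() - true_val),
            "bias_pct_of_truth": float(100.0 * (arr.mean() - true_val) / true_val),
            "mc_se_of_mean": float(arr.std(ddof=1) / np.sqrt(len(arr))),
        }
    out["n_reps"] = n_reps
    out["n"] = n
    return out


def eligibility_recovery_study(
    n_reps: int = 200, n: int = 20_000, seed: int = 0, n_mc: int = 50
) -> dict:
    """Mean eligibility-TCE estimate over replicates vs exact DGP integration."""
    spec = CausalSpec(
        exposure="women_girls",
        outcome="eligible",
        confounders=("prior_support", "disability_group"),
        scale="per_1000",
        stratifier=None,
    )
    base = SynthConfig(n_applications=n, seed=0)
    truth = true_eligibility_effect(base)
    points = []
    for r in range(n_reps):
        rep = _child_seed(seed, 10_000 + r)
        cfg = SynthConfig(n_applications=n, seed=rep)
        kept, _ = filter_eligibility_cohort(generate_applications(cfg))
        data = prepare_applications(kept)
        points.append(estimate_tce(data, spec, n_mc=n_mc, seed=rep)[0].point)
    arr = np.asarray(points)
    return {
        "truth": truth,
        "mean_estimate": float(arr.mean()),
        "bias": float(arr.mean() - truth),
        "bias_pct_of_truth": float(100.0 * (arr.mean() - truth) / truth),
        "mc_se_of_mean": float(arr.std(ddof=1) / np.sqrt(len(arr))),
        "n_reps": n_reps,
        "n": n,
    }


def coverage_study(
    n_datasets: int = 200,
    n: int = 1_200,
    n_boot: int = 100,
    n_mc: int = 40,
    seed: int = 0,
    gA: float = -8000.0,
    sA: float = -1500.0,
    bM: float = 0.7,
) -> dict:
    """Fraction of simulated datasets whose 95% bootstrap CI covers the
    true spending TCE."""
    truth = sA + bM * gA
    spec = CausalSpec(
        exposure="women_girls",
        outcome="spend_annual",
        confounders=("severity_band",),
        scale="dollars",
        stratifier=None,
    )
    covered = 0
    for d in range(n_datasets):
        rep = _child_seed(seed, 20_000 + d)
        cfg = linear_gaussian_config(seed=rep, n_participants=n, gA=gA, sA=sA, bM=bM)
        data = prepare_participants(generate_participants(cfg))

        def point(df, s, _spec=spec):
            return estimate_tce(df, _spec, n_mc=n_mc, seed=s)[0].point

        res = bootstrap_ci(point, data, BootstrapConfig(n_boot=n_boot, seed=rep))
        if res.ci_low <= truth <= res.ci_high:
            covered += 1
    return {
        "truth": truth,
        "coverage": covered / n_datasets,
        "n_covered": covered,
        "n_datasets": n_datasets,
        "n": n,
        "n_boot": n_boot,
    }
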