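"""Configuration-driven pipeline tying the stages together.

Two analyses:

* ``eligibility`` — TCE of each exposure on being deemed eligible, per 1000
  access requests, adjusted for prior source of disability support, per
  disability group;
* ``plan_spend`` — TCE on annualised plan size, and TCE/IDE/IIE on
  annualised spending with plan size as mediator, adjusted for age band,
  remoteness, severity, years in scheme, accommodation-program flags and
  prior support, per disability group.

Age-related inequality is examined only for eligibility (support needs rise
with age, so an age contrast on plan size or spending is not a pure
inequality); requesting it for ``plan_spend`` is a validation error before
any computation.  Output cells from strata smaller than the suppression
threshold (15) are masked after estimation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cohort, gcomp, mediation, synthetic
from .inference import bootstrap_ci
from .types import BootstrapConfig, CausalSpec

logger = logging.getLogger(__name__)

ELIGIBILITY_CONFOUNDERS = ("prior_support",)
PLAN_SPEND_CONFOUNDERS = (
    "age_band",
    "remoteness",
    "severity_band",
    "years_band",
    "ypirac",
    "sil",
    "sda",
    "trial_plan",
    "prior_support",
)

ANALYSES = ("eligibility", "plan_spend", "both")
EXPOSURES = ("women_girls", "low_ses", "age_55plus")
SUPPRESSION_THRESHOLD = 15


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    synth: synthetic.SynthConfig = field(default_factory=synthetic.SynthConfig)
    applications_path: str | None = None
    participants_path: str | None = None
    analysis: str = "both"
    exposures: tuple[str, ...] = ("women_girls", "low_ses", "age_55plus")
    n_mc: int = 200
    boot: BootstrapConfig = field(default_factory=BootstrapConfig)
    seed: int = 0
    output_dir: str = "results"
    suppress_threshold: int = SUPPRESSION_THRESHOLD
    min_stratum_n: int = 50
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.analysis not in ANALYSES:
            raise ConfigError(f"analysis must be one of {ANALYSES}")
        for exp in self.exposures:
            if exp not in EXPOSURES:
                raise ConfigError(f"unknown exposure {exp!r}")
        if self.analysis in ("plan_spend", "both") and "age_55plus" in self.exposures:
            if self.analysis == "plan_spend":
                raise ConfigError(
                    "age_55plus is an eligibility-only exposure: age-related "
                    "inequality is not assessed for plan allocation or spending"
                )
        if self.n_mc < 1:
            raise ConfigError("n_mc must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        synth_raw = raw.pop("synth", {})
        for key in ("coef_outcome", "coef_mediator", "coef_spend"):
            if key in synth_raw:
                synth_raw[key] = synthetic.CoefSet(**synth_raw[key])
        boot_raw = raw.pop("boot", {})
        cfg = cls(
            synth=synthetic.SynthConfig(**synth_raw),
            boot=BootstrapConfig(**boot_raw),
            **raw,
        )
        if "exposures" in raw or isinstance(cfg.exposures, list):
            cfg.exposures = tuple(cfg.exposures)
        return cfg

    def to_dict(self) -> dict:
        def clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {str(k): clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, pd.DataFrame):
                return obj.to_dict(orient="records")
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj

        return clean(self)


def _exposure_eligibility_tables(config: RunConfig):
    apps = (
        pd.read_csv(config.applications_path, parse_dates=["decision_date"])
        if config.applications_path
        else synthetic.generate_applications(config.synth)
    )
    analytic, log = cohort.filter_eligibility_cohort(apps)
    return cohort.prepare_applications(analytic), log


def _participant_tables(config: RunConfig):
    parts = (
        pd.read_csv(config.participants_path, parse_dates=["plan_start"])
        if config.participants_path
        else synthetic.generate_participants(config.synth)
    )
    analytic, log = cohort.filter_participant_cohort(parts, config.synth.cutoff_date)
    return cohort.prepare_participants(analytic), log


def _ci_for_stratum(config, data, spec, point_fn, n_out: int):
    """End-to-end refit bootstrap for a single stratum; vector estimators ok."""
    result = bootstrap_ci(
        point_fn,
        data,
        BootstrapConfig(
            n_boot=config.boot.n_boot,
            seed=config.boot.seed,
            stratified=False,
            max_failure_rate=config.boot.max_failure_rate,
        ),
        stratify=None,
    )
    low = np.atleast_1d(result.ci_low)
    high = np.atleast_1d(result.ci_high)
    return low[:n_out], high[:n_out]


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured analyses; returns result tables and exclusion logs."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    results: dict = {"metadata": _metadata(config)}

    if config.analysis in ("eligibility", "both"):
        apps, app_log = _exposure_eligibility_tables(config)
        results["exclusions_applications"] = app_log
        rows = []
        for exposure in config.exposures:
            spec = CausalSpec(
                exposure=exposure,
                outcome="eligible",
                confounders=ELIGIBILITY_CONFOUNDERS,
                scale="per_1000",
            )
            estimates = gcomp.estimate_tce(
                apps, spec, n_mc=config.n_mc, seed=config.seed,
                min_stratum_n=config.min_stratum_n,
            )
            for est in estimates:
                ci_low = ci_high = np.nan
                if est.estimable and config.boot.n_boot >= 2:
                    stratum_data = apps[apps[spec.stratifier] == est.stratum]
                    sub_spec = dataclasses.replace(spec, stratifier=None)

                    def point(df, seed, _s=sub_spec):
                        return gcomp.estimate_tce(
                            df, _s, n_mc=config.n_mc, seed=seed,
                            min_stratum_n=config.min_stratum_n,
                        )[0].point

                    (ci_low,), (ci_high,) = _ci_for_stratum(
                        config, stratum_data, sub_spec, point, 1
                    )
                rows.append(
                    {
                        "exposure": exposure,
                        "stratum": est.stratum,
                        "n": est.n,
                        "comparator_rate_crude": est.comparator_mean_crude,
                        "comparator_rate_std": est.comparator_mean,
                        "difference_per_1000": est.point,
                        "ci_low": ci_low,
                        "ci_high": ci_high,
                        "n_mc": config.n_mc,
                        "n_boot": config.boot.n_boot,
                        "seed": config.seed,
                    }
                )
        results["eligibility"] = pd.DataFrame(rows)

    if config.analysis in ("plan_spend", "both"):
        parts, part_log = _participant_tables(config)
        results["exclusions_participants"] = part_log
        rows = []
        exposures = [e for e in config.exposures if e != "age_55plus"]
        for exposure in exposures:
            plan_spec = CausalSpec(
                exposure=exposure,
                outcome="plan_annual",
                confounders=PLAN_SPEND_CONFOUNDERS,
                scale="dollars",
            )
            for est in gcomp.estimate_tce(
                parts, plan_spec, n_mc=config.n_mc, seed=config.seed,
                min_stratum_n=config.min_stratum_n,
            ):
                ci_low = ci_high = np.nan
                if est.estimable and config.boot.n_boot >= 2:
                    stratum_data = parts[parts[plan_spec.stratifier] == est.stratum]
                    sub_spec = dataclasses.replace(plan_spec, stratifier=None)

                    def point(df, seed, _s=sub_spec):
                        return gcomp.estimate_tce(
                            df, _s, n_mc=config.n_mc, seed=seed,
                            min_stratum_n=config.min_stratum_n,
                        )[0].point

                    (ci_low,), (ci_high,) = _ci_for_stratum(
                        config, stratum_data, sub_spec, point, 1
                    )
                rows.append(
                    {
                        "exposure": exposure,
                        "outcome": "plan",
                        "effect": "tce",
                        "stratum": est.stratum,
                        "n": est.n,
                        "comparator_mean": est.comparator_mean,
                        "point": est.point,
                        "ci_low": ci_low,
                        "ci_high": ci_high,
                    }
                )

            spend_spec = CausalSpec(
                exposure=exposure,
                outcome="spend_annual",
                confounders=PLAN_SPEND_CONFOUNDERS,
                mediator="plan_annual",
                scale="dollars",
            )
            for dec in mediation.decompose(
                parts, spend_spec, n_mc=config.n_mc, seed=config.seed,
                min_stratum_n=config.min_stratum_n,
            ):
                cis = {k: (np.nan, np.nan) for k in ("tce", "ide", "iie")}
                if config.boot.n_boot >= 2:
                    stratum_data = parts[parts[spend_spec.stratifier] == dec.stratum]
                    sub_spec = dataclasses.replace(spend_spec, stratifier=None)

                    def triple(df, seed, _s=sub_spec):
                        d = mediation.decompose(
                            df, _s, n_mc=config.n_mc, seed=seed,
                            min_stratum_n=config.min_stratum_n,
                        )[0]
                        return np.array([d.tce.point, d.ide.point, d.iie.point])

                    low, high = _ci_for_stratum(
                        config, stratum_data, sub_spec, triple, 3
                    )
                    cis = {
                        "tce": (low[0], high[0]),
                        "ide": (low[1], high[1]),
                        "iie": (low[2], high[2]),
                    }
                for effect in ("tce", "iie", "ide"):
                    est = getattr(dec, effect)
                    rows.append(
                        {
                            "exposure": exposure,
                            "outcome": "spend",
                            "effect": effect,
                            "stratum": dec.stratum,
                            "n": est.n,
                            "comparator_mean": est.comparator_mean,
                            "point": est.point,
                            "ci_low": cis[effect][0],
                            "ci_high": cis[effect][1],
                        }
                    )
        results["plan_spend"] = pd.DataFrame(rows)

    return results


def _metadata(config: RunConfig) -> dict:
    echo = config.to_dict()
    echo.pop("output_dir", None)  # incidental to the estimates
    digest = hashlib.sha256(
        json.dumps(echo, sort_keys=True, default=str).encode()
    ).hexdigest()
    return {
        "package": "ndisparity",
        "version": __version__,
        "seed": config.seed,
        "config": echo,
        "config_sha256": digest,
        "suppress_threshold": config.suppress_threshold,
    }


def _suppress(table: pd.DataFrame, threshold: int) -> pd.DataFrame:
    out = table.copy()
    mask = out["n"] < threshold
    value_cols = [
        c
        for c in out.columns
        if c not in ("exposure", "outcome", "effect", "stratum", "n", "n_mc", "n_boot", "seed")
    ]
    out.loc[mask, value_cols] = np.nan
    out["suppressed"] = mask
    return out


def write_results(results: dict, directory) -> list[Path]:
    """Write result tables, exclusion logs and run metadata; idempotent.

    Small-cell suppression (stratum n below the threshold) is applied here,
    after estimation, never before.
    """
    tables = {k: v for k, v in results.items() if isinstance(v, pd.DataFrame)}
    if not tables:
        raise ValueError("results contain no tables; nothing to write")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    threshold = results.get("metadata", {}).get(
        "suppress_threshold", SUPPRESSION_THRESHOLD
    )
    written = []
    for name, table in sorted(tables.items()):
        path = directory / f"{name}.csv"
        _suppress(table, threshold).to_csv(path, index=False, float_format="%.6f")
        written.append(path)
    for name in ("exclusions_applications", "exclusions_participants"):
        if name in results:
            log = results[name]
            path = directory / f"{name}_log.csv"
            log.to_frame().to_csv(path, index=False)
            (directory / f"{name}_log.txt").write_text(str(log) + "\n")
            written.append(path)
    if "metadata" in results:
        path = directory / "run_metadata.json"
        path.write_text(
            json.dumps(results["metadata"], indent=2, sort_keys=True, default=str) + "\n"
        )
        written.append(path)
    return written
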