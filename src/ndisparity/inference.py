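"""Nonparametric bootstrap confidence intervals.

Records are resampled with replacement (within disability-group stratum
when requested); the supplied estimator — any data-to-estimate callable
from the g-computation or mediation stages — is re-run end to end on every
replicate, so the interval reflects nuisance-model estimation uncertainty
as well as sampling noise.  Intervals are percentile (2.5th/97.5th),
replicate seeds derive from the root seed, and estimators may be
vector-valued (e.g. a TCE/IDE/IIE triple) in which case bounds are
per-component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import BootstrapConfig


class BootstrapError(RuntimeError):
    pass


@dataclass
class BootstrapResult:
    ci_low: np.ndarray | float
    ci_high: np.ndarray | float
    replicates: np.ndarray
    n_failed: int


def _resample(
    data: pd.DataFrame, rng: np.random.Generator, stratify: str | None
) -> pd.DataFrame:
    if stratify is None or stratify not in data.columns:
        idx = rng.integers(0, len(data), size=len(data))
        return data.iloc[idx].reset_index(drop=True)
    pieces = []
    for _, grp in data.groupby(stratify, sort=True):
        idx = rng.integers(0, len(grp), size=len(grp))
        pieces.append(grp.iloc[idx])
    return pd.concat(pieces, ignore_index=True)


def bootstrap_ci(
    estimator,
    data: pd.DataFrame,
    config: BootstrapConfig,
    stratify: str | None = None,
) -> BootstrapResult:
    """Percentile bootstrap around ``estimator(data, seed)``.

    Replicates where the estimator raises are dropped and counted; if more
    than ``config.max_failure_rate`` of replicates fail the whole bootstrap
    errors out with the tally.
    """
    if len(data) == 0:
        raise ValueError("data must be non-empty")
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_boot)
    reps = []
    failures = 0
    errors: list[str] = []
    for child in children:
        rng = np.random.default_rng(child)
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        sample = _resample(data, rng, stratify)
        try:
            reps.append(np.asarray(estimator(sample, rep_seed), dtype=float))
        except Exception as exc:  # noqa: BLE001 - tallied, rethrown if frequent
            failures += 1
            if len(errors) < 3:
                errors.append(str(exc))
    if failures > config.max_failure_rate * config.n_boot:
        raise BootstrapError(
            f"{failures}/{config.n_boot} bootstrap replicates failed "
            f"(first errors: {errors})"
        )
    arr = np.vstack(reps)
    low, high = np.percentile(arr, [2.5, 97.5], axis=0)
    if arr.shape[1] == 1:
        return BootstrapResult(float(low[0]), float(high[0]), arr[:, 0], failures)
    return BootstrapResult(low, high, arr, failures)
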