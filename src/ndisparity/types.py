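"""Core value types shared across the pipeline.

The analysis estimates inequalities between an exposure group (women and
girls, residents of socio-economically disadvantaged areas, or people aged
55+) and its comparator, within broad disability groups.  Estimates are
reported either per 1000 access requests (binary eligibility outcome) or in
annualised dollars (plan size and spending outcomes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace  # noqa: F401  (replace re-exported for callers)

SCALES = ("per_1000", "dollars")


@dataclass(frozen=True)
class CausalSpec:
    """Declaration of a causal contrast.

    Parameters
    ----------
    exposure
        Name of the binary (0/1) exposure column, e.g. ``"women_girls"``.
    outcome
        Outcome column: ``"eligible"`` (binary) or an annualised dollar
        column such as ``"plan_annual"`` / ``"spend_annual"``.
    confounders
        Covariates the outcome (and mediator) models adjust for.
    mediator
        Optional continuous mediator column (plan size) for the
        interventional direct/indirect decomposition.
    scale
        ``"per_1000"`` (binary outcomes only) or ``"dollars"``.
    stratifier
        Column defining analysis strata (broad disability group); ``None``
        pools everything into a single stratum.
    """

    exposure: str
    outcome: str
    confounders: tuple[str, ...] = ()
    mediator: str | None = None
    scale: str = "dollars"
    stratifier: str | None = "disability_group"
    comparator_level: int = 0
    exposure_level: int = 1

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"scale must be one of {SCALES}, got {self.scale!r}")
        if self.comparator_level == self.exposure_level:
            raise ValueError("comparator_level and exposure_level must differ")


@dataclass
class EffectEstimate:
    """A point estimate with optional 95% CI and Monte Carlo metadata."""

    stratum: str
    point: float
    scale: str
    ci_low: float = math.nan
    ci_high: float = math.nan
    comparator_mean: float = math.nan
    comparator_mean_crude: float = math.nan
    n: int = 0
    n_mc: int = 0
    n_boot: int = 0
    seed: int | None = None
    mc_se: float = math.nan
    estimable: bool = True

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"scale must be one of {SCALES}, got {self.scale!r}")
        if not (math.isnan(self.ci_low) or math.isnan(self.ci_high)):
            if not (self.ci_low <= self.point <= self.ci_high):
                raise ValueError(
                    f"CI [{self.ci_low}, {self.ci_high}] does not bracket "
                    f"point {self.point} (stratum {self.stratum})"
                )
        if self.scale == "per_1000" and self.estimable and not math.isnan(self.point):
            if abs(self.point) > 1000 + 1e-9:
                raise ValueError("per_1000 effects must lie in [-1000, 1000]")


@dataclass
class Decomposition:
    """Total causal effect split into interventional direct and indirect parts.

    With shared Monte Carlo draws the identity ``tce = ide + iie`` holds
    exactly: the direct effect is defined as total minus indirect.
    """

    stratum: str
    tce: EffectEstimate
    ide: EffectEstimate
    iie: EffectEstimate
    clamped: bool = False

    def __post_init__(self) -> None:
        scales = {self.tce.scale, self.ide.scale, self.iie.scale}
        if len(scales) != 1:
            raise ValueError("tce/ide/iie must share a scale")
        strata = {self.tce.stratum, self.ide.stratum, self.iie.stratum}
        if strata != {self.stratum}:
            raise ValueError("tce/ide/iie must share the decomposition's stratum")
        gap = self.tce.point - (self.ide.point + self.iie.point)
        if not math.isnan(gap) and abs(gap) > 1e-8 * max(1.0, abs(self.tce.point)):
            raise ValueError(f"additivity violated: tce - (ide + iie) = {gap}")


@dataclass(frozen=True)
class ExclusionStep:
    name: str
    n_removed: int
    n_remaining: int


@dataclass
class ExclusionLog:
    """Audit trail of cohort filters: one line per rule, conservation checked."""

    n_input: int
    steps: list[ExclusionStep] = field(default_factory=list)

    def record(self, name: str, n_removed: int, n_remaining: int) -> None:
        if n_removed < 0 or n_remaining < 0:
            raise ValueError("exclusion counts must be non-negative")
        prev = self.steps[-1].n_remaining if self.steps else self.n_input
        if n_remaining != prev - n_removed:
            raise ValueError(
                f"step {name!r}: {prev} - {n_removed} != {n_remaining}"
            )
        self.steps.append(ExclusionStep(name, int(n_removed), int(n_remaining)))

    @property
    def n_final(self) -> int:
        return self.steps[-1].n_remaining if self.steps else self.n_input

    @property
    def total_removed(self) -> int:
        return sum(s.n_removed for s in self.steps)

    def removed(self, name: str) -> int:
        for s in self.steps:
            if s.name == name:
                return s.n_removed
        raise KeyError(name)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [(s.name, s.n_removed, s.n_remaining) for s in self.steps],
            columns=["filter", "n_removed", "n_remaining"],
        )

    def __str__(self) -> str:
        lines = [f"input: {self.n_input}"]
        for s in self.steps:
            lines.append(f"  - {s.name}: removed {s.n_removed}, remaining {s.n_remaining}")
        return "\n".join(lines)


@dataclass(frozen=True)
class BootstrapConfig:
    """Nonparametric percentile bootstrap settings."""

    n_boot: int = 200
    method: str = "percentile"
    seed: int = 0
    stratified: bool = True
    max_failure_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.n_boot < 2:
            raise ValueError("n_boot must be >= 2")
        if self.method != "percentile":
            raise ValueError("only the percentile method is implemented")
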