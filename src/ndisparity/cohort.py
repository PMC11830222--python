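"""Cohort construction: inclusion/exclusion rules, disability-group mapping,
exposure derivation and annualisation of dollar amounts.

The eligibility cohort keeps each applicant's most recent decided access
request (access met / access not met) with complete socio-demographics, aged
7 years or older.  The plan/spending cohort keeps each active participant's
most recent completed plan providing more than 180 days' support.  Every
filter writes one line into an :class:`~ndisparity.types.ExclusionLog` so
the flow is auditable against published exclusion counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import ExclusionLog

DAYS_PER_YEAR = 365.25

DECISION_TYPES = (
    "access_met",
    "access_not_met",
    "withdrawn",
    "cancelled",
    "in_progress",
    "revoked_ceased",
)

DISABILITY_GROUPS = (
    "sensory",
    "autism",
    "intellectual_other",
    "physical",
    "psychosocial",
    "brain_injury_stroke",
    "other",
)

# Primary disability codes -> the seven broad survey disability groups.
DISABILITY_GROUP_MAP: dict[str, str] = {
    "visual_impairment": "sensory",
    "hearing_impairment": "sensory",
    "other_sensory_speech": "sensory",
    "autism": "autism",
    "intellectual_disability": "intellectual_other",
    "trisomy_21": "intellectual_other",
    "developmental_delay": "intellectual_other",
    "global_developmental_delay": "intellectual_other",
    "cerebral_palsy": "physical",
    "spinal_cord_injury": "physical",
    "other_physical": "physical",
    "psychosocial": "psychosocial",
    "acquired_brain_injury": "brain_injury_stroke",
    "stroke": "brain_injury_stroke",
    "other": "other",
    "multiple_sclerosis": "other",
    "other_neurological": "other",
}


class UnknownDisabilityCode(ValueError):
    pass


def map_disability_group(code: str) -> str:
    """Map a primary disability code to its broad analysis group."""
    try:
        return DISABILITY_GROUP_MAP[code]
    except KeyError:
        raise UnknownDisabilityCode(
            f"unknown primary disability code: {code!r}"
        ) from None


def map_disability_groups(codes: pd.Series) -> pd.Series:
    """Vectorised group mapping; raises on any unknown code."""
    mapped = codes.map(DISABILITY_GROUP_MAP)
    if mapped.isna().any():
        bad = sorted(codes[mapped.isna()].unique().tolist())
        raise UnknownDisabilityCode(f"unknown primary disability codes: {bad}")
    return mapped


def derive_exposures(data: pd.DataFrame) -> pd.DataFrame:
    """Attach the three binary exposure flags.

    ``low_ses`` marks the three lowest IRSD deciles, ``age_55plus`` age at
    the eligibility decision (or plan start) of 55 years or older, and
    ``women_girls`` self-reported gender.
    """
    out = data.copy()
    out["women_girls"] = (out["gender"] == "women_girls").astype(int)
    out["low_ses"] = (out["irsd_decile"] <= 3).astype(int)
    age_col = "age_at_decision" if "age_at_decision" in out.columns else "age_at_plan_start"
    out["age_55plus"] = (out[age_col] >= 55).astype(int)
    return out


def annualize(amount, plan_days):
    """Convert a plan-period dollar amount to dollars per year (365.25 days)."""
    days = np.asarray(plan_days, dtype=float)
    if np.any(days <= 0):
        raise ValueError("plan_days must be positive")
    result = np.asarray(amount, dtype=float) * DAYS_PER_YEAR / days
    if result.ndim == 0:
        return float(result)
    return result


def filter_eligibility_cohort(
    applications: pd.DataFrame,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the eligibility-analysis inclusion rules, in order.

    Keeps: age >= 7; the most recent access request per applicant (latest
    decision date, ties broken by row order); decided requests only; and
    complete socio-demographic information.  The decided-only rule is logged
    as three lines (cancelled/withdrawn, in progress, revoked/ceased) so the
    log is comparable with published flow counts.
    """
    log = ExclusionLog(n_input=len(applications))
    df = applications

    keep = df["age_at_decision"] >= 7
    log.record("age_under_7", int((~keep).sum()), int(keep.sum()))
    df = df[keep]

    if len(df):
        order = df.assign(_seq=np.arange(len(df))).sort_values(
            ["decision_date", "_seq"], na_position="first", kind="stable"
        )
        latest_idx = order.groupby("applicant_id", sort=False).tail(1).index
        kept = df.index.isin(latest_idx)
    else:
        kept = np.zeros(0, dtype=bool)
    log.record("not_most_recent_request", int((~kept).sum()), int(kept.sum()))
    df = df[kept]

    missing = df["decision_type"].isna()
    log.record("missing_decision_type", int(missing.sum()), int((~missing).sum()))
    df = df[~missing]

    cw = df["decision_type"].isin(["cancelled", "withdrawn"])
    log.record("cancelled_or_withdrawn", int(cw.sum()), int((~cw).sum()))
    df = df[~cw]

    ip = df["decision_type"] == "in_progress"
    log.record("in_progress", int(ip.sum()), int((~ip).sum()))
    df = df[~ip]

    rc = df["decision_type"] == "revoked_ceased"
    log.record("revoked_or_ceased", int(rc.sum()), int((~rc).sum()))
    df = df[~rc]

    inc = ~df["demographics_complete"].astype(bool)
    log.record("incomplete_demographics", int(inc.sum()), int((~inc).sum()))
    df = df[~inc]

    df = df.copy()
    df["eligible"] = (df["decision_type"] == "access_met").astype(int)
    return df, log


def filter_participant_cohort(
    participants: pd.DataFrame,
    cutoff_date,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the plan/spending-analysis inclusion rules.

    Keeps, in order: age >= 7 at plan start; plans completed by the cutoff
    date; plans providing strictly more than 180 days' support; and the most
    recent such plan per participant.
    """
    if (participants["plan_days"] <= 0).any():
        raise ValueError("plan_days must be positive for all rows")
    cutoff = pd.Timestamp(cutoff_date)
    log = ExclusionLog(n_input=len(participants))
    df = participants

    keep = df["age_at_plan_start"] >= 7
    log.record("age_under_7", int((~keep).sum()), int(keep.sum()))
    df = df[keep]

    plan_end = df["plan_start"] + pd.to_timedelta(df["plan_days"], unit="D")
    keep = plan_end <= cutoff
    log.record("plan_not_completed_by_cutoff", int((~keep).sum()), int(keep.sum()))
    df = df[keep]

    keep = df["plan_days"] > 180
    log.record("plan_180_days_or_less", int((~keep).sum()), int(keep.sum()))
    df = df[keep]

    if len(df):
        order = df.assign(_seq=np.arange(len(df))).sort_values(
            ["plan_start", "_seq"], na_position="first", kind="stable"
        )
        latest_idx = order.groupby("participant_id", sort=False).tail(1).index
        kept = df.index.isin(latest_idx)
    else:
        kept = np.zeros(0, dtype=bool)
    log.record("not_most_recent_plan", int((~kept).sum()), int(kept.sum()))
    df = df[kept].copy()
    return df, log


AGE_BAND_BINS = [6.5, 14.5, 18.5, 24.5, 34.5, 44.5, 54.5, np.inf]
AGE_BAND_LABELS = ["7-14", "15-18", "19-24", "25-34", "35-44", "45-54", "55-64"]


def age_band(ages) -> pd.Series:
    """Broad age bands used as an adjustment covariate."""
    return pd.cut(ages, bins=AGE_BAND_BINS, labels=AGE_BAND_LABELS).astype(str)


def prepare_applications(cohort: pd.DataFrame) -> pd.DataFrame:
    """Analytic applicant table: disability group and exposure flags attached."""
    out = derive_exposures(cohort)
    out["disability_group"] = map_disability_groups(out["primary_disability_code"])
    return out


def prepare_participants(cohort: pd.DataFrame) -> pd.DataFrame:
    """Analytic participant table: annualised dollars, group, exposures."""
    out = derive_exposures(cohort)
    out["disability_group"] = map_disability_groups(out["primary_disability_code"])
    out["age_band"] = age_band(out["age_at_plan_start"])
    out["plan_annual"] = annualize(out["plan_amount"], out["plan_days"])
    out["spend_annual"] = annualize(out["spend_amount"], out["plan_days"])
    return out
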