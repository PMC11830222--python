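"""Cohort filters, disability-group mapping, exposure flags, annualisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import ndisparity as nd
from ndisparity.cohort import (
    DISABILITY_GROUP_MAP,
    DISABILITY_GROUPS,
    UnknownDisabilityCode,
    annualize,
    map_disability_group,
)


# ---------------------------------------------------------------------------
# Disability-group mapping
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "code,group",
    [
        ("stroke", "brain_injury_stroke"),
        ("acquired_brain_injury", "brain_injury_stroke"),
        ("multiple_sclerosis", "other"),
        ("trisomy_21", "intellectual_other"),
        ("cerebral_palsy", "physical"),
        ("autism", "autism"),
        ("hearing_impairment", "sensory"),
        ("psychosocial", "psychosocial"),
    ],
)
def test_disability_mapping(code, group):
    assert map_disability_group(code) == group


def test_unknown_code_raises_with_name():
    with pytest.raises(UnknownDisabilityCode, match="unknown_xyz"):
        map_disability_group("unknown_xyz")


def test_mapping_partitions_codes_into_seven_groups():
    assert set(DISABILITY_GROUP_MAP.values()) == set(DISABILITY_GROUPS)
    # every configured code maps (totality over the generator's code list)
    cfg = nd.SynthConfig()
    for code in cfg.confounder_dist["disability_code"]:
        assert map_disability_group(code) in DISABILITY_GROUPS


# ---------------------------------------------------------------------------
# Exposure derivation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "decile,expected", [(1, 1), (3, 1), (4, 0), (10, 0)]
)
def test_low_ses_boundary(decile, expected):
    df = pd.DataFrame(
        {"gender": ["other"], "irsd_decile": [decile], "age_at_decision": [30]}
    )
    assert nd.derive_exposures(df)["low_ses"].iloc[0] == expected


@pytest.mark.parametrize("age,expected", [(54, 0), (55, 1), (64, 1)])
def test_age_55plus_boundary(age, expected):
    df = pd.DataFrame(
        {"gender": ["women_girls"], "irsd_decile": [5], "age_at_decision": [age]}
    )
    out = nd.derive_exposures(df)
    assert out["age_55plus"].iloc[0] == expected
    assert out["women_girls"].iloc[0] == 1


# ---------------------------------------------------------------------------
# Annualisation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "amount,days,expected",
    [(10_000, 365.25, 10_000.0), (50_000, 500, 36_525.0), (0, 200, 0.0)],
)
def test_annualize(amount, days, expected):
    assert annualize(amount, days) == pytest.approx(expected)


def test_annualize_rejects_nonpositive_days():
    with pytest.raises(ValueError):
        annualize(100.0, 0)


# ---------------------------------------------------------------------------
# Eligibility cohort filter
# ---------------------------------------------------------------------------

def _app_row(applicant_id, decision_type="access_met", date="2020-01-01", age=30,
             complete=True):
    return {
        "applicant_id": applicant_id,
        "decision_type": decision_type,
        "decision_date": pd.Timestamp(date),
        "age_at_decision": age,
        "gender": "other",
        "irsd_decile": 5,
        "remoteness": "major_city",
        "indigenous": 0,
        "prior_support": "none",
        "primary_disability_code": "autism",
        "demographics_complete": complete,
    }


def test_empty_input_gives_empty_output_and_zero_log():
    df = pd.DataFrame([_app_row("x")]).iloc[0:0]
    out, log = nd.filter_eligibility_cohort(df)
    assert len(out) == 0
    assert all(s.n_removed == 0 for s in log.steps)


def test_most_recent_request_kept():
    df = pd.DataFrame(
        [
            _app_row("p1", "access_not_met", "2019-05-01"),
            _app_row("p1", "access_met", "2021-06-01"),
        ]
    )
    out, log = nd.filter_eligibility_cohort(df)
    assert len(out) == 1
    assert out["decision_date"].iloc[0] == pd.Timestamp("2021-06-01")
    assert log.removed("not_most_recent_request") == 1


def test_missing_decision_type_excluded_with_own_log_line():
    df = pd.DataFrame([_app_row("a"), _app_row("b", decision_type=None)])
    out, log = nd.filter_eligibility_cohort(df)
    assert len(out) == 1
    assert log.removed("missing_decision_type") == 1


def test_age_under_seven_excluded():
    df = pd.DataFrame([_app_row("a", age=6), _app_row("b", age=7)])
    out, log = nd.filter_eligibility_cohort(df)
    assert len(out) == 1
    assert log.removed("age_under_7") == 1


decision_strategy = st.sampled_from(
    ["access_met", "access_not_met", "withdrawn", "cancelled",
     "in_progress", "revoked_ceased", None]
)


@given(
    rows=st.lists(
        st.tuples(
            st.integers(min_value=0, max_value=5),     # applicant id (dups likely)
            decision_strategy,
            st.integers(min_value=0, max_value=80),    # age
            st.integers(min_value=0, max_value=2000),  # date offset
            st.booleans(),
        ),
        max_size=40,
    )
)
def test_exclusion_log_conservation_and_idempotence(rows):
    df = pd.DataFrame(
        [
            _app_row(
                f"p{i}",
                decision_type=dt,
                date=pd.Timestamp("2017-01-01") + pd.Timedelta(days=off),
                age=age,
                complete=comp,
            )
            for (i, dt, age, off, comp) in rows
        ],
        columns=list(_app_row("x")),
    )
    out, log = nd.filter_eligibility_cohort(df)
    assert log.n_input == len(df)
    assert log.n_final == len(out)
    assert log.n_input == log.n_final + log.total_removed
    # filtering an already-filtered cohort removes nothing
    out2, log2 = nd.filter_eligibility_cohort(out.drop(columns=["eligible"]))
    assert len(out2) == len(out)
    assert log2.total_removed == 0


# ---------------------------------------------------------------------------
# Participant cohort filter
# ---------------------------------------------------------------------------

def _part_row(pid, plan_days=400, start="2020-01-01", age=30):
    return {
        "participant_id": pid,
        "gender": "other",
        "irsd_decile": 5,
        "remoteness": "major_city",
        "indigenous": 0,
        "age_at_plan_start": age,
        "primary_disability_code": "autism",
        "severity_score": 8,
        "severity_band": "6-10",
        "years_band": "1-2",
        "ypirac": 0,
        "sil": 0,
        "sda": 0,
        "trial_plan": 0,
        "prior_support": "none",
        "plan_start": pd.Timestamp(start),
        "plan_days": plan_days,
        "plan_amount": 50_000.0,
        "spend_amount": 30_000.0,
    }


def test_longer_completed_plan_kept_over_short_one():
    df = pd.DataFrame(
        [_part_row("q1", plan_days=100), _part_row("q1", plan_days=400)]
    )
    out, log = nd.filter_participant_cohort(df, "2022-08-31")
    assert len(out) == 1
    assert out["plan_days"].iloc[0] == 400


def test_exactly_180_day_plan_excluded():
    df = pd.DataFrame([_part_row("q1", plan_days=180)])
    out, log = nd.filter_participant_cohort(df, "2022-08-31")
    assert len(out) == 0
    assert log.removed("plan_180_days_or_less") == 1


def test_plan_not_completed_by_cutoff_excluded():
    df = pd.DataFrame([_part_row("q1", start="2022-06-01", plan_days=365)])
    out, log = nd.filter_participant_cohort(df, "2022-08-31")
    assert len(out) == 0
    assert log.removed("plan_not_completed_by_cutoff") == 1


def test_most_recent_plan_kept():
    df = pd.DataFrame(
        [
            _part_row("q1", start="2019-01-01"),
            _part_row("q1", start="2021-01-01"),
        ]
    )
    out, _ = nd.filter_participant_cohort(df, "2022-08-31")
    assert len(out) == 1
    assert out["plan_start"].iloc[0] == pd.Timestamp("2021-01-01")


def test_nonpositive_plan_days_rejected():
    df = pd.DataFrame([_part_row("q1", plan_days=0)])
    with pytest.raises(ValueError):
        nd.filter_participant_cohort(df, "2022-08-31")


def test_calibrated_participant_cohort_matches_published_total():
    from ndisparity import marginals

    cfg = nd.SynthConfig(seed=11)
    parts = nd.generate_participants(
        cfg,
        group_sizes={
            0: marginals.PARTICIPANTS_OTHER,
            1: marginals.PARTICIPANTS_WOMEN_GIRLS,
        },
    )
    kept, _ = nd.filter_participant_cohort(parts, cfg.cutoff_date)
    assert len(kept) == marginals.PARTICIPANTS_TOTAL
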