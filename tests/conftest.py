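import hypothesis
import pytest

import ndisparity as nd

hypothesis.settings.register_profile(
    "deterministic", derandomize=True, deadline=None, max_examples=25
)
hypothesis.settings.load_profile("deterministic")


from ndisparity.experiments import LINEAR_SPEC, linear_gaussian_config  # noqa: E402


@pytest.fixture(scope="session")
def make_linear_config():
    return linear_gaussian_config


@pytest.fixture(scope="session")
def linear_spec():
    return LINEAR_SPEC


@pytest.fixture(scope="session")
def small_default_apps():
    """Analytic applicant cohort from the default DGP (session-cached)."""
    cfg = nd.SynthConfig(n_applications=12_000, seed=101)
    kept, _ = nd.filter_eligibility_cohort(nd.generate_applications(cfg))
    return nd.prepare_applications(kept)


@pytest.fixture(scope="session")
def small_default_participants():
    cfg = nd.SynthConfig(n_participants=8_000, seed=202)
    kept, _ = nd.filter_participant_cohort(
        nd.generate_participants(cfg), "2022-08-31"
    )
    return nd.prepare_participants(kept)
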