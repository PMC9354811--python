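import warnings

import pytest

import emgpress as e


@pytest.fixture(autouse=True)
def _quiet_nyquist_clamp():
    # the default 10-500 Hz band at fs=1000 always triggers the clamp notice
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="high_cut.*Nyquist")
        yield


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down cohort: fast enough for disk round-trips."""
    return e.SynthConfig(
        n_participants=2,
        muscles=("anterior_deltoid", "posterior_deltoid"),
        n_reps=4,
        mvic_attempts=2,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return e.make_cohort(small_config)


@pytest.fixture(scope="session")
def default_cohort():
    """Full-design cohort (8 participants, 6 muscles) shared across tests."""
    return e.make_cohort(e.SynthConfig(seed=2024))


@pytest.fixture(scope="session")
def default_activations(default_cohort):
    return e.build_activation_table(default_cohort)
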