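import numpy as np
import pytest

from mvslab import (
    build_field_map,
    default_params,
    duration_response_table,
    generate_cohort,
)

DURATIONS = [0, 20, 60, 120, 180, 300]


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def fmap():
    return build_field_map()


@pytest.fixture(scope="session")
def entry_sweep(params):
    """Per-period table across entry durations with the exit fixed at 20 s."""
    return duration_response_table(params, DURATIONS, vary="entry", fixed_exit_s=20.0)


@pytest.fixture(scope="session")
def exit_sweep(params):
    """Per-period table across exit durations with the entry fixed at 20 s."""
    return duration_response_table(params, DURATIONS, vary="exit", fixed_entry_s=20.0)


@pytest.fixture(scope="session")
def both_sweep(params):
    """Entry and exit varied together, the paradigm run in the scanner."""
    return duration_response_table(params, DURATIONS, vary="both")


@pytest.fixture(scope="session")
def small_cohort():
    """A compact synthetic cohort (3 subjects, all 3 conditions, short dwell)."""
    recordings, truth = generate_cohort(
        n_subjects=3, conditions=(20.0, 120.0, 300.0), seed=11,
        dwell_s=120.0, pre_s=60.0, post_s=90.0,
    )
    return recordings, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
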