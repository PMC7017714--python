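import numpy as np
import pytest

from ertwave import GeneratorParams, TraceMatrix, generate_populations


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def small_params():
    """Reduced-size generator for ensemble tests that don't need 10k lines."""
    return GeneratorParams(population_lines=2000, population_subjects=300, seed=42)


@pytest.fixture(scope="session")
def small_populations(small_params):
    return generate_populations(small_params)


@pytest.fixture
def noiseless_populations():
    """Deterministic populations: null = all-zero rows, ert = unit parabola rows.

    Every ert row is identical (magnitude 1 transient at the halfway
    point), so noise-free detection checks have exact expectations.
    """
    from ertwave import parabolic_transient, transient_support

    params = GeneratorParams()
    lo, hi = transient_support(params)
    null = np.zeros((50, params.n_points))
    ert = np.zeros((50, params.n_points))
    ert[:, lo:hi] = parabolic_transient(
        params.transient_duration, params.fs, 1.0
    )
    return (
        TraceMatrix(null, fs=params.fs, condition="null"),
        TraceMatrix(ert, fs=params.fs, condition="ert"),
    )
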