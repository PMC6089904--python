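import pytest
from hypothesis import HealthCheck, settings

import resistmix as rm
from resistmix import reference as ref

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def two_pop_truth():
    """Generative two-population truth over an 8-week course."""
    return rm.TwoPopulationParams(
        sensitive=ref.SENSITIVE_STATE,
        resistant=ref.RESISTANT_STATE,
        groups=tuple(range(1, 9)),
        f_sens=ref.DEFAULT_FSENS_TRAJECTORY,
        v_max=0.9,
    )


@pytest.fixture(scope="session")
def time_course_design(two_pop_truth):
    return rm.make_time_course_design(
        ref.DEFAULT_FSENS_TRAJECTORY, two_pop_truth)


@pytest.fixture(scope="session")
def noiseless_time_course(time_course_design):
    return rm.simulate_assay(time_course_design, rm.NoiseModel.constant(0.0))


@pytest.fixture(scope="session")
def noisy_time_course(time_course_design):
    return rm.simulate_assay(
        time_course_design, rm.NoiseModel.constant(0.03, seed=42))


@pytest.fixture(scope="session")
def mixture_truth():
    return rm.TwoPopulationParams(
        sensitive=ref.SENSITIVE_STATE,
        resistant=ref.RESISTANT_STATE,
        v_max=0.9,
    )


@pytest.fixture(scope="session")
def mixture_dataset(mixture_truth):
    """Low-noise assay of the five validation mixtures."""
    design = rm.make_mixture_design(
        ref.MIXTURE_RESISTANT_FRACTIONS, mixture_truth)
    return rm.simulate_assay(design, rm.NoiseModel.constant(0.02, seed=11))
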