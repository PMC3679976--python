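import numpy as np
import pytest

from cvdrisk import GeneratorConfig, generate, make_fixture_chart


@pytest.fixture(scope="session")
def uniform_charts():
    return (make_fixture_chart("uniform", "with_cholesterol"),
            make_fixture_chart("uniform", "without_cholesterol"))


@pytest.fixture(scope="session")
def threshold_charts():
    return (make_fixture_chart("threshold", "with_cholesterol"),
            make_fixture_chart("threshold", "without_cholesterol"))


@pytest.fixture(scope="session")
def adversarial_charts():
    return (make_fixture_chart("adversarial", "with_cholesterol"),
            make_fixture_chart("adversarial", "without_cholesterol"))


@pytest.fixture(scope="session")
def default_cohort():
    """One default-sized synthetic survey shared across read-only tests."""
    records, truth = generate(GeneratorConfig(seed=20260930))
    return records, truth


def random_profiles(n, rng):
    """Randomized but admissible risk profiles straddling every threshold."""
    from cvdrisk import RiskProfile

    profiles = []
    for _ in range(n):
        tc = None if rng.random() < 0.3 else float(rng.uniform(2.5, 9.5))
        profiles.append(RiskProfile(
            sex=str(rng.choice(["male", "female"])),
            age=float(rng.integers(40, 80)),
            smoker=bool(rng.random() < 0.5),
            diabetic=bool(rng.random() < 0.5),
            sbp=float(rng.uniform(90, 220)),
            dbp=float(rng.uniform(50, 130)),
            total_cholesterol=tc,
            on_ht_medication=bool(rng.random() < 0.3),
            on_dm_medication=bool(rng.random() < 0.1),
            on_chol_medication=bool(rng.random() < 0.1),
            bmi=float(rng.uniform(16, 45)),
            met_minutes=float(rng.uniform(0, 4000)),
            pulse=float(rng.uniform(45, 130)),
            triglycerides=float(rng.uniform(0.3, 6.0)),
            hdl=float(rng.uniform(0.4, 2.5)),
        ))
    return profiles


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
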