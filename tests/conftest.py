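import numpy as np
import pytest

from aptamarkers import SimulationConfig, cohort_to_frame, simulate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast cohort: 20 samples, 6-aptamer panel, 2 informative."""
    return SimulationConfig(
        n_samples=20,
        pos_fraction=0.5,
        panel_size=6,
        n_informative=2,
        reads_per_library=2000,
        background_pool_size=50,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_meta(small_cohort):
    return cohort_to_frame(small_cohort).set_index("sample_id")


def random_logistic_curve(rng: np.random.Generator, n_cycles: int = 30):
    """One random sigmoid amplification curve (midpoint 12-25, slope 0.5-2)."""
    mid = rng.uniform(12.0, 25.0)
    slope = rng.uniform(0.5, 2.0)
    noise = rng.uniform(0.0, 0.5)
    plateau = rng.uniform(200.0, 2000.0)
    baseline = rng.uniform(0.0, 200.0)
    c = np.arange(1, n_cycles + 1)
    f = baseline + plateau / (1.0 + np.exp(-slope * (c - mid)))
    if noise > 0:
        f = f + rng.normal(0.0, noise, n_cycles)
    return f


def oracle_call_cq(f, lo: int = 3, hi: int = 10, k: float = 6.0):
    """Independent exhaustive-scan Cq caller (pure-python re-statement).

    Derivative = first difference; threshold = mean + k * sample SD of the
    derivative over cycles lo..hi; first post-window cycle whose derivative
    exceeds the threshold, linearly interpolated across the crossing.
    Returns None for a no-call.
    """
    f = list(map(float, f))
    n = len(f)
    d = {c: f[c - 1] - f[c - 2] for c in range(2, n + 1)}
    base = [d[c] for c in range(lo, hi + 1)]
    mu = sum(base) / len(base)
    var = sum((x - mu) ** 2 for x in base) / (len(base) - 1)
    threshold = mu + k * var**0.5
    for c in range(hi + 1, n + 1):
        if d[c] > threshold:
            prev = d[c - 1]
            if d[c] - prev > 0 and prev < threshold:
                return (c - 1) + (threshold - prev) / (d[c] - prev)
            return float(c)
    return None
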