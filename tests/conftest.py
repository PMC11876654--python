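import numpy as np
import pytest

from dermavec import gan, simulate


@pytest.fixture(scope="session")
def base_factors():
    return simulate.LesionFactors(severity=2.0, area_fraction=0.3, seed=11)


@pytest.fixture(scope="session")
def oracle32():
    return gan.oracle_generator(resolution=32)


@pytest.fixture(scope="session")
def small_training_set():
    """128 simulator images at 32x32 for short training smoke runs."""
    return [im for im, _ in simulate.sample_dataset(128, correlation=0.0, seed=4, size=32)]


def severity_thresholded_groups(pool: np.ndarray, n_pos: int, n_neg: int):
    """Severe / moderate w groups by ground-truth severity consensus.

    Severity decodes from w[0]; severe = rounded severity 3-4, moderate = 2.
    Returns (severe, moderate) rows, first-come order.
    """
    sev = np.clip((pool[:, 0] + 3.0) * 4.0 / 6.0, 0.0, 4.0)
    cons = np.floor(sev + 0.5)
    severe = pool[cons >= 3][:n_pos]
    moderate = pool[cons == 2][:n_neg]
    return severe, moderate
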