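import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.special import expit

from meltstr import Genotype, MeltCurve, canonical_grid, load_locus
from meltstr.synthetic_data import SimulationConfig, simulate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def logistic_curve(tms, weights, slope, amplitude=1000.0, baseline=(0.0, 0.0), sample_id="toy"):
    """Noiseless logistic melt mixture on the canonical grid."""
    T = canonical_grid()
    F = baseline[0] + baseline[1] * (T - T[0])
    for tm, w in zip(np.atleast_1d(tms), np.atleast_1d(weights)):
        F = F + amplitude * w * expit((tm - T) / slope)
    return MeltCurve(sample_id=sample_id, locus="TOY", temperatures=T, fluorescence=F)


@pytest.fixture(scope="session")
def d5s818():
    return load_locus("D5S818")


@pytest.fixture(scope="session")
def d18s51():
    return load_locus("D18S51")


# Well-separated regime used for recovery checks: one repeat unit moves Tm
# by >= 0.25 degC across the whole panel (length coefficient raised, offset
# compensated to keep the panel near 78 degC).
RECOVERY_COEFFS = (74.3, 41.0, 1850.0)


@pytest.fixture(scope="session")
def separable_dataset(d5s818):
    cfg = SimulationConfig(tm_coeffs=RECOVERY_COEFFS, seed=11)
    return simulate_dataset(d5s818, n_standards=8, n_unknowns=20, cfg=cfg)
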