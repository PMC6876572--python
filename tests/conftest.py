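import numpy as np
import pytest

from capdep import KineticParams, LabelingModel, MMFitResult


@pytest.fixture
def study_params() -> KineticParams:
    """Rate constants of the 83 nM single-molecule condition."""
    return KineticParams(k_on=1.1e7, k_off=0.45, c=83e-9)


@pytest.fixture
def saturation_fit() -> MMFitResult:
    """Saturation-kinetics parameters of the concentration series."""
    return MMFitResult(K_M=50e-9, k_cat=53.0, se_K_M=10e-9, se_k_cat=8.0)


@pytest.fixture
def labeling() -> LabelingModel:
    """Six-site dye model with 77.9% of hexamers carrying >= 1 dye."""
    return LabelingModel(p_site=0.2223)


def thinned_gap_sample(
    rng: np.random.Generator,
    n_events: int,
    lam: float,
    k_off: float,
    f: float,
) -> np.ndarray:
    """Observed inter-event gaps under random dwell deletion.

    Independent oracle for the labeling correction: draw alternating
    exponential gaps (rate lam) and dwells (rate k_off), delete each
    dwell with probability 1 - f, and merge the flanking gaps (plus the
    hidden dwell) into one observed gap.
    """
    gaps = rng.exponential(1.0 / lam, size=n_events)
    dwells = rng.exponential(1.0 / k_off, size=n_events)
    visible = rng.random(n_events) < f
    observed = []
    acc = 0.0
    for g, d, v in zip(gaps, dwells, visible):
        acc += g
        if v:
            observed.append(acc)
            acc = 0.0
        else:
            acc += d
    return np.asarray(observed[1:])  # first gap has no preceding visible dwell
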