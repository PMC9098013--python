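import numpy as np
import pytest

from ridgenet.ridge_io import (
    AnnotationRecord,
    Experiment,
    Ridge,
    RidgeCollection,
    TimeGrid,
)


@pytest.fixture
def grid30():
    return TimeGrid(np.linspace(0.0, 10.0, 30))


@pytest.fixture
def noisy_sine(grid30):
    rng = np.random.default_rng(42)
    return np.sin(grid30.times) + 0.1 * rng.standard_normal(len(grid30))


def make_ridge(feature_id, exp_id, intensities, ppm=1.0, compound=None, labeled=False):
    n = len(intensities)
    ann = AnnotationRecord(compound) if compound else None
    return Ridge(
        feature_id=feature_id,
        experiment_id=exp_id,
        ppm_trace=np.full(n, ppm, dtype=float),
        intensity_trace=np.asarray(intensities, dtype=float),
        annotation=ann,
        labeled=labeled,
    )


def make_experiment(exp_id, times, ridge_specs, condition=None):
    """ridge_specs: list of (feature_id, intensities, ppm[, compound])."""
    exp = Experiment(exp_id, TimeGrid(np.asarray(times, dtype=float)), condition=condition or {})
    for spec in ridge_specs:
        fid, intens, ppm = spec[0], spec[1], spec[2]
        compound = spec[3] if len(spec) > 3 else None
        exp.add(make_ridge(fid, exp_id, intens, ppm, compound))
    return exp


@pytest.fixture
def two_experiment_collection():
    """Two experiments, two features each, 5 time points."""
    t = [0.0, 1.0, 2.0, 3.0, 4.0]
    coll = RidgeCollection()
    coll.add(
        make_experiment(
            "expA",
            t,
            [("f1", [1, 2, 3, 4, 5], 1.480), ("f2", [5, 4, 3, 2, 1], 2.100)],
        )
    )
    coll.add(
        make_experiment(
            "expB",
            t,
            [("f1", [2, 3, 4, 5, 6], 1.481), ("f2", [6, 5, 4, 3, 2], 2.102)],
        )
    )
    return coll
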