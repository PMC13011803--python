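"""Shared fixtures: small matrices built by hand and one default simulation."""

import warnings

import numpy as np
import pandas as pd
import pytest

import domlink as dl
from domlink.containers import IntensityMatrix, SampleKey


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


def make_intensity(values: np.ndarray, keys: list[SampleKey], fids=None,
                   normalized=False) -> IntensityMatrix:
    values = np.asarray(values, dtype=float)
    fids = fids or [f"f{i}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=pd.Index(fids, name="formula_id"))
    return IntensityMatrix.from_keys(df, keys, normalized=normalized)


def grid_keys(sources, reps, days, control_reps=()):
    keys = []
    for s in sources:
        for r in reps:
            for d in days:
                keys.append(SampleKey(s, r, d))
        for r in control_reps:
            for d in days:
                keys.append(SampleKey(s, r, d, is_control=True))
    return keys


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulation shared across read-only tests."""
    return dl.simulate(dl.SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def default_filtered(default_sim):
    return dl.replicate_presence_filter(default_sim.intensity, min_reps=2)


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free, dropout-free, identical-inoculum simulation."""
    return dl.simulate(
        dl.SimulationConfig(seed=1, noise_cv=0.0, dropout_prob=0.0, inoculum_cv=0.0)
    )
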