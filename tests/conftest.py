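"""Shared fixtures and generators for the pmevalkit test suite."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import pmevalkit as pk
from pmevalkit.chamber import (
    build_design,
    experiments_to_frame,
    resample_series,
    simulate_design,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

CONDITION_DEFAULTS = {
    "temperature": 20.0,
    "relative_humidity": 50.0,
    "power": "battery",
    "pattern": "transient",
    "session_time": 0.0,
    "unit_id": "u1",
    "material": "ard",
}


def model_frame(x, y, **conditions) -> pd.DataFrame:
    """Long-format modelling table from log10-scale x (monitor) and y (reference)."""
    df = pd.DataFrame({"monitor": 10.0 ** np.asarray(x), "reference": 10.0 ** np.asarray(y)})
    for key, default in CONDITION_DEFAULTS.items():
        df[key] = conditions.get(key, default)
    return df


@pytest.fixture(scope="session")
def clean_screening_frame() -> pd.DataFrame:
    """One full screening design for a well-behaved monitor, 1-min aligned."""
    design = build_design({"kind": "screening", "units": ("u1", "u2", "u3")})
    exps = simulate_design(design, pk.SensorResponseSpec(), seed=42, id_prefix="s")
    frame = experiments_to_frame([resample_series(e) for e in exps])
    return frame[(frame.monitor > 0) & (frame.reference > 0)].reset_index(drop=True)
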