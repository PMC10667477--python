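import numpy as np
import pandas as pd
import pytest

from shopeeg.io import Montage, Recording
from shopeeg.simulate import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def montage():
    return Montage.standard_63()


@pytest.fixture(scope="session")
def square_montage():
    """Tiny 4-channel montage: unit square on the z=0.05 plane, every
    pair of adjacent corners at distance 0.1, diagonals excluded."""
    names = ("A", "B", "C", "D")
    positions = np.array([
        [0.0, 0.0, 0.05],
        [0.1, 0.0, 0.05],
        [0.1, 0.1, 0.05],
        [0.0, 0.1, 0.05],
    ])
    graph = {
        "A": (("B", 0.1), ("D", 0.1)),
        "B": (("A", 0.1), ("C", 0.1)),
        "C": (("B", 0.1), ("D", 0.1)),
        "D": (("C", 0.1), ("A", 0.1)),
    }
    return Montage(names, positions, ground="A", reference="B", neighbor_graph=graph)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Two synthetic subjects with a strong planted effect; shared across
    tests that only need structurally valid sessions."""
    cfg = GeneratorConfig(n_subjects=2, effect_size_hz=2.0, seed=7)
    return generate_cohort(cfg)


def make_recording(data, rate=500.0, names=None, start=0.0):
    data = np.asarray(data, dtype=float)
    if names is None:
        names = tuple(f"E{i + 1}" for i in range(data.shape[0]))
    return Recording(data=data, sampling_rate=rate, channel_names=names, start_time=start)


def make_events(rows):
    """Events frame from (subject, product, view, enter, leave, action) tuples."""
    return pd.DataFrame(
        [
            {
                "subject_id": r[0], "product_id": r[1], "view_index": r[2],
                "enter_time": r[3], "leave_time": r[4],
                "action": r[5] if len(r) > 5 else "none",
                "action_time": r[6] if len(r) > 6 else np.nan,
            }
            for r in rows
        ]
    )
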