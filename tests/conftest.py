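import numpy as np
import pandas as pd
import pytest

import eaekit as ek
from eaekit import profiles_io

MOG_SC_17 = ("MOG.CFA.PTX", "SC", 17)
MOG_SC_8 = ("MOG.CFA.PTX", "SC", 8)


@pytest.fixture(scope="session")
def profiles():
    return ek.default_profiles()


@pytest.fixture(scope="session")
def marker_levels():
    model = profiles_io.marker_model()
    return model["levels"], model["log_sd"]


@pytest.fixture(scope="session")
def sc17_sample(profiles):
    pops, comps = profiles
    return ek.simulate_cytometry_sample(
        pops, comps[MOG_SC_17], 20_000, n_jurkat_spike=1_000,
        dead_fraction=0.05, seed=101,
    )


@pytest.fixture(scope="session")
def sc17_thresholds(sc17_sample):
    return ek.derive_thresholds(sc17_sample, random_state=7)


@pytest.fixture(scope="session")
def sc17_gate(sc17_sample, sc17_thresholds):
    return ek.gate_events(sc17_sample, sc17_thresholds)


@pytest.fixture(scope="session")
def day14_slice(profiles):
    cfg = ek.load_slice_profiles()[("MOG.CFA.PTX", 14)]
    return ek.simulate_slice(cfg, seed=42)


def circle_boundary(radius=100.0, n=256, center=(0.0, 0.0)):
    phi = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.stack([center[0] + radius * np.cos(phi),
                     center[1] + radius * np.sin(phi)], axis=1)


def make_slice(boundary, xy, channel="EGFP", **extra):
    cells = pd.DataFrame({
        "x": np.asarray(xy, dtype=float)[:, 0],
        "y": np.asarray(xy, dtype=float)[:, 1],
        "channel": channel,
    })
    for k, v in extra.items():
        cells[k] = v
    return ek.SliceRecord(boundary=np.asarray(boundary, dtype=float), cells=cells)
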