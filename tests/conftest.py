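import numpy as np
import pandas as pd
import pytest

from resikit import AcquisitionMeta, LocalizationTable


def make_table(
    xy: np.ndarray,
    lp: float = 2.0,
    n_frames: int = 10_000,
    frames: np.ndarray | None = None,
    z: np.ndarray | None = None,
    channel: int = 0,
    seed: int = 0,
) -> LocalizationTable:
    """Build a LocalizationTable from a coordinate array."""
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    n = len(xy)
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "frame": frames if frames is not None else rng.integers(0, n_frames, n),
            "x": xy[:, 0],
            "y": xy[:, 1],
        }
    )
    if z is not None:
        df["z"] = z
    df["lp"] = lp
    df["channel"] = channel
    return LocalizationTable(df, AcquisitionMeta(n_frames=n_frames))


@pytest.fixture
def gaussian_cloud_table():
    """Single Gaussian localization cloud: 200 draws, sigma 2 nm."""
    rng = np.random.default_rng(7)
    xy = rng.normal(0.0, 2.0, size=(200, 2))
    return make_table(xy, lp=2.0, seed=7)
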