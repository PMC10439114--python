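"""Shared fixtures and helpers for the synclust test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from synclust.types import LOC_COLUMNS


def make_table(frame, x_nm, y_nm, sigma_nm=None, photons=None,
               uncertainty_nm=None, **extras) -> pd.DataFrame:
    """Build a localization table from parallel sequences, with defaults for
    the quality columns so positional tests stay short."""
    frame = np.asarray(frame)
    n = len(frame)
    data = {
        "frame": frame.astype(int),
        "x_nm": np.asarray(x_nm, float),
        "y_nm": np.asarray(y_nm, float),
        "sigma_nm": np.full(n, 150.0) if sigma_nm is None else np.asarray(sigma_nm, float),
        "photons": np.full(n, 1000.0) if photons is None else np.asarray(photons, float),
        "uncertainty_nm": np.full(n, 10.0) if uncertainty_nm is None else np.asarray(uncertainty_nm, float),
    }
    data.update(extras)
    return pd.DataFrame(data, columns=LOC_COLUMNS + list(extras))


def simulate_drifted_table(rate_nm_per_frame: tuple[float, float],
                           n_sites: int = 300, n_locs: int = 2000,
                           n_frames: int = 3000, loc_noise_nm: float = 10.0,
                           field_nm: float = 5000.0, seed: int = 0) -> tuple[pd.DataFrame, np.ndarray]:
    """Localization table with a known linear stage drift injected.

    Fixed binding sites are revisited at random frames; every localization is
    site position + localization noise + drift(frame).  Returns the table and
    the per-localization site index (for closed-loop checks).
    """
    rng = np.random.default_rng(seed)
    sites = rng.uniform(500, field_nm - 500, size=(n_sites, 2))
    which = rng.integers(0, n_sites, size=n_locs)
    frames = np.sort(rng.integers(1, n_frames + 1, size=n_locs))
    rate = np.asarray(rate_nm_per_frame, float)
    drift = (frames - 1)[:, None] * rate[None, :]
    xy = sites[which] + rng.normal(0, loc_noise_nm, size=(n_locs, 2)) + drift
    table = make_table(frames, xy[:, 0], xy[:, 1])
    return table, which


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
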