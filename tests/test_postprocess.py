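"""Quality filtering, drift correction, re-blink merging, cropping."""

import numpy as np
import pandas as pd
import pytest

from synclust.postprocess import (
    DriftEstimationError,
    DriftTrack,
    FilterCriteria,
    apply_drift,
    crop_region,
    estimate_drift,
    filter_localizations,
    merge_reblinks,
)
from synclust.types import Rect

from conftest import make_table, simulate_drifted_table


# --------------------------------------------------------------------------
# Quality filters

def test_filter_four_row_worked_example():
    """Exactly one of four rows survives the published thresholds:
    photons > 600 (strict), sigma in [50, 200] (closed), uncertainty < 30
    (strict)."""
    table = make_table(
        frame=[1, 2, 3, 4],
        x_nm=[10.0, 20.0, 30.0, 40.0],
        y_nm=[10.0, 20.0, 30.0, 40.0],
        photons=[700.0, 600.0, 900.0, 800.0],     # row 2 fails (strict >)
        sigma_nm=[120.0, 150.0, 210.0, 200.0],    # row 3 fails; 200 passes
        uncertainty_nm=[10.0, 15.0, 20.0, 30.0],  # row 4 fails (strict <)
    )
    kept = filter_localizations(table)
    assert len(kept) == 1
    assert kept["frame"].tolist() == [1]


def test_filter_boundary_semantics():
    table = make_table(
        frame=[1, 2, 3],
        x_nm=[0.0, 0.0, 0.0], y_nm=[0.0, 0.0, 0.0],
        photons=[601.0, 601.0, 601.0],
        sigma_nm=[50.0, 200.0, 49.999],
        uncertainty_nm=[29.999, 29.999, 10.0],
    )
    kept = filter_localizations(table)
    assert kept["frame"].tolist() == [1, 2]   # closed sigma range


def test_filter_preserves_order_and_extras():
    table = make_table(frame=[5, 1, 9], x_nm=[1, 2, 3], y_nm=[1, 2, 3],
                       tag=[10, 20, 30])
    kept = filter_localizations(table)
    assert kept["frame"].tolist() == [5, 1, 9]
    assert kept["tag"].tolist() == [10, 20, 30]


def test_filter_empty_table():
    assert len(filter_localizations(make_table([], [], []))) == 0


def test_filter_criteria_validation():
    with pytest.raises(ValueError):
        FilterCriteria(sigma_range_nm=(200.0, 50.0))
    with pytest.raises(ValueError):
        FilterCriteria(min_photons=-5)


# --------------------------------------------------------------------------
# Drift correction

def test_drift_null_is_near_zero():
    table, _ = simulate_drifted_table((0.0, 0.0), seed=11)
    track = estimate_drift(table)
    assert np.hypot(track.dx_nm[-1], track.dy_nm[-1]) < 5.0


def test_drift_linear_recovery():
    """0.5 nm/frame injected drift recovered within 10 nm over the span
    between the first and last temporal-bin midpoints."""
    rate = (0.5, -0.3)
    table, _ = simulate_drifted_table(rate, seed=1)
    track = estimate_drift(table)
    f_min, f_max = table["frame"].min(), table["frame"].max()
    edges = np.linspace(f_min, f_max + 1, 4)
    mids = 0.5 * (edges[:-1] + edges[1:] - 1)
    span = mids[-1] - mids[0]
    err = np.hypot(track.dx_nm[-1] - rate[0] * span,
                   track.dy_nm[-1] - rate[1] * span)
    assert err < 10.0


def test_drift_closed_loop_tightens_sites():
    rate = (0.5, -0.3)
    table, which = simulate_drifted_table(rate, seed=2)
    corrected = apply_drift(table, estimate_drift(table))
    # between the first and last temporal-bin midpoints (where the track is
    # defined by data, not end extrapolation) every binding site collapses
    # back to a tight cloud of the localization-noise scale
    frames = table["frame"].to_numpy()
    f_min, f_max = frames.min(), frames.max()
    edges = np.linspace(f_min, f_max + 1, 4)
    mids = 0.5 * (edges[:-1] + edges[1:] - 1)
    in_span = (frames >= mids[0]) & (frames <= mids[-1])
    spreads, raw_spreads = [], []
    for site in np.unique(which):
        sel = (which == site) & in_span
        if sel.sum() < 5:
            continue
        xy = corrected.loc[sel, ["x_nm", "y_nm"]].to_numpy()
        spreads.append(xy.std(axis=0).max())
        raw_spreads.append(table.loc[sel, ["x_nm", "y_nm"]].to_numpy()
                           .std(axis=0).max())
    assert np.median(spreads) < 25.0
    assert np.median(spreads) < 0.2 * np.median(raw_spreads)


def test_drift_track_lookup_contract():
    track = DriftTrack(np.arange(10, 15), np.arange(5.0), np.zeros(5))
    dx, dy = track.lookup(np.array([10, 14]))
    np.testing.assert_allclose(dx, [0.0, 4.0])
    with pytest.raises(ValueError):
        track.lookup(np.array([9]))
    with pytest.raises(ValueError):
        track.lookup(np.array([15]))


@pytest.mark.filterwarnings("ignore:fewer than")
def test_drift_sparse_bin_raises():
    table = make_table(frame=[1] * 30, x_nm=np.linspace(0, 900, 30),
                       y_nm=np.linspace(0, 900, 30))
    # all localizations in one frame: later temporal bins are empty
    with pytest.raises(DriftEstimationError):
        estimate_drift(table)


def test_drift_empty_table_raises():
    with pytest.raises(DriftEstimationError):
        estimate_drift(make_table([], [], []))


def test_apply_drift_identity_for_zero_track():
    table = make_table(frame=[1, 2], x_nm=[10.0, 20.0], y_nm=[30.0, 40.0])
    track = DriftTrack(np.arange(1, 3), np.zeros(2), np.zeros(2))
    out = apply_drift(table, track)
    pd.testing.assert_frame_equal(out, table)


def test_apply_drift_subtracts_constant():
    table = make_table(frame=[1, 2], x_nm=[10.0, 20.0], y_nm=[30.0, 40.0])
    track = DriftTrack(np.arange(1, 3), np.array([1.0, 2.0]),
                       np.array([-1.0, -2.0]))
    out = apply_drift(table, track)
    assert out["x_nm"].tolist() == [9.0, 18.0]
    assert out["y_nm"].tolist() == [31.0, 42.0]


# --------------------------------------------------------------------------
# Re-blink merging

def test_merge_worked_example_gap_semantics():
    """Events in frames 1 and 5 chain (gap 4 <= 20); frame 40 starts a new
    molecule (gap 35 > 20) even at zero distance."""
    table = make_table(frame=[1, 5, 40], x_nm=[100.0, 110.0, 105.0],
                       y_nm=[100.0, 100.0, 100.0])
    merged = merge_reblinks(table)
    assert len(merged) == 2
    assert sorted(merged["n_merged"].tolist()) == [1, 2]
    assert merged["frame"].tolist() == [1, 40]


def test_merge_photon_weighted_centroid_arithmetic():
    table = make_table(frame=[1, 2], x_nm=[100.0, 130.0], y_nm=[0.0, 0.0],
                       photons=[1000.0, 3000.0], sigma_nm=[100.0, 200.0],
                       uncertainty_nm=[10.0, 10.0])
    merged = merge_reblinks(table)
    assert len(merged) == 1
    row = merged.iloc[0]
    assert row["x_nm"] == pytest.approx((100 * 1000 + 130 * 3000) / 4000)
    assert row["sigma_nm"] == pytest.approx((100 * 1000 + 200 * 3000) / 4000)
    assert row["photons"] == 4000.0
    assert row["uncertainty_nm"] == pytest.approx((2 / 10.0 ** 2) ** -0.5)
    assert row["frame"] == 1 and row["n_merged"] == 2


def test_merge_distance_semantics():
    table = make_table(frame=[1, 2], x_nm=[0.0, 60.0], y_nm=[0.0, 0.0])
    assert len(merge_reblinks(table)) == 2          # 60 nm > 50 nm
    table2 = make_table(frame=[1, 2], x_nm=[0.0, 45.0], y_nm=[0.0, 0.0])
    assert len(merge_reblinks(table2)) == 1


def test_merge_photon_conservation(rng):
    n = 200
    table = make_table(frame=rng.integers(1, 100, n),
                       x_nm=rng.uniform(0, 4000, n),
                       y_nm=rng.uniform(0, 4000, n),
                       photons=rng.uniform(600, 3000, n))
    merged = merge_reblinks(table)
    assert merged["photons"].sum() == pytest.approx(table["photons"].sum())
    assert merged["n_merged"].sum() == n


def test_merge_idempotent_for_separated_molecules():
    table = make_table(frame=[1, 1, 1], x_nm=[0.0, 500.0, 1000.0],
                       y_nm=[0.0, 0.0, 0.0])
    once = merge_reblinks(table)
    twice = merge_reblinks(once)
    assert len(once) == len(twice) == 3
    np.testing.assert_allclose(once["x_nm"], twice["x_nm"])


def test_merge_exact_molecule_count_on_blink_chains(rng):
    """Molecules >= 200 nm apart, each re-blinking a few times within the
    gap window, merge back to exactly the ground-truth count."""
    n_mol = 40
    grid = np.stack(np.meshgrid(np.arange(8), np.arange(5)), -1).reshape(-1, 2)
    positions = grid * 400.0 + 200.0
    rows_f, rows_x, rows_y = [], [], []
    for i, (px, py) in enumerate(positions[:n_mol]):
        n_blinks = rng.integers(1, 5)
        f = 1 + i * 3
        for _ in range(n_blinks):
            rows_f.append(f)
            rows_x.append(px + rng.normal(0, 5))
            rows_y.append(py + rng.normal(0, 5))
            f += rng.integers(1, 15)
    table = make_table(rows_f, rows_x, rows_y)
    merged = merge_reblinks(table)
    assert len(merged) == n_mol


def test_merge_anchor_modes_and_validation():
    table = make_table(frame=[1, 2], x_nm=[0.0, 40.0], y_nm=[0.0, 0.0])
    assert len(merge_reblinks(table, anchor="first")) == 1
    with pytest.raises(ValueError):
        merge_reblinks(table, anchor="median")


def test_merge_empty_table():
    merged = merge_reblinks(make_table([], [], []))
    assert len(merged) == 0 and "n_merged" in merged.columns


# --------------------------------------------------------------------------
# Region cropping

def test_crop_half_open_boundaries():
    table = make_table(frame=[1, 2, 3, 4],
                       x_nm=[100.0, 200.0, 100.0, 150.0],
                       y_nm=[100.0, 100.0, 200.0, 150.0])
    pattern = crop_region(table, Rect(100, 100, 200, 200))
    # x0/y0 included, x1/y1 excluded
    assert pattern.n == 2
    np.testing.assert_allclose(sorted(pattern.xy[:, 0]), [0.0, 50.0])


def test_crop_rebases_origin_and_area():
    table = make_table(frame=[1], x_nm=[1500.0], y_nm=[2500.0])
    pattern = crop_region(table, Rect(1000, 2000, 3000, 5000))
    np.testing.assert_allclose(pattern.xy, [[500.0, 500.0]])
    assert pattern.width_nm == 2000 and pattern.height_nm == 3000
    assert pattern.area_um2 == pytest.approx(6.0)


def test_crop_count_expectation(rng):
    n = 5000
    table = make_table(frame=np.ones(n, int),
                       x_nm=rng.uniform(0, 10000, n),
                       y_nm=rng.uniform(0, 10000, n))
    pattern = crop_region(table, Rect(0, 0, 5000, 5000))
    assert pattern.n == pytest.approx(n / 4, abs=4 * np.sqrt(n * 0.25 * 0.75))
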