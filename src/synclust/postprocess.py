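"""Quality filters, drift correction, re-blink merging and region cropping.

The canonical order of the post-processing chain is
filter -> drift-correct -> merge -> crop; each stage logs what it removed
or combined so reconstructions remain auditable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .types import LOC_COLUMNS, PointPattern, Rect

logger = logging.getLogger(__name__)


@dataclass
class FilterCriteria:
    """Localization quality thresholds.

    Defaults are the published reconstruction filters: photon count
    strictly above 600, PSF sigma within the closed range [50, 200] nm,
    lateral uncertainty strictly below 30 nm.
    """

    min_photons: float = 600.0
    sigma_range_nm: tuple[float, float] = (50.0, 200.0)
    max_uncertainty_nm: float = 30.0

    def __post_init__(self) -> None:
        lo, hi = self.sigma_range_nm
        if min(self.min_photons, lo, self.max_uncertainty_nm) < 0 or hi < lo:
            raise ValueError("criteria bounds must be positive and ordered")


def filter_localizations(table: pd.DataFrame,
                         criteria: FilterCriteria | None = None) -> pd.DataFrame:
    """Keep localizations passing all quality filters, preserving order."""
    criteria = criteria or FilterCriteria()
    if not len(table):
        return table.copy()
    lo, hi = criteria.sigma_range_nm
    pass_photons = table["photons"] > criteria.min_photons
    pass_sigma = (table["sigma_nm"] >= lo) & (table["sigma_nm"] <= hi)
    pass_unc = table["uncertainty_nm"] < criteria.max_uncertainty_nm
    keep = pass_photons & pass_sigma & pass_unc
    logger.info("filter: removed %d by photons, %d by sigma, %d by uncertainty; kept %d/%d",
                int((~pass_photons).sum()), int((~pass_sigma).sum()),
                int((~pass_unc).sum()), int(keep.sum()), len(table))
    return table[keep].reset_index(drop=True)


@dataclass
class DriftTrack:
    """Per-frame (dx, dy) displacement relative to the first temporal bin."""

    frames: np.ndarray   # contiguous integer frame range covered
    dx_nm: np.ndarray
    dy_nm: np.ndarray

    def lookup(self, frame: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        frame = np.asarray(frame)
        if frame.min() < self.frames[0] or frame.max() > self.frames[-1]:
            raise ValueError("frame outside drift track range")
        idx = (frame - self.frames[0]).astype(int)
        return self.dx_nm[idx], self.dy_nm[idx]


class DriftEstimationError(RuntimeError):
    pass


def _parabolic_offset(c: np.ndarray) -> float:
    """Sub-bin peak offset from three correlation samples."""
    denom = c[0] - 2.0 * c[1] + c[2]
    if denom == 0:
        return 0.0
    return float(np.clip(0.5 * (c[0] - c[2]) / denom, -1, 1))


def _render_histogram(x: np.ndarray, y: np.ndarray, bin_nm: float,
                      extent: tuple[float, float, float, float]) -> np.ndarray:
    x0, x1, y0, y1 = extent
    nx = max(int(np.ceil((x1 - x0) / bin_nm)), 1)
    ny = max(int(np.ceil((y1 - y0) / bin_nm)), 1)
    hist, _, _ = np.histogram2d(y, x, bins=(ny, nx),
                                range=((y0, y0 + ny * bin_nm), (x0, x0 + nx * bin_nm)))
    return hist


def _correlate_bins(x: np.ndarray, y: np.ndarray, frames: np.ndarray,
                    edges: np.ndarray, bin_nm: float) -> np.ndarray:
    """(n_bins, 2) histogram cross-correlation offsets of bin k vs bin 1."""
    extent = (float(x.min()), float(x.max()) + bin_nm,
              float(y.min()), float(y.max()) + bin_nm)
    hists = []
    for k in range(len(edges) - 1):
        sel = (frames >= edges[k]) & (frames < edges[k + 1])
        if sel.sum() < 10:
            raise DriftEstimationError(
                f"temporal bin {k + 1} has fewer than 10 localizations")
        hists.append(_render_histogram(x[sel], y[sel], bin_nm, extent))
    ref = hists[0] - hists[0].mean()
    offsets = [(0.0, 0.0)]
    for k in range(1, len(hists)):
        cur = hists[k] - hists[k].mean()
        corr = fftconvolve(cur, ref[::-1, ::-1], mode="full")
        pr, pc = np.unravel_index(np.argmax(corr), corr.shape)
        dr = float(pr - (ref.shape[0] - 1))
        dc = float(pc - (ref.shape[1] - 1))
        if 0 < pr < corr.shape[0] - 1:
            dr += _parabolic_offset(corr[pr - 1: pr + 2, pc])
        if 0 < pc < corr.shape[1] - 1:
            dc += _parabolic_offset(corr[pr, pc - 1: pc + 2])
        offsets.append((dc * bin_nm, dr * bin_nm))
    return np.asarray(offsets)


def _interp_with_slope_ends(frames: np.ndarray, mids: np.ndarray,
                            offs: np.ndarray) -> np.ndarray:
    """Linear interpolation between midpoints, linearly extrapolated ends
    (used only inside the iterative refinement, where a flat end segment
    would leave residual within-bin smear)."""
    out = np.interp(frames, mids, offs)
    if len(mids) >= 2:
        lo = frames < mids[0]
        hi = frames > mids[-1]
        s_lo = (offs[1] - offs[0]) / (mids[1] - mids[0])
        s_hi = (offs[-1] - offs[-2]) / (mids[-1] - mids[-2])
        out[lo] = offs[0] + s_lo * (frames[lo] - mids[0])
        out[hi] = offs[-1] + s_hi * (frames[hi] - mids[-1])
    return out


def estimate_drift(table: pd.DataFrame, n_bins: int = 3,
                   magnification: float = 5.0,
                   pixel_size_nm: float = 100.0,
                   n_refinements: int = 3) -> DriftTrack:
    """Estimate drift by cross-correlation of temporally binned renderings.

    Frames are split into ``n_bins`` equal temporal bins; each bin is
    rendered as a 2-D histogram with bin size ``pixel_size_nm /
    magnification``.  The cross-correlation of bin k against bin 1 is
    maximized with a 3x3 parabolic sub-bin peak fit.  Because drift within
    a bin smears its rendering (and so broadens the correlation peak), the
    estimate is refined iteratively: the current midpoint offsets are
    interpolated, subtracted, and the sharpened bins re-correlated; the
    offsets accumulate over ``n_refinements`` passes.  The returned
    per-frame track linearly interpolates between the bin-midpoint offsets
    and is constant beyond the first/last midpoints.
    """
    if not len(table):
        raise DriftEstimationError("empty localization table")
    if len(table) < n_bins * 100:
        warnings.warn("fewer than 100 localizations per drift bin; "
                      "estimate may be unreliable", stacklevel=2)
    bin_nm = pixel_size_nm / magnification
    frames = table["frame"].to_numpy()
    f_min, f_max = int(frames.min()), int(frames.max())
    edges = np.linspace(f_min, f_max + 1, n_bins + 1)
    mids = 0.5 * (edges[:-1] + edges[1:] - 1)

    x0 = table["x_nm"].to_numpy(dtype=float)
    y0 = table["y_nm"].to_numpy(dtype=float)
    total = np.zeros((n_bins, 2))
    x, y = x0, y0
    for _ in range(max(n_refinements, 1)):
        total += _correlate_bins(x, y, frames, edges, bin_nm)
        x = x0 - _interp_with_slope_ends(frames, mids, total[:, 0])
        y = y0 - _interp_with_slope_ends(frames, mids, total[:, 1])

    all_frames = np.arange(f_min, f_max + 1)
    dx = np.interp(all_frames, mids, total[:, 0])  # constant extrapolation
    dy = np.interp(all_frames, mids, total[:, 1])
    logger.info("drift: %d bins, endpoint offset (%.1f, %.1f) nm",
                n_bins, total[-1, 0], total[-1, 1])
    return DriftTrack(all_frames, dx, dy)


def apply_drift(table: pd.DataFrame, drift: DriftTrack) -> pd.DataFrame:
    """Subtract the per-frame drift from the coordinates."""
    out = table.copy()
    if not len(out):
        return out
    dx, dy = drift.lookup(out["frame"].to_numpy())
    out["x_nm"] = out["x_nm"] - dx
    out["y_nm"] = out["y_nm"] - dy
    return out


def merge_reblinks(table: pd.DataFrame, max_distance_nm: float = 50.0,
                   max_gap_frames: int = 20,
                   anchor: str = "centroid") -> pd.DataFrame:
    """Merge re-blinking events of one fluorophore into single molecules.

    Localizations are chained greedily in frame order: an event joins an
    open chain if it lies within ``max_distance_nm`` of the chain's anchor
    (photon-weighted running centroid by default, or the chain's first
    event with ``anchor='first'``) and within ``max_gap_frames`` of the
    chain's last frame.  When several chains qualify the nearest wins, ties
    going to the earliest-opened chain.  Each chain merges to: position and
    sigma = photon-weighted means, photons = sum, frame = first,
    uncertainty = inverse-variance combination, n_merged = chain length.
    """
    if anchor not in ("centroid", "first"):
        raise ValueError("anchor must be 'centroid' or 'first'")
    if not len(table):
        out = table.copy()
        out["n_merged"] = pd.Series(dtype=int)
        return out
    order = np.lexsort((table["x_nm"].to_numpy(), table["frame"].to_numpy()))
    chains: list[dict] = []
    open_idx: list[int] = []
    for i in order:
        row = table.iloc[i]
        f, x, y = int(row["frame"]), row["x_nm"], row["y_nm"]
        open_idx = [j for j in open_idx if f - chains[j]["last_frame"] <= max_gap_frames]
        best, best_d = None, np.inf
        for j in open_idx:
            ch = chains[j]
            ax, ay = ch["anchor"]
            d = np.hypot(x - ax, y - ay)
            if d <= max_distance_nm and d < best_d:
                best, best_d = j, d
        if best is None:
            chains.append({
                "anchor": (x, y), "first_xy": (x, y),
                "wx": x * row["photons"], "wy": y * row["photons"],
                "wsigma": row["sigma_nm"] * row["photons"],
                "photons": row["photons"],
                "inv_var": 1.0 / row["uncertainty_nm"] ** 2,
                "first_frame": f, "last_frame": f, "n": 1,
            })
            open_idx.append(len(chains) - 1)
        else:
            ch = chains[best]
            ch["wx"] += x * row["photons"]
            ch["wy"] += y * row["photons"]
            ch["wsigma"] += row["sigma_nm"] * row["photons"]
            ch["photons"] += row["photons"]
            ch["inv_var"] += 1.0 / row["uncertainty_nm"] ** 2
            ch["last_frame"] = f
            ch["n"] += 1
            if anchor == "centroid":
                ch["anchor"] = (ch["wx"] / ch["photons"], ch["wy"] / ch["photons"])
    rows = []
    for ch in chains:
        rows.append({
            "frame": ch["first_frame"],
            "x_nm": ch["wx"] / ch["photons"],
            "y_nm": ch["wy"] / ch["photons"],
            "sigma_nm": ch["wsigma"] / ch["photons"],
            "photons": ch["photons"],
            "uncertainty_nm": ch["inv_var"] ** -0.5,
            "n_merged": ch["n"],
        })
    out = pd.DataFrame(rows, columns=LOC_COLUMNS + ["n_merged"])
    out = out.sort_values(["frame", "x_nm"], kind="mergesort").reset_index(drop=True)
    logger.info("merge: %d events -> %d molecules", len(table), len(out))
    return out


def crop_region(table: pd.DataFrame, region: Rect) -> PointPattern:
    """Crop localizations to a half-open rectangle (coordinates re-expressed
    relative to the region origin); the region area travels with the pattern."""
    inside = region.contains(table["x_nm"].to_numpy(), table["y_nm"].to_numpy()) \
        if len(table) else np.zeros(0, bool)
    xy = np.column_stack([table["x_nm"].to_numpy()[inside] - region.x0,
                          table["y_nm"].to_numpy()[inside] - region.y0]) \
        if len(table) else np.empty((0, 2))
    return PointPattern(xy, region.width, region.height)
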