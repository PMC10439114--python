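"""Two-channel nanoscale colocalization statistics.

Three complementary measures of cross-channel registration on localization
data — coordinate-based colocalization (CBC) scores, nearest-neighbour
distances (NND) and Voronoi-tessellation correlations (Spearman + Mander's)
— plus a coordinate-reversal negative control and pixel-level Pearson
correlation for diffraction-limited images.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import QhullError, Voronoi, cKDTree
from scipy.stats import rankdata, spearmanr

from .types import PixelImage, PointPattern

logger = logging.getLogger(__name__)

UM2_PER_NM2 = 1e-6


# --------------------------------------------------------------------------
# Coordinate-based colocalization

@dataclass
class CBCResult:
    """Per-localization CBC scores for channel A (in [-1, 1])."""

    scores: np.ndarray
    nnd_nm: np.ndarray
    r_max_nm: float

    def fraction_above(self, cutoff: float = 0.8) -> float:
        """Fraction of localizations scoring above ``cutoff`` (scores > 0.8
        are conventionally read as strong colocalization)."""
        if not len(self.scores):
            return 0.0
        return float(np.mean(self.scores > cutoff))

    @property
    def mean_score(self) -> float:
        return float(self.scores.mean()) if len(self.scores) else 0.0


def _cumulative_counts(query_xy: np.ndarray, tree: cKDTree,
                       r_grid: np.ndarray) -> np.ndarray:
    """(n, n_radii) cumulative neighbour counts within each radius.

    Zero-distance matches are dropped: the query point itself for the
    same-channel counts, and coincident localizations (e.g. a duplicated
    channel) for the cross-channel counts, so that a channel compared with
    an exact copy of itself sees identical density profiles.
    """
    n = len(query_xy)
    counts = np.zeros((n, len(r_grid)), dtype=float)
    neighbours = tree.query_ball_point(query_xy, r_grid[-1])
    for i, idx in enumerate(neighbours):
        if not idx:
            continue
        d = np.hypot(*(tree.data[idx] - query_xy[i]).T)
        d = d[d > 0]
        if len(d):
            counts[i] = np.searchsorted(np.sort(d), r_grid, side="right")
    return counts


def _rowwise_spearman(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Spearman rank correlation per row; NaN where either row is constant."""
    ra = rankdata(a, axis=1)
    rb = rankdata(b, axis=1)
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    sa = np.sqrt((ra ** 2).sum(axis=1))
    sb = np.sqrt((rb ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (ra * rb).sum(axis=1) / (sa * sb)
    return rho


def cbc(a: PointPattern, b: PointPattern, r_max_nm: float = 500.0,
        n_steps: int = 20) -> CBCResult:
    """Coordinate-based colocalization scores of channel A against B.

    For each localization the distributions of same-channel and
    cross-channel neighbour densities over a radius grid,
    ``D(r_k) = N(r_k) / N(r_max) * r_max^2 / r_k^2``, are rank-correlated;
    the Spearman coefficient is then damped by ``exp(-d_NN / r_max)`` with
    d_NN the distance to the nearest B localization.  Undefined
    correlations (constant profiles, no neighbours) score 0.
    """
    if a.n < 10 or b.n < 10:
        raise ValueError("CBC needs at least 10 localizations per channel")
    r_grid = np.arange(1, n_steps + 1) * (r_max_nm / n_steps)
    tree_a = cKDTree(a.xy)
    tree_b = cKDTree(b.xy)
    n_aa = _cumulative_counts(a.xy, tree_a, r_grid)
    n_ab = _cumulative_counts(a.xy, tree_b, r_grid)
    scale = r_max_nm ** 2 / r_grid ** 2

    def _profile(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        total = counts[:, -1]
        valid = total > 0
        prof = np.zeros_like(counts)
        prof[valid] = counts[valid] / total[valid, None] * scale[None, :]
        return prof, valid

    d_aa, valid_a = _profile(n_aa)
    d_ab, valid_b = _profile(n_ab)
    rho = _rowwise_spearman(d_aa, d_ab)
    rho[~(valid_a & valid_b)] = 0.0
    rho = np.nan_to_num(rho, nan=0.0)
    nnd_a, _ = tree_b.query(a.xy, k=1)
    scores = rho * np.exp(-nnd_a / r_max_nm)
    return CBCResult(scores, nnd_a, r_max_nm)


# --------------------------------------------------------------------------
# Nearest-neighbour distances

@dataclass
class NNDResult:
    """Cross-channel nearest-neighbour distances (nm) with 10-nm histogram."""

    distances_nm: np.ndarray
    bin_edges_nm: np.ndarray
    histogram: np.ndarray

    @property
    def modal_bin_centre_nm(self) -> float:
        i = int(np.argmax(self.histogram))
        return float(0.5 * (self.bin_edges_nm[i] + self.bin_edges_nm[i + 1]))

    @property
    def median_nm(self) -> float:
        return float(np.median(self.distances_nm))


def nnd(a: PointPattern, b: PointPattern, bin_nm: float = 10.0) -> NNDResult:
    """Distance from each A localization to its nearest B localization."""
    if b.n < 1:
        raise ValueError("channel B is empty")
    d, _ = cKDTree(b.xy).query(a.xy, k=1)
    top = max(float(d.max()), bin_nm) if len(d) else bin_nm
    edges = np.arange(0, top + bin_nm, bin_nm)
    hist, edges = np.histogram(d, bins=edges)
    return NNDResult(d, edges, hist)


def randomize_control(pattern: PointPattern, mode: str = "reflect") -> PointPattern:
    """Matched negative control with intra-channel structure preserved.

    'reflect' mirrors every coordinate through the region centre (an
    involution), destroying cross-channel registration while keeping the
    pattern's own clustering and count; 'shuffle-pairing' re-pairs the x
    list with the reversed y list.
    """
    x, y = pattern.xy[:, 0], pattern.xy[:, 1]
    w, h = pattern.width_nm, pattern.height_nm
    if mode == "reflect":
        xy = np.column_stack([(w - x) % w, (h - y) % h])
    elif mode == "shuffle-pairing":
        xy = np.column_stack([x, y[::-1]])
    else:
        raise ValueError("mode must be 'reflect' or 'shuffle-pairing'")
    return PointPattern(xy, w, h)


# --------------------------------------------------------------------------
# Voronoi tessellation

def _polygon_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def voronoi_densities(pattern: PointPattern, _jitter_nm: float = 0.01) -> np.ndarray:
    """First-rank Voronoi density (1 / own-cell area, per um^2) per point.

    The tessellation is clipped exactly to the region by augmenting the
    pattern with its mirror images across all four region edges, which makes
    every original cell bounded by the region boundary.  Degenerate
    (collinear) inputs are jittered by 0.01 nm with a warning.
    """
    if pattern.n < 4:
        raise ValueError("tessellation needs at least 4 points")
    xy = pattern.xy
    w, h = pattern.width_nm, pattern.height_nm

    def _attempt(points: np.ndarray) -> np.ndarray:
        mirrored = np.vstack([
            points,
            np.column_stack([-points[:, 0], points[:, 1]]),
            np.column_stack([2 * w - points[:, 0], points[:, 1]]),
            np.column_stack([points[:, 0], -points[:, 1]]),
            np.column_stack([points[:, 0], 2 * h - points[:, 1]]),
        ])
        vor = Voronoi(mirrored)
        areas = np.empty(len(points))
        for i in range(len(points)):
            region = vor.regions[vor.point_region[i]]
            if -1 in region or not region:
                raise QhullError("unbounded cell")  # mirror trick failed
            areas[i] = _polygon_area(vor.vertices[region])
        return areas

    try:
        areas = _attempt(xy)
    except QhullError:
        warnings.warn("degenerate point configuration; jittering by 0.01 nm",
                      stacklevel=2)
        rng = np.random.default_rng(0)
        areas = _attempt(xy + rng.normal(0, _jitter_nm, xy.shape))
    return 1.0 / (areas * UM2_PER_NM2)


@dataclass
class TessellationResult:
    """Tessellation colocalization summary for a channel pair."""

    spearman: float
    manders_a: float
    manders_b: float
    densities_a: np.ndarray   # per-A-point own-cell densities
    densities_b: np.ndarray


def tessellation_correlation(a: PointPattern, b: PointPattern,
                             seg_factor: float = 2.0) -> TessellationResult:
    """Spearman and Mander's coefficients of channel tessellations.

    Every localization of A union B is assigned the Voronoi-cell density of
    each channel's tessellation (the cell of its nearest same/cross-channel
    seed); the Spearman coefficient correlates those two density fields.
    For Mander's, each channel's object mask is the union of its cells with
    density >= ``seg_factor`` times the channel mean; M_A is the fraction of
    A localizations falling inside B's mask (M_B symmetric).
    """
    dens_a = voronoi_densities(a)
    dens_b = voronoi_densities(b)
    tree_a = cKDTree(a.xy)
    tree_b = cKDTree(b.xy)
    everything = np.vstack([a.xy, b.xy])
    _, own_a = tree_a.query(everything, k=1)
    _, own_b = tree_b.query(everything, k=1)
    delta_a = dens_a[own_a]
    delta_b = dens_b[own_b]
    rho = spearmanr(delta_a, delta_b).statistic

    mask_a = dens_a >= seg_factor * dens_a.mean()
    mask_b = dens_b >= seg_factor * dens_b.mean()

    def _manders(points: np.ndarray, other_tree: cKDTree,
                 other_mask: np.ndarray) -> float:
        if not other_mask.any():
            warnings.warn("empty tessellation mask; Mander's set to 0",
                          stacklevel=3)
            return 0.0
        _, nearest = other_tree.query(points, k=1)
        return float(other_mask[nearest].mean())

    m_a = _manders(a.xy, tree_b, mask_b)
    m_b = _manders(b.xy, tree_a, mask_a)
    return TessellationResult(float(rho), m_a, m_b, dens_a, dens_b)


# --------------------------------------------------------------------------
# Pixel-level correlation and trend testing

def pearson_pixel(image_a: PixelImage, image_b: PixelImage,
                  mask: np.ndarray | None = None) -> float:
    """Pearson correlation of two images over masked pixels."""
    if image_a.values.shape != image_b.values.shape:
        raise ValueError("images must have equal shape")
    if mask is None:
        mask = image_a.mask if image_a.mask is not None else \
            np.ones(image_a.values.shape, dtype=bool)
    va = image_a.values[mask]
    vb = image_b.values[mask]
    if len(va) < 2 or va.std() == 0 or vb.std() == 0:
        raise ValueError("Pearson undefined: too few pixels or zero variance")
    return float(np.corrcoef(va, vb)[0, 1])


def permutation_trend_test(levels: np.ndarray, values: np.ndarray,
                           n_perm: int = 10000, seed: int = 0) -> tuple[float, float]:
    """One-sided permutation test for an increasing trend.

    Returns the Spearman correlation between condition level and measured
    value and the permutation p-value for rho > 0.
    """
    levels = np.asarray(levels, float)
    values = np.asarray(values, float)
    rho = spearmanr(levels, values).statistic
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(values)
        if spearmanr(levels, perm).statistic >= rho:
            count += 1
    return float(rho), (count + 1) / (n_perm + 1)
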