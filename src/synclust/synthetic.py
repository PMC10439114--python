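"""Synthetic data with known ground truth for every pipeline input.

The generators emulate the acquisition conditions of a TIRF/dSTORM study of
receptor clustering at the immune synapse: clustered (Thomas / Neyman-Scott)
and completely-spatially-random localization patterns at realistic synapse
densities, two-channel patterns with a tunable colocalized fraction of
cluster centres, blinking-emitter movies (integrated-Gaussian PSF, Poisson
shot noise, re-blinking, linear stage drift), synapse images with a known
fraction of bright pixels, and single-exponential fluorescence-recovery
traces.

All generators take an integer seed and are bit-reproducible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .types import FRAPTrace, PixelImage, PointPattern, RawMovie

logger = logging.getLogger(__name__)

UM2_TO_NM2 = 1e6


@dataclass
class ThomasParams:
    """Parameters of a Thomas (Neyman-Scott) cluster process.

    kappa_per_um2
        Intensity of the Poisson parent (cluster-centre) process.
    mu
        Mean number of offspring (localizations) per parent.
    sigma_nm
        Isotropic Gaussian scatter of offspring around their parent;
        sets the cluster radius scale.
    width_um, height_um
        Rectangular simulation window.
    """

    kappa_per_um2: float
    mu: float
    sigma_nm: float
    width_um: float = 5.0
    height_um: float = 5.0

    def __post_init__(self) -> None:
        if min(self.kappa_per_um2, self.mu, self.sigma_nm) <= 0:
            raise ValueError("kappa, mu and sigma must be positive")
        if self.width_um <= 0 or self.height_um <= 0:
            raise ValueError("window sides must be positive")

    @property
    def width_nm(self) -> float:
        return self.width_um * 1e3

    @property
    def height_nm(self) -> float:
        return self.height_um * 1e3

    @property
    def expected_count(self) -> float:
        return self.kappa_per_um2 * self.mu * self.width_um * self.height_um


def simulate_csr(width_um: float, height_um: float, density_per_um2: float,
                 seed: int) -> PointPattern:
    """Homogeneous Poisson (CSR) pattern: the null model for clustering.

    The count is Poisson(density x area); positions are i.i.d. uniform.
    """
    if width_um <= 0 or height_um <= 0:
        raise ValueError("region must have positive area")
    if density_per_um2 <= 0:
        raise ValueError("density must be positive")
    rng = np.random.default_rng(seed)
    area = width_um * height_um
    n = rng.poisson(density_per_um2 * area)
    xy = rng.uniform((0, 0), (width_um * 1e3, height_um * 1e3), size=(n, 2))
    return PointPattern(xy, width_um * 1e3, height_um * 1e3)


def simulate_thomas(params: ThomasParams, seed: int) -> PointPattern:
    """Thomas cluster process with toroidal wrapping of offspring.

    Parents are Poisson(kappa x area) uniform in the window; each parent
    emits Poisson(mu) offspring scattered i.i.d. Normal(0, sigma^2) per
    axis.  Offspring are wrapped toroidally so the closed-form Ripley K
    (:func:`thomas_k_closed_form`) holds without edge terms.
    """
    rng = np.random.default_rng(seed)
    w, h = params.width_nm, params.height_nm
    area_um2 = params.width_um * params.height_um
    n_parents = rng.poisson(params.kappa_per_um2 * area_um2)
    parents = rng.uniform((0, 0), (w, h), size=(n_parents, 2))
    counts = rng.poisson(params.mu, size=n_parents)
    offspring = np.repeat(parents, counts, axis=0)
    offspring = offspring + rng.normal(0, params.sigma_nm, size=offspring.shape)
    offspring[:, 0] %= w
    offspring[:, 1] %= h
    return PointPattern(offspring, w, h)


def thomas_k_closed_form(r_nm: np.ndarray, kappa_per_um2: float,
                         sigma_nm: float) -> np.ndarray:
    """Analytic Ripley K of the Thomas process (nm^2).

    K(r) = pi r^2 + (1/kappa) (1 - exp(-r^2 / (4 sigma^2))).
    """
    r = np.asarray(r_nm, dtype=float)
    kappa_nm = kappa_per_um2 / UM2_TO_NM2
    return np.pi * r ** 2 + (1.0 / kappa_nm) * (1.0 - np.exp(-r ** 2 / (4 * sigma_nm ** 2)))


@dataclass
class TwoChannelTruth:
    """Ground truth for a two-channel simulation."""

    channel_a: PointPattern
    channel_b: PointPattern
    parents_a: np.ndarray          # (p, 2) nm
    parents_b: np.ndarray          # (q, 2) nm
    shared_b: np.ndarray           # boolean over parents_b: reused from A
    coloc_fraction: float
    offset_nm: float


def simulate_two_channel(base_params: ThomasParams, coloc_fraction: float,
                         offset_nm: float, seed: int) -> TwoChannelTruth:
    """Two clustered channels with a tunable colocalized fraction.

    Channel A is a Thomas process.  Channel B reuses ``coloc_fraction`` of
    A's cluster centres (each displaced by Normal(0, offset_nm^2) per axis)
    and draws independent centres for the remainder, then scatters its own
    offspring.  The parent pairing is recorded as ground truth.
    """
    if not 0 <= coloc_fraction <= 1:
        raise ValueError("coloc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    w, h = base_params.width_nm, base_params.height_nm
    area_um2 = base_params.width_um * base_params.height_um

    n_parents_a = rng.poisson(base_params.kappa_per_um2 * area_um2)
    parents_a = rng.uniform((0, 0), (w, h), size=(n_parents_a, 2))

    n_shared = int(round(coloc_fraction * n_parents_a))
    shared_idx = rng.choice(n_parents_a, size=n_shared, replace=False) if n_shared else np.empty(0, int)
    shared = parents_a[shared_idx] + rng.normal(0, offset_nm, size=(n_shared, 2))
    n_indep = n_parents_a - n_shared
    indep = rng.uniform((0, 0), (w, h), size=(n_indep, 2))
    parents_b = np.vstack([shared, indep]) if n_parents_a else np.empty((0, 2))
    shared_b = np.zeros(len(parents_b), dtype=bool)
    shared_b[: n_shared] = True

    def _offspring(parents: np.ndarray) -> np.ndarray:
        counts = rng.poisson(base_params.mu, size=len(parents))
        pts = np.repeat(parents, counts, axis=0)
        pts = pts + rng.normal(0, base_params.sigma_nm, size=pts.shape)
        pts[:, 0] %= w
        pts[:, 1] %= h
        return pts

    a = PointPattern(_offspring(parents_a), w, h)
    b = PointPattern(_offspring(parents_b), w, h)
    return TwoChannelTruth(a, b, parents_a, parents_b, shared_b,
                           coloc_fraction, offset_nm)


# --------------------------------------------------------------------------
# Blinking-emitter movies

@dataclass
class EmitterGroundTruth:
    """True emitter states behind a simulated movie.

    positions_nm : (n_emitters, 2) true positions (drift-free).
    on : (n_frames, n_emitters) boolean on/off states.
    photons : photons emitted per on-frame, per emitter.
    drift_nm : (n_frames, 2) stage-drift track added to all positions.
    """

    positions_nm: np.ndarray
    on: np.ndarray
    photons: np.ndarray
    drift_nm: np.ndarray

    def __post_init__(self) -> None:
        self.positions_nm = np.atleast_2d(np.asarray(self.positions_nm, float))
        self.on = np.atleast_2d(np.asarray(self.on, bool))
        self.photons = np.asarray(self.photons, float)
        self.drift_nm = np.atleast_2d(np.asarray(self.drift_nm, float))
        if self.on.shape[1] != len(self.positions_nm):
            raise ValueError("on-state matrix must have one column per emitter")
        if len(self.drift_nm) != len(self.on):
            raise ValueError("drift track must cover every frame")
        if (self.photons <= 0).any():
            raise ValueError("photons per on-frame must be positive")

    @property
    def n_frames(self) -> int:
        return self.on.shape[0]

    @property
    def n_emitters(self) -> int:
        return self.on.shape[1]


def random_emitter_truth(n_emitters: int, field_nm: tuple[float, float],
                         n_frames: int, photons: float, seed: int,
                         on_prob: float = 0.1, mean_on_run: float = 2.0,
                         drift_nm_per_frame: tuple[float, float] = (0.0, 0.0),
                         margin_nm: float = 800.0,
                         min_separation_nm: float = 0.0) -> EmitterGroundTruth:
    """Random emitters with geometric-run blinking and linear drift.

    Emitters switch on with probability ``on_prob`` per dark frame and stay
    on for a geometric run of mean ``mean_on_run`` frames.  ``margin_nm``
    keeps emitters away from the field border so every blink is fittable.
    """
    rng = np.random.default_rng(seed)
    w, h = field_nm
    positions = np.empty((n_emitters, 2))
    k = 0
    attempts = 0
    while k < n_emitters:
        p = rng.uniform((margin_nm, margin_nm), (w - margin_nm, h - margin_nm))
        if min_separation_nm > 0 and k:
            if np.min(np.hypot(*(positions[:k] - p).T)) < min_separation_nm:
                attempts += 1
                if attempts > 10000:
                    raise ValueError("cannot place emitters with requested separation")
                continue
        positions[k] = p
        k += 1
    on = np.zeros((n_frames, n_emitters), dtype=bool)
    p_off = 1.0 / mean_on_run
    for j in range(n_emitters):
        state = False
        for t in range(n_frames):
            if state:
                state = rng.random() >= p_off
            else:
                state = rng.random() < on_prob
            on[t, j] = state
    frames = np.arange(n_frames)[:, None]
    drift = frames * np.asarray(drift_nm_per_frame, float)[None, :]
    return EmitterGroundTruth(positions, on, np.full(n_emitters, photons), drift)


def _integrated_gaussian(positions_px: np.ndarray, photons: np.ndarray,
                         sigma_px: float, shape: tuple[int, int]) -> np.ndarray:
    """Sum of expected integrated-Gaussian spots on a pixel grid."""
    nrow, ncol = shape
    img = np.zeros(shape)
    edges_x = np.arange(ncol + 1)
    edges_y = np.arange(nrow + 1)
    s = sigma_px * np.sqrt(2.0)
    for (x, y), n_ph in zip(positions_px, photons):
        fx = 0.5 * (erf((edges_x - x) / s))
        fy = 0.5 * (erf((edges_y - y) / s))
        img += n_ph * np.outer(np.diff(fy), np.diff(fx))
    return img


def simulate_blink_movie(truth: EmitterGroundTruth, field_px: tuple[int, int],
                         pixel_size_nm: float, psf_sigma_nm: float,
                         background_photons: float, seed: int,
                         poisson_noise: bool = True) -> RawMovie:
    """Render a blinking-emitter movie.

    Each on-emitter contributes an integrated 2-D Gaussian (erf difference
    per pixel) scaled to its photons; a constant background is added and
    Poisson noise applied per pixel.  The drift track displaces emitter
    positions per frame.  Emitters outside the field are skipped with a
    warning.
    """
    if psf_sigma_nm <= 0:
        raise ValueError("psf_sigma_nm must be positive")
    rng = np.random.default_rng(seed)
    nrow, ncol = field_px
    sigma_px = psf_sigma_nm / pixel_size_nm
    frames = np.empty((truth.n_frames, nrow, ncol))
    field_w = ncol * pixel_size_nm
    field_h = nrow * pixel_size_nm
    for t in range(truth.n_frames):
        active = np.flatnonzero(truth.on[t])
        pos = truth.positions_nm[active] + truth.drift_nm[t]
        inside = (pos[:, 0] >= 0) & (pos[:, 0] < field_w) & \
                 (pos[:, 1] >= 0) & (pos[:, 1] < field_h)
        if not inside.all():
            warnings.warn("emitter outside field skipped", stacklevel=2)
        pos = pos[inside] / pixel_size_nm
        expected = _integrated_gaussian(pos, truth.photons[active][inside],
                                        sigma_px, (nrow, ncol))
        expected += background_photons
        frames[t] = rng.poisson(expected) if poisson_noise else expected
    return RawMovie(frames, pixel_size_nm=pixel_size_nm)


# --------------------------------------------------------------------------
# FRAP traces and synapse images

def simulate_frap_trace(t_half_s: float, mobile_fraction: float,
                        noise_sd: float, duration_s: float, dt_s: float,
                        seed: int, bleach_time_s: float = 10.0) -> FRAPTrace:
    """Single-exponential recovery trace.

    Post-bleach intensity follows
    ``mobile_fraction * (1 - 2**(-t / t_half_s))`` (t measured from the
    bleach) plus Gaussian noise; pre-bleach samples are exactly 1.
    """
    if t_half_s <= 0:
        raise ValueError("t_half_s must be positive")
    if not 0 < mobile_fraction <= 1:
        raise ValueError("mobile_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    time = np.arange(0.0, duration_s + 0.5 * dt_s, dt_s)
    intensity = np.ones_like(time)
    post = time >= bleach_time_s
    t_rel = time[post] - bleach_time_s
    intensity[post] = mobile_fraction * (1.0 - 2.0 ** (-t_rel / t_half_s))
    if noise_sd > 0:
        intensity[post] += rng.normal(0, noise_sd, size=post.sum())
    return FRAPTrace(time, intensity, bleach_time_s)


def frap_model(t: np.ndarray, mobile_fraction: float, t_half_s: float) -> np.ndarray:
    """Closed-form recovery curve used by both generator and fitter tests."""
    return mobile_fraction * (1.0 - 2.0 ** (-np.asarray(t, float) / t_half_s))


def simulate_synapse_image(shape: tuple[int, int], cell_mask: np.ndarray,
                           bright_fraction: float, contrast: float,
                           seed: int, base: float = 100.0,
                           pixel_size_nm: float = 100.0
                           ) -> tuple[PixelImage, np.ndarray]:
    """Synapse image with a known fraction of bright clustered pixels.

    Inside the mask, ``bright_fraction`` of the pixels are set to
    ``contrast * base`` and the rest to ``base``; masked-out pixels are 0.
    Returns the image and the ground-truth bright-pixel mask.
    """
    if not 0 <= bright_fraction < 1:
        raise ValueError("bright_fraction must be in [0, 1)")
    if contrast <= 1.5:
        raise ValueError("contrast must exceed 1.5")
    rng = np.random.default_rng(seed)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if cell_mask.shape != tuple(shape):
        raise ValueError("mask shape must equal image shape")
    values = np.zeros(shape)
    values[cell_mask] = base
    idx = np.flatnonzero(cell_mask.ravel())
    n_bright = int(round(bright_fraction * idx.size))
    bright = rng.choice(idx, size=n_bright, replace=False)
    flat = values.ravel()
    flat[bright] = contrast * base
    bright_mask = np.zeros(values.size, dtype=bool)
    bright_mask[bright] = True
    return (PixelImage(values, pixel_size_nm=pixel_size_nm, mask=cell_mask),
            bright_mask.reshape(shape))
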