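"""Single-molecule reconstruction: wavelet detection + integrated-Gaussian MLE.

The recipe follows the standard SMLM reconstruction chain: each frame is
decomposed with an a-trous B-spline wavelet (order 3, scale 2); blink
candidates are local maxima of the second wavelet plane above a threshold of
``threshold_multiplier`` times the standard deviation of the first plane
(8-neighbourhood connectivity); each candidate is fitted with an integrated
Gaussian PSF under a Poisson maximum-likelihood model (fitting radius 5
pixels, initial sigma 1.6 pixels).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import minimize
from scipy.special import erf
from scipy.stats import norm

from .types import LOC_COLUMNS, RawMovie, empty_localization_table

logger = logging.getLogger(__name__)

#: Order-3 B-spline kernel for the a-trous decomposition.
_K1 = np.array([1, 4, 6, 4, 1], dtype=float) / 16.0
#: Scale-2 kernel: the same kernel dilated with one inserted zero.
_K2 = np.array([1, 0, 4, 0, 6, 0, 4, 0, 1], dtype=float) / 16.0

SIGMA_VALID_PX = (0.3, 10.0)


@dataclass
class WaveletPlanes:
    """Band-pass planes of the a-trous decomposition (same shape as input)."""

    F1: np.ndarray
    F2: np.ndarray
    V2: np.ndarray  # residual low-pass; F1 + F2 + V2 == input


@dataclass(frozen=True)
class Candidate:
    """Integer-pixel local maximum in one frame."""

    frame: int
    row: int
    col: int


def _sep_convolve(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    out = ndimage.convolve1d(img, kernel, axis=0, mode="mirror")
    return ndimage.convolve1d(out, kernel, axis=1, mode="mirror")


def wavelet_filter(frame: np.ndarray) -> WaveletPlanes:
    """A-trous B-spline decomposition, order 3, scale 2.

    V1 = k * V0 and V2 = k(up 2) * V1 with the separable kernel
    k = [1,4,6,4,1]/16; the band-pass planes are F1 = V0 - V1 and
    F2 = V1 - V2.  Boundaries are mirrored.  By construction
    F1 + F2 + V2 telescopes back to the input.
    """
    v0 = np.asarray(frame, dtype=float)
    if v0.ndim != 2 or min(v0.shape) < 8:
        raise ValueError("frame must be 2-D and at least 8x8")
    if not np.all(np.isfinite(v0)):
        raise ValueError("frame contains non-finite pixels")
    v1 = _sep_convolve(v0, _K1)
    v2 = _sep_convolve(v1, _K2)
    return WaveletPlanes(F1=v0 - v1, F2=v1 - v2, V2=v2)


def detect_peaks(planes: WaveletPlanes, threshold_multiplier: float = 2.0,
                 frame_index: int = 1, margin_px: int = 0) -> list[Candidate]:
    """Local maxima of F2 above ``threshold_multiplier * std(F1)``.

    A pixel qualifies if no 8-neighbour exceeds it; plateaus of equal value
    yield a single candidate at their lexicographically-first (row, col)
    pixel.  ``margin_px`` suppresses candidates too close to the border to
    be fitted.
    """
    f2 = planes.F2
    threshold = threshold_multiplier * planes.F1.std()
    local_max = f2 >= ndimage.maximum_filter(f2, size=3, mode="nearest")
    mask = local_max & (f2 > threshold)
    if margin_px > 0:
        border = np.zeros_like(mask)
        border[margin_px:-margin_px or None, margin_px:-margin_px or None] = True
        mask &= border
    if not mask.any():
        return []
    # collapse 8-connected plateaus to their first pixel in row-major order
    labels, n_lab = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    candidates = []
    for lab in range(1, n_lab + 1):
        rows, cols = np.nonzero(labels == lab)
        order = np.lexsort((cols, rows))
        candidates.append(Candidate(frame_index, int(rows[order[0]]), int(cols[order[0]])))
    return candidates


class FitError(RuntimeError):
    """Emitter fit failed or violated its preconditions."""


def _psf_pieces(edges: np.ndarray, centre: float, sigma: float):
    """Integrated-Gaussian pixel factors and their derivatives.

    Returns E_j (per-pixel integral), dE/dcentre and dE/dsigma for pixels
    bounded by ``edges``.
    """
    u = (edges - centre) / sigma
    cdf = norm.cdf(u)
    pdf = norm.pdf(u)
    e = np.diff(cdf)
    de_dc = -np.diff(pdf) / sigma
    de_ds = -np.diff(u * pdf) / sigma
    return e, de_dc, de_ds


def fit_emitter(frame: np.ndarray, candidate: Candidate,
                fit_radius_px: int = 5, sigma0_px: float = 1.6,
                pixel_size_nm: float = 100.0) -> dict:
    """Poisson MLE of an integrated-Gaussian emitter around a candidate.

    The model per pixel is ``N * Ex(x, sigma) * Ey(y, sigma) + b`` where
    Ex/Ey are normal-CDF differences over the pixel edges.  Optimization is
    a deterministic bounded quasi-Newton (L-BFGS-B) with analytic gradients
    on (x, y, N, b, sigma); convergence at relative log-likelihood change
    < 1e-8 or 200 iterations.

    Returns a dict with keys x_nm, y_nm, sigma_nm, photons, background,
    uncertainty_nm (localization precision from the MLE approximation
    ``var = (sigma_a^2 / N) * (16/9 + 8 pi sigma_a^2 b / (N a^2))`` with
    ``sigma_a^2 = sigma_psf^2 + a^2 / 12`` and a the pixel size).

    Raises
    ------
    FitError
        If the candidate is too close to the border, the optimizer fails,
        or the fitted sigma leaves (0.3, 10) px.
    """
    r = fit_radius_px
    nrow, ncol = frame.shape
    if not (r <= candidate.row < nrow - r and r <= candidate.col < ncol - r):
        raise FitError("candidate closer than fit_radius to the border")
    window = np.asarray(frame[candidate.row - r: candidate.row + r + 1,
                              candidate.col - r: candidate.col + r + 1], float)
    size = 2 * r + 1
    edges = np.arange(size + 1, dtype=float)
    counts = window

    b0 = max(float(np.median(np.concatenate([window[0], window[-1],
                                             window[1:-1, 0], window[1:-1, -1]]))),
             1e-3)
    n0 = max(float(window.sum() - b0 * window.size), 10.0)
    theta0 = np.array([r + 0.5, r + 0.5, n0, b0, sigma0_px])
    bounds = [(0.5, size - 0.5), (0.5, size - 0.5),
              (1.0, None), (1e-6, None), (0.2, 12.0)]

    def nll_and_grad(theta):
        x, y, n_ph, b, s = theta
        ex, dex_dx, dex_ds = _psf_pieces(edges, x, s)
        ey, dey_dy, dey_ds = _psf_pieces(edges, y, s)
        shape2d = np.outer(ey, ex)
        mu = n_ph * shape2d + b
        mu = np.clip(mu, 1e-12, None)
        resid = 1.0 - counts / mu
        nll = float(np.sum(mu - counts * np.log(mu)))
        g_x = n_ph * np.sum(resid * np.outer(ey, dex_dx))
        g_y = n_ph * np.sum(resid * np.outer(dey_dy, ex))
        g_n = float(np.sum(resid * shape2d))
        g_b = float(np.sum(resid))
        g_s = n_ph * np.sum(resid * (np.outer(ey, dex_ds) + np.outer(dey_ds, ex)))
        return nll, np.array([g_x, g_y, g_n, g_b, g_s])

    res = minimize(nll_and_grad, theta0, jac=True, method="L-BFGS-B",
                   bounds=bounds,
                   options={"ftol": 1e-12, "gtol": 1e-9, "maxiter": 200})
    x, y, n_ph, b, s = res.x
    if not res.success and res.status != 1:  # status 1 = maxiter reached
        raise FitError(f"optimizer failed: {res.message}")
    if not (SIGMA_VALID_PX[0] < s < SIGMA_VALID_PX[1]):
        raise FitError(f"fitted sigma {s:.3f} px outside valid range")

    a = pixel_size_nm
    sigma_nm = s * a
    sigma_a2 = sigma_nm ** 2 + a ** 2 / 12.0
    var = (sigma_a2 / n_ph) * (16.0 / 9.0 + 8.0 * np.pi * sigma_a2 * b / (n_ph * a ** 2))
    return {
        "frame": candidate.frame,
        "x_nm": (candidate.col - r + x) * a,
        "y_nm": (candidate.row - r + y) * a,
        "sigma_nm": sigma_nm,
        "photons": float(n_ph),
        "background": float(b),
        "uncertainty_nm": float(np.sqrt(var)),
    }


def _deduplicate(candidates: list[Candidate], f2: np.ndarray,
                 min_distance_px: float) -> list[Candidate]:
    """Within a frame, keep only the brighter of candidates closer than
    ``min_distance_px`` (prevents double-fitting one molecule)."""
    if len(candidates) < 2:
        return candidates
    order = sorted(range(len(candidates)),
                   key=lambda i: -f2[candidates[i].row, candidates[i].col])
    kept: list[Candidate] = []
    for i in order:
        c = candidates[i]
        if all(np.hypot(c.row - k.row, c.col - k.col) >= min_distance_px
               for k in kept):
            kept.append(c)
    return sorted(kept, key=lambda c: (c.row, c.col))


def reconstruct_movie(movie: RawMovie, threshold_multiplier: float = 2.0,
                      fit_radius_px: int = 5, sigma0_px: float = 1.6) -> pd.DataFrame:
    """Full per-frame reconstruction: wavelet -> detect -> fit.

    Returns a localization table (1-based frame index) sorted by frame then
    x; per-stage counts are logged at INFO.
    """
    rows = []
    n_candidates = n_dropped = 0
    for t in range(movie.n_frames):
        frame = movie.frames[t]
        planes = wavelet_filter(frame)
        cands = detect_peaks(planes, threshold_multiplier,
                             frame_index=t + 1, margin_px=fit_radius_px)
        cands = _deduplicate(cands, planes.F2, fit_radius_px)
        n_candidates += len(cands)
        for cand in cands:
            try:
                loc = fit_emitter(frame, cand, fit_radius_px=fit_radius_px,
                                  sigma0_px=sigma0_px,
                                  pixel_size_nm=movie.pixel_size_nm)
            except FitError:
                n_dropped += 1
                continue
            rows.append(loc)
    logger.info("reconstruct: %d frames, %d candidates, %d fits dropped, %d localizations",
                movie.n_frames, n_candidates, n_dropped, len(rows))
    if not rows:
        return empty_localization_table()
    table = pd.DataFrame(rows)
    table = table.sort_values(["frame", "x_nm"], kind="mergesort").reset_index(drop=True)
    return table[LOC_COLUMNS + ["background"]]
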