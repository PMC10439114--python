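"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* All coordinates and PSF widths are in nanometres; intensities are photons.
  Camera-pixel coordinates appear only inside :mod:`synclust.reconstruction`.
* The field origin is the top-left corner; ``x`` runs along columns, ``y``
  along rows.  Continuous coordinates place pixel centres at
  ``(k + 0.5) * pixel_size_nm``.  All rectangular regions are half-open,
  ``[x0, x1) x [y0, y1)``.
* Localization tables are plain :class:`pandas.DataFrame` objects with the
  canonical columns in :data:`LOC_COLUMNS`; extra columns are carried along
  untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical localization-table columns, in output order.
LOC_COLUMNS = ["frame", "x_nm", "y_nm", "sigma_nm", "photons", "uncertainty_nm"]

#: Columns that must be present for a table to be valid.
MANDATORY_LOC_COLUMNS = tuple(LOC_COLUMNS)


def empty_localization_table() -> pd.DataFrame:
    """Return an empty localization table with the canonical columns."""
    return pd.DataFrame({c: pd.Series(dtype=float) for c in LOC_COLUMNS})


def validate_localization_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the canonical-column contract; return the table unchanged.

    Raises
    ------
    ValueError
        If a mandatory column is missing or a numeric field is non-finite.
    """
    for col in MANDATORY_LOC_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"localization table is missing column {col!r}")
    if len(table):
        values = table[list(MANDATORY_LOC_COLUMNS)].to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("localization table contains non-finite values")
        if "n_merged" in table.columns and (table["n_merged"] < 1).any():
            raise ValueError("n_merged must be >= 1")
    return table


@dataclass
class Rect:
    """Half-open axis-aligned rectangle ``[x0, x1) x [y0, y1)`` in nm."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError("rectangle must have positive width and height")

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def area_nm2(self) -> float:
        return self.width * self.height

    @property
    def area_um2(self) -> float:
        return self.area_nm2 / 1e6

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Half-open inclusion test."""
        x = np.asarray(x)
        y = np.asarray(y)
        return (x >= self.x0) & (x < self.x1) & (y >= self.y0) & (y < self.y1)


@dataclass
class PointPattern:
    """Localizations cropped to a rectangular analysis region.

    ``xy`` is an ``(n, 2)`` array of coordinates in nm, expressed relative
    to the region origin; the unit of all spatial statistics.
    """

    xy: np.ndarray
    width_nm: float
    height_nm: float

    def __post_init__(self) -> None:
        self.xy = np.atleast_2d(np.asarray(self.xy, dtype=float))
        if self.xy.size == 0:
            self.xy = np.empty((0, 2))
        if self.xy.shape[1] != 2:
            raise ValueError("xy must be an (n, 2) array")
        if self.width_nm <= 0 or self.height_nm <= 0:
            raise ValueError("region sides must be positive")
        if len(self.xy):
            x, y = self.xy[:, 0], self.xy[:, 1]
            if (x < 0).any() or (y < 0).any() or (x >= self.width_nm).any() or (
                y >= self.height_nm
            ).any():
                raise ValueError("points must lie inside the half-open region")

    @property
    def n(self) -> int:
        return len(self.xy)

    @property
    def area_nm2(self) -> float:
        return self.width_nm * self.height_nm

    @property
    def area_um2(self) -> float:
        return self.area_nm2 / 1e6

    @property
    def density_per_um2(self) -> float:
        return self.n / self.area_um2


@dataclass
class RawMovie:
    """Acquired frame stack in photon units.

    ``frames`` has shape (frame, row, col).  ``read_movie`` converts camera
    counts to photons via ``(counts - camera_offset) / counts_per_photon``,
    clipped at zero.
    """

    frames: np.ndarray
    pixel_size_nm: float = 100.0
    camera_offset: float = 0.0
    counts_per_photon: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3-D (frame, row, col) array")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if (self.frames < 0).any():
            raise ValueError("photon frames must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class PixelImage:
    """Diffraction-limited image with an optional boolean ROI mask."""

    values: np.ndarray
    pixel_size_nm: float = 100.0
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must equal values shape")


@dataclass
class FRAPTrace:
    """Normalized fluorescence-recovery trace.

    Intensity is scaled so the pre-bleach level is 1 and the first
    post-bleach sample is ~0; ``bleach_time_s`` marks the bleach event on
    the ``time_s`` axis.
    """

    time_s: np.ndarray
    intensity: np.ndarray
    bleach_time_s: float

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time_s.shape != self.intensity.shape:
            raise ValueError("time and intensity must have equal length")
        if not np.all(np.diff(self.time_s) > 0):
            raise ValueError("time must be strictly increasing")

    def post_bleach(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (t - bleach_time, intensity) for samples after the bleach."""
        sel = self.time_s >= self.bleach_time_s
        return self.time_s[sel] - self.bleach_time_s, self.intensity[sel]
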