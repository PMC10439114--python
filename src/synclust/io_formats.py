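"""Readers/writers for every external representation the pipeline touches.

Localization tables are exchanged as ThunderSTORM-style CSV (the de-facto
interchange format for 2-D SMLM data), movies and pixel images as plain
TIFF, and run configuration as YAML.
"""

from __future__ import annotations

import dataclasses
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .types import (
    LOC_COLUMNS,
    MANDATORY_LOC_COLUMNS,
    PixelImage,
    RawMovie,
    validate_localization_table,
)

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file does not conform to the declared dialect."""


#: ThunderSTORM header strings, in canonical order, mapped to our fields.
THUNDERSTORM_HEADERS = {
    "frame": "frame",
    "x [nm]": "x_nm",
    "y [nm]": "y_nm",
    "sigma [nm]": "sigma_nm",
    "intensity [photon]": "photons",
    "uncertainty [nm]": "uncertainty_nm",
}
_CANONICAL_TO_TS = {v: k for k, v in THUNDERSTORM_HEADERS.items()}

DIALECTS = ("thunderstorm_csv", "plain_csv")


def _header_map(dialect: str) -> dict[str, str]:
    if dialect == "thunderstorm_csv":
        return dict(THUNDERSTORM_HEADERS)
    if dialect == "plain_csv":
        return {c: c for c in LOC_COLUMNS}
    raise ValueError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")


def read_localizations(path, dialect: str = "thunderstorm_csv") -> pd.DataFrame:
    """Read a localization table from CSV.

    Mandatory columns are mapped onto the canonical fields
    (frame, x_nm, y_nm, sigma_nm, photons, uncertainty_nm); any other
    columns are preserved untouched after the canonical six.
    """
    header_map = _header_map(dialect)
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    raw.columns = [c.strip().strip('"') for c in raw.columns]

    for external in header_map:
        if external not in raw.columns:
            raise FormatError(
                f"missing mandatory column {external!r} in {dialect} file"
            )

    out = pd.DataFrame(index=raw.index)
    for external, canonical in header_map.items():
        out[canonical] = _to_numeric(raw[external], external)
    for col in raw.columns:
        if col not in header_map:
            out[col] = _to_numeric(raw[col], col)
    out["frame"] = out["frame"].astype(int)
    if "n_merged" in out.columns:
        out["n_merged"] = out["n_merged"].astype(int)
    return validate_localization_table(out) if len(out) else out


def _to_numeric(series: pd.Series, name: str) -> pd.Series:
    converted = pd.to_numeric(series, errors="coerce")
    bad = converted.isna() & series.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(
            f"non-numeric value {series.iloc[row]!r} in column {name!r}, row {row}"
        )
    return converted.astype(float)


def write_localizations(table: pd.DataFrame, path, dialect: str = "thunderstorm_csv") -> None:
    """Write a localization table as CSV in the given dialect.

    Numbers are written as plain decimals ('.' separator, no grouping) with
    6 significant digits, so write -> read round-trips to the printed
    precision and read -> write is byte-stable.
    """
    header_map = _header_map(dialect)
    if len(table):
        validate_localization_table(table)
    extras = [c for c in table.columns if c not in LOC_COLUMNS]
    columns = list(LOC_COLUMNS) + extras
    headers = [_CANONICAL_TO_TS.get(c, c) if dialect == "thunderstorm_csv" else c
               for c in columns]

    buf = io.StringIO()
    if dialect == "thunderstorm_csv":
        buf.write(",".join(f'"{h}"' for h in headers) + "\n")
    else:
        buf.write(",".join(headers) + "\n")
    int_cols = {"frame", "n_merged"}
    for _, row in table.iterrows():
        cells = []
        for c in columns:
            v = row.get(c, np.nan) if c in table.columns else np.nan
            if c in int_cols:
                cells.append(str(int(v)))
            else:
                cells.append(format(float(v), ".6g"))
        buf.write(",".join(cells) + "\n")
    Path(path).write_text(buf.getvalue())


def read_movie(path, pixel_size_nm: float = 100.0, camera_offset: float = 0.0,
               counts_per_photon: float = 1.0) -> RawMovie:
    """Read a single-channel TIFF stack and convert counts to photons.

    photons = (counts - camera_offset) / counts_per_photon, clipped at 0.
    """
    data = tifffile.imread(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise FormatError(
            f"expected a single-channel stack, got array of shape {data.shape}"
        )
    photons = np.clip((data.astype(float) - camera_offset), 0, None) / counts_per_photon
    return RawMovie(photons, pixel_size_nm=pixel_size_nm,
                    camera_offset=camera_offset,
                    counts_per_photon=counts_per_photon)


def write_movie(movie: RawMovie, path) -> None:
    """Write a movie back to TIFF in camera counts (offset/gain re-applied)."""
    counts = movie.frames * movie.counts_per_photon + movie.camera_offset
    tifffile.imwrite(path, np.round(counts).astype(np.uint16),
                     photometric="minisblack")


def read_pixel_image(path, pixel_size_nm: float = 100.0, mask_path=None) -> PixelImage:
    """Read a 2-D TIFF image, optionally with a same-shape mask TIFF."""
    values = np.asarray(tifffile.imread(path), dtype=float)
    if values.ndim != 2:
        raise FormatError("pixel image must be 2-D")
    mask = None
    if mask_path is not None:
        mask = np.asarray(tifffile.imread(mask_path)) > 0
    return PixelImage(values, pixel_size_nm=pixel_size_nm, mask=mask)


def write_pixel_image(image: PixelImage, path) -> None:
    tifffile.imwrite(path, image.values.astype(np.float32))


# --------------------------------------------------------------------------
# Run configuration

@dataclass
class RunConfig:
    """All tunables of every stage, with defaults.

    Thresholds that the reconstruction recipe states explicitly (photon,
    sigma and uncertainty filters; drift binning; merge distance/gap;
    detection threshold, fit radius and initial sigma) default to those
    stated values.  Camera offset/gain have no published defaults and
    default to a photon-counting identity.
    """

    # camera / geometry
    pixel_size_nm: float = 100.0
    camera_offset: float = 0.0
    counts_per_photon: float = 1.0
    # reconstruction
    threshold_multiplier: float = 2.0
    fit_radius_px: int = 5
    sigma0_px: float = 1.6
    # quality filters
    min_photons: float = 600.0
    sigma_range_nm: tuple[float, float] = (50.0, 200.0)
    max_uncertainty_nm: float = 30.0
    # drift correction
    drift_bins: int = 3
    drift_magnification: float = 5.0
    # re-blink merging
    merge_distance_nm: float = 50.0
    merge_gap_frames: int = 20
    merge_anchor: str = "centroid"
    # cluster statistics
    radii_nm: tuple[float, float, float] = (10.0, 500.0, 10.0)  # start, stop, step
    edge_correction: str = "none"
    r_local_nm: float = 50.0
    grid_step_nm: float = 5.0
    threshold_sims: int = 100
    min_cluster_cells: int = 3
    # colocalization
    cbc_r_max_nm: float = 500.0
    cbc_n_steps: int = 20
    seg_factor: float = 2.0
    control_mode: str = "reflect"
    # pixel metrics
    clustering_threshold_factor: float = 1.5
    background_percentile: float = 5.0
    # randomness
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load a config, rejecting unknown keys."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for k, v in data.items():
            if isinstance(v, list):
                v = tuple(v)
            kwargs[k] = v
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data = {k: (list(v) if isinstance(v, tuple) else v) for k, v in data.items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @property
    def radius_grid(self) -> np.ndarray:
        start, stop, step = self.radii_nm
        return np.arange(start, stop + 0.5 * step, step)
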