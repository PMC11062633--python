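"""Spot quantification for array images and line-profile colocalization.

The array readout is a grayscale raster (film scan or fluorescence image)
with one intensity disk per spot on a regular grid.  Quantification uses a
layout prior: for each nominal grid point the spot center is refined
locally, foreground is the median inside a disk, background the median in
a surrounding annulus, and the background-corrected value is clipped at
zero.  Intensities must be oriented so that larger means stronger binding.

The same module measures colocalization of two imaging channels along a
polyline (the white-line quantification of chromosome spreads): channels
are sampled by bilinear interpolation at a fixed step and compared by
Pearson correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .array_model import ArrayLayout, Position
from .errors import (
    CorrelationError,
    DataError,
    GeometryError,
    NormalizationError,
)

QC_OK = "ok"
QC_SATURATED = "saturated"
QC_EMPTY = "empty"


@dataclass(frozen=True)
class SpotMeasurement:
    """One quantified spot: center, foreground, background, corrected value."""

    spot_id: str
    subarray: int
    center: tuple[float, float]  # (y, x) pixels
    raw_fg: float
    bg: float
    corrected: float
    qc_flag: str = QC_OK
    is_control: bool = False


@dataclass
class ArrayResult:
    """Per-(spot, subarray) corrected and normalized intensities.

    ``data`` has columns spot_id, subarray, corrected, normalized,
    is_control.  Normalized values lie in [0, 1] under max scaling;
    controls carry measurements but are flagged and excluded from
    statistics downstream.
    """

    layout: ArrayLayout
    data: pd.DataFrame
    method: str = "max"

    def observations(self, include_controls: bool = False) -> pd.DataFrame:
        if include_controls:
            return self.data
        return self.data[~self.data["is_control"]]


def _grid_center(
    grid_origin, subarray: int, row: int, col: int, pitch: float, n_rows: int
) -> tuple[float, float]:
    """Nominal spot center. ``grid_origin`` is either a dict subarray ->
    (y, x) of the (row 1, col 1) center, or a single (y, x) with subarrays
    stacked vertically one blank row apart."""
    if isinstance(grid_origin, dict):
        y0, x0 = grid_origin[subarray]
    else:
        y0, x0 = grid_origin
        y0 = y0 + (subarray - 1) * (n_rows * pitch + pitch)
    return (y0 + (row - 1) * pitch, x0 + (col - 1) * pitch)


def _disk_offsets(radius: float) -> tuple[np.ndarray, np.ndarray]:
    r = int(np.ceil(radius))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    mask = dy**2 + dx**2 <= radius**2
    return dy[mask], dx[mask]


def _annulus_offsets(inner: float, outer: float) -> tuple[np.ndarray, np.ndarray]:
    r = int(np.ceil(outer))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = dy**2 + dx**2
    mask = (d2 >= inner**2) & (d2 <= outer**2)
    return dy[mask], dx[mask]


def quantify_spots(
    image: np.ndarray,
    layout: ArrayLayout,
    grid_origin,
    pitch: float,
    spot_radius: float,
    search_radius: int = 0,
    saturation: float | None = None,
) -> list[SpotMeasurement]:
    """Measure every layout position on a 2-D intensity raster.

    Foreground is the median inside ``disk(spot_radius)`` around the
    refined center, background the median in the 1.5-2.5x radius annulus,
    and ``corrected = max(fg - bg, 0)``.  Center refinement maximizes the
    mean disk intensity over integer offsets within ``search_radius`` of
    the nominal grid point.  ``saturation`` marks spots whose disk touches
    the detector ceiling (defaults to the dtype maximum of integer images).
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise GeometryError("image must be a 2-D grayscale raster")
    if not np.isfinite(image).all():
        raise DataError("image contains non-finite pixels")
    if pitch <= 2 * spot_radius:
        raise GeometryError("pitch must exceed twice the spot radius")
    if saturation is None and np.issubdtype(image.dtype, np.integer):
        saturation = float(np.iinfo(image.dtype).max)
    image = image.astype(float, copy=False)

    n_rows = layout.shape[0]
    disk_dy, disk_dx = _disk_offsets(spot_radius)
    ann_dy, ann_dx = _annulus_offsets(1.5 * spot_radius, 2.5 * spot_radius)
    h, w = image.shape

    out: list[SpotMeasurement] = []
    for pos in layout.positions():
        s, r, c = pos
        cy, cx = _grid_center(grid_origin, s, r, c, pitch, n_rows)
        cy_i, cx_i = int(round(cy)), int(round(cx))

        best = (cy_i, cx_i)
        if search_radius > 0:
            best_mean = -np.inf
            for dy in range(-search_radius, search_radius + 1):
                for dx in range(-search_radius, search_radius + 1):
                    yy, xx = cy_i + dy + disk_dy, cx_i + dx + disk_dx
                    if yy.min() < 0 or xx.min() < 0 or yy.max() >= h or xx.max() >= w:
                        continue
                    m = image[yy, xx].mean()
                    if m > best_mean:
                        best_mean, best = m, (cy_i + dy, cx_i + dx)
            if not np.isfinite(best_mean):
                raise GeometryError(f"spot grid position {pos} falls outside the image")
        cy_i, cx_i = best

        yy, xx = cy_i + disk_dy, cx_i + disk_dx
        ay, ax = cy_i + ann_dy, cx_i + ann_dx
        if (
            yy.min() < 0 or xx.min() < 0 or yy.max() >= h or xx.max() >= w
            or ay.min() < 0 or ax.min() < 0 or ay.max() >= h or ax.max() >= w
        ):
            raise GeometryError(f"spot grid position {pos} falls outside the image")

        fg_pixels = image[yy, xx]
        raw_fg = float(np.median(fg_pixels))
        bg = float(np.median(image[ay, ax]))
        corrected = max(raw_fg - bg, 0.0)

        qc = QC_OK
        if saturation is not None and fg_pixels.max() >= saturation:
            qc = QC_SATURATED
        elif corrected == 0.0:
            qc = QC_EMPTY

        entry = layout.peptide_at(pos)
        is_control = isinstance(entry, str)
        spot_id = entry if is_control else entry.spot_id
        out.append(
            SpotMeasurement(
                spot_id=spot_id,
                subarray=s,
                center=(float(cy_i), float(cx_i)),
                raw_fg=raw_fg,
                bg=bg,
                corrected=corrected,
                qc_flag=qc,
                is_control=is_control,
            )
        )
    return out


def normalize_intensities(
    measurements: Union[Sequence[SpotMeasurement], pd.DataFrame],
    layout: ArrayLayout,
    method: str = "max",
) -> ArrayResult:
    """Build an :class:`ArrayResult` from measurements or an intensity table.

    ``method="max"`` divides every corrected value by the single maximum
    over non-control spots of all subarrays (duplicates stay on one common
    scale); ``method="none"`` copies corrected values unscaled.
    """
    if isinstance(measurements, pd.DataFrame):
        df = measurements.loc[:, ["spot_id", "subarray", "corrected"]].copy()
        control_ids = set(layout.control_spot_ids().values())
        df["is_control"] = df["spot_id"].isin(control_ids)
    else:
        df = pd.DataFrame(
            {
                "spot_id": [m.spot_id for m in measurements],
                "subarray": [m.subarray for m in measurements],
                "corrected": [m.corrected for m in measurements],
                "is_control": [m.is_control for m in measurements],
            }
        )
    if (df["corrected"] < 0).any():
        raise DataError("corrected intensities must be non-negative")

    if method == "max":
        peak = df.loc[~df["is_control"], "corrected"].max()
        if not np.isfinite(peak) or peak <= 0:
            raise NormalizationError(
                "max-normalization impossible: no non-control spot with positive intensity"
            )
        df["normalized"] = df["corrected"] / peak
    elif method == "none":
        df["normalized"] = df["corrected"]
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return ArrayResult(layout=layout, data=df.reset_index(drop=True), method=method)


def read_intensity_table(path: Union[str, Path], layout: ArrayLayout,
                         method: str = "max") -> ArrayResult:
    """Load a TSV of (spot_id, subarray, corrected), bypassing imaging."""
    df = pd.read_csv(path, sep="\t")
    required = {"spot_id", "subarray", "corrected"}
    if not required <= set(df.columns):
        raise DataError(f"intensity table needs columns {sorted(required)}")
    return normalize_intensities(df, layout, method=method)


@dataclass
class LineProfile:
    """Multi-channel intensity series sampled along one polyline."""

    positions: np.ndarray
    channels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if np.any(np.diff(self.positions) <= 0):
            raise DataError("profile positions must be strictly increasing")
        for name, series in self.channels.items():
            series = np.asarray(series, dtype=float)
            if series.shape != self.positions.shape:
                raise DataError(f"channel {name!r} length differs from positions")
            self.channels[name] = series


def extract_line_profile(
    image_channels: Mapping[str, np.ndarray],
    vertices: Sequence[tuple[float, float]],
    step: float = 1.0,
) -> LineProfile:
    """Sample every channel along a polyline at evenly spaced arc lengths.

    ``vertices`` are (y, x) pixel coordinates; interpolation is bilinear
    and all channels are sampled at identical points.
    """
    if len(vertices) < 2:
        raise GeometryError("polyline needs at least two vertices")
    if step <= 0:
        raise GeometryError("sampling step must be positive")
    verts = np.asarray(vertices, dtype=float)
    seg = np.diff(verts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    if np.any(seg_len == 0):
        raise GeometryError("polyline has zero-length segment")
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    positions = np.arange(0.0, total + step / 2, step)
    positions = positions[positions <= total]

    # arc length -> (y, x)
    idx = np.clip(np.searchsorted(cum, positions, side="right") - 1, 0, len(seg) - 1)
    frac = (positions - cum[idx]) / seg_len[idx]
    pts = verts[idx] + seg[idx] * frac[:, None]

    channels: dict[str, np.ndarray] = {}
    for name, img in image_channels.items():
        img = np.asarray(img, dtype=float)
        if img.ndim != 2:
            raise GeometryError(f"channel {name!r} is not a 2-D image")
        h, w = img.shape
        if (
            pts[:, 0].min() < 0 or pts[:, 1].min() < 0
            or pts[:, 0].max() > h - 1 or pts[:, 1].max() > w - 1
        ):
            raise GeometryError("polyline exits the image")
        channels[name] = ndimage.map_coordinates(img, pts.T, order=1, mode="nearest")
    return LineProfile(positions=positions, channels=channels)


def colocalization_r(profile: LineProfile, channel_a: str, channel_b: str) -> float:
    """Pearson correlation of two channels of a line profile."""
    a = profile.channels[channel_a]
    b = profile.channels[channel_b]
    if len(a) < 3:
        raise CorrelationError("need at least 3 samples for a correlation")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise CorrelationError("correlation undefined for a constant channel")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = stats.pearsonr(a, b).statistic
    return float(r)
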