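"""Reduction of 2D scattering frames to averaged 1D scattering curves.

A matrix-mode measurement records many short exposures on a grid of sample
positions.  Each detector frame is corrected for backgrounds and exposure
time, azimuthally averaged into a 1D curve I(q), screened for outliers
(cosmic-ray spikes, empty positions), normalized on the intensity scale and
averaged into a single scattering curve per sample.

The momentum transfer is q = 4*pi*sin(theta)/lambda with theta half the
scattering angle; all q values are in nm^-1 and wavelengths in nm.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: q window (nm^-1) used both for outlier screening and for the peak fit.
DEFAULT_FIT_WINDOW = (0.038, 0.2)

#: Pilatus-class pixel pitch in mm; configurable in Geometry.
DEFAULT_PIXEL_SIZE_MM = 0.172


class InvalidGeometryError(ValueError):
    """Raised when detector geometry parameters are unphysical."""


@dataclass(frozen=True)
class Geometry:
    """Detector geometry for converting pixel positions to momentum transfer.

    Parameters
    ----------
    wavelength_nm :
        X-ray wavelength in nm.  Default 0.154 (Cu K-alpha).
    distance_mm :
        Sample-detector distance in mm.  Default 2507.
    beam_center_px :
        (row, col) pixel coordinates of the direct beam.
    pixel_size_mm :
        Detector pixel pitch in mm.
    """

    wavelength_nm: float = 0.154
    distance_mm: float = 2507.0
    beam_center_px: tuple[float, float] = (0.0, 0.0)
    pixel_size_mm: float = DEFAULT_PIXEL_SIZE_MM

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise InvalidGeometryError("wavelength_nm must be positive")
        if self.distance_mm <= 0:
            raise InvalidGeometryError("distance_mm must be positive")
        if self.pixel_size_mm <= 0:
            raise InvalidGeometryError("pixel_size_mm must be positive")


@dataclass
class DetectorFrame:
    """A 2D detector image with geometry and a usable-pixel mask."""

    intensities: np.ndarray
    geometry: Geometry
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2D array")
        if self.mask is None:
            self.mask = np.ones(self.intensities.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.intensities.shape:
                raise ValueError("mask shape must match intensities shape")
        if not np.all(np.isfinite(self.intensities[self.mask])):
            raise ValueError("intensities must be finite where mask is true")


@dataclass
class ScatteringCurve:
    """A 1D scattering curve: (q, I, sigma) triples with provenance.

    q must be strictly increasing (nm^-1); sigma is non-negative.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (self.q.shape == self.intensity.shape == self.sigma.shape):
            raise ValueError("q, intensity and sigma must have equal length")
        if self.q.ndim != 1 or self.q.size == 0:
            raise ValueError("curve must be a non-empty 1D sequence")
        if self.q.size > 1 and not np.all(np.diff(self.q) > 0):
            raise ValueError("q must be strictly increasing")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative")

    def __len__(self) -> int:
        return self.q.size


def q_from_angle(theta_rad, wavelength_nm: float):
    """Momentum transfer q = 4*pi*sin(theta)/lambda.

    Parameters
    ----------
    theta_rad :
        Half the scattering angle, radians, in [0, pi/2).
    wavelength_nm :
        X-ray wavelength in nm.

    Returns
    -------
    q in nm^-1 (scalar or array matching ``theta_rad``).
    """
    if wavelength_nm <= 0:
        raise InvalidGeometryError("wavelength_nm must be positive")
    theta = np.asarray(theta_rad, dtype=float)
    if np.any(theta < 0) or np.any(theta >= np.pi / 2):
        raise ValueError("theta must be in [0, pi/2)")
    q = 4.0 * np.pi * np.sin(theta) / wavelength_nm
    return q if q.ndim else float(q)


def pixel_q_map(shape: tuple[int, int], geometry: Geometry) -> np.ndarray:
    """q value (nm^-1) of each pixel centre for the given geometry."""
    rows, cols = np.indices(shape)
    r0, c0 = geometry.beam_center_px
    r_mm = np.hypot(rows - r0, cols - c0) * geometry.pixel_size_mm
    # scattering angle 2*theta from the flat-detector radial distance
    theta = 0.5 * np.arctan2(r_mm, geometry.distance_mm)
    return 4.0 * np.pi * np.sin(theta) / geometry.wavelength_nm


def correct_frame(
    frame: DetectorFrame,
    dark: DetectorFrame | None = None,
    empty: DetectorFrame | None = None,
    scalars: Mapping[str, float] | None = None,
) -> DetectorFrame:
    """Apply background and normalization corrections to a frame.

    output = (frame - dark - transmission*empty)
             / (exposure_time * flatness * absorption)

    Every omitted correction defaults to identity.  ``scalars`` may contain
    ``transmission``, ``exposure_time``, ``flatness`` and ``absorption``
    (scalar or per-pixel array for the last two).  Masks are combined with
    logical AND.
    """
    scalars = dict(scalars or {})
    exposure_time = float(scalars.get("exposure_time", 1.0))
    if exposure_time <= 0:
        raise ValueError("exposure_time must be positive")
    transmission = float(scalars.get("transmission", 1.0))
    flatness = np.asarray(scalars.get("flatness", 1.0), dtype=float)
    absorption = np.asarray(scalars.get("absorption", 1.0), dtype=float)

    out = frame.intensities.copy()
    mask = frame.mask.copy()
    for other, factor in ((dark, 1.0), (empty, transmission)):
        if other is None:
            continue
        if other.intensities.shape != frame.intensities.shape:
            raise ValueError("correction frame shape mismatch")
        out = out - factor * other.intensities
        mask &= other.mask
    out = out / (exposure_time * flatness * absorption)
    return DetectorFrame(out, frame.geometry, mask, dict(frame.meta))


def azimuthal_average(
    frame: DetectorFrame,
    n_bins: int = 256,
    q_range: tuple[float, float] | None = None,
) -> ScatteringCurve:
    """Azimuthally average a frame into a 1D scattering curve.

    Pixels are mapped to q through the detector geometry, gathered into
    ``n_bins`` equal-width q bins, and averaged; per-bin sigma is the
    standard error of the mean, with a Poisson fallback (sqrt of counts)
    for single-pixel bins.  Masked pixels are excluded; empty bins dropped.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    qmap = pixel_q_map(frame.intensities.shape, frame.geometry)
    usable = frame.mask
    if q_range is not None:
        usable = usable & (qmap >= q_range[0]) & (qmap <= q_range[1])
    qs = qmap[usable]
    vals = frame.intensities[usable]
    if qs.size == 0:
        raise ValueError("all pixels masked: cannot form a scattering curve")
    if qs.size == 1:
        sig = np.sqrt(max(float(vals[0]), 0.0))
        return ScatteringCurve(qs, vals, np.array([sig]), dict(frame.meta))

    lo = q_range[0] if q_range is not None else qs.min()
    hi = q_range[1] if q_range is not None else qs.max()
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(qs, edges) - 1, 0, n_bins - 1)

    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=vals, minlength=n_bins)
    sq_sums = np.bincount(idx, weights=vals**2, minlength=n_bins)

    nonempty = counts > 0
    n = counts[nonempty].astype(float)
    mean = sums[nonempty] / n
    # SEM with sample variance; Poisson fallback where a bin has one pixel
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (sq_sums[nonempty] - n * mean**2) / np.maximum(n - 1, 1)
    var = np.clip(var, 0.0, None)
    sem = np.sqrt(var / n)
    single = n == 1
    sem[single] = np.sqrt(np.clip(mean[single], 0.0, None))

    centers = 0.5 * (edges[:-1] + edges[1:])[nonempty]
    return ScatteringCurve(centers, mean, sem, dict(frame.meta))


def _window_totals(curves: Sequence[ScatteringCurve], q_window) -> np.ndarray:
    lo, hi = q_window
    totals = []
    for c in curves:
        sel = (c.q >= lo) & (c.q <= hi)
        totals.append(float(np.sum(c.intensity[sel])) if sel.any() else 0.0)
    return np.asarray(totals)


def detect_outlier_curves(
    curves: Sequence[ScatteringCurve],
    threshold: float = 3.5,
    q_window: tuple[float, float] = DEFAULT_FIT_WINDOW,
) -> np.ndarray:
    """Flag replicate curves whose total window intensity is a robust outlier.

    The statistic is the robust z-score (deviation from the median scaled by
    1.4826*MAD) of summed intensity over ``q_window``; curves with |z| above
    ``threshold`` in either direction are flagged.  This catches both empty
    positions (near-zero intensity) and cosmic-ray spikes (excess intensity).
    Inputs are not modified.
    """
    flags = np.zeros(len(curves), dtype=bool)
    if len(curves) < 3:
        logger.warning("fewer than 3 curves: outlier detection skipped")
        return flags
    totals = _window_totals(curves, q_window)
    med = np.median(totals)
    mad = np.median(np.abs(totals - med))
    if mad == 0:
        # no dispersion in the bulk: anything off the median is an outlier
        return totals != med
    z = (totals - med) / (1.4826 * mad)
    return np.abs(z) > threshold


def normalize_and_average(
    curves: Sequence[ScatteringCurve],
    q_window: tuple[float, float] = DEFAULT_FIT_WINDOW,
) -> ScatteringCurve:
    """Scale replicate curves onto a common intensity level and average them.

    Each curve is multiplied by the non-negative factor that minimizes its
    squared deviation from the pointwise median curve over ``q_window``
    (closed form: s = <I, m>/<I, I>); the output intensity is the pointwise
    mean of the scaled curves and the output sigma the standard error across
    them (the input sigma is copied when only one curve is given).
    """
    curves = list(curves)
    if not curves:
        raise ValueError("no curves to average")
    q = curves[0].q
    for c in curves[1:]:
        if c.q.shape != q.shape or not np.allclose(c.q, q):
            raise ValueError("curves must share a common q grid")
    if len(curves) == 1:
        c = curves[0]
        return ScatteringCurve(c.q, c.intensity.copy(), c.sigma.copy(), dict(c.meta))

    lo, hi = q_window
    sel = (q >= lo) & (q <= hi)
    if not sel.any():
        raise ValueError("q_window does not overlap the curve grid")
    stack = np.vstack([c.intensity for c in curves])
    # reference = pointwise median of unit-window-mean curves, so the
    # reference (and hence the output, up to overall scale) is invariant to
    # rescaling any single input curve
    window_means = stack[:, sel].mean(axis=1)
    usable = window_means > 0
    for c, ok in zip(curves, usable):
        if not ok:
            warnings.warn(
                f"curve {c.meta.get('position', '?')} has zero intensity over "
                "the normalization window; excluded",
                stacklevel=2,
            )
    if not usable.any():
        raise ValueError("no usable curves after normalization")
    median_curve = np.median(stack[usable] / window_means[usable, None], axis=0)

    scaled = []
    for row, ok in zip(stack, usable):
        if not ok:
            continue
        denom = float(np.sum(row[sel] ** 2))
        s = max(float(np.sum(row[sel] * median_curve[sel])) / denom, 0.0)
        scaled.append(s * row)
    if not scaled:
        raise ValueError("no usable curves after normalization")
    arr = np.vstack(scaled)
    mean = arr.mean(axis=0)
    if arr.shape[0] > 1:
        sem = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
    else:
        sem = curves[0].sigma.copy()
    meta = dict(curves[0].meta)
    meta["n_curves_averaged"] = arr.shape[0]
    return ScatteringCurve(q, mean, sem, meta)


def reduce_sample(
    curves: Sequence[ScatteringCurve],
    outlier_z: float = 3.5,
    q_window: tuple[float, float] = DEFAULT_FIT_WINDOW,
) -> ScatteringCurve:
    """Full matrix-mode reduction: outlier screen, normalize, average."""
    flags = detect_outlier_curves(curves, threshold=outlier_z, q_window=q_window)
    kept = [c for c, f in zip(curves, flags) if not f]
    if not kept:
        raise ValueError("all replicate curves flagged as outliers")
    return normalize_and_average(kept, q_window=q_window)
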