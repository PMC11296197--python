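"""Reflectance colourimetry: brightness, UV chroma and hue from spectra.

Spectra are percent reflectance relative to a white standard.  Three
variables summarize each spectrum on a canonical 1-nm grid from 320 to
700 nm (endpoints inclusive, linear interpolation from the instrument
grid):

* brightness — mean reflectance over 320-700 nm;
* UV chroma — reflectance in the 320-400 nm band relative to brightness
  (band-mean over brightness by default, so a flat spectrum scores exactly
  1; a band-sum over full-sum convention is available and differs only by
  a constant factor);
* hue — wavelength of maximum reflectance (lowest wavelength on ties).

Replicate measurements of a sample are averaged at the variable level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

WAVELENGTH_GRID = np.arange(320.0, 701.0)  # 1-nm canonical grid, inclusive
UV_BAND = (320.0, 400.0)


@dataclass
class ReflectanceSpectrum:
    """Wavelength-indexed percent reflectance with sample/replicate labels."""

    wavelength: np.ndarray
    reflectance: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelength.shape != self.reflectance.shape:
            raise ValueError("wavelength and reflectance must have equal length")
        if self.wavelength.size > 1 and not np.all(np.diff(self.wavelength) > 0):
            raise ValueError("wavelength must be strictly increasing")
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("reflectance must be finite")
        if self.wavelength[0] > WAVELENGTH_GRID[0] or self.wavelength[-1] < WAVELENGTH_GRID[-1]:
            raise ValueError("spectrum must cover 320-700 nm")


@dataclass
class ColourSummary:
    brightness: float
    uv_chroma: float
    hue: float
    n_replicates: int = 1
    meta: dict = field(default_factory=dict)


def _resample(spectrum: ReflectanceSpectrum) -> np.ndarray:
    return np.interp(WAVELENGTH_GRID, spectrum.wavelength, spectrum.reflectance)


def summarize_reflectance(
    spectrum: ReflectanceSpectrum,
    uv_convention: str = "mean",
    smooth: int = 0,
) -> ColourSummary:
    """Compute brightness, UV chroma and hue for one spectrum.

    ``uv_convention`` selects band-mean/brightness ("mean", default) or
    band-sum/full-sum ("sum").  ``smooth`` > 1 applies a boxcar of that
    width before the hue argmax (off by default).
    """
    r = _resample(spectrum)
    brightness = float(np.mean(r))
    uv_sel = (WAVELENGTH_GRID >= UV_BAND[0]) & (WAVELENGTH_GRID <= UV_BAND[1])
    if brightness == 0:
        raise ValueError("brightness is zero: UV chroma undefined")
    if uv_convention == "mean":
        uv_chroma = float(np.mean(r[uv_sel])) / brightness
    elif uv_convention == "sum":
        uv_chroma = float(np.sum(r[uv_sel])) / float(np.sum(r))
    else:
        raise ValueError("uv_convention must be 'mean' or 'sum'")

    r_hue = r
    if smooth and smooth > 1:
        kernel = np.ones(smooth) / smooth
        pad = smooth // 2
        padded = np.concatenate([np.full(pad, r[0]), r, np.full(pad, r[-1])])
        r_hue = np.convolve(padded, kernel, mode="valid")[: r.size]
    hue = float(WAVELENGTH_GRID[int(np.argmax(r_hue))])  # argmax takes lowest tie

    return ColourSummary(
        brightness=brightness,
        uv_chroma=uv_chroma,
        hue=hue,
        n_replicates=1,
        meta={**spectrum.meta, "uv_convention": uv_convention},
    )


def average_replicates(
    spectra: Sequence[ReflectanceSpectrum], uv_convention: str = "mean"
) -> ColourSummary:
    """Per-sample summary: arithmetic mean of per-replicate variables."""
    spectra = list(spectra)
    if not spectra:
        raise ValueError("need at least one replicate")
    ids = {s.meta.get("sample") for s in spectra}
    if len(ids) > 1:
        raise ValueError(f"mixed sample ids in replicates: {sorted(map(str, ids))}")
    summaries = [summarize_reflectance(s, uv_convention) for s in spectra]
    return ColourSummary(
        brightness=float(np.mean([s.brightness for s in summaries])),
        uv_chroma=float(np.mean([s.uv_chroma for s in summaries])),
        hue=float(np.mean([s.hue for s in summaries])),
        n_replicates=len(summaries),
        meta={"sample": ids.pop(), "uv_convention": uv_convention},
    )


def summarize_spectra_table(df: pd.DataFrame, uv_convention: str = "mean") -> pd.DataFrame:
    """Summarize a long-format spectra table into one row per sample.

    Expects columns wavelength_nm, reflectance_pct, sample, replicate.
    """
    records = []
    for sample, group in df.groupby("sample", sort=True):
        spectra = [
            ReflectanceSpectrum(
                rep.sort_values("wavelength_nm")["wavelength_nm"].to_numpy(),
                rep.sort_values("wavelength_nm")["reflectance_pct"].to_numpy(),
                {"sample": sample, "replicate": replicate},
            )
            for replicate, rep in group.groupby("replicate")
        ]
        summary = average_replicates(spectra, uv_convention)
        records.append(
            {
                "sample": sample,
                "brightness": summary.brightness,
                "uv_chroma": summary.uv_chroma,
                "hue": summary.hue,
                "n_replicates": summary.n_replicates,
            }
        )
    return pd.DataFrame.from_records(records)
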