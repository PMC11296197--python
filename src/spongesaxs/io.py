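"""File I/O: scattering curves (.dat), detector frames, spectra and tables.

Curves travel as 3-column ASCII ``.dat`` files (q [nm^-1], intensity,
sigma) with '#'-prefixed header lines carrying provenance.  Frames are
single-channel TIFF or whitespace-delimited matrix text, with geometry and
mask supplied through a YAML/JSON sidecar.  Reflectance spectra and cohort
tables are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .reduction import DetectorFrame, Geometry, ScatteringCurve

_META_KEYS = ("sample", "position", "exposure")


def write_curve(curve: ScatteringCurve, path) -> None:
    """Write a scattering curve as 3-column ASCII with '#' headers."""
    path = Path(path)
    lines = ["# spongesaxs scattering curve", "# columns: q_nm_inv intensity sigma"]
    for key in _META_KEYS:
        if key in curve.meta:
            lines.append(f"# {key}: {curve.meta[key]}")
    body = "\n".join(
        f"{q:.9e} {i:.9e} {s:.9e}"
        for q, i, s in zip(curve.q, curve.intensity, curve.sigma)
    )
    path.write_text("\n".join(lines) + "\n" + body + "\n")


def read_curve(path) -> ScatteringCurve:
    """Read a 3-column ASCII curve; '#' headers become meta entries."""
    path = Path(path)
    meta: dict = {}
    rows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if ":" in stripped:
                key, _, val = stripped.partition(":")
                key = key.strip()
                if key in _META_KEYS:
                    val = val.strip()
                    meta[key] = int(val) if val.lstrip("-").isdigit() else val
            continue
        rows.append([float(x) for x in line.split()])
    if not rows:
        raise ValueError(f"no data rows in {path}")
    arr = np.asarray(rows)
    if arr.shape[1] < 3:
        raise ValueError(f"{path} must have 3 columns (q, intensity, sigma)")
    return ScatteringCurve(arr[:, 0], arr[:, 1], arr[:, 2], meta)


def _load_sidecar(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def geometry_from_mapping(data: dict) -> Geometry:
    """Build a Geometry from a sidecar mapping (missing keys use defaults)."""
    kwargs = {}
    for key in ("wavelength_nm", "distance_mm", "pixel_size_mm"):
        if key in data:
            kwargs[key] = float(data[key])
    if "beam_center_px" in data:
        kwargs["beam_center_px"] = tuple(float(v) for v in data["beam_center_px"])
    return Geometry(**kwargs)


def read_frame(path, sidecar=None) -> DetectorFrame:
    """Read a detector frame from TIFF or matrix text.

    ``sidecar`` is a YAML/JSON file with geometry keys and optionally a
    ``mask`` path (matrix text of 0/1, 1 = usable) and ``meta`` mapping.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = np.asarray(tifffile.imread(path), dtype=float)
    else:
        arr = np.loadtxt(path)
    side = _load_sidecar(sidecar) if sidecar else {}
    geometry = geometry_from_mapping(side)
    mask = None
    if "mask" in side:
        mask = np.loadtxt(Path(sidecar).parent / side["mask"]).astype(bool)
    return DetectorFrame(arr, geometry, mask, dict(side.get("meta", {})))


def write_frame_text(frame: DetectorFrame, path) -> None:
    """Write frame intensities as whitespace-delimited matrix text."""
    np.savetxt(path, frame.intensities, fmt="%.6e")


def read_spectra_csv(path) -> pd.DataFrame:
    """Read spectra CSV with columns wavelength_nm, reflectance_pct, sample, replicate."""
    df = pd.read_csv(path)
    required = {"wavelength_nm", "reflectance_pct", "sample", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"spectra CSV missing columns: {sorted(missing)}")
    return df


def write_spectra_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
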