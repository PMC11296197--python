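"""Synthetic cohorts: latent nanostructure, scattering data and spectra.

Generates everything the analysis consumes, with known ground truth, so the
full pipeline is testable without any measured data:

* per-individual latent Porod-peak parameters drawn by sex from truncated
  normals (male crowns more UV-tuned: higher primary-peak position);
* matrix-mode replicate scattering curves — the Porod-space two-Gaussian
  model divided by q^4, a per-position lognormal intensity scale, additive
  Gaussian noise, and occasional outliers (empty positions, cosmic spikes);
* optional 2D detector frames (isotropic rendering with Poisson counts and
  a beamstop mask);
* triplicate reflectance spectra whose hue follows the Bragg/refractive-
  index prediction from the latent primary-peak position plus a sex-specific
  offset (females realize a lower hue than their nanostructure predicts,
  standing in for other structural elements), and whose overall level
  follows a brightness that increases with peak amplitude and decreases
  with peak position.

All draws are keyed by (seed, sample, position, exposure) through numpy
SeedSequences, so any subset regenerates bit-identically.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .colorimetry import WAVELENGTH_GRID, ReflectanceSpectrum
from .huepredict import OpticalModel, predict_hue
from .porodfit import PeakModelParams, model_eval, transform_amplitude
from .reduction import DetectorFrame, Geometry, ScatteringCurve, pixel_q_map

SEXES = ("M", "F")


@dataclass(frozen=True)
class SexTrait:
    """Truncated-normal generator for one latent parameter, by sex."""

    mean_m: float
    mean_f: float
    sd: float
    low: float
    high: float

    def mean(self, sex: str) -> float:
        return self.mean_m if sex == "M" else self.mean_f


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition defaults for the synthetic cohort.

    Sample sizes and measurement design mirror the matrix-mode protocol
    (21 positions, 6 exposures, 53 males / 29 females); the primary peak is
    centred on the observed ~0.045 nm^-1 region with male crowns more
    UV-tuned, and peak widths use the reported ~0.007 (M) / 0.008 (F).
    The female hue offset of -8 nm reproduces the overestimation pattern:
    female spectra realize a hue about 8 nm below the nanostructural
    prediction.
    """

    n_males: int = 53
    n_females: int = 29
    q1: SexTrait = SexTrait(0.047, 0.044, 0.002, 0.038, 0.06)
    h1: SexTrait = SexTrait(0.007, 0.008, 0.001, 0.002, 0.03)
    a1: SexTrait = SexTrait(120.0, 90.0, 20.0, 10.0, 400.0)
    alpha: SexTrait = SexTrait(0.3, 0.3, 0.05, 0.05, 1.0)
    beta: SexTrait = SexTrait(5.0 / 3.0, 5.0 / 3.0, 0.05, 1.35, 2.1)
    h2: SexTrait = SexTrait(0.012, 0.012, 0.002, 0.002, 0.04)
    c: SexTrait = SexTrait(2.0, 2.0, 0.5, 0.2, 20.0)
    q_grid: tuple[float, float, int] = (0.01, 0.25, 400)
    n_positions: int = 21
    n_exposures: int = 6
    curve_noise_frac: float = 0.02
    position_scale_sd: float = 0.1
    outlier_probability: float = 0.0
    outlier_mode: str = "mixed"  # "empty" | "spike" | "mixed"
    # structure -> colour links
    brightness_base_m: float = 18.0
    brightness_base_f: float = 13.0
    brightness_per_a1_sd: float = 1.5
    brightness_per_q1_sd: float = -1.2
    brightness_noise_sd: float = 1.0
    hue_offset_m: float = 0.0
    hue_offset_f: float = -8.0
    hue_noise_sd: float = 2.0
    # spectral shape
    spectral_peak_width_nm: float = 45.0
    spectral_base_fraction: float = 0.35
    spectral_noise_sd: float = 0.3
    n_spectra: int = 3
    year_levels: tuple[int, int] = (2007, 2022)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_males <= 0 or self.n_females <= 0:
            raise ValueError("sample counts must be positive")
        if not 0.0 <= self.outlier_probability <= 1.0:
            raise ValueError("outlier_probability must be in [0, 1]")
        for name in ("q1", "h1", "a1", "alpha", "beta", "h2", "c"):
            trait: SexTrait = getattr(self, name)
            if trait.low >= trait.high:
                raise ValueError(f"truncation bounds inverted for {name}")
            if trait.sd < 0:
                raise ValueError(f"negative sd for {name}")

    @property
    def q_values(self) -> np.ndarray:
        lo, hi, n = self.q_grid
        return np.linspace(lo, hi, int(n))


@dataclass
class TrueParameters:
    """Ground truth for one synthetic individual."""

    sample: str
    index: int
    sex: str
    year: int
    peak: PeakModelParams
    brightness_true: float
    hue_true: float


def _rng(*keys: int) -> np.random.Generator:
    return np.random.default_rng([int(k) & 0x7FFFFFFF for k in keys])


def _draw_trunc_normal(rng: np.random.Generator, mean, sd, low, high) -> float:
    if sd == 0:
        return float(np.clip(mean, low, high))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if low <= x <= high:
            return float(x)
    return float(np.clip(mean, low, high))


def draw_cohort(config: CohortConfig, seed: int | None = None) -> list[TrueParameters]:
    """Draw per-individual latent parameters for the whole cohort."""
    seed = config.seed if seed is None else seed
    optical = OpticalModel()
    cohort: list[TrueParameters] = []
    sexes = ["M"] * config.n_males + ["F"] * config.n_females
    for idx, sex in enumerate(sexes):
        rng = _rng(seed, 1, idx)
        draws = {
            name: _draw_trunc_normal(
                rng, getattr(config, name).mean(sex), getattr(config, name).sd,
                getattr(config, name).low, getattr(config, name).high,
            )
            for name in ("q1", "h1", "a1", "alpha", "beta", "h2", "c")
        }
        peak = PeakModelParams(**draws)
        offset = config.hue_offset_m if sex == "M" else config.hue_offset_f
        hue = predict_hue(peak.q1, optical) + offset
        if config.hue_noise_sd > 0:
            hue += rng.normal(0.0, config.hue_noise_sd)
        hue = float(np.clip(hue, 320.5, 699.5))
        a1_z = (draws["a1"] - config.a1.mean(sex)) / max(config.a1.sd, 1e-12)
        q1_z = (draws["q1"] - config.q1.mean(sex)) / max(config.q1.sd, 1e-12)
        base = config.brightness_base_m if sex == "M" else config.brightness_base_f
        brightness = (
            base
            + config.brightness_per_a1_sd * a1_z
            + config.brightness_per_q1_sd * q1_z
        )
        if config.brightness_noise_sd > 0:
            brightness += rng.normal(0.0, config.brightness_noise_sd)
        brightness = float(max(brightness, 0.5))
        year = int(rng.choice(config.year_levels))
        cohort.append(
            TrueParameters(
                sample=f"S{idx:03d}", index=idx, sex=sex, year=year,
                peak=peak, brightness_true=brightness, hue_true=hue,
            )
        )
    return cohort


def simulate_curve(
    truth: TrueParameters,
    config: CohortConfig,
    position: int = 0,
    exposure: int = 0,
    seed: int | None = None,
) -> ScatteringCurve:
    """One replicate scattering curve for a sample position/exposure.

    I(q) = [c + G1(q) + G2(q)] / q^4, scaled by a per-position lognormal
    factor, with additive Gaussian noise whose sd is ``curve_noise_frac``
    of the primary peak height in Porod space (so it is constant relative
    to the peaks after the Porod transform).  With probability
    ``outlier_probability`` the curve becomes an empty position or carries
    a cosmic-ray spike.
    """
    seed = config.seed if seed is None else seed
    q = config.q_values
    porod_y = model_eval(truth.peak, q)
    base = porod_y / q**4

    pos_rng = _rng(seed, 2, truth.index, position)
    scale = (
        float(np.exp(pos_rng.normal(0.0, config.position_scale_sd)))
        if config.position_scale_sd > 0
        else 1.0
    )
    rng = _rng(seed, 3, truth.index, position, exposure)
    noise_sd = config.curve_noise_frac * truth.peak.a1
    intensity = base * scale
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, q.size) / q**4
    sigma = np.full(q.size, noise_sd) / q**4

    meta = {"sample": truth.sample, "position": position, "exposure": exposure}
    if config.outlier_probability > 0 and rng.random() < config.outlier_probability:
        mode = config.outlier_mode
        if mode == "mixed":
            mode = "empty" if rng.random() < 0.5 else "spike"
        if mode == "empty":
            intensity = np.abs(rng.normal(0.0, 1e-6 * truth.peak.a1, q.size))
            meta["outlier"] = "empty"
        else:
            spike_at = int(rng.integers(0, q.size))
            intensity = intensity.copy()
            intensity[spike_at] += 50.0 * truth.peak.a1 / q[spike_at] ** 4
            meta["outlier"] = "spike"
    return ScatteringCurve(q, intensity, sigma, meta)


def simulate_sample_curves(
    truth: TrueParameters, config: CohortConfig, seed: int | None = None
) -> list[ScatteringCurve]:
    """All matrix-mode replicate curves (positions x exposures) of a sample."""
    return [
        simulate_curve(truth, config, position, exposure, seed)
        for position in range(config.n_positions)
        for exposure in range(config.n_exposures)
    ]


def simulate_frame(
    intensity_fn,
    geometry: Geometry,
    shape: tuple[int, int] = (256, 256),
    total_counts: float = 1e7,
    seed: int = 0,
    beamstop_px: float = 8.0,
    poisson: bool = True,
) -> DetectorFrame:
    """Render an isotropic I(q) model onto a detector frame.

    Expected pixel counts are proportional to ``intensity_fn(q)`` at each
    pixel's q, normalized so unmasked pixels sum to ``total_counts``, then
    Poisson-sampled (set ``poisson=False`` for the noiseless expectation).
    A disc of radius ``beamstop_px`` around the beam centre is masked.
    """
    if total_counts <= 0:
        raise ValueError("total_counts must be positive")
    qmap = pixel_q_map(shape, geometry)
    rows, cols = np.indices(shape)
    r0, c0 = geometry.beam_center_px
    radius = np.hypot(rows - r0, cols - c0)
    mask = radius > beamstop_px

    expected = np.zeros(shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        expected[mask] = intensity_fn(qmap[mask])
    expected = np.clip(expected, 0.0, None)
    total = expected[mask].sum()
    if total <= 0:
        raise ValueError("model intensity vanishes on the unmasked detector")
    expected *= total_counts / total
    if poisson:
        counts = _rng(seed, 4).poisson(expected).astype(float)
    else:
        counts = expected
    return DetectorFrame(counts, geometry, mask, {"total_counts": total_counts})


def _gaussian_band_mean(hue: float, width: float) -> float:
    g = np.exp(-((WAVELENGTH_GRID - hue) ** 2) / (2.0 * width**2))
    return float(np.mean(g))


def simulate_spectra(
    truth: TrueParameters, config: CohortConfig, seed: int | None = None
) -> list[ReflectanceSpectrum]:
    """Triplicate reflectance spectra realizing the sample's true colour.

    Each replicate is a Gaussian reflectance peak centred on the true hue
    over a flat base, with amplitude and base chosen so the noiseless
    brightness equals the configured true brightness, plus white noise.
    """
    seed = config.seed if seed is None else seed
    if not 320.0 <= truth.hue_true <= 700.0:
        raise ValueError("true hue must lie within the 320-700 nm grid")
    B = truth.brightness_true
    base = config.spectral_base_fraction * B
    gmean = _gaussian_band_mean(truth.hue_true, config.spectral_peak_width_nm)
    amp = (B - base) / gmean
    clean = base + amp * np.exp(
        -((WAVELENGTH_GRID - truth.hue_true) ** 2)
        / (2.0 * config.spectral_peak_width_nm**2)
    )
    spectra = []
    for rep in range(config.n_spectra):
        rng = _rng(seed, 5, truth.index, rep)
        noise = (
            rng.normal(0.0, config.spectral_noise_sd, WAVELENGTH_GRID.size)
            if config.spectral_noise_sd > 0
            else 0.0
        )
        spectra.append(
            ReflectanceSpectrum(
                WAVELENGTH_GRID.copy(),
                clean + noise,
                {"sample": truth.sample, "replicate": rep},
            )
        )
    return spectra


def simulate_cohort_table(
    config: CohortConfig,
    seed: int | None = None,
    q1_measurement_sd: float = 0.0,
) -> pd.DataFrame:
    """Build the per-sample analysis table directly from latent truth.

    SAXS columns are the latent peak parameters (optionally with Gaussian
    measurement error on q1), colour columns come from simulating and
    summarizing the triplicate spectra, and predicted_hue applies the
    Bragg/refractive-index formula to the (measured) q1.  This is the fast
    path for cohort-level statistics; the curve-level pipeline is exercised
    separately.
    """
    from .colorimetry import average_replicates

    seed = config.seed if seed is None else seed
    cohort = draw_cohort(config, seed)
    optical = OpticalModel()
    rows = []
    for truth in cohort:
        spectra = simulate_spectra(truth, config, seed)
        colour = average_replicates(spectra)
        q1_meas = truth.peak.q1
        if q1_measurement_sd > 0:
            q1_meas += float(_rng(seed, 6, truth.index).normal(0.0, q1_measurement_sd))
        rows.append({
            "sample": truth.sample,
            "sex": truth.sex,
            "year": truth.year,
            "q1": q1_meas,
            "h1": truth.peak.h1,
            "loga1": transform_amplitude(truth.peak.a1),
            "q2": truth.peak.q2,
            "h2": truth.peak.h2,
            "loga2": transform_amplitude(truth.peak.a2),
            "brightness": colour.brightness,
            "uv_chroma": colour.uv_chroma,
            "hue": colour.hue,
            "predicted_hue": predict_hue(q1_meas, optical),
        })
    return pd.DataFrame.from_records(rows)


def export_cohort(
    truths: list[TrueParameters],
    curves: dict[str, list[ScatteringCurve]],
    spectra: dict[str, list[ReflectanceSpectrum]],
    outdir,
    config: CohortConfig | None = None,
) -> None:
    """Write a cohort to disk in the layout the analysis CLI consumes.

    ``<outdir>/curves/<sample>_p<position>_e<exposure>.dat``, a long-format
    ``spectra.csv``, a ``truth.csv`` with the latent parameters and, when a
    config is given, ``config.yaml``.
    """
    from .io import write_curve

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not truths:
        import warnings

        warnings.warn("exporting an empty cohort", stacklevel=2)
    curve_dir = outdir / "curves"
    curve_dir.mkdir(exist_ok=True)
    for sample, sample_curves in curves.items():
        for c in sample_curves:
            name = f"{sample}_p{c.meta.get('position', 0):02d}_e{c.meta.get('exposure', 0):02d}.dat"
            write_curve(c, curve_dir / name)

    spec_rows = []
    for sample, sample_spectra in spectra.items():
        for s in sample_spectra:
            spec_rows.append(pd.DataFrame({
                "wavelength_nm": s.wavelength,
                "reflectance_pct": s.reflectance,
                "sample": sample,
                "replicate": s.meta.get("replicate", 0),
            }))
    spec_df = (
        pd.concat(spec_rows, ignore_index=True)
        if spec_rows
        else pd.DataFrame(columns=["wavelength_nm", "reflectance_pct", "sample", "replicate"])
    )
    spec_df.to_csv(outdir / "spectra.csv", index=False)

    truth_df = pd.DataFrame.from_records([
        {
            "sample": t.sample, "sex": t.sex, "year": t.year,
            **{k: getattr(t.peak, k) for k in ("c", "a1", "q1", "h1", "alpha", "beta", "h2")},
            "q2": t.peak.q2, "a2": t.peak.a2,
            "brightness_true": t.brightness_true, "hue_true": t.hue_true,
        }
        for t in truths
    ])
    truth_df.to_csv(outdir / "truth.csv", index=False)

    if config is not None:
        data = asdict(config)
        (outdir / "config.yaml").write_text(yaml.safe_dump(data, sort_keys=False))


def config_from_yaml(path) -> CohortConfig:
    """Load a CohortConfig from YAML (SexTrait fields as 5-value mappings)."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    base = CohortConfig()
    for key, value in data.items():
        if isinstance(getattr(base, key, None), SexTrait) and isinstance(value, dict):
            kwargs[key] = SexTrait(**value)
        elif key in ("q_grid", "year_levels") and isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return replace(base, **kwargs)
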