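"""Hue prediction from nanostructural periodicity.

Coherent scattering by the quasi-ordered spongy layer selectively
reinforces the wavelength

    lambda = 2 * (2*pi/q1) * n_avg,

where 2*pi/q1 is the Bragg repeat distance of the primary scattering peak
and n_avg the volume-averaged refractive index of the keratin-air
composite.  With keratin index 1.58 and keratin volume fraction 0.57
(air = 1.0), linear volume-weighted mixing gives n_avg = 1.3306, i.e. 1.33
at two decimals.  A squared-index (Maxwell Garnett-like) mixing rule is
available as an option but is not the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .porodfit import bragg_spacing

N_KERATIN_DEFAULT = 1.58
KERATIN_FRACTION_DEFAULT = 0.57


def average_refractive_index(
    n_keratin: float = N_KERATIN_DEFAULT,
    keratin_fraction: float = KERATIN_FRACTION_DEFAULT,
    n_air: float = 1.0,
    mixing: str = "linear",
) -> float:
    """Volume-averaged refractive index of the spongy keratin-air layer.

    ``mixing='linear'`` (default) is the volume-weighted mean of indices;
    ``mixing='squared'`` mixes the squared indices (dielectric averaging)
    and returns the square root.
    """
    if not 0.0 <= keratin_fraction <= 1.0:
        raise ValueError("keratin_fraction must be in [0, 1]")
    if n_keratin < 1.0 or n_air < 1.0:
        raise ValueError("refractive indices must be >= 1")
    f = keratin_fraction
    if mixing == "linear":
        return f * n_keratin + (1.0 - f) * n_air
    if mixing == "squared":
        return float(np.sqrt(f * n_keratin**2 + (1.0 - f) * n_air**2))
    raise ValueError("mixing must be 'linear' or 'squared'")


@dataclass(frozen=True)
class OpticalModel:
    """Optical constants of the spongy layer used for hue prediction."""

    n_keratin: float = N_KERATIN_DEFAULT
    keratin_fraction: float = KERATIN_FRACTION_DEFAULT
    n_air: float = 1.0
    mixing: str = "linear"

    @property
    def n_avg(self) -> float:
        return average_refractive_index(
            self.n_keratin, self.keratin_fraction, self.n_air, self.mixing
        )


def predict_hue(q1, optical: OpticalModel | None = None):
    """Predicted hue (nm) from the primary peak position q1 (nm^-1).

    lambda = 2 * (2*pi/q1) * n_avg; strictly decreasing in q1.
    """
    optical = optical or OpticalModel()
    q = np.asarray(q1, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q1 must be positive")
    lam = 2.0 * (2.0 * np.pi / q) * optical.n_avg
    return lam if lam.ndim else float(lam)


def add_predicted_hue(fits: pd.DataFrame, optical: OpticalModel | None = None) -> pd.DataFrame:
    """Append a predicted_hue_nm column to a per-sample fit table."""
    out = fits.copy()
    out["predicted_hue_nm"] = [predict_hue(q, optical) for q in out["q1"]]
    return out


def _consistency_check(q: float) -> float:
    # predict_hue(q) must equal 2*n_avg*bragg_spacing(q) by construction
    return 2.0 * OpticalModel().n_avg * bragg_spacing(q)
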