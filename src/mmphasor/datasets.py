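"""Bundled reference measurements.

Small printed reference data acquired on a Mueller-matrix laser scanning
microscope (808 nm, epi geometry, 256x256 pixels): ROI-averaged normalized
Mueller matrices of air and of a transparent adhesive film with their
per-element standard deviations, and the ROI-averaged retardance /
fast-axis statistics of a collagen fiber recorded at five physical sample
rotations.

The instrument records the circular Stokes component with the opposite
handedness to this package's detector-view convention (its epi mirror
reverses the sense of circular polarization), so the matrix loaders
convert by default via :func:`mmphasor.core.flip_circular_handedness`;
pass ``handedness="instrument"`` for the raw values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import flip_circular_handedness

__all__ = [
    "reference_air_mueller",
    "reference_air_sd",
    "reference_film_mueller",
    "reference_film_sd",
    "REFERENCE_LC_VALUES",
    "collagen_rotation_series",
]

_AIR = np.array([
    [1.000, 0.003, -0.009, 0.012],
    [-0.005, 0.999, -0.002, -0.008],
    [0.011, 0.007, 1.002, -0.011],
    [0.007, -0.009, 0.004, 1.014],
])
_AIR_SD = np.array([
    [0.0, 0.009, 0.011, 0.022],
    [0.024, 0.022, 0.025, 0.049],
    [0.019, 0.018, 0.025, 0.042],
    [0.014, 0.010, 0.012, 0.031],
])
_FILM = np.array([
    [1.000, 0.012, -0.005, 0.071],
    [-0.012, 1.023, -0.222, -0.327],
    [0.007, 0.376, 0.678, 1.022],
    [-0.023, 0.055, -0.342, 0.562],
])
_FILM_SD = np.array([
    [0.0, 0.009, 0.011, 0.029],
    [0.029, 0.032, 0.026, 0.063],
    [0.054, 0.024, 0.026, 0.078],
    [0.016, 0.019, 0.018, 0.036],
])

# ROI-averaged per-pixel decomposition statistics reported with the
# matrices above (mean, SD).
REFERENCE_LC_VALUES = {
    "air": {"D": (0.027, 0.014), "R": (1.9, 0.9), "P_d": (1.007, 0.01)},
    "film": {"D": (0.072, 0.026), "R": (55.5, 1.9),
             "alpha_R": (-85.7, 0.9), "P_d": (1.051, 0.029)},
}


def _matrix(raw, handedness):
    if handedness == "canonical":
        return flip_circular_handedness(raw)
    if handedness == "instrument":
        return raw.copy()
    raise ValueError("handedness must be 'canonical' or 'instrument'")


def reference_air_mueller(handedness: str = "canonical") -> np.ndarray:
    """ROI-averaged normalized Mueller matrix of air."""
    return _matrix(_AIR, handedness)


def reference_film_mueller(handedness: str = "canonical") -> np.ndarray:
    """ROI-averaged normalized Mueller matrix of the transparent film."""
    return _matrix(_FILM, handedness)


def reference_air_sd() -> np.ndarray:
    """Per-element SDs of the air measurement (noise model input)."""
    return _AIR_SD.copy()


def reference_film_sd() -> np.ndarray:
    return _FILM_SD.copy()


def collagen_rotation_series() -> pd.DataFrame:
    """Collagen-fiber (R, alpha_R) estimates at five sample rotations.

    One row per physical rotation of the sample (degrees); columns hold the
    ROI-averaged estimates from the Lu-Chipman decomposition and from the
    RCP-phasor readout, in degrees.
    """
    return pd.DataFrame(
        {
            "rotation": [0.0, 45.0, 90.0, 135.0, 180.0],
            "lc_R": [45.4, 58.7, 59.6, 60.9, 64.6],
            "lc_alpha_R": [-68.6, -20.4, 16.3, 55.8, 104.4],
            "phasor_R": [69.9, 51.2, 62.3, 56.1, 71.9],
            "phasor_alpha_R": [-69.2, -38.2, 9.3, 51.9, 95.6],
        }
    )
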