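"""Forward simulation of a Mueller-matrix scanning polarimeter.

The polarimeter sequentially generates four input polarization states
(PSG, columns of ``W``) and projects the light emerging from the sample
onto four analyzer states (PSA, rows of ``A``).  The 16 recorded
intensities per pixel form the matrix ``I = A M W``, inverted back to the
sample matrix by ``M = A^{-1} I W^{-1}``.  Measurement noise is modeled as
per-element zero-mean Gaussian perturbations of the (m00-normalized)
Mueller matrix, with standard deviations taken by default from the
bundled air calibration measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    MuellerImage,
    STOKES_45,
    STOKES_H,
    STOKES_RCP,
    STOKES_V,
)
from . import datasets

__all__ = [
    "InstrumentModel",
    "condition_number",
    "simulate_measurement",
    "reconstruct_mueller",
    "correct_microscope",
]

_IDEAL_STATES = (STOKES_H, STOKES_V, STOKES_45, STOKES_RCP)


@dataclass
class InstrumentModel:
    """PSG states, PSA projections and per-element noise levels.

    ``W``: 4x4 matrix whose columns are the generator Stokes vectors.
    ``A``: 4x4 matrix whose rows are the analyzer projection vectors; an
    ideal projector onto state ``s_hat`` is ``0.5 * (1, s_hat)``.
    ``sigma``: per-element Gaussian noise SDs on the normalized Mueller
    matrix (``sigma[0, 0] = 0`` by normalization).
    """

    W: np.ndarray
    A: np.ndarray
    sigma: np.ndarray = field(default_factory=lambda: np.zeros((4, 4)))

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.W.shape != (4, 4) or self.A.shape != (4, 4):
            raise ValueError("W and A must be 4x4")
        if np.any(self.sigma < 0):
            raise ValueError("noise SDs must be non-negative")

    @classmethod
    def ideal(cls, noise: bool = False) -> "InstrumentModel":
        """Ideal H/V/45/RCP generator and analyzer set.

        With ``noise=True`` the air-calibration SDs are attached.
        """
        W = np.stack(_IDEAL_STATES, axis=1)
        A = 0.5 * np.stack(_IDEAL_STATES, axis=0)
        sigma = datasets.reference_air_sd() if noise else np.zeros((4, 4))
        return cls(W=W, A=A, sigma=sigma)

    @property
    def generator_condition_number(self) -> float:
        return condition_number(list(self.W.T))

    def is_complete(self) -> bool:
        return np.isfinite(self.generator_condition_number) and np.isfinite(
            condition_number(list(self.A)))


def condition_number(states) -> float:
    """2-norm condition number of the matrix with the states as columns.

    Infinity for a rank-deficient state set.  Lower is better; the ideal
    H/V/45/RCP set gives about 3.23.
    """
    m = np.stack([np.asarray(s, dtype=float) for s in states], axis=1)
    if np.linalg.matrix_rank(m) < m.shape[1]:
        return float("inf")
    return float(np.linalg.cond(m))


def apply_mueller_noise(m, sigma, rng) -> np.ndarray:
    """Add independent per-element Gaussian perturbations to each matrix."""
    m = np.asarray(m, dtype=float)
    return m + rng.normal(0.0, np.broadcast_to(sigma, m.shape))


def simulate_measurement(img, inst: InstrumentModel, seed=None,
                         noise: bool = True):
    """Simulate the 16 polarization-resolved intensities per pixel.

    Returns an array of shape ``(..., 4, 4)`` indexed (analyzer, input).
    Noise (when enabled and ``inst.sigma`` is nonzero) perturbs the Mueller
    matrix before projection, with independent draws per pixel and element.
    A rank-deficient W or A triggers a warning (reconstruction would fail)
    but the forward simulation proceeds.
    """
    import warnings

    m = img.m if isinstance(img, MuellerImage) else np.asarray(img, dtype=float)
    if not np.isfinite(condition_number(list(inst.W.T))) or not np.isfinite(
            condition_number(list(inst.A))):
        warnings.warn("rank-deficient PSG/PSA states: reconstruction will fail",
                      stacklevel=2)
    if noise and np.any(inst.sigma > 0):
        rng = np.random.default_rng(seed)
        m = apply_mueller_noise(m, inst.sigma, rng)
    return inst.A @ m @ inst.W


def reconstruct_mueller(intensities, inst: InstrumentModel) -> MuellerImage:
    """Invert the measurement: ``M = A^{-1} I W^{-1}`` per pixel."""
    for name, mat in (("A", inst.A), ("W", inst.W)):
        if np.linalg.matrix_rank(mat) < 4:
            raise np.linalg.LinAlgError(f"instrument matrix {name} is singular")
    I = np.asarray(intensities, dtype=float)
    m = np.linalg.inv(inst.A) @ I @ np.linalg.inv(inst.W)
    if m.ndim == 2:
        return m
    return MuellerImage(m)


def correct_microscope(m_mes: MuellerImage, m_mu: MuellerImage):
    """Remove the microscope's polarimetric fingerprint.

    Applies ``M_sample = M_mes @ M_mu^{-1}`` pixel by pixel.  Pixels where
    the fingerprint matrix is singular are masked and counted instead of
    aborting the whole image.
    """
    mes = m_mes.m if isinstance(m_mes, MuellerImage) else np.asarray(m_mes, float)
    mu = m_mu.m if isinstance(m_mu, MuellerImage) else np.asarray(m_mu, float)
    det = np.linalg.det(mu)
    singular = np.abs(det) < 1e-12
    mu_safe = np.where(singular[..., None, None], np.eye(4), mu)
    out = mes @ np.linalg.inv(mu_safe)
    out = np.where(singular[..., None, None], np.nan, out)
    img = MuellerImage(out, mask=singular,
                       meta={"singular_pixels": int(singular.sum())})
    return img
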