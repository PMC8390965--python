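"""Synthetic phantom scenes for exercising the analysis pipeline.

Every scene returns a :class:`Phantom` carrying the Mueller image, integer
region labels and per-pixel ground-truth retardance / fast-axis maps, so
estimator output can be scored pixel by pixel.  All randomness flows from
the seed recorded in each ``PhantomSpec``; outputs are reproducible bit
for bit.

Scenes
------
``air``
    Identity matrices plus per-element Gaussian noise at the air
    calibration SD levels.
``film_on_air``
    A uniformly retarding film patch (defaults: the measured film values,
    R = 55.5 deg at alpha_R = -85.7 deg) surrounded by air, with
    region-matched noise levels.
``layered_fibers``
    A stack of identically retarding layers rotated 10 deg from one to the
    next (type-I collagen defaults: dn = 0.0017, e = 50 um at 808 nm, so
    R1 = 37.87 deg per layer).  Disorder is modeled as per-pixel,
    per-layer fast-axis jitter (sigma_alpha = 14 deg, calibrated once to a
    single-fiber ROI depolarization index of 0.97) on top of per-element
    measurement noise; ROI averaging of the disordered medium is what
    depolarizes the scene-level matrix.
``rotated_fiber``
    A horizontal fiber stripe whose fast axis is offset by a configurable
    scene rotation; used for rotation-covariance checks.
``striped_myosin``
    Alternating stripes with fast axes at -20 and +20 deg, emulating the
    sarcomere-scale orientation alternation of muscle tissue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict

from .core import MuellerImage, retardance_from_physical, retarder_mueller, fold_orientation
from . import datasets

__all__ = ["PhantomSpec", "Phantom", "make_phantom", "COLLAGEN_LAYER_RETARDANCE"]

# Single type-I collagen layer: dn = 0.0017, e = 50 um, lambda = 808 nm.
COLLAGEN_LAYER_RETARDANCE = retardance_from_physical(0.0017, 50.0, 808.0)


class PhantomSpec(BaseModel):
    """Validated description of a synthetic scene.

    Unknown keys are rejected; the seed is recorded in the phantom output
    so every scene is reproducible.
    """

    model_config = ConfigDict(extra="forbid")

    scene: Literal["air", "film_on_air", "layered_fibers",
                   "rotated_fiber", "striped_myosin"]
    height: int = 256
    width: int = 256
    seed: int = 0
    noise: bool = True

    # film_on_air
    film_retardance: float = 55.5
    film_orientation: float = -85.7

    # layered_fibers
    n_layers: int = 1
    layer_retardance: float = COLLAGEN_LAYER_RETARDANCE
    layer_step_deg: float = 10.0
    orientation_jitter_deg: float = 14.0

    # rotated_fiber
    fiber_retardance: float = 56.3
    fiber_orientation: float = -68.6
    rotation_deg: float = 0.0

    # striped_myosin
    stripe_period_px: int = 16
    stripe_orientation_deg: float = 20.0
    myosin_retardance: float = 30.0


@dataclass
class Phantom:
    """A synthetic scene plus its ground truth."""

    mueller: MuellerImage
    labels: np.ndarray          # integer region id per pixel (0 = air)
    region_names: dict
    truth_R: np.ndarray         # NaN where no retarder is present
    truth_alpha: np.ndarray
    spec: PhantomSpec

    def region_mask(self, name: str) -> np.ndarray:
        ids = [k for k, v in self.region_names.items() if v == name]
        if not ids:
            raise KeyError(name)
        return np.isin(self.labels, ids)


def _air_matrices(shape, sigma, rng, noise):
    m = np.broadcast_to(np.eye(4), shape + (4, 4)).copy()
    if noise:
        m += rng.normal(0.0, np.broadcast_to(sigma, m.shape))
    return m


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Generate the scene described by ``spec``."""
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height, spec.width)
    builder = {
        "air": _build_air,
        "film_on_air": _build_film_on_air,
        "layered_fibers": _build_layered,
        "rotated_fiber": _build_rotated_fiber,
        "striped_myosin": _build_striped,
    }[spec.scene]
    return builder(spec, rng, shape)


def _finish(spec, m, labels, names, truth_R, truth_alpha):
    img = MuellerImage(m, meta={"seed": spec.seed,
                                "spec": spec.model_dump()})
    return Phantom(mueller=img, labels=labels, region_names=names,
                   truth_R=truth_R, truth_alpha=truth_alpha, spec=spec)


def _build_air(spec, rng, shape):
    m = _air_matrices(shape, datasets.reference_air_sd(), rng, spec.noise)
    nan = np.full(shape, np.nan)
    return _finish(spec, m, np.zeros(shape, dtype=np.int8), {0: "air"}, nan, nan)


def _build_film_on_air(spec, rng, shape):
    h, w = shape
    labels = np.zeros(shape, dtype=np.int8)
    labels[h // 4: 3 * h // 4, w // 4: 3 * w // 4] = 1
    film = labels == 1
    m = _air_matrices(shape, datasets.reference_air_sd(), rng, spec.noise)
    film_m = retarder_mueller(spec.film_retardance, spec.film_orientation)
    m[film] = film_m
    if spec.noise:
        m[film] += rng.normal(0.0, np.broadcast_to(
            datasets.reference_film_sd(), (int(film.sum()), 4, 4)))
    truth_R = np.where(film, spec.film_retardance, np.nan)
    truth_alpha = np.where(film, fold_orientation(spec.film_orientation), np.nan)
    return _finish(spec, m, labels, {0: "air", 1: "film"}, truth_R, truth_alpha)


def _build_layered(spec, rng, shape):
    if spec.n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    m = np.broadcast_to(np.eye(4), shape + (4, 4)).copy()
    sigma = datasets.reference_air_sd()
    for k in range(spec.n_layers):
        alpha = np.full(shape, k * spec.layer_step_deg)
        if spec.noise and spec.orientation_jitter_deg > 0:
            alpha = alpha + rng.normal(0.0, spec.orientation_jitter_deg, shape)
        layer = retarder_mueller(np.full(shape, spec.layer_retardance), alpha)
        if spec.noise:
            layer = layer + rng.normal(0.0, np.broadcast_to(sigma, layer.shape))
        m = layer @ m
    labels = np.ones(shape, dtype=np.int8)
    truth_R = np.full(shape, spec.n_layers * spec.layer_retardance)
    mean_alpha = fold_orientation(spec.layer_step_deg * (spec.n_layers - 1) / 2.0)
    truth_alpha = np.full(shape, mean_alpha)
    return _finish(spec, m, labels, {1: "fibers"}, truth_R, truth_alpha)


def _build_rotated_fiber(spec, rng, shape):
    h, w = shape
    labels = np.zeros(shape, dtype=np.int8)
    labels[3 * h // 8: 5 * h // 8, :] = 1
    fiber = labels == 1
    alpha = fold_orientation(spec.fiber_orientation + spec.rotation_deg)
    m = _air_matrices(shape, datasets.reference_air_sd(), rng, spec.noise)
    m[fiber] = retarder_mueller(spec.fiber_retardance, alpha)
    if spec.noise:
        m[fiber] += rng.normal(0.0, np.broadcast_to(
            datasets.reference_air_sd(), (int(fiber.sum()), 4, 4)))
    truth_R = np.where(fiber, spec.fiber_retardance, np.nan)
    truth_alpha = np.where(fiber, alpha, np.nan)
    return _finish(spec, m, labels, {0: "air", 1: "fiber"}, truth_R, truth_alpha)


def _build_striped(spec, rng, shape):
    h, w = shape
    rows = np.arange(h)[:, None]
    odd = ((rows // spec.stripe_period_px) % 2 == 1)
    odd = np.broadcast_to(odd, shape)
    labels = np.where(odd, 2, 1).astype(np.int8)
    a = spec.stripe_orientation_deg
    alpha = np.where(odd, a, -a).astype(float)
    m = retarder_mueller(np.full(shape, spec.myosin_retardance), alpha)
    if spec.noise:
        m = m + rng.normal(0.0, np.broadcast_to(
            datasets.reference_air_sd(), m.shape))
    truth_R = np.full(shape, spec.myosin_retardance)
    return _finish(spec, m, labels,
                   {1: "fiber_minus", 2: "fiber_plus"}, truth_R, alpha)
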