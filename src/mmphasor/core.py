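"""Stokes-Mueller algebra and elementary polarimetric elements.

Conventions
-----------
* Stokes basis: ``S1 = I_H - I_V``, ``S2 = I_45 - I_135``, ``S3 = I_RCP -
  I_LCP`` (right-handed, detector-view convention).
* All public angles are in degrees; fast-axis orientations are reported on
  the 180-degree-periodic axis, folded into ``(-90, 90]``.
* A linear retarder of retardance ``R`` and fast-axis azimuth ``alpha`` has
  the Mueller matrix whose lower-right 3x3 block is the rotation by ``R``
  about the equatorial Poincare axis ``(cos 2a, sin 2a, 0)``, with the sign
  convention ``m13 = -sin(2a) sin(R)`` (a right-circular probe leaves the
  retarder with phasor phase ``+90`` degrees when ``alpha = 0``).

Functions broadcast over leading axes, so a single matrix, an image of
matrices ``(H, W, 4, 4)`` or any batch can be passed interchangeably.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "StokesVector",
    "MuellerImage",
    "RetarderSpec",
    "LayeredMediumSpec",
    "EquivalentRetarder",
    "stokes_from_intensities",
    "intensities_from_stokes",
    "propagate",
    "degree_of_polarization",
    "retarder_mueller",
    "retardance_from_physical",
    "wrap_retardance",
    "double_pass_correct",
    "layered_mueller",
    "equivalent_retarder",
    "flip_circular_handedness",
    "fold_orientation",
]

# Ideal generator states (detector view).
STOKES_H = np.array([1.0, 1.0, 0.0, 0.0])
STOKES_V = np.array([1.0, -1.0, 0.0, 0.0])
STOKES_45 = np.array([1.0, 0.0, 1.0, 0.0])
STOKES_135 = np.array([1.0, 0.0, -1.0, 0.0])
STOKES_RCP = np.array([1.0, 0.0, 0.0, 1.0])
STOKES_LCP = np.array([1.0, 0.0, 0.0, -1.0])


def fold_orientation(alpha_deg):
    """Fold an axis orientation (180-degree periodic) into ``(-90, 90]``."""
    a = np.asarray(alpha_deg, dtype=float)
    folded = np.mod(-a + 90.0, 180.0)
    folded = 90.0 - folded
    return folded if folded.ndim else float(folded)


@dataclass
class StokesVector:
    """A (S0, S1, S2, S3) polarization state.

    ``S0`` is the total intensity; the remaining components measure the
    horizontal/vertical, diagonal and circular balance in the same units.
    Noisy experimental vectors may carry a degree of polarization slightly
    above one; they are flagged, not rejected.
    """

    s: np.ndarray

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float)
        if self.s.shape[-1] != 4:
            raise ValueError("Stokes vector needs 4 components")

    @property
    def S0(self):
        return self.s[..., 0]

    @property
    def dop(self):
        return degree_of_polarization(self.s)

    def is_physical(self, tol: float = 1e-9) -> np.ndarray:
        return (self.S0 >= 0) & (self.dop <= 1.0 + tol)


def degree_of_polarization(s) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.linalg.norm(s[..., 1:], axis=-1) / s[..., 0]


def stokes_from_intensities(i0, i45, i90, i135, i_rcp, i_lcp) -> np.ndarray:
    """Assemble a Stokes vector from the six polarization-resolved intensities.

    ``S0 = I0 + I90``, ``S1 = I0 - I90``, ``S2 = I45 - I135``,
    ``S3 = I_RCP - I_LCP``.
    """
    parts = [np.asarray(x, dtype=float) for x in (i0, i45, i90, i135, i_rcp, i_lcp)]
    if any(np.any(p < 0) for p in parts):
        raise ValueError("intensities must be non-negative")
    i0, i45, i90, i135, i_rcp, i_lcp = np.broadcast_arrays(*parts)
    return np.stack([i0 + i90, i0 - i90, i45 - i135, i_rcp - i_lcp], axis=-1)


def intensities_from_stokes(s) -> tuple:
    """Linear analyzer intensities (I0, I90, I45, I135) of a Stokes vector.

    May return negative values for unphysical inputs; callers that care
    should check :func:`degree_of_polarization`.
    """
    s = np.asarray(s, dtype=float)
    i0 = 0.5 * (s[..., 0] + s[..., 1])
    i90 = 0.5 * (s[..., 0] - s[..., 1])
    i45 = 0.5 * (s[..., 0] + s[..., 2])
    i135 = 0.5 * (s[..., 0] - s[..., 2])
    return i0, i90, i45, i135


def propagate(mueller, s_in) -> np.ndarray:
    """Apply a Mueller matrix (or batch) to a Stokes vector (or batch)."""
    m = np.asarray(mueller, dtype=float)
    s = np.asarray(s_in, dtype=float)
    return np.einsum("...ij,...j->...i", m, s)


@dataclass(frozen=True)
class RetarderSpec:
    """A linear retarder: retardance plus fast-axis orientation.

    Parameters
    ----------
    retardance : float
        Retardance in the units given by ``unit``; may exceed a full wave.
    orientation : float
        Fast-axis azimuth in degrees, folded into ``(-90, 90]`` on access.
    unit : str
        ``"deg"`` or ``"rad"``; the tag is mandatory so stored specs are
        unambiguous.
    birefringence, thickness_um, wavelength_nm : float, optional
        Physical triple (dimensionless ``n_e - n_o``, micrometres,
        nanometres).  When present it must reproduce the retardance via
        ``R = 360 * dn * e / lambda``.
    """

    retardance: float
    orientation: float
    unit: str = "deg"
    birefringence: float | None = None
    thickness_um: float | None = None
    wavelength_nm: float | None = None

    def __post_init__(self):
        if self.unit not in ("deg", "rad"):
            raise ValueError("unit must be 'deg' or 'rad'")
        triple = (self.birefringence, self.thickness_um, self.wavelength_nm)
        if any(v is not None for v in triple):
            if any(v is None for v in triple):
                raise ValueError("physical triple must be complete")
            expected = retardance_from_physical(*triple)
            if abs(expected - self.retardance_deg) > 1e-6 * max(1.0, abs(expected)):
                raise ValueError(
                    "retardance inconsistent with physical triple: "
                    f"{self.retardance_deg:.6g} vs {expected:.6g} deg"
                )

    @property
    def retardance_deg(self) -> float:
        r = float(self.retardance)
        return np.degrees(r) if self.unit == "rad" else r

    @property
    def orientation_deg(self) -> float:
        return fold_orientation(float(self.orientation))

    @classmethod
    def from_physical(cls, birefringence, thickness_um, wavelength_nm, orientation=0.0):
        r = retardance_from_physical(birefringence, thickness_um, wavelength_nm)
        return cls(r, orientation, "deg", birefringence, thickness_um, wavelength_nm)


@dataclass(frozen=True)
class LayeredMediumSpec:
    """Ordered stack of retarding layers; the first entry is hit first."""

    layers: tuple

    def __post_init__(self):
        if len(self.layers) == 0:
            raise ValueError("a layered medium needs at least one layer")


def retardance_from_physical(birefringence, thickness_um, wavelength_nm) -> float:
    """Unwrapped retardance ``360 * dn * e / lambda`` in degrees.

    ``thickness_um`` is in micrometres and ``wavelength_nm`` in nanometres;
    the result may exceed 360 degrees for thick samples.
    """
    if thickness_um <= 0 or wavelength_nm <= 0:
        raise ValueError("thickness and wavelength must be positive")
    return 360.0 * birefringence * (thickness_um * 1000.0) / wavelength_nm


def wrap_retardance(r_deg):
    """Fold an absolute retardance onto the observable interval [0, 180].

    A retarder of retardance R is indistinguishable from one of 360 - R, so
    measured values live on [0, 180] degrees.
    """
    r = np.asarray(r_deg, dtype=float)
    if np.any(r < 0):
        raise ValueError("retardance must be non-negative")
    m = np.mod(r, 360.0)
    out = np.where(m > 180.0, 360.0 - m, m)
    return out if out.ndim else float(out)


def double_pass_correct(r_deg):
    """Epi-geometry correction ``R_exact = 360 - R_measured``.

    In reflection imaging the beam crosses the sample twice and picks up a
    pi dephasing at the mirror; this opt-in correction undoes the effect.
    Input must lie in [0, 360].
    """
    r = np.asarray(r_deg, dtype=float)
    if np.any((r < 0) | (r > 360)):
        raise ValueError("measured retardance must lie in [0, 360] degrees")
    out = 360.0 - r
    return out if out.ndim else float(out)


def retarder_mueller(retardance_deg, orientation_deg=None) -> np.ndarray:
    """Mueller matrix of a linear retarder.

    Accepts either ``(retardance_deg, orientation_deg)`` arrays (broadcast
    together) or a single :class:`RetarderSpec`.
    """
    if isinstance(retardance_deg, RetarderSpec):
        spec = retardance_deg
        retardance_deg, orientation_deg = spec.retardance_deg, spec.orientation_deg
    r = np.radians(np.asarray(retardance_deg, dtype=float))
    a = np.radians(np.asarray(orientation_deg, dtype=float))
    r, a = np.broadcast_arrays(r, a)
    c = np.cos(2 * a)
    s = np.sin(2 * a)
    u = np.cos(r)
    v = np.sin(r)
    z = np.zeros_like(c)
    o = np.ones_like(c)
    m = np.stack(
        [
            np.stack([o, z, z, z], axis=-1),
            np.stack([z, c * c + s * s * u, c * s * (1 - u), -s * v], axis=-1),
            np.stack([z, c * s * (1 - u), s * s + c * c * u, c * v], axis=-1),
            np.stack([z, s * v, -c * v, u], axis=-1),
        ],
        axis=-2,
    )
    return m


def layered_mueller(spec, order: str = "traversal") -> np.ndarray:
    """Mueller matrix of a stack of retarders.

    With ``order="traversal"`` (default) the first layer in ``spec`` is the
    first crossed by the light, so later layers left-multiply:
    ``M = M_N ... M_2 M_1``.  ``order="reversed"`` flips the product for
    sensitivity studies.
    """
    if isinstance(spec, LayeredMediumSpec):
        layers = spec.layers
    else:
        layers = tuple(spec)
    if len(layers) == 0:
        raise ValueError("a layered medium needs at least one layer")
    if order not in ("traversal", "reversed"):
        raise ValueError("order must be 'traversal' or 'reversed'")
    mats = [retarder_mueller(l) for l in layers]
    if order == "reversed":
        mats = mats[::-1]
    m = mats[0]
    for layer in mats[1:]:
        m = layer @ m
    return m


@dataclass(frozen=True)
class EquivalentRetarder:
    """Single-retarder equivalent of a retarder product.

    ``total_deg`` is the rotation angle of the combined Poincare rotation.
    A product of linear retarders at different azimuths is in general an
    *elliptical* retarder; ``linear_deg`` is the linear retardance of its
    circular-linear factorization (the quantity a rotating-analyzer
    modulation measurement reads out), ``optical_rotation_deg`` the
    accompanying circular part, and ``azimuth_deg`` the fast-axis azimuth
    of the linear factor.
    """

    total_deg: float
    linear_deg: float
    optical_rotation_deg: float
    azimuth_deg: float


def _quat_multiply(q, p):
    w1, x1, y1, z1 = q
    w2, x2, y2, z2 = p
    return np.array(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )


def equivalent_retarder(spec) -> EquivalentRetarder:
    """Compose retarding layers by quaternion (half-angle) multiplication.

    For two co-axial layers the total retardance is the plain sum; for two
    layers separated by ``delta_alpha`` it satisfies
    ``cos(R_eq/2) = cos^2(R/2) - sin^2(R/2) cos(2 delta_alpha)``.
    """
    if isinstance(spec, LayeredMediumSpec):
        layers = spec.layers
    else:
        layers = tuple(spec)
    q = np.array([1.0, 0.0, 0.0, 0.0])
    for layer in layers:
        if not isinstance(layer, RetarderSpec):
            raise TypeError("layers must be RetarderSpec instances")
        h = np.radians(layer.retardance_deg) / 2.0
        a = np.radians(layer.orientation_deg)
        ql = np.array([np.cos(h), np.sin(h) * np.cos(2 * a), np.sin(h) * np.sin(2 * a), 0.0])
        q = _quat_multiply(ql, q)
    w, x, y, z = q
    total = 2.0 * np.degrees(np.arccos(np.clip(abs(w), 0.0, 1.0)))
    linear = 2.0 * np.degrees(np.arctan2(np.hypot(x, y), np.hypot(w, z)))
    rot = 2.0 * np.degrees(np.arctan2(z, w)) if (abs(w) + abs(z)) > 0 else 0.0
    azimuth = fold_orientation(0.5 * np.degrees(np.arctan2(y, x))) if (abs(x) + abs(y)) > 0 else 0.0
    return EquivalentRetarder(total, linear, rot, azimuth)


def flip_circular_handedness(m) -> np.ndarray:
    """Flip the sign convention of the circular Stokes component.

    Conjugates the matrix by ``diag(1, 1, 1, -1)``: the S3 row and column
    change sign, the rest is untouched.  Useful for data recorded with the
    opposite circular-handedness convention (e.g. epi-geometry instruments
    whose mirror reverses the sense of circular polarization).
    """
    m = np.asarray(m, dtype=float).copy()
    m[..., 3, :3] *= -1.0
    m[..., :3, 3] *= -1.0
    return m


@dataclass
class MuellerImage:
    """Per-pixel 4x4 Mueller matrices with bookkeeping metadata.

    ``m`` has shape ``(height, width, 4, 4)``.  All pixels share one
    normalization convention, recorded in ``normalized``.
    """

    m: np.ndarray
    normalized: bool = False
    pixel_size_um: float | None = None
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.m = np.asarray(self.m, dtype=float)
        if self.m.ndim != 4 or self.m.shape[-2:] != (4, 4):
            raise ValueError("expected an array of shape (H, W, 4, 4)")

    @property
    def shape(self):
        return self.m.shape[:2]

    @classmethod
    def uniform(cls, matrix, shape, **kw):
        m = np.broadcast_to(np.asarray(matrix, dtype=float), shape + (4, 4)).copy()
        return cls(m, **kw)

    @classmethod
    def from_planes(cls, planes, order: str = "row-major", **kw):
        """Build from a 16-plane stack (16, H, W) in m00..m33 order."""
        planes = np.asarray(planes, dtype=float)
        if planes.shape[0] != 16:
            raise ValueError(f"expected 16 planes, got {planes.shape[0]}")
        m = np.moveaxis(planes, 0, -1).reshape(planes.shape[1], planes.shape[2], 4, 4)
        if order == "column-major":
            m = np.swapaxes(m, -1, -2)
        elif order != "row-major":
            raise ValueError("order must be 'row-major' or 'column-major'")
        return cls(m, **kw)

    def to_planes(self, order: str = "row-major") -> np.ndarray:
        m = self.m
        if order == "column-major":
            m = np.swapaxes(m, -1, -2)
        return np.moveaxis(m.reshape(*self.shape, 16), -1, 0)

    def normalize(self) -> "MuellerImage":
        """Return a copy normalized pixelwise by m00."""
        m00 = self.m[..., 0:1, 0:1]
        with np.errstate(divide="ignore", invalid="ignore"):
            m = self.m / m00
        return MuellerImage(m, normalized=True, pixel_size_um=self.pixel_size_um,
                            mask=self.mask, meta=dict(self.meta))
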