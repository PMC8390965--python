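"""Phasor analysis of Mueller-matrix images.

The Mueller image is converted into four polarization-resolved intensity
stacks (one per generator state H, V, 45, RCP, four analyzer angles each),
and each stack is mapped to a single-frequency Fourier pair

    g = sum_theta I_theta cos(2 pi theta / Theta) / sum_theta I_theta
    s = sum_theta I_theta sin(2 pi theta / Theta) / sum_theta I_theta

with period Theta = 180 degrees.  Each pixel becomes a point (g, s) in
phasor space with modulation ``M = sqrt(g^2 + s^2)`` (at most 0.5 for
physical states) and phase ``phi = atan2(s, g)``.

For a linear retarder the right-circular-probe phasor obeys the closed
forms ``M = sin(R)/2`` and ``phi = 90 + 2 alpha_R`` degrees, which invert to

    alpha_R = phi/2 - 45          (phi taken in (-90, 270])
    R       = arcsin(2 M)         or  180 - arcsin(2 M)

The two retardance branches are distinguished from the linear-probe
phasors: either by the position of the H phasor relative to the circle of
center (0.25, 0) and radius 0.25 (``branch_from_h_phasor``), or by the
default cosine readout ``cos R = 2 g_H + 2 s_45 - 1``
(``branch_from_linear_phasors``), which is exact for every linear retarder
including the fast-axis-aligned case where the H circle is degenerate.
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
    fold_orientation,
    intensities_from_stokes,
    propagate,
)

__all__ = [
    "CHANNELS",
    "PhasorConfig",
    "PolarizationStack",
    "PhasorField",
    "PhasorHistogram",
    "PhasorRetardanceResult",
    "DiscGate",
    "PolygonGate",
    "BRANCH_LOW",
    "BRANCH_HIGH",
    "BRANCH_BOUNDARY",
    "BRANCH_UNDETERMINED",
    "polarization_stack_from_mueller",
    "phasor_transform",
    "merge_linear_phasors",
    "alpha_from_rcp_phase",
    "retardance_from_rcp_modulation",
    "branch_from_h_phasor",
    "branch_from_linear_phasors",
    "phasor_parameter_images",
    "phasor_histogram",
    "phasor_gate_segment",
]

CHANNELS = ("H", "V", "45", "RCP")
DEFAULT_INPUT_STATES = {
    "H": STOKES_H, "V": STOKES_V, "45": STOKES_45, "RCP": STOKES_RCP,
}

BRANCH_LOW = 0          # R < 90 deg
BRANCH_HIGH = 1         # R > 90 deg
BRANCH_BOUNDARY = 2     # R = 90 deg (or indistinguishable)
BRANCH_UNDETERMINED = 3


@dataclass(frozen=True)
class PhasorConfig:
    """Analyzer angles and Fourier period of the phasor transform."""

    thetas: tuple = (0.0, 45.0, 90.0, 135.0)
    period: float = 180.0
    harmonic: int = 1

    def __post_init__(self):
        if self.harmonic < 1:
            raise ValueError("harmonic must be >= 1")
        if any(t < 0 or t >= self.period for t in self.thetas):
            raise ValueError("analyzer angles must lie in [0, period)")

    @property
    def weights(self):
        ang = 2.0 * np.pi * self.harmonic * np.asarray(self.thetas) / self.period
        return np.cos(ang), np.sin(ang)


@dataclass
class PolarizationStack:
    """Linear-analyzer intensities per generator state.

    ``intensities`` has shape ``(..., n_channels, n_thetas)``; channel order
    follows ``channels``, analyzer order follows ``thetas``.
    """

    intensities: np.ndarray
    channels: tuple = CHANNELS
    thetas: tuple = (0.0, 45.0, 90.0, 135.0)

    def channel(self, name: str) -> np.ndarray:
        return self.intensities[..., self.channels.index(name), :]


@dataclass
class PhasorField:
    """Per-pixel (g, s) coordinates for each input-state channel."""

    g: np.ndarray               # (..., n_channels)
    s: np.ndarray
    channels: tuple = CHANNELS
    mask: np.ndarray | None = None  # True where the pixel is invalid

    def _idx(self, name):
        return self.channels.index(name)

    def channel(self, name: str):
        i = self._idx(name)
        return self.g[..., i], self.s[..., i]

    def modulation(self, name: str) -> np.ndarray:
        g, s = self.channel(name)
        return np.hypot(g, s)

    def phase_deg(self, name: str) -> np.ndarray:
        g, s = self.channel(name)
        return np.degrees(np.arctan2(s, g))

    def polarization_angle_deg(self, name: str) -> np.ndarray:
        """Observed polarization azimuth psi = phi / 2."""
        return self.phase_deg(name) / 2.0


def polarization_stack_from_mueller(img, input_states=None,
                                    cfg: PhasorConfig = PhasorConfig()) -> PolarizationStack:
    """Propagate the generator states through the image and read I_theta.

    ``img`` may be a :class:`MuellerImage` or a bare ``(..., 4, 4)`` array.
    ``input_states`` maps channel names to Stokes vectors; defaults to the
    ideal H, V, 45, RCP set, but experimentally calibrated states are
    accepted.
    """
    m = img.m if isinstance(img, MuellerImage) else np.asarray(img, dtype=float)
    states = dict(DEFAULT_INPUT_STATES)
    if input_states is not None:
        states.update(input_states)
    chans = []
    for name in CHANNELS:
        s_out = propagate(m, states[name])
        i0, i90, i45, i135 = intensities_from_stokes(s_out)
        by_theta = {0.0: i0, 45.0: i45, 90.0: i90, 135.0: i135}
        chans.append(np.stack([by_theta[t] for t in cfg.thetas], axis=-1))
    return PolarizationStack(np.stack(chans, axis=-2), CHANNELS, tuple(cfg.thetas))


def phasor_transform(stack: PolarizationStack,
                     cfg: PhasorConfig = PhasorConfig()) -> PhasorField:
    """Single-frequency Fourier (phasor) transform of an intensity stack.

    Pixels whose total intensity is not positive are masked, not errors.
    """
    I = np.asarray(stack.intensities, dtype=float)
    cw, sw = cfg.weights
    total = I.sum(axis=-1)
    bad = ~(total > 0)
    safe = np.where(bad, 1.0, total)
    g = (I * cw).sum(axis=-1) / safe
    s = (I * sw).sum(axis=-1) / safe
    g = np.where(bad, np.nan, g)
    s = np.where(bad, np.nan, s)
    return PhasorField(g=g, s=s, channels=stack.channels, mask=bad)


# Input azimuths of the linear channels; de-rotation uses twice the azimuth
# because the phasor phase is 2x the polarization angle.
_LINEAR_AZIMUTH = {"H": 0.0, "45": 45.0, "V": 90.0}


def merge_linear_phasors(field: PhasorField) -> PhasorField:
    """Average the three linear-input phasors into one channel.

    Each channel is first de-rotated by twice its input azimuth so that the
    phasors of a sample with aligned fast axes coincide; the de-rotated
    (g, s) pairs are then averaged pixelwise.  For air the merged phasor is
    (0.5, 0); for a half-wave retarder the merged phase keeps the H-channel
    invariant ``phi = 4 alpha``.
    """
    for name in _LINEAR_AZIMUTH:
        if name not in field.channels:
            raise ValueError(f"channel {name!r} missing")
        g, s = field.channel(name)
        if field.mask is not None and np.any(field.mask[..., field._idx(name)]):
            raise ValueError(f"channel {name!r} has masked pixels; cannot merge")
    acc_g = 0.0
    acc_s = 0.0
    for name, azim in _LINEAR_AZIMUTH.items():
        g, s = field.channel(name)
        rot = np.radians(2.0 * azim)
        acc_g = acc_g + g * np.cos(rot) + s * np.sin(rot)
        acc_s = acc_s + s * np.cos(rot) - g * np.sin(rot)
    g = acc_g / 3.0
    s = acc_s / 3.0
    return PhasorField(g=g[..., None], s=s[..., None], channels=("linear",), mask=None)


def alpha_from_rcp_phase(phi_deg):
    """Fast-axis orientation from the RCP phasor phase.

    ``alpha_R = phi/2 - 45`` with phi remapped into the branch window
    (-90, 270] before halving; the result is folded into (-90, 90].
    Non-finite phases yield NaN.
    """
    phi = np.asarray(phi_deg, dtype=float)
    phi_w = np.mod(phi + 90.0, 360.0) - 90.0  # -> (-90, 270]
    alpha = fold_orientation(phi_w / 2.0 - 45.0)
    out = np.where(np.isfinite(phi), alpha, np.nan)
    return out if out.ndim else float(out)


def retardance_from_rcp_modulation(m, branch, tol: float = 1e-6):
    """Invert ``M = sin(R)/2`` on the selected branch.

    branch low -> ``arcsin(2M)``; high -> ``180 - arcsin(2M)``; boundary
    -> 90; undetermined -> NaN.  Modulations within ``tol`` above 0.5 are
    clipped; larger values are rejected.
    """
    m = np.asarray(m, dtype=float)
    branch = np.asarray(branch)
    if np.any(m > 0.5 + tol):
        raise ValueError("modulation exceeds the physical bound 0.5")
    if np.any(m < -tol):
        raise ValueError("modulation must be non-negative")
    m = np.clip(m, 0.0, 0.5)
    base = np.degrees(np.arcsin(2.0 * m))
    out = np.where(branch == BRANCH_LOW, base,
                   np.where(branch == BRANCH_HIGH, 180.0 - base,
                            np.where(branch == BRANCH_BOUNDARY, 90.0, np.nan)))
    return out if out.ndim else float(out)


def branch_from_h_phasor(g_h, s_h, eps: float = 0.005, tol: float = 1e-6):
    """Retardance branch from the H phasor's position (circle rule).

    The H phasor of a linear retarder lies inside the circle of center
    (0.25, 0) and radius 0.25 for R < 90 degrees and outside it (but within
    the outer circle of radius 0.5) for R > 90 degrees; at R = 90 it lies on
    the circle exactly.  ``eps`` is the boundary band in (g, s) units.

    Note the rule is blind at ``alpha_R = 0`` (the H phasor sits on the
    circle for every R); see :func:`branch_from_linear_phasors` for a
    readout without that degeneracy.
    """
    g = np.asarray(g_h, dtype=float)
    s = np.asarray(s_h, dtype=float)
    d = np.hypot(g - 0.25, s)
    radius = np.hypot(g, s)
    finite = np.isfinite(g) & np.isfinite(s)
    out = np.select(
        [~finite,
         np.abs(d - 0.25) <= eps,
         d < 0.25 - eps,
         (d > 0.25 + eps) & (radius <= 0.5 + tol)],
        [BRANCH_UNDETERMINED, BRANCH_BOUNDARY, BRANCH_LOW, BRANCH_HIGH],
        default=BRANCH_UNDETERMINED,
    ).astype(np.int8)
    return out if out.ndim else int(out)


def branch_from_linear_phasors(field: PhasorField, eps: float = 1e-9):
    """Retardance branch from the cosine readout of the linear phasors.

    For a linear retarder ``2 g_H + 2 s_45 - 1 = cos R`` identically, so the
    sign of that combination selects the branch for every orientation,
    including fast axes aligned with H where the circle rule degenerates.
    ``eps`` is the half-width of the boundary band on cos R.
    """
    g_h, _ = field.channel("H")
    _, s_45 = field.channel("45")
    cos_r = np.asarray(2.0 * g_h + 2.0 * s_45 - 1.0)
    out = np.select(
        [~np.isfinite(cos_r), cos_r > eps, cos_r < -eps],
        [BRANCH_UNDETERMINED, BRANCH_LOW, BRANCH_HIGH],
        default=BRANCH_BOUNDARY,
    ).astype(np.int8)
    return out if out.ndim else int(out)


@dataclass
class PhasorRetardanceResult:
    """Per-pixel retardance and orientation from the phasor readout."""

    R: np.ndarray
    alpha_R: np.ndarray
    branch: np.ndarray
    undetermined: np.ndarray

    @property
    def maps(self) -> dict:
        return {"R": self.R, "alpha_R": self.alpha_R}


def phasor_parameter_images(field: PhasorField, noise_floor_m: float = 0.05,
                            branch_method: str = "linear") -> PhasorRetardanceResult:
    """Closed-form (R, alpha_R) maps from the H/45/RCP phasors.

    Retardance comes from the RCP modulation, orientation from the RCP
    phase, branch from the linear channels (``branch_method``: "linear"
    for the cosine readout, "h_circle" for the circle rule).  Pixels whose
    RCP modulation falls below ``noise_floor_m`` are indistinguishable from
    air and marked undetermined.
    """
    m_rcp = field.modulation("RCP")
    phi_rcp = field.phase_deg("RCP")
    if branch_method == "linear":
        branch = branch_from_linear_phasors(field)
    elif branch_method == "h_circle":
        g_h, s_h = field.channel("H")
        branch = branch_from_h_phasor(g_h, s_h)
    else:
        raise ValueError("branch_method must be 'linear' or 'h_circle'")
    branch = np.asarray(branch, dtype=np.int8)
    low_signal = np.asarray(~(m_rcp >= noise_floor_m))
    branch = np.where(low_signal, np.int8(BRANCH_UNDETERMINED), branch)
    R = retardance_from_rcp_modulation(np.where(low_signal, 0.0, m_rcp), branch)
    alpha = alpha_from_rcp_phase(phi_rcp)
    alpha = np.where(low_signal, np.nan, alpha)
    return PhasorRetardanceResult(R=np.asarray(R), alpha_R=np.asarray(alpha),
                                  branch=branch, undetermined=low_signal)


@dataclass
class PhasorHistogram:
    """2-D histogram of phasor coordinates over the unit phasor square."""

    counts: np.ndarray
    g_edges: np.ndarray
    s_edges: np.ndarray
    n_pixels: int
    colormap: str = "RdYlBu_r"  # red = highest bin, blue = lowest


def phasor_histogram(field: PhasorField, channel: str = "RCP",
                     roi_mask=None, bins: int = 256,
                     extent: float = 0.5) -> PhasorHistogram:
    """Histogram the (g, s) points of one channel over an optional ROI."""
    g, s = field.channel(channel)
    sel = np.isfinite(g) & np.isfinite(s)
    if roi_mask is not None:
        roi_mask = np.asarray(roi_mask, dtype=bool)
        if roi_mask.shape != np.shape(g):
            raise ValueError("ROI mask shape does not match the field")
        sel &= roi_mask
    if not np.any(sel):
        raise ValueError("empty ROI")
    counts, ge, se = np.histogram2d(
        np.ravel(g[sel]), np.ravel(s[sel]), bins=bins,
        range=[[-extent, extent], [-extent, extent]])
    return PhasorHistogram(counts=counts, g_edges=ge, s_edges=se,
                           n_pixels=int(sel.sum()))


@dataclass(frozen=True)
class DiscGate:
    """Disc-shaped gate in the (g, s) plane."""

    center: tuple
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("gate radius must be positive")

    def contains(self, g, s):
        return np.hypot(np.asarray(g) - self.center[0],
                        np.asarray(s) - self.center[1]) <= self.radius


@dataclass(frozen=True)
class PolygonGate:
    """Polygonal gate in the (g, s) plane."""

    vertices: tuple

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[0] < 3 or v.shape[1] != 2:
            raise ValueError("polygon needs at least 3 (g, s) vertices")
        x, y = v[:, 0], v[:, 1]
        area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        if area <= 0:
            raise ValueError("degenerate (zero-area) polygon gate")

    def contains(self, g, s):
        from matplotlib.path import Path

        pts = np.column_stack([np.ravel(g), np.ravel(s)])
        inside = Path(np.asarray(self.vertices, dtype=float)).contains_points(pts)
        return inside.reshape(np.shape(g))


def phasor_gate_segment(field: PhasorField, gate, channel: str = "RCP") -> np.ndarray:
    """Pixel mask of phasor points falling inside a gate region.

    Back-maps a cluster selected in phasor space to the image: the returned
    boolean mask is True where the pixel's (g, s) lies inside ``gate``.
    """
    g, s = field.channel(channel)
    finite = np.isfinite(g) & np.isfinite(s)
    inside = np.zeros(np.shape(g), dtype=bool)
    inside[finite] = np.asarray(gate.contains(g[finite], s[finite]), dtype=bool)
    return inside
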