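"""Lu-Chipman polar decomposition of Mueller matrices.

Factorizes a (normalized) Mueller matrix as ``M = M_delta @ M_R @ M_D`` —
depolarizer times retarder times diattenuator, in the order the probe light
crosses them — and extracts the scalar polarimetric parameters:

* diattenuation ``D = sqrt(m01^2 + m02^2 + m03^2)``,
* retardance ``R = arccos(tr(M_R)/2 - 1)`` in degrees (3x3 rotation-block
  trace; equivalently ``(tr4 - 2)/2`` with the full 4x4 trace),
* fast-axis orientation ``alpha_R = 0.5 * atan2(r2, r1)`` from the
  retardance vector, folded into ``(-90, 90]``,
* depolarization index ``P_d = sqrt((sum_ij m_ij^2 - m00^2) / (3 m00^2))``.

All routines are vectorized over leading axes, so whole images decompose in
one call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MuellerImage, fold_orientation

__all__ = [
    "LCResult",
    "LCImage",
    "diattenuation",
    "depolarization_index",
    "lc_decompose",
    "lc_image",
]

# Flag bits set per pixel when the factorization degenerates.
FLAG_SINGULAR_DIATTENUATOR = 1
FLAG_SINGULAR_DEPOLARIZER = 2


def diattenuation(m) -> np.ndarray:
    """Diattenuation from the first row of an m00-normalized matrix."""
    m = np.asarray(m, dtype=float)
    m00 = m[..., 0, 0]
    if np.any(m00 <= 0):
        raise ValueError("m00 must be positive")
    d = np.linalg.norm(m[..., 0, 1:], axis=-1) / m00
    return d if d.ndim else float(d)


def depolarization_index(m) -> np.ndarray:
    """Depolarization index P_d; 1 for a nondepolarizing matrix.

    Noisy experimental matrices may exceed 1 slightly; the value is
    returned as computed, not clipped.
    """
    m = np.asarray(m, dtype=float)
    m00 = m[..., 0, 0]
    total = np.sum(m * m, axis=(-2, -1))
    pd = np.sqrt(np.maximum(total - m00**2, 0.0) / (3.0 * m00**2))
    return pd if pd.ndim else float(pd)


@dataclass
class LCResult:
    """Outcome of a Lu-Chipman decomposition (scalar or batch).

    ``M_delta @ M_R @ M_D`` reconstructs the normalized input to numerical
    precision for nondegenerate inputs; ``reconstruction_error`` holds the
    max-abs residual.  ``r`` is the unit retardance vector (r1, r2, r3);
    ``r3`` is the circular-retardance component.
    """

    M_delta: np.ndarray
    M_R: np.ndarray
    M_D: np.ndarray
    D: np.ndarray
    R: np.ndarray
    alpha_R: np.ndarray
    P_d: np.ndarray
    r: np.ndarray
    flags: np.ndarray
    reconstruction_error: np.ndarray

    def summary(self) -> str:
        d, r, a, p = (np.atleast_1d(x).ravel() for x in (self.D, self.R, self.alpha_R, self.P_d))
        lines = ["Lu-Chipman decomposition",
                 f"{'D':>8} {'R [deg]':>10} {'alpha_R [deg]':>14} {'P_d':>8}"]
        for i in range(min(d.size, 10)):
            lines.append(f"{d[i]:8.3f} {r[i]:10.1f} {a[i]:14.1f} {p[i]:8.3f}")
        if d.size > 10:
            lines.append(f"... ({d.size} entries)")
        return "\n".join(lines)


def _build_diattenuator(d_vec, D):
    """M_D from the diattenuation vector; D=1 handled by the rank-1 limit."""
    batch = D.shape
    eye3 = np.eye(3)
    safe_D = np.where(D > 0, D, 1.0)
    dhat = d_vec / safe_D[..., None]
    k = np.sqrt(np.clip(1.0 - D**2, 0.0, None))
    outer = dhat[..., :, None] * dhat[..., None, :]
    mD = k[..., None, None] * eye3 + (1.0 - k)[..., None, None] * outer
    MD = np.zeros(batch + (4, 4))
    MD[..., 0, 0] = 1.0
    MD[..., 0, 1:] = d_vec
    MD[..., 1:, 0] = d_vec
    MD[..., 1:, 1:] = mD
    return MD


def lc_decompose(m) -> LCResult:
    """Lu-Chipman polar decomposition, vectorized over leading axes.

    The canonical sequence: the diattenuation vector from row 0 builds
    ``M_D``; ``M' = M M_D^{-1}``; the depolarizer block comes from an
    eigen-analysis of ``m' m'^T`` (Cayley-Hamilton form, sign from
    ``det m'``); the retarder is ``M_R = M_delta^{-1} M'``.  Degenerate
    pixels (D -> 1, or a non-invertible depolarizer block) are flagged and
    their retarder parameters set to NaN rather than raising.
    """
    m_in = np.asarray(m, dtype=float)
    scalar = m_in.ndim == 2
    M = m_in[None] if scalar else m_in
    m00 = M[..., 0, 0]
    if np.any(m00 <= 0):
        raise ValueError("m00 must be positive")
    M = M / m00[..., None, None]
    batch = M.shape[:-2]
    flags = np.zeros(batch, dtype=np.uint8)

    d_vec = M[..., 0, 1:]
    D = np.linalg.norm(d_vec, axis=-1)
    sing_D = D >= 1.0 - 1e-12
    flags[sing_D] |= FLAG_SINGULAR_DIATTENUATOR
    MD = _build_diattenuator(d_vec, np.where(sing_D, 0.999999, D))
    Mp = M @ np.linalg.inv(MD)

    mp = Mp[..., 1:, 1:]
    det_mp = np.linalg.det(mp)
    sing_dep = np.abs(det_mp) < 1e-14
    flags[sing_dep] |= FLAG_SINGULAR_DEPOLARIZER

    mmT = mp @ np.swapaxes(mp, -1, -2)
    lam = np.linalg.eigvalsh(mmT)  # ascending
    sl = np.sqrt(np.clip(lam, 0.0, None))
    s1, s2, s3 = sl[..., 2], sl[..., 1], sl[..., 0]
    sign = np.where(det_mp >= 0, 1.0, -1.0)
    eye3 = np.eye(3)
    A = mmT + (s1 * s2 + s2 * s3 + s3 * s1)[..., None, None] * eye3
    B = (s1 + s2 + s3)[..., None, None] * mmT + (s1 * s2 * s3)[..., None, None] * eye3
    # Guard singular A on flagged pixels so the batched solve cannot raise.
    A = np.where(sing_dep[..., None, None], np.broadcast_to(eye3, A.shape), A)
    m_delta = sign[..., None, None] * np.linalg.solve(A, B)
    m_delta_safe = np.where(sing_dep[..., None, None],
                            np.broadcast_to(eye3, m_delta.shape), m_delta)
    m_r = np.linalg.solve(m_delta_safe, mp)

    tr = np.einsum("...ii->...", m_r)
    R = np.degrees(np.arccos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0)))
    sinR = np.sin(np.radians(R))
    # Antisymmetric part of the rotation block; symmetric-part fallback
    # where sinR underflows (R near 0 or 180 degrees).
    anti = np.stack([
        m_r[..., 1, 2] - m_r[..., 2, 1],
        m_r[..., 2, 0] - m_r[..., 0, 2],
        m_r[..., 0, 1] - m_r[..., 1, 0],
    ], axis=-1)
    small = sinR < 1e-7
    with np.errstate(divide="ignore", invalid="ignore"):
        r_vec = anti / (2.0 * sinR[..., None])
    if np.any(small):
        # Near R=180 the axis survives in the symmetric part:
        # m_r ~ 2 a a^T - I, so a_i^2 = (m_ii + 1)/2; signs from off-diagonals.
        diag = np.stack([m_r[..., 0, 0], m_r[..., 1, 1], m_r[..., 2, 2]], axis=-1)
        a_abs = np.sqrt(np.clip((diag + 1.0) / 2.0, 0.0, None))
        s01 = np.sign(m_r[..., 0, 1] + m_r[..., 1, 0])
        s02 = np.sign(m_r[..., 0, 2] + m_r[..., 2, 0])
        fallback = np.stack([a_abs[..., 0],
                             s01 * a_abs[..., 1],
                             s02 * a_abs[..., 2]], axis=-1)
        near_zero = (np.abs(R) < 90.0)  # R~0: axis undefined, keep (1,0,0)
        fallback = np.where(near_zero[..., None],
                            np.broadcast_to([1.0, 0.0, 0.0], fallback.shape),
                            fallback)
        r_vec = np.where(small[..., None], fallback, r_vec)
    norm = np.linalg.norm(r_vec, axis=-1, keepdims=True)
    r_vec = r_vec / np.where(norm > 0, norm, 1.0)

    alpha = fold_orientation(0.5 * np.degrees(np.arctan2(r_vec[..., 1], r_vec[..., 0])))
    P_d = depolarization_index(M)

    M_R = np.zeros(batch + (4, 4))
    M_R[..., 0, 0] = 1.0
    M_R[..., 1:, 1:] = m_r
    M_delta = Mp @ np.linalg.inv(M_R)

    bad = flags > 0
    for arr in (R, alpha):
        arr[bad] = np.nan
    recon = np.max(np.abs(M_delta @ M_R @ MD - M), axis=(-2, -1))

    def _maybe_scalar(a):
        return a[0] if scalar else a

    return LCResult(
        M_delta=_maybe_scalar(M_delta), M_R=_maybe_scalar(M_R), M_D=_maybe_scalar(MD),
        D=_maybe_scalar(D), R=_maybe_scalar(R), alpha_R=_maybe_scalar(np.asarray(alpha)),
        P_d=_maybe_scalar(np.asarray(P_d)), r=_maybe_scalar(r_vec),
        flags=_maybe_scalar(flags), reconstruction_error=_maybe_scalar(recon),
    )


@dataclass
class LCImage:
    """Per-pixel Lu-Chipman parameter maps with a weak-signal mask.

    Orientation at pixels with both diattenuation and retardance below the
    signal threshold is not physical; those pixels are flagged in
    ``orientation_mask`` (True = untrustworthy, rendered black in maps).
    """

    D: np.ndarray
    R: np.ndarray
    alpha_R: np.ndarray
    P_d: np.ndarray
    orientation_mask: np.ndarray
    flags: np.ndarray
    result: LCResult = field(repr=False, default=None)

    @property
    def maps(self) -> dict:
        return {"D": self.D, "R": self.R, "alpha_R": self.alpha_R, "P_d": self.P_d}


def lc_image(img: MuellerImage, signal_threshold=(0.02, 2.0)) -> LCImage:
    """Decompose every pixel of a Mueller image.

    ``signal_threshold`` is ``(D_min, R_min_deg)``: orientation is masked
    where D and R both fall below it (air-level noise).  Isolated degenerate
    pixels are flagged, never fatal.
    """
    res = lc_decompose(img.m)
    d_min, r_min = signal_threshold
    with np.errstate(invalid="ignore"):
        weak = (res.D < d_min) & ((res.R < r_min) | np.isnan(res.R))
    mask = weak | (res.flags > 0)
    if img.mask is not None:
        mask = mask | img.mask
    return LCImage(D=res.D, R=res.R, alpha_R=res.alpha_R, P_d=res.P_d,
                   orientation_mask=mask, flags=res.flags, result=res)
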