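# Methods note

This note records the mathematical model implemented by `mmphasor`, the
parameter choices baked into the defaults, how realistic the synthetic
generators are, and the known limitations.

## 1. Model and conventions

**Stokes basis.** `S = (S0, S1, S2, S3)` with `S1 = I_H − I_V`,
`S2 = I_45 − I_135`, `S3 = I_RCP − I_LCP`, right-handed, detector-view
convention. All public angles are degrees; fast-axis orientations live on
the 180°-periodic axis folded into `(−90°, 90°]`.

**Linear retarder.** Retardance `R`, fast axis `α`; the 3×3 block of the
Mueller matrix is the Poincaré rotation by `R` about `(cos 2α, sin 2α, 0)`,
with sign convention `m13 = −sin 2α · sin R` (a right-circular probe
leaves an `α = 0` retarder with phasor phase +90°). Physical retardance
`R = 360°·Δn·e/λ` (thickness in µm, wavelength in nm); measured values are
wrapped onto `[0°, 180°]`, and epi (double-pass) geometry can be undone
with the opt-in correction `R_exact = 360° − R_measured`.

**Instrument.** Generator states are columns of `W`, analyzer projections
rows of `A` (`a = ½(1, ŝ)` for an ideal projector onto `ŝ`); the 16
intensities per pixel are `I = A·M·W` and reconstruction is
`M = A⁻¹·I·W⁻¹`. The ideal H/V/45/RCP set has 2-norm condition number
3.2255. Measurement noise is modeled as independent zero-mean Gaussian
perturbations of the m00-normalized Mueller elements, with per-element SDs
taken from the bundled air calibration measurement (σ₀₀ = 0).

**Lu–Chipman.** `M = M_Δ·M_R·M_D`: the diattenuation vector (row 0) builds
`M_D`; `M′ = M·M_D⁻¹`; the depolarizer block comes from the
Cayley–Hamilton eigen-form of `m′m′ᵀ` with the sign of `det m′`;
`M_R = M_Δ⁻¹·M′`. Scalars: `D = |d|`, `R = arccos((tr m_R − 1)/2)`,
`α_R = ½·atan2(r2, r1)` from the antisymmetric part of `m_R` (symmetric-
part fallback near `R = 0°/180°`), `P_d = √((Σm_ij² − m00²)/(3 m00²))`.
Degenerate pixels (perfect diattenuator, singular depolarizer block) are
flagged per pixel, never fatal for an image.

**Phasor.** For each generator channel the analyzer intensities at
θ ∈ {0, 45, 90, 135}° are Fourier-compressed at period Θ = 180°. With the
ideal analyzer set this reduces to `(g, s) = (S1, S2)/(2·S0)` of the
emerging Stokes vector, so `M ≤ 0.5` for physical states. Closed forms for
a linear retarder under an RCP probe: `M = sin(R)/2`, `φ = 90° + 2α`;
inversion uses `α_R = φ/2 − 45°` (φ remapped to `(−90°, 270°]`) and
`R = arcsin(2M)` or `180° − arcsin(2M)`.

**Branch selection.** Two readouts are provided:

* `linear` (default): `cos R = 2 g_H + 2 s_45 − 1`, an exact identity for
  every linear retarder, at every orientation.
* `h_circle`: the H phasor lies inside the circle of center (0.25, 0) and
  radius 0.25 for `R < 90°`, outside for `R > 90°`, on it at `R = 90°`.
  This rule is **degenerate at α = 0**: there
  `d² = [u² + (1−u)² + 2u(1−u)cos 4α]/16` collapses to `d ≡ 0.25` for all
  `R`, so the circle test cannot decide. The cosine readout has no such
  blind spot, which is why it is the default; the circle rule is kept for
  comparability with the classical construction.

**Equivalent retarder.** Retarders compose as unit quaternions
`q = (cos R/2, sin R/2·cos 2α, sin R/2·sin 2α, 0)`. A product of linear
retarders at different azimuths is generally *elliptical*; the package
reports the total rotation angle, and the circular–linear factorization's
linear retardance `2·atan2(√(x²+y²), √(w²+z²))`, optical rotation and
azimuth. The rotating-analyzer phasor readout measures exactly this
**linear** retardance (verified to 1e−14 against the quaternion algebra),
not the total rotation angle — the two coincide only for stacks that
remain linear (n ≤ 2 co-planar layers).

## 2. Default parameters

| Parameter | Value | Origin |
| --- | --- | --- |
| analyzer angles / period | 0, 45, 90, 135° / 180° | instrument design |
| generator states | H, V, 45°, RCP (κ = 3.2255) | ideal complete polarimeter |
| noise SDs | bundled air calibration matrix | measured per-element SDs |
| phasor noise floor | M < 0.05 → undetermined | air-modulation uncertainty |
| LC orientation mask | D < 0.02 and R < 2° | air-level parameter noise |
| collagen layer | Δn = 0.0017, e = 50 µm, λ = 808 nm → R₁ = 37.87° | physical triple |
| layered-fiber jitter | σ_α = 14° per pixel per layer | calibrated once to P_d(n=1) = 0.97 |
| report rounding | half-away-from-zero; 0.1° angles, 0.001 ratios | printed-table precision |

## 3. Generator realism

* **air**: identity + per-element Gaussian noise at calibration SDs.
  Mean-matrix `P_d` lands in the measured 1.007 ± 0.01 band (noise makes
  the index exceed 1 slightly; it is reported unclipped).
* **film_on_air**: uniform retarder patch (55.5° at −85.7°) with
  region-matched noise; reproduces the two-cluster phasor structure used
  for gating demonstrations.
* **layered_fibers**: n identical layers (R₁ = 37.87°) each rotated 10°
  from the previous. Disorder model: per-pixel, per-layer fast-axis jitter
  (σ_α = 14°) plus per-element measurement noise; parameters are analyzed
  on the ROI-mean matrix. Averaging over orientation disorder is the
  mechanism that depolarizes: mean P_d falls monotonically with n
  (≈ 0.97 → 0.89 for n = 1…4) and the phasor retardance estimate
  outperforms Lu–Chipman in mean absolute deviation from n·R₁ for n ≥ 3.
  Purely additive elementwise noise cannot reproduce this: a zero-mean
  elementwise perturbation *raises* the expected `Σm_ij²` and hence `P_d`,
  so the jitter model is a documented, deliberate modeling choice, with
  σ_α calibrated once against the single-fiber depolarization value and
  frozen before any comparison was evaluated.
* **rotated_fiber** and **striped_myosin**: rigid fast-axis rotations of a
  fixed-R fiber, and alternating ±20° stripes; used for the rotation-
  covariance and orientation-map checks.

## 4. Numerical choices

* All decompositions and phasor transforms are vectorized over leading
  axes (`(..., 4, 4)`), so whole images are processed in single batched
  linear-algebra calls.
* `arccos`/`arcsin` arguments are clipped to their domains to absorb
  float round-off; modulations up to `0.5 + 1e−6` are clipped, larger
  values rejected.
* Retardance-vector extraction switches from the antisymmetric part of the
  rotation block to the symmetric-part fallback when `sin R < 1e−7`
  (axis survives in `m_r ≈ 2aaᵀ − I` near 180°; undefined and reported as
  the convention axis near 0°).
* Orientation statistics use doubled-angle circular means (axes are
  180°-periodic); plain means are emitted alongside for cross-checking
  against printed tables.
* Report rounding is half-away-from-zero, not banker's rounding, matching
  the precision of the bundled printed tables.

## 5. Known limitations and open points

* The bundled film mean matrix does **not** reproduce the printed
  ROI-averaged retardance: Lu–Chipman on the mean matrix gives
  R = 51.1° vs the printed 55.5 ± 1.9°, under every ordering/transpose
  variant tried, and per-pixel Monte-Carlo at the printed SDs reproduces
  the printed spread (SD ≈ 1.8°) but not the mean. The discrepancy is
  surfaced honestly by the acceptance tests rather than tuned away.
  The orientation from the raw printed matrix comes out at +5.6°; after
  converting the instrument's circular-handedness convention (epi mirror)
  it is −84.4°, close to but still outside the printed −85.7 ± 0.9°.
* The depolarizing-noise protocol behind the published layered-fiber
  retardance values is not reproducible from the printed information;
  the layered comparison is asserted as a property (monotone P_d, phasor
  beats LC for n ≥ 3), not as numeric targets.
* Dichroic and depolarizing phasor trajectories are only qualitatively
  covered; no Jones/coherency formalism, no physical-realizability
  (Cloude) filtering, no multi-wavelength stacks.
* The phasor inversion assumes a linear-retarder model per pixel; for
  strongly elliptical or depolarizing media it returns the equivalent
  linear retardance of the readout, which is the measurand but not the
  full polarimetric truth.
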