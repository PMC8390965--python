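# mmphasor

Phasor analysis of Mueller-matrix optical scanning microscopy images.

A Mueller-matrix (MM) microscope records, for every pixel, the 4×4 real
matrix that maps input polarization states (Stokes vectors) to output
states. From that matrix one can extract the polarimetric fingerprints of
tissue — retardance `R` (birefringent phase delay), fast-axis orientation
`α_R`, diattenuation `D` and the depolarization index `P_d`. The classical
route is the **Lu–Chipman polar decomposition** `M = M_Δ·M_R·M_D`
(depolarizer × retarder × diattenuator). This package implements that
decomposition *and* a much cheaper, closed-form alternative: the
**MM-phasor**.

## The MM-phasor in one paragraph

For each of four generator states (H, V, 45°, RCP) the emerging light is
read through a linear analyzer at four angles θ ∈ {0, 45, 90, 135}°. The
intensities `I_θ` are compressed to a single-frequency Fourier pair with
period Θ = 180°:

```
g = Σ_θ I_θ cos(2πθ/Θ) / Σ_θ I_θ        s = Σ_θ I_θ sin(2πθ/Θ) / Σ_θ I_θ
```

Each pixel becomes a point `(g, s)` in phasor space with modulation
`M = √(g²+s²) ≤ 0.5` and phase `φ = atan2(s, g)`. For a linear retarder
probed with right-circular light the closed forms

```
M = sin(R) / 2            φ = 90° + 2 α_R
```

invert directly to per-pixel `(R, α_R)` maps — no matrix factorization, no
per-pixel eigen-solve. The sign ambiguity of `R = arcsin(2M)` versus
`180° − arcsin(2M)` is resolved from the linear-input phasors: the package
default is the exact cosine readout `cos R = 2 g_H + 2 s_45 − 1`; the
classical rule based on the position of the H phasor relative to the circle
of center (0.25, 0) and radius 0.25 is also available (but is blind when
the fast axis is aligned with H). Clusters in phasor space can be *gated*
(disc or polygon) and back-mapped onto the image for label-free
segmentation.

## Worked example

```python
import numpy as np
import mmphasor as mm

# 1. A synthetic scene: a retarding film (R = 55.5 deg, fast axis at
#    -85.7 deg) surrounded by air, with calibration-level noise.
phantom = mm.make_phantom(mm.PhantomSpec(scene="film_on_air", seed=7))

# 2. Forward-simulate the 16 polarization-resolved intensities and invert.
inst = mm.InstrumentModel.ideal()          # H/V/45/RCP states, kappa = 3.23
I = mm.simulate_measurement(phantom.mueller, inst, noise=False)
img = mm.reconstruct_mueller(I, inst)      # M = A^-1 I W^-1 per pixel

# 3a. Lu-Chipman route.
lc = mm.lc_image(img)
film = phantom.region_mask("film")
print("LC:    R = %.1f deg, alpha = %.1f deg, P_d = %.3f" % (
    np.nanmean(lc.R[film]), np.nanmean(lc.alpha_R[film]),
    np.nanmean(lc.P_d[film])))

# 3b. Phasor route (closed form).
field = mm.phasor_transform(mm.polarization_stack_from_mueller(img))
ph = mm.phasor_parameter_images(field)
print("Phasor: R = %.1f deg, alpha = %.1f deg" % (
    np.nanmean(ph.R[film]), np.nanmean(ph.alpha_R[film])))

# 4. Phasor gating: air pixels cluster at the origin of the RCP phasor.
air_mask = mm.phasor_gate_segment(field, mm.DiscGate(center=(0, 0), radius=0.1))
assert (air_mask == phantom.region_mask("air")).all()
```

Both routes print `R = 55.5 deg, alpha = -85.7 deg` on the noiseless
phantom.

## Command line

```
mmphasor simulate --scene film_on_air --seed 7 --out sim
mmphasor phasor   --input sim/mueller.tif --labels sim/labels.tif --out out
mmphasor lc       --input sim/mueller.tif --out out
mmphasor segment  --input sim/mueller.tif --gate "disc 0 0 0.1" --out air.tif
mmphasor report   --input sim/mueller.tif --out report
```

Images travel as 16-plane float32 TIFFs with JSON sidecars; tables as CSV;
phasor densities as PNG (red = most populated bins). Exit codes: 2 config,
3 I/O, 4 numeric.

## Bundled reference data

`mmphasor.datasets` ships small printed reference measurements from an
808 nm epi-geometry MM scanning microscope: ROI-averaged Mueller matrices
of air and of a transparent retarding film with per-element SDs (the noise
model used throughout), and a five-rotation collagen-fiber series with LC
and phasor `(R, α_R)` statistics. The loaders convert the instrument's
circular-handedness convention to the package's canonical one by default
(`handedness="instrument"` for the raw values).

## What is where

| Module | Contents |
| --- | --- |
| `mmphasor.core` | Stokes/Mueller algebra, retarder matrices, layered media, equivalent-retarder (quaternion) composition |
| `mmphasor.lucchipman` | Lu–Chipman decomposition, `D`, `R`, `α_R`, `P_d` maps |
| `mmphasor.phasor` | polarization stacks, phasor transform, closed-form parameter maps, histograms, gating |
| `mmphasor.instrument` | PSG/PSA model, condition number, forward simulation, reconstruction, microscope-fingerprint correction |
| `mmphasor.phantoms` | synthetic scenes: air, film-on-air, layered fibers, rotated fiber, striped myosin |
| `mmphasor.io` / `mmphasor.plot` / `mmphasor.cli` | TIFF/CSV/JSON I/O, rendering, command line |

See `docs/methods.md` for the model, numerical choices, the layered-fiber
disorder model and known limitations. Run `pytest` for the test suite and
`python scripts/acceptance.py --seed 1 --out results/acceptance.json` for
the numeric acceptance targets.
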