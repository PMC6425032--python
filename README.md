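# phagokit

Quantitative biophysics of phagocytosis, in Python.

When a macrophage spreads on an IgG-coated surface ("frustrated
phagocytosis") it builds the same machinery it uses to engulf an
antibody-coated target: punctate Fc-receptor (FcR) actin adhesions
organized into a propagating circular actin wave, traction on the
substrate, membrane added and tensed, adhesions turning over. Studies of
this system combine half a dozen quantitative assays, each with its own
custom analysis. `phagokit` implements that full analysis stack as a
tested library, together with synthetic-data generators that provide exact
ground truth for every stage — so each measurement can be validated end to
end without access to proprietary microscopy data.

## What it computes

| module | measurement |
| --- | --- |
| `phagokit.waves` | per-angle wave boundary radius r(θ,t), signed boundary speed v(θ,t) = Δr·px/Δt (µm/min, positive = expansion), mean actin intensity from the boundary 30 px inward, per-cell normalization to 1 at null speed, binned speed–intensity relation |
| `phagokit.traction` | drift registration (phase correlation), PIV displacements (3.46 µm windows, 1.73 µm spacing, subpixel Gaussian peaks), outlier filtering + ordinary Kriging, regularized Fourier Transform Traction Cytometry on the Boussinesq half-space (G = 1.5 kPa gels), L-curve choice of λ, strain energy U = ½∫**T**·**u** dA |
| `phagokit.recovery` | FRAP double normalization, fit of y(t) = y₀ + a(1 − e^(−bt)), half-life t₁/₂ = ln 2 / b, mobile fraction X_m = F_∞/F_i |
| `phagokit.mechanics` | Hertz indentation F = (4/3)·E/(1−ν²)·√(Rδ³) with contact-point search (fit restricted to δ ≤ 0.5 µm), equipartition trap calibration k = k_BT/Var(x), tether force k·⟨Δx⟩, FM-dye surface-area increase |
| `phagokit.morphometry` | adhesion blob detection, 4 × 4 µm adhesion-centred channel averaging with radial profiles, 3-D adhesion footprint/height, phagocytic-cup voxel intensities, phagocytosis scoring (FOV → experiment → genotype, mean ± SEM), t-test / Welch / ANOVA + Tukey comparisons |
| `phagokit.synthgen` | deterministic generators with ground-truth sidecars for every input above |

## Worked example

```python
import numpy as np
from phagokit import synthgen as sg, waves as wv

cfg = sg.SynthConfig(seed=3, image_shape=(256, 256))   # 0.133 µm/px, 10 s/frame
speeds = 0.5 + 1.0 * np.sin(np.deg2rad(np.arange(360)))  # µm/min, per angle
radii = sg.expanding_wave_radii(8.0, speeds, n_frames=12,
                                frame_interval_s=cfg.frame_interval_s)
actin, membrane, truth = sg.gen_wave_movie(cfg, radii, coupling_beta=0.1)

df = wv.track_movie(actin, threshold=50.0, center_px=truth.center_px)
dfn = wv.normalize_at_null_speed(df)
rel = wv.speed_intensity_relation(dfn, bin_width=0.2)
```

Running `python examples/wave_kinematics.py` (which does exactly this)
prints:

```
tracked 3960 (angle, frame) boundary samples
median |v_hat - v_true| = 0.0072 um/min (subpixel ray-casting accuracy)
binned speed-intensity slope = -0.0960 per (um/min); programmed coupling = -0.1
```

The tracker recovers the programmed per-angle boundary speeds to
~0.007 µm/min, and the binned intensity-vs-speed table recovers the
programmed negative coupling (bright actin where the wave is stalled, dim
where it protrudes fast) within a few percent. The other
`examples/*.py` scripts walk through traction reconstruction, FRAP
fitting, AFM/trap mechanics and morphometry the same way, each printing
the recovered values next to the programmed truth.

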