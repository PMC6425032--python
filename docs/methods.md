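# Methods

This note documents the models, parameter choices, and numerical decisions
behind each `phagokit` module, and what the synthetic ground truth does and
does not establish about real data.

## Synthetic data and what it stands in for

The imaging and single-cell trace data these pipelines address (TIRF
movies of macrophages spreading on IgG, substrate bead images, FRAP/AFM/
optical-trap traces, per-cell bead counts) are not publicly deposited.
Every analysis stage is therefore validated against a generator in
`phagokit.synthgen` that emulates the corresponding modality with an exact,
machine-readable ground truth. All generators draw from a single
`numpy.random.Generator` seeded through `SynthConfig.seed` (or an
explicitly passed generator); identical seed and parameters give
bit-identical output. The noise model is Poisson shot noise (intensity
scaled by `poisson_scale` photons per count) plus additive Gaussian read
noise — a standard EMCCD/sCMOS approximation that ignores camera gain
structure, fixed-pattern noise and the PSF.

What passing these tests shows: the estimators are consistent — they
recover programmed kinematics, elasticity, rates, stiffnesses and
probabilities from data generated by the stated forward models at
realistic noise levels. What they do not show: robustness to model
mismatch present in real microscopy (out-of-focus light, uneven
illumination, segmentation ambiguity at ragged wave edges, non-exponential
recovery, viscoelastic indentation, non-Gaussian camera noise).

## Wave boundary kinematics (`waves`)

The wave is treated as a star-shaped region around a fixed centre: for each
integer degree θ ∈ {0,…,359} a ray is cast and the **outermost** crossing of
the boundary is taken (the expanding front; punctate interiors produce
inner crossings that are deliberately ignored). Crossings are located on
bilinear-interpolated samples every 0.25 px and refined by linear
interpolation, giving ~0.01 px radial precision on smooth edges. The
centre is computed once from the first frame and held fixed; per-frame
re-centring is available behind a flag but mixes translation into the
radial speeds. Boundary speed is v(θ) = (r_{t+1} − r_t) · pixel_size ·
60 / frame_interval, reported in µm/min, positive for expansion.

Band intensity averages bilinear samples from r(θ) to max(r(θ) − 30 px, 1 px)
along the ray (≈4 µm at 0.133 µm/px); bands reaching the 1 px inner limit
are truncated and flagged. Per-cell intensities are normalized to 1 at
null speed by the intercept of a linear regression of I on v restricted to
|v| < bandwidth (default 10 % of the cell's speed range) — the estimator of
I(0) is a design choice, since only the normalization target ("1 at null
speed") is part of the measurement definition. The binned
speed–intensity table reports mean ± SD and n per bin, dropping bins with
n < 5.

The generator's speed–intensity coupling is linear and decreasing,
g(v) = I₀(1 − βv) clipped at I₀/10 (default β = 0.1 per µm/min): stalled or
retracting boundary segments carry the brightest actin, the qualitative
behaviour of adhesion-dense waves. No functional form is claimed for real
cells; g is a programmable test oracle. A known, accepted bias: with
threshold-based outlines the measured radius carries a small
amplitude-dependent offset (the fixed threshold crosses the soft edge at an
amplitude-dependent height), which compresses the recovered slope by
~4–8 %. It cancels in the speed (the offset is constant over time at fixed
θ) and is within the 10 % recovery bands used in the tests.

## Traction force microscopy (`traction`)

**Substrate.** Linear elastic half-space with shear modulus G (study gels:
1.5 kPa) and Poisson ratio ν. ν is not stated for the gels; the default is
0.5 (incompressible polyacrylamide convention), configurable, with
E = 2G(1+ν) — at ν = 0.5, E = 3G = 4.5 kPa.

**Registration.** Rigid per-frame translation from phase correlation on a
cell-free ROI, coarse-to-fine: an integer peak first (exact for integer
drifts), then subpixel refinement of the integer-aligned frame with
upsampled phase correlation; the ROI is mean-subtracted and Hann-windowed
to suppress edge leakage. Frames are shifted in Fourier space.

**PIV.** Normalized cross-correlation of mean-subtracted interrogation
windows (3.46 µm, centre spacing 1.73 µm — 50 % overlap). The correlation
is divided by the triangular overlap envelope (equal-window correlation
otherwise biases peaks toward zero lag) and lightly Gaussian-smoothed
(σ = 0.75 px) before a 3-point Gaussian subpixel fit; the smoothing
preserves the Gaussian particle-peak shape while damping the random
cross-term background that limits subpixel accuracy. The primary-to-
secondary peak ratio is stored; windows below 1.2 are masked.

**Filtering + Kriging.** Outliers by the normalized-median (universal)
test on 3×3 neighbourhoods, default threshold 2.0 with a 0.02 µm noise
floor — which outlier filter precedes Kriging is not pinned down by the
measurement definition, so this standard choice is a documented decision. Masked
nodes are re-estimated by ordinary Kriging: an isotropic spherical
variogram fitted by weighted least squares to the empirical variogram of
valid vectors, then per-node solves against the 16 nearest valid
neighbours. Kriging weights sum to one, so constant fields are reproduced
exactly.

**FTTC.** The displacement is mean-subtracted, padded to twice its extent,
and inverted per wavevector against the analytic Fourier-space Boussinesq
tensor with zeroth-order Tikhonov regularization λ (units µm/Pa); the
zero-frequency traction is gauged to zero and the DC traction of the
cropped field is removed, so reconstructions are net-force-free. The pad
region is filled with a smooth cosine bridge between opposite edges rather
than zeros: a zero-pad step at the crop boundary is amplified by the
deconvolving inverse into large edge artifacts (≈25 % L2 error on the
noiseless 64×64 round trip; ≈3 % with the bridge).

The *forward* model (`forward_displacement`, used by the generator) is an
independent operator: linear convolution with the sampled real-space
Green's tensor, the singular self-cell handled by its analytic integral
over a square cell (∫dA/r = 4h·ln(1+√2)). It matches brute-force fine
quadrature of the surface integral to <1 %, so the inverse is tested
against an operator it does not share code with. Patch sets passed to the
generator must be force-balanced (an adherent cell exerts no net force).

**λ selection.** The L-curve (log residual norm vs log solution norm over
≥20 λ spanning ≥3 decades, computed spectrally so both norms are exactly
monotone) is returned in full; the corner is the signed maximum-curvature
point with endpoints excluded. On noise-free data the curve is flat at
small λ and the corner lands there, leaving the reconstruction within 10 %
of the λ→0 solution. A caveat documented here deliberately: on a square
N×N grid the discrete operator's condition number is only ~N, so a
pure-noise field is also fit exactly as λ→0 and its L-curve has no convex
corner either — corner selection is only informative when the data mix
signal with noise, and the full curve is emitted so alternative criteria
can be applied.

**Strain energy.** U = ½ Σ (T·u) h² over grid nodes, converted to joules
(Pa·µm³ = 10⁻¹⁸ J); an optional cell mask or hand-traced area gives
U per area. U is bilinear, invariant under common rigid shifts of both
fields, and non-negative for conjugate field pairs.

## FRAP (`recovery`)

Double normalization:
y(t) = [(roi − bg)/(ctrl − bg)] / [(pre_roi − bg)/(pre_ctrl − bg)], which
cancels acquisition bleaching against the control ROI and anchors the
pre-bleach level at 1. Anchoring the first post-bleach point to 0 is
available behind a flag (default off) since conventions differ. The model
y(t) = y₀ + a(1 − e^(−bt)) is fitted by nonlinear least squares,
initialized from the data (y₀ = first point, a = last − first, b =
1/t at half rise) with up to 5 perturbed restarts; b is bounded at 0.
t₁/₂ = ln 0.5/(−b) and the mobile fraction X_m = (y₀+a)/F_i with F_i = 1
after normalization; the plateau is taken from the fit, not the last raw
point, for noise robustness. Near-flat traces fit but are flagged
(rate×span < 0.05 or |a| ≈ 0): their parameters are unidentifiable. All
outputs are invariant to a common gain on the raw intensities.

The generator multiplies the recovery model by e^(−bleach·t) and provides
a control ROI carrying only the bleach decay, plus pre-bleach frames at the
unbleached level; defaults (1 s sampling, 120 post-bleach frames, noise SD
0.02) match spinning-disk FRAP of adhesion-scale ROIs.

## Single-cell mechanics (`mechanics`)

**Hertz.** F = (4/3)·E/(1−ν²)·√(Rδ³) for a 10 µm spherical probe
(R = 5 µm), cantilever k ≈ 0.03 N/m, ν = 0.5, indentation defined as
δ = z − z₀ − deflection (cantilever compliance subtracted — the standard
AFM convention, a documented choice). The contact point is found by least
squares over a flat-then-Hertz piecewise model: for each candidate z₀ the
baseline deflection is the pre-contact mean and the Hertz prefactor is the
closed-form least-squares solution on δ ∈ (0, 0.5 µm]; residuals are
evaluated over the **whole** curve with the model extrapolated past the fit
window — restricting residuals to the window lets a spurious early contact
point with E ≈ 0 hide the real force rise and appear perfect. A coarse
scan over sample positions is refined by bounded 1-D minimization. The
generator solves the implicit cantilever–indentation coupling per point
(k·d = C(z − z₀ − d)^{3/2}) and truncates the ramp at the 2 nN force
trigger.

**Trap.** Equipartition only, matching a thermal-motion calibration:
k = k_B·T/Var(x) on the mean-subtracted calibration segment (≥10⁴
samples); a block-mean variance test rejects drifting segments.
Power-spectral calibration and motion-blur corrections are out of scope —
at sub-millisecond exposure and the default trap relaxation time
(τ = 10 µs, the γ/k of a 1 µm bead in water at k = 10⁻³ N/m) blur and
sample correlation are negligible, and the generator's exact OU
discretization reproduces the stationary variance k_BT/k by construction.
The tether force is k·(mean hold displacement − pre-pull baseline mean);
the trap centre is the baseline mean (a documented choice), and the result
carries magnitude, direction sign, and the hold-segment SD. Conversion of
tether force to membrane tension is deliberately not performed.

**FM dye.** Background-corrected whole-cell intensity normalized to its
initial value; percentage area increase is 100·(Ĩ−1), resting on the
linearity of dye intensity in exposed membrane area. The generator's
default programs the ~40 % saturating increase typical of spreading
macrophages.

## Morphometry and statistics (`morphometry`)

Adhesion detection is Laplacian-of-Gaussian blob detection (in manual
workflows these windows are drawn by hand; automated detection is
plumbing, not a claim of equivalence), with detections whose 4 µm window would leave the image
excluded. Window averaging extracts subpixel-centred 4×4 µm squares per
channel, optionally normalizing each window by its own mean before
averaging (both global and per-adhesion modes exist because either could
have been used upstream), and reports radial mean profiles — the membrane
channel of the synthetic lifting scene shows its minimum at the programmed
annulus radius. 3-D adhesion measurements threshold, label 3-D connected
components, and report the xy-projected footprint area and z-extent height;
cup measurements are the mean and integrated intensity over a supplied ROI
mask (mask definition is a human task and stays an input).

Phagocytosis scoring computes per-FOV percentages (FOVs with zero cells
dropped with a warning), averages FOVs within experiment, and reports
mean ± SEM (or SD) across experiments — the hierarchy used for bulk
assays. The generator draws one uniform variate per cell so that
internalized ⊆ bound holds exactly while marginal rates equal the
programmed probabilities.

Group comparison: two groups use a pooled-variance unpaired two-tailed
t-test, switching to Welch's test when the sample SDs differ by more than
2× ("markedly different" quantified as a ratio, configurable, since no
numeric criterion is standard); identical zero-variance groups return
t = 0, p = 1. Three or more groups use one-way ANOVA with Tukey's HSD
post-hoc (statsmodels). Significance at p < 0.05. The null simulation in
the tests (1000 replicate pairs of n = 10 normals) keeps the empirical
type-I error within [3.5 %, 6.5 %].

## Problem sizes

The validation suite runs at sizes chosen to exercise every code path at
interactive speed: 12-frame 256² wave movies, 64×64 traction grids
(1.73 µm spacing), 512² speckle images, 100 FRAP traces, 50 AFM
replicates, 10⁵-sample trap traces, 1000-replicate null simulations. The
estimators contain nothing size-specific; larger inputs only change run
time.

## Known limitations

* Wave tracking assumes a star-shaped wave about the centre; strongly
  non-convex or fragmented waves violate the single-outermost-crossing
  model.
* FTTC is 2-D (no z-component) on an infinite half-space; no
  finite-thickness correction.
* FRAP fitting is purely phenomenological (single exponential); no
  diffusion–reaction model or bleach-geometry correction.
* Hertz fitting assumes elastic, time-independent response and spherical
  probe geometry.
* The statistics module implements the comparisons as specified
  (including the SD-ratio Welch trigger); it does not attempt hierarchical
  modelling of the FOV/experiment structure beyond the averaging described.
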