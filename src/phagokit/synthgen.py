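"""Synthetic ground-truth generators for every analysis stage.

The experimental data these pipelines were built for (time-lapse TIRF
movies of spreading macrophages, substrate bead images, FRAP/AFM/optical
trap traces, bead-count tables) are not publicly deposited, so each
generator here emulates one input modality with a known ground truth so the
corresponding analysis stage can be validated end to end:

* ``gen_wave_movie`` — expanding/contracting circular actin wave with a
  programmable per-angle boundary radius, speed-coupled intensity, punctate
  adhesions, and a membrane channel with annular dips around adhesions.
* ``gen_tfm_field`` — balanced Gaussian traction patches on a
  1.5 kPa-shear-modulus elastic half-space, forward-convolved into the true
  displacement field (optionally rendered as a warped bead speckle pair).
* ``gen_frap_trace`` — single-exponential recovery with acquisition
  bleaching and a matched control ROI.
* ``gen_afm_curve`` — Hertz force-indentation approach curve with contact
  offset and cantilever compliance.
* ``gen_trap_trace`` / ``gen_tether_trace`` — stationary Ornstein-Uhlenbeck
  trapped-bead traces (position variance k_B T / k) with a tether-force
  hold segment.
* ``gen_fm_trace`` — FM-dye intensity ramp for a programmed surface-area
  increase.
* ``gen_adhesion_volume`` — 3-D volumes of box adhesions with known
  footprint and height.
* ``gen_phagocytosis_table`` — Bernoulli per-cell internalization/binding
  tables.

Every generator is deterministic for a fixed :class:`SynthConfig` seed and
returns its ground truth alongside the data (write it out with
:func:`phagokit.core.write_truth_json`).  Noise is Poisson shot noise
(scaled by ``poisson_scale``) plus additive Gaussian read noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import brentq
from scipy.signal import lfilter

from .core import ImageStack
from .mechanics import BeadTrace, FmTrace, ForceIndentationCurve, K_B
from .recovery import RecoveryCurve
from .traction import ElasticSubstrate, forward_displacement

__all__ = [
    "SynthConfig",
    "WaveGroundTruth",
    "TractionGroundTruth",
    "expanding_wave_radii",
    "gen_wave_movie",
    "gaussian_traction_dipole",
    "gen_tfm_field",
    "render_speckle",
    "warp_image",
    "gen_frap_trace",
    "gen_afm_curve",
    "gen_trap_trace",
    "gen_tether_trace",
    "gen_fm_trace",
    "gen_adhesion_volume",
    "gen_phagocytosis_table",
]


@dataclass(frozen=True)
class SynthConfig:
    """Acquisition parameters shared by the image/trace generators.

    Defaults emulate TIRF time-lapse acquisition of spreading macrophages:
    0.133 um pixels, 10 s frame interval.  ``poisson_scale`` converts
    intensity to expected photon counts (0 disables shot noise);
    ``gaussian_sd`` is additive read noise.  A fixed seed plus identical
    parameters gives bit-identical output.
    """

    seed: int = 0
    pixel_size_um: float = 0.133
    frame_interval_s: float = 10.0
    image_shape: tuple = (256, 256)
    gaussian_sd: float = 0.0
    poisson_scale: float = 0.0

    def __post_init__(self):
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.gaussian_sd < 0 or self.poisson_scale < 0:
            raise ValueError("noise parameters must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _apply_noise(img: np.ndarray, cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    out = np.asarray(img, dtype=float)
    if cfg.poisson_scale > 0:
        out = rng.poisson(np.clip(out, 0, None) * cfg.poisson_scale) / cfg.poisson_scale
    if cfg.gaussian_sd > 0:
        out = out + rng.normal(0.0, cfg.gaussian_sd, size=out.shape)
    return out


# ---------------------------------------------------------------------------
# Actin wave movies
# ---------------------------------------------------------------------------

@dataclass
class WaveGroundTruth:
    """Programmed wave kinematics paired with a generated movie."""

    center_px: tuple
    r_true_um: np.ndarray        # (T, 360)
    v_true_um_min: np.ndarray    # (T-1, 360), exactly diff(r) / dt
    intensity0: float
    coupling_beta: float
    adhesion_centroids: list = field(default_factory=list)  # (x_px, y_px, t_first)
    pixel_size_um: float = 0.133
    frame_interval_s: float = 10.0


def expanding_wave_radii(r0_um, speed_um_min, n_frames: int,
                         frame_interval_s: float) -> np.ndarray:
    """Radius schedule r(t, theta) = r0 + v * t for programmed speeds.

    ``r0_um`` and ``speed_um_min`` may be scalars or per-angle (360,)
    arrays; the returned array has shape (n_frames, 360).
    """
    r0 = np.broadcast_to(np.asarray(r0_um, dtype=float), (360,))
    v = np.broadcast_to(np.asarray(speed_um_min, dtype=float), (360,))
    t_min = np.arange(n_frames)[:, None] * frame_interval_s / 60.0
    return r0[None, :] + v[None, :] * t_min


def _coupling(v_um_min: np.ndarray, intensity0: float, beta: float,
              floor_frac: float = 0.1) -> np.ndarray:
    """Default speed-intensity coupling g(v) = I0 (1 - beta v), clipped.

    Linear and decreasing so stalled or retracting boundary segments carry
    the brightest actin, the qualitative behaviour seen in myosin-1
    double-knockout waves; the true functional form in cells is unknown and
    this is purely a programmable test coupling.
    """
    return intensity0 * np.clip(1.0 - beta * v_um_min, floor_frac, None)


def gen_wave_movie(cfg: SynthConfig, radii_um: np.ndarray, center_px=None,
                   intensity0: float = 100.0, coupling_beta: float = 0.1,
                   edge_width_px: float = 1.5, n_adhesions: int = 0,
                   adhesion_sigma_px: float = 2.0,
                   membrane_level: float = 100.0, membrane_dip_depth: float = 50.0,
                   membrane_dip_radius_um: float = 0.5,
                   membrane_dip_sigma_um: float = 0.15):
    """Two-channel synthetic actin-wave movie with exact kinematic truth.

    The actin channel is a filled wave with a soft (sigmoidal) outer edge at
    the programmed radius r(theta, t); its amplitude along each angle is the
    speed-coupled g(v).  ``n_adhesions`` > 0 sprinkles punctate adhesions
    inside the wave (amplitude co-scaled with g).  The membrane channel is a
    uniform field with an annular dip (membrane lifting) around each active
    adhesion.  Returns ``(actin, membrane, truth)``.
    """
    radii_um = np.asarray(radii_um, dtype=float)
    if radii_um.ndim != 2 or radii_um.shape[1] != 360:
        raise ValueError("radii_um must have shape (n_frames, 360)")
    n_frames = radii_um.shape[0]
    if n_frames < 2:
        raise ValueError("need at least two frames")
    h, w = cfg.image_shape
    if center_px is None:
        center_px = ((w - 1) / 2.0, (h - 1) / 2.0)
    cx, cy = center_px

    r_px = radii_um / cfg.pixel_size_um
    margin = min(cx, cy, w - 1 - cx, h - 1 - cy)
    if r_px.max() > margin - 5:
        raise ValueError(f"wave would leave the field of view: max radius "
                         f"{r_px.max():.1f} px vs allowed {margin - 5:.1f} px")
    if r_px.min() < 2:
        raise ValueError("wave radius must stay above 2 px")

    dt_min = cfg.frame_interval_s / 60.0
    v_true = np.diff(radii_um, axis=0) / dt_min           # (T-1, 360)
    v_frame = np.vstack([v_true, v_true[-1:]])            # amplitude uses last speed twice

    yy, xx = np.mgrid[0:h, 0:w]
    rho = np.hypot(xx - cx, yy - cy)
    theta_idx = (np.degrees(np.arctan2(yy - cy, xx - cx)).astype(int)) % 360

    rng = cfg.rng()
    adhesions = []
    if n_adhesions > 0:
        ang = rng.uniform(0, 2 * np.pi, n_adhesions)
        rad = np.sqrt(rng.uniform((0.3 * r_px.min()) ** 2, (0.98 * r_px.max()) ** 2,
                                  n_adhesions))
        ax, ay = cx + rad * np.cos(ang), cy + rad * np.sin(ang)
        a_theta = (np.degrees(np.arctan2(ay - cy, ax - cx)).astype(int)) % 360
        adhesions = list(zip(ax, ay, rad, a_theta))

    actin = np.empty((n_frames, h, w))
    membrane = np.empty((n_frames, h, w))
    dip_r_px = membrane_dip_radius_um / cfg.pixel_size_um
    dip_sig_px = membrane_dip_sigma_um / cfg.pixel_size_um
    centroid_first_seen = {}
    for t in range(n_frames):
        amp = _coupling(v_frame[t], intensity0, coupling_beta)
        edge = 1.0 / (1.0 + np.exp(-(r_px[t][theta_idx] - rho) / edge_width_px))
        frame = amp[theta_idx] * edge
        mem = np.full((h, w), membrane_level)
        for i, (ax, ay, rad, ath) in enumerate(adhesions):
            if rad >= r_px[t, ath]:
                continue
            if i not in centroid_first_seen:
                centroid_first_seen[i] = (float(ax), float(ay), t)
            d = np.hypot(xx - ax, yy - ay)
            frame += (amp[ath] * 0.8) * np.exp(-d ** 2 / (2 * adhesion_sigma_px ** 2))
            mem -= membrane_dip_depth * np.exp(-(d - dip_r_px) ** 2 / (2 * dip_sig_px ** 2))
        actin[t] = _apply_noise(frame, cfg, rng)
        membrane[t] = _apply_noise(np.clip(mem, 0, None), cfg, rng)

    truth = WaveGroundTruth(
        center_px=(float(cx), float(cy)), r_true_um=radii_um,
        v_true_um_min=v_true, intensity0=intensity0, coupling_beta=coupling_beta,
        adhesion_centroids=sorted(centroid_first_seen.values(), key=lambda c: c[2]),
        pixel_size_um=cfg.pixel_size_um, frame_interval_s=cfg.frame_interval_s)
    mk = lambda data, ch: ImageStack(data, cfg.pixel_size_um, cfg.frame_interval_s,
                                     channel=ch)
    return mk(actin, "actin"), mk(membrane, "membrane"), truth


# ---------------------------------------------------------------------------
# Traction fields and bead images
# ---------------------------------------------------------------------------

@dataclass
class TractionGroundTruth:
    """True traction/displacement pair with the programmed substrate."""

    x_um: np.ndarray
    y_um: np.ndarray
    traction_pa: np.ndarray      # (ny, nx, 2)
    displacement_um: np.ndarray  # (ny, nx, 2)
    spacing_um: float
    shear_modulus_pa: float
    poisson_ratio: float
    strain_energy_j: float


def gaussian_traction_dipole(center_um, separation_um: float, sigma_um: float,
                             peak_pa: float, axis=(1.0, 0.0)) -> list:
    """Two opposing (contractile) Gaussian traction patches with zero net
    force — the elementary balanced traction unit of an adherent cell."""
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    c = np.asarray(center_um, dtype=float)
    off = 0.5 * separation_um * ax
    return [
        {"center_um": tuple(c - off), "sigma_um": sigma_um, "peak_pa": peak_pa,
         "direction": tuple(ax)},
        {"center_um": tuple(c + off), "sigma_um": sigma_um, "peak_pa": peak_pa,
         "direction": tuple(-ax)},
    ]


def gen_tfm_field(cfg: SynthConfig, patches: list, grid_shape=(64, 64),
                  spacing_um: float = 1.73,
                  substrate: ElasticSubstrate | None = None,
                  net_force_tol: float = 1e-6) -> TractionGroundTruth:
    """Forward TFM ground truth: Gaussian traction patches convolved with
    the Boussinesq half-space Green's function into displacements.

    Each patch is ``{"center_um": (x, y), "sigma_um": s, "peak_pa": p,
    "direction": (dx, dy)}``.  The patch set must be force-balanced to
    within ``net_force_tol`` of the total absolute traction (an adherent
    cell exerts no net force on its substrate).
    """
    if substrate is None:
        substrate = ElasticSubstrate()
    ny, nx = grid_shape
    x = np.arange(nx) * spacing_um
    y = np.arange(ny) * spacing_um
    xx, yy = np.meshgrid(x, y)
    t = np.zeros((ny, nx, 2))
    for p in patches:
        px, py = p["center_um"]
        d = np.asarray(p["direction"], dtype=float)
        d = d / np.linalg.norm(d)
        g = p["peak_pa"] * np.exp(-((xx - px) ** 2 + (yy - py) ** 2)
                                  / (2 * p["sigma_um"] ** 2))
        t[..., 0] += g * d[0]
        t[..., 1] += g * d[1]
    total_abs = np.abs(t).sum()
    if total_abs > 0:
        net = np.abs(t.sum(axis=(0, 1)))
        if net.max() > net_force_tol * total_abs:
            raise ValueError(f"traction patches are not force-balanced "
                             f"(net/|T| = {net.max() / total_abs:.2e} > {net_force_tol})")
    u = forward_displacement(t, spacing_um, substrate)
    energy = 0.5 * float((t * u).sum()) * (spacing_um * 1e-6) ** 2 * 1e-6
    return TractionGroundTruth(x_um=x, y_um=y, traction_pa=t, displacement_um=u,
                               spacing_um=spacing_um,
                               shear_modulus_pa=substrate.shear_modulus_pa,
                               poisson_ratio=substrate.poisson_ratio,
                               strain_energy_j=energy)


def render_speckle(cfg: SynthConfig, shape=None, density_per_px2: float = 0.02,
                   sigma_px: float = 1.2, amplitude: float = 100.0,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Random fluorescent-bead speckle image (Gaussian spots)."""
    if rng is None:
        rng = cfg.rng()
    h, w = shape if shape is not None else cfg.image_shape
    n = int(density_per_px2 * h * w)
    img = np.zeros((h, w))
    xs = rng.uniform(0, w - 1, n)
    ys = rng.uniform(0, h - 1, n)
    half = int(np.ceil(4 * sigma_px))
    for x0, y0 in zip(xs, ys):
        ix, iy = int(round(x0)), int(round(y0))
        sl_y = slice(max(0, iy - half), min(h, iy + half + 1))
        sl_x = slice(max(0, ix - half), min(w, ix + half + 1))
        yy, xx = np.mgrid[sl_y, sl_x]
        img[sl_y, sl_x] += amplitude * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2)
                                              / (2 * sigma_px ** 2))
    return img


def warp_image(image: np.ndarray, shift_px=None,
               displacement_px: np.ndarray | None = None) -> np.ndarray:
    """Warp an image by a uniform subpixel shift (exact, Fourier) or by a
    per-pixel displacement field (cubic interpolation, inverse mapping)."""
    img = np.asarray(image, dtype=float)
    if shift_px is not None:
        dx, dy = shift_px
        return np.real(np.fft.ifft2(ndimage.fourier_shift(np.fft.fft2(img), (dy, dx))))
    if displacement_px is None:
        raise ValueError("provide shift_px or displacement_px")
    yy, xx = np.mgrid[0:img.shape[0], 0:img.shape[1]].astype(float)
    return ndimage.map_coordinates(img, [yy - displacement_px[..., 1],
                                         xx - displacement_px[..., 0]], order=3,
                                   mode="reflect")


# ---------------------------------------------------------------------------
# FRAP traces
# ---------------------------------------------------------------------------

def gen_frap_trace(cfg: SynthConfig, y0: float = 0.2, a: float = 0.6,
                   b: float = 0.1, bleach_rate: float = 0.005,
                   noise_sd: float = 0.02, n_pre: int = 5, n_post: int = 120,
                   dt_s: float = 1.0, roi_gain: float = 1.0,
                   ctrl_gain: float = 1.0, background: float = 0.0,
                   rng: np.random.Generator | None = None):
    """Synthetic FRAP trace: exponential recovery times acquisition bleach.

    The bleached-ROI signal is ``(y0 + a (1 - e^{-bt})) e^{-bleach_rate t}``
    scaled by ``roi_gain``; the control ROI carries only the bleach decay.
    Pre-bleach frames sit at the unbleached level (normalized 1.0).
    Returns ``(curve, truth)``.
    """
    if b < 0 or bleach_rate < 0:
        raise ValueError("rates must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not (0 <= y0 and y0 + a <= 1 + 1e-9):
        raise ValueError("require 0 <= y0 and y0 + a <= 1 on the normalized scale")
    if rng is None:
        rng = cfg.rng()
    t = np.arange(n_post) * dt_s
    model = y0 + a * (1.0 - np.exp(-b * t))
    bleach = np.exp(-bleach_rate * t)
    noise = lambda n, gain: (rng.normal(0.0, noise_sd * gain, n) if noise_sd > 0
                             else np.zeros(n))
    curve = RecoveryCurve(
        t_s=t,
        roi=background + roi_gain * model * bleach + noise(n_post, roi_gain),
        background=np.full(n_post, background),
        control=background + ctrl_gain * bleach + noise(n_post, ctrl_gain),
        prebleach_roi=np.full(n_pre, background + roi_gain) + noise(n_pre, roi_gain),
        prebleach_background=np.full(n_pre, background),
        prebleach_control=np.full(n_pre, background + ctrl_gain) + noise(n_pre, ctrl_gain),
    )
    truth = {"y0": y0, "a": a, "b": b, "plateau": y0 + a,
             "bleach_rate": bleach_rate,
             "t_half_s": float(np.log(2) / b) if b > 0 else np.inf}
    return curve, truth


# ---------------------------------------------------------------------------
# AFM curves
# ---------------------------------------------------------------------------

def gen_afm_curve(cfg: SynthConfig, young_modulus_pa: float = 4500.0,
                  contact_z_m: float = 1e-6, k_cantilever_n_per_m: float = 0.03,
                  probe_radius_m: float = 5e-6, poisson_ratio: float = 0.5,
                  ramp_m: float = 3e-6, n: int = 600,
                  force_noise_sd_n: float = 0.0,
                  force_threshold_n: float = 2e-9,
                  rng: np.random.Generator | None = None):
    """Hertzian approach curve with contact offset and cantilever compliance.

    For piezo positions past the contact point the deflection d solves
    ``k d = (4/3) E / (1 - nu^2) sqrt(R (z - z0 - d)^3)``; the ramp stops
    when the force reaches ``force_threshold_n`` (2 nN trigger).  Returns
    ``(curve, truth)``.
    """
    if min(young_modulus_pa, k_cantilever_n_per_m, probe_radius_m, ramp_m) <= 0:
        raise ValueError("physical parameters must be strictly positive")
    if force_noise_sd_n < 0:
        raise ValueError("force noise must be >= 0")
    if rng is None:
        rng = cfg.rng()
    c = (4.0 / 3.0) * young_modulus_pa / (1.0 - poisson_ratio ** 2) * np.sqrt(probe_radius_m)
    z = np.linspace(0.0, ramp_m, n)
    k = k_cantilever_n_per_m
    d = np.zeros(n)
    for i, zi in enumerate(z):
        if zi <= contact_z_m:
            continue
        span = zi - contact_z_m
        d[i] = brentq(lambda x: k * x - c * (span - x) ** 1.5, 0.0, span,
                      xtol=1e-20, rtol=8.9e-16)
    force = k * d
    keep = force <= force_threshold_n
    if keep.sum() < n:  # truncate at the trigger like the instrument does
        last = np.argmin(keep)
        z, d = z[:last], d[:last]
    if force_noise_sd_n > 0:
        d = d + rng.normal(0.0, force_noise_sd_n / k, size=len(d))
    curve = ForceIndentationCurve(z_m=z, deflection_m=d,
                                  k_cantilever_n_per_m=k, probe_radius_m=probe_radius_m)
    truth = {"young_modulus_pa": young_modulus_pa, "contact_z_m": contact_z_m,
             "poisson_ratio": poisson_ratio}
    return curve, truth


# ---------------------------------------------------------------------------
# Optical trap traces
# ---------------------------------------------------------------------------

def _ou_trace(rng: np.random.Generator, n: int, dt_s: float, tau_s: float,
              sigma2_m2: float, mean_m: float = 0.0) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck samples, exact discretization."""
    rho = np.exp(-dt_s / tau_s)
    innov = np.sqrt(sigma2_m2 * (1.0 - rho ** 2)) * rng.standard_normal(n)
    x0 = np.sqrt(sigma2_m2) * rng.standard_normal()
    x, _ = lfilter([1.0], [1.0, -rho], innov, zi=[rho * x0])
    return mean_m + x


def gen_trap_trace(cfg: SynthConfig, stiffness_n_per_m: float = 1e-3,
                   temperature_k: float = 295.0, n: int = 100_000,
                   dt_s: float = 1e-3, tau_s: float = 1e-5,
                   rng: np.random.Generator | None = None):
    """Thermal position trace of a trapped bead (stationary OU process).

    The stationary variance is k_B T / k (equipartition); ``tau_s`` is the
    trap relaxation time gamma/k, far below typical camera exposure for a
    micron bead in water, so successive samples are nearly independent.
    Returns ``(trace, truth)``.
    """
    if stiffness_n_per_m <= 0 or temperature_k <= 0 or tau_s <= 0:
        raise ValueError("physical parameters must be strictly positive")
    if dt_s <= 0:
        raise ValueError("dt must be > 0")
    if n < 2:
        raise ValueError("need at least 2 samples")
    if rng is None:
        rng = cfg.rng()
    sigma2 = K_B * temperature_k / stiffness_n_per_m
    x = _ou_trace(rng, n, dt_s, tau_s, sigma2)
    trace = BeadTrace(t_s=np.arange(n) * dt_s, x_m=x,
                      segment=np.full(n, "calibration"))
    truth = {"stiffness_n_per_m": stiffness_n_per_m,
             "temperature_k": temperature_k, "variance_m2": sigma2}
    return trace, truth


def gen_tether_trace(cfg: SynthConfig, stiffness_n_per_m: float = 1e-3,
                     tether_force_n: float = 40e-12, temperature_k: float = 295.0,
                     n_baseline: int = 20_000, n_hold: int = 20_000,
                     dt_s: float = 1e-3, tau_s: float = 1e-5,
                     rng: np.random.Generator | None = None):
    """Bead trace with a baseline segment then a tether-hold segment offset
    by ``tether_force / stiffness`` from the trap centre.  Returns
    ``(trace, truth)``."""
    if stiffness_n_per_m <= 0 or temperature_k <= 0:
        raise ValueError("physical parameters must be strictly positive")
    if dt_s <= 0 or n_baseline < 2 or n_hold < 2:
        raise ValueError("dt must be > 0 and both segments need >= 2 samples")
    if rng is None:
        rng = cfg.rng()
    sigma2 = K_B * temperature_k / stiffness_n_per_m
    offset = tether_force_n / stiffness_n_per_m
    base = _ou_trace(rng, n_baseline, dt_s, tau_s, sigma2)
    hold = _ou_trace(rng, n_hold, dt_s, tau_s, sigma2, mean_m=offset)
    n = n_baseline + n_hold
    trace = BeadTrace(t_s=np.arange(n) * dt_s, x_m=np.concatenate([base, hold]),
                      segment=np.array(["baseline"] * n_baseline + ["hold"] * n_hold))
    truth = {"stiffness_n_per_m": stiffness_n_per_m,
             "tether_force_n": tether_force_n, "offset_m": offset}
    return trace, truth


# ---------------------------------------------------------------------------
# FM dye traces
# ---------------------------------------------------------------------------

def gen_fm_trace(cfg: SynthConfig, area_increase_pct: float = 40.0,
                 n: int = 100, dt_s: float = 15.0, tau_spread_s: float = 200.0,
                 intensity0: float = 1000.0, background: float = 50.0,
                 noise_sd: float = 0.0, rng: np.random.Generator | None = None):
    """FM-dye intensity trace for a cell spreading to ``area_increase_pct``
    more surface area (saturating exponential ramp).  Returns
    ``(trace, truth)``."""
    if intensity0 <= 0 or tau_spread_s <= 0:
        raise ValueError("physical parameters must be strictly positive")
    if rng is None:
        rng = cfg.rng()
    t = np.arange(n) * dt_s
    ramp = 1.0 - np.exp(-t / tau_spread_s)
    signal = intensity0 * (1.0 + area_increase_pct / 100.0 * ramp)
    noise = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else 0.0
    trace = FmTrace(t_s=t, intensity=background + signal + noise,
                    background=np.full(n, background))
    truth = {"area_increase_pct": area_increase_pct,
             "final_increase_pct": float(area_increase_pct * ramp[-1])}
    return trace, truth


# ---------------------------------------------------------------------------
# 3-D adhesion volumes
# ---------------------------------------------------------------------------

def gen_adhesion_volume(cfg: SynthConfig, footprint_areas_um2,
                        heights_um, pixel_size_um: float = 0.05,
                        z_step_um: float = 0.1, shape=(20, 128, 128),
                        intensity: float = 100.0,
                        rng: np.random.Generator | None = None):
    """3-D volume of square-footprint box adhesions rising from z = 0.

    Footprint side lengths and heights are quantized to the voxel grid; the
    returned truth records the rendered (quantized) area and height per
    adhesion.  Returns ``(volume, truth_table)``.
    """
    if rng is None:
        rng = cfg.rng()
    nz, h, w = shape
    vol = np.zeros(shape)
    rows = []
    occupied = []
    for area, height in zip(np.atleast_1d(footprint_areas_um2),
                            np.atleast_1d(heights_um)):
        side_px = max(1, int(round(np.sqrt(area) / pixel_size_um)))
        n_z = max(1, int(round(height / z_step_um)))
        if n_z > nz:
            raise ValueError("adhesion taller than the volume")
        for _ in range(200):
            x0 = rng.integers(2, w - side_px - 2)
            y0 = rng.integers(2, h - side_px - 2)
            box = (x0 - 2, y0 - 2, x0 + side_px + 2, y0 + side_px + 2)
            if all(box[2] < o[0] or o[2] < box[0] or box[3] < o[1] or o[3] < box[1]
                   for o in occupied):
                break
        else:
            raise ValueError("could not place adhesions without overlap")
        occupied.append(box)
        vol[:n_z, y0:y0 + side_px, x0:x0 + side_px] = intensity
        rows.append({"x_um": (x0 + side_px / 2) * pixel_size_um,
                     "y_um": (y0 + side_px / 2) * pixel_size_um,
                     "area_um2": (side_px * pixel_size_um) ** 2,
                     "height_um": n_z * z_step_um})
    stack = ImageStack(vol, pixel_size_um, z_step_um=z_step_um, channel="actin")
    return stack, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Phagocytosis count tables
# ---------------------------------------------------------------------------

def gen_phagocytosis_table(cfg: SynthConfig, p_internal: float = 0.3,
                           p_bound: float = 0.9, p_cup: float | None = None,
                           cells_per_fov: int = 50, n_fov: int = 20,
                           genotype: str = "WT", time_min: float = 30.0,
                           n_experiments: int = 1,
                           rng: np.random.Generator | None = None):
    """Per-FOV Bernoulli phagocytosis counts with exact nesting.

    A single uniform draw per cell makes internalized cells a subset of
    bead-associated cells while keeping the marginal probabilities exactly
    ``p_internal`` and ``p_bound`` (requires p_bound >= p_internal).
    Returns ``(table, truth)``.
    """
    for name, p in (("p_internal", p_internal), ("p_bound", p_bound)):
        if not 0 <= p <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    if p_bound < p_internal:
        raise ValueError("p_bound must be >= p_internal (internalized cells are bound)")
    if rng is None:
        rng = cfg.rng()
    rows = []
    for exp in range(n_experiments):
        for fov in range(n_fov):
            u = rng.random(cells_per_fov)
            n_int = int((u < p_internal).sum())
            n_assoc = int((u < p_bound).sum())
            n_cup = int((rng.random(cells_per_fov) < p_cup).sum()) if p_cup is not None else 0
            rows.append({"experiment": exp, "fov": fov, "genotype": genotype,
                         "time_min": time_min, "n_cells": cells_per_fov,
                         "n_internalized": n_int, "n_associated": n_assoc,
                         "n_cups": n_cup})
    truth = {"p_internal": p_internal, "p_bound": p_bound, "p_cup": p_cup}
    return pd.DataFrame(rows), truth
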