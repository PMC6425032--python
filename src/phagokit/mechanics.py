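"""Single-cell mechanics: Hertz indentation, optical-trap calibration,
membrane-tether force, and FM-dye surface-area traces.

Hertz model for a spherical probe of radius R on an incompressible cell:

    F = (4/3) * E / (1 - nu^2) * sqrt(R * delta^3)

with indentation delta = z - z0 - deflection (cantilever compliance
subtracted, the standard AFM convention).  Fitting is restricted to small
indentations (delta <= 0.5 um by default) to stay in the small-deformation
regime and minimize substrate contributions.

Trap stiffness comes from equipartition on the thermal position
fluctuations of a trapped bead, k = k_B T / Var(x); the tether-holding
force is the trap stiffness times the mean bead displacement from the trap
centre during the hold segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.constants import Boltzmann as K_B
from scipy.optimize import minimize_scalar

__all__ = [
    "ForceIndentationCurve",
    "HertzFit",
    "BeadTrace",
    "TrapCalibration",
    "TetherForceResult",
    "FmTrace",
    "SurfaceAreaResult",
    "hertz_force",
    "find_contact_and_fit",
    "calibrate_trap",
    "tether_force",
    "fm_area_increase",
]


@dataclass
class ForceIndentationCurve:
    """AFM approach curve: piezo position and cantilever deflection (m).

    Study values: cantilever spring constant ~0.03 N/m, 10 um probe bead
    (R = 5e-6 m).
    """

    z_m: np.ndarray
    deflection_m: np.ndarray
    k_cantilever_n_per_m: float = 0.03
    probe_radius_m: float = 5e-6

    def __post_init__(self):
        self.z_m = np.asarray(self.z_m, dtype=float)
        self.deflection_m = np.asarray(self.deflection_m, dtype=float)
        if self.z_m.shape != self.deflection_m.shape:
            raise ValueError("z and deflection must have the same length")
        if self.k_cantilever_n_per_m <= 0 or self.probe_radius_m <= 0:
            raise ValueError("cantilever stiffness and probe radius must be > 0")

    @property
    def force_n(self) -> np.ndarray:
        return self.k_cantilever_n_per_m * self.deflection_m


@dataclass
class HertzFit:
    young_modulus_pa: float
    contact_z_m: float
    poisson_ratio: float
    max_depth_m: float
    n_points: int
    baseline_deflection_m: float


@dataclass
class BeadTrace:
    """Trapped-bead position trace with optional segment labels
    (e.g. 'calibration', 'baseline', 'hold')."""

    t_s: np.ndarray
    x_m: np.ndarray
    segment: np.ndarray | None = None

    def __post_init__(self):
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_m = np.asarray(self.x_m, dtype=float)
        if self.segment is not None:
            self.segment = np.asarray(self.segment)
            if len(self.segment) != len(self.x_m):
                raise ValueError("segment labels must match trace length")

    def select(self, label: str) -> np.ndarray:
        if self.segment is None:
            return self.x_m
        return self.x_m[self.segment == label]


@dataclass
class TrapCalibration:
    stiffness_n_per_m: float
    temperature_k: float
    variance_m2: float
    n_samples: int


@dataclass
class TetherForceResult:
    force_n: float
    force_sd_n: float
    direction: int
    mean_displacement_m: float


@dataclass
class FmTrace:
    """FM-dye whole-cell intensity trace with matched background."""

    t_s: np.ndarray
    intensity: np.ndarray
    background: np.ndarray

    def __post_init__(self):
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.background = np.broadcast_to(np.asarray(self.background, dtype=float),
                                          self.intensity.shape).copy()


@dataclass
class SurfaceAreaResult:
    t_s: np.ndarray
    normalized: np.ndarray
    area_increase_pct: np.ndarray

    @property
    def final_increase_pct(self) -> float:
        return float(self.area_increase_pct[-1])


# ---------------------------------------------------------------------------
# Hertz indentation
# ---------------------------------------------------------------------------

def hertz_force(young_modulus_pa: float, poisson_ratio: float,
                probe_radius_m: float, indentation_m) -> np.ndarray:
    """F = (4/3) E / (1 - nu^2) sqrt(R delta^3) for a spherical indenter."""
    if poisson_ratio >= 1:
        raise ValueError("Poisson ratio must be < 1")
    delta = np.asarray(indentation_m, dtype=float)
    if np.any(delta < 0):
        raise ValueError("indentation depth must be >= 0")
    f = (4.0 / 3.0) * young_modulus_pa / (1.0 - poisson_ratio ** 2) \
        * np.sqrt(probe_radius_m * delta ** 3)
    return f if f.ndim else float(f)


def _hertz_sse(curve: ForceIndentationCurve, z0: float, max_depth_m: float,
               min_points: int = 5):
    """Mean squared force residual of the flat-then-Hertz model at contact z0.

    Returns (mse, C, d0, n_fit) where C is the Hertz prefactor
    F = C delta^{3/2}; C < 0 or too few fit points -> (inf, ...).
    """
    z, d = curve.z_m, curve.deflection_m
    pre = z < z0
    if pre.sum() < 3:
        return np.inf, np.nan, np.nan, 0
    d0 = float(d[pre].mean())
    dd = d - d0
    delta = z - z0 - dd
    f = curve.k_cantilever_n_per_m * dd
    fit_pts = (delta > 0) & (delta <= max_depth_m)
    if fit_pts.sum() < min_points:
        return np.inf, np.nan, np.nan, int(fit_pts.sum())
    x = delta[fit_pts] ** 1.5
    c = float((f[fit_pts] * x).sum() / (x * x).sum())
    if c <= 0:
        return np.inf, np.nan, d0, int(fit_pts.sum())
    # residuals over the WHOLE curve (model extrapolated past the fit
    # window): otherwise an early contact point with E ~ 0 can hide the
    # real force rise outside the small-depth window and look perfect
    post = delta > 0
    resid = np.concatenate([f[pre], f[post] - c * delta[post] ** 1.5])
    return float((resid ** 2).mean()), c, d0, int(fit_pts.sum())


def find_contact_and_fit(curve: ForceIndentationCurve, poisson_ratio: float = 0.5,
                         max_depth_m: float = 0.5e-6,
                         force_threshold_n: float = 2e-9) -> HertzFit:
    """Locate the contact point and fit the Young's modulus.

    The contact point z0 is found by least squares over a piecewise model:
    zero force (flat baseline) before contact, Hertz growth after, using
    only points with delta <= ``max_depth_m`` (0.5 um, small-deformation
    regime).  A coarse scan over candidate contact points is refined by
    bounded 1-D minimization.
    """
    z = curve.z_m
    if len(z) < 20:
        raise ValueError("need at least 20 samples on the approach segment")
    if np.any(np.diff(z) < 0):
        raise ValueError("approach segment must have monotonically increasing z")
    baseline_f = curve.k_cantilever_n_per_m * (curve.deflection_m[:10]
                                               - np.median(curve.deflection_m[:10]))
    if np.any(np.abs(baseline_f) > force_threshold_n):
        raise ValueError("force exceeds the trigger threshold before the "
                         "contact search window; not an approach curve")

    candidates = z[3:-5]
    scores = np.array([_hertz_sse(curve, z0, max_depth_m)[0] for z0 in candidates])
    if not np.isfinite(scores).any():
        raise ValueError("no contact detected (curve may be truncated before contact)")
    best = int(np.argmin(scores))
    lo = candidates[max(best - 2, 0)]
    hi = candidates[min(best + 2, len(candidates) - 1)]
    if hi > lo:
        res = minimize_scalar(lambda z0: _hertz_sse(curve, z0, max_depth_m)[0],
                              bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-12})
        z0 = float(res.x)
        if not np.isfinite(_hertz_sse(curve, z0, max_depth_m)[0]):
            z0 = float(candidates[best])
    else:
        z0 = float(candidates[best])
    mse, c, d0, n_fit = _hertz_sse(curve, z0, max_depth_m)
    if not np.isfinite(mse):
        raise ValueError("no contact detected (curve may be truncated before contact)")
    e = c * 0.75 * (1.0 - poisson_ratio ** 2) / np.sqrt(curve.probe_radius_m)
    return HertzFit(young_modulus_pa=float(e), contact_z_m=z0,
                    poisson_ratio=poisson_ratio, max_depth_m=max_depth_m,
                    n_points=n_fit, baseline_deflection_m=d0)


# ---------------------------------------------------------------------------
# Optical trap
# ---------------------------------------------------------------------------

def calibrate_trap(trace: BeadTrace, temperature_k: float = 295.0,
                   segment: str | None = "calibration",
                   min_samples: int = 10_000, n_blocks: int = 10,
                   drift_factor: float = 20.0) -> TrapCalibration:
    """Equipartition trap-stiffness estimate k = k_B T / Var(x).

    The calibration segment must be stationary: the variance of block means
    is compared against the value expected for a stationary trace and a
    large excess (slow drift) raises.  Adding a constant offset to x leaves
    the result unchanged.
    """
    x = trace.select(segment) if segment is not None else trace.x_m
    if len(x) == 0 and trace.segment is not None:
        x = trace.x_m  # unlabelled trace: use everything
    if len(x) < min_samples:
        raise ValueError(f"calibration needs >= {min_samples} samples, got {len(x)}")
    x = x - x.mean()
    var = float(x.var(ddof=1))
    if var <= 0:
        raise ValueError("zero position variance; not a thermal trace")
    block = len(x) // n_blocks
    means = x[:block * n_blocks].reshape(n_blocks, block).mean(axis=1)
    if means.var(ddof=1) > drift_factor * var / block:
        raise ValueError("drift detected in calibration segment "
                         "(block-mean variance far exceeds the stationary expectation)")
    k = K_B * temperature_k / var
    return TrapCalibration(stiffness_n_per_m=float(k), temperature_k=temperature_k,
                           variance_m2=var, n_samples=len(x))


def tether_force(trace: BeadTrace, calibration: TrapCalibration,
                 hold_segment: str = "hold",
                 baseline_segment: str = "baseline") -> TetherForceResult:
    """Tether force F = k_trap * mean bead displacement during the hold.

    The trap centre is the mean position over the pre-pull baseline
    segment; the force is reported as magnitude plus direction sign.
    """
    hold = trace.select(hold_segment)
    if len(hold) < 10:
        raise ValueError("hold segment must contain at least 10 samples")
    if trace.segment is not None and np.any(trace.segment == baseline_segment):
        centre = float(trace.select(baseline_segment).mean())
    else:
        centre = 0.0
    disp = float(hold.mean() - centre)
    k = calibration.stiffness_n_per_m
    return TetherForceResult(force_n=abs(k * disp),
                             force_sd_n=float(k * hold.std(ddof=1)) if len(hold) > 1 else 0.0,
                             direction=int(np.sign(disp)) if disp != 0 else 0,
                             mean_displacement_m=disp)


# ---------------------------------------------------------------------------
# FM-dye surface area
# ---------------------------------------------------------------------------

def fm_area_increase(trace: FmTrace) -> SurfaceAreaResult:
    """Relative surface-area increase from a background-corrected FM trace.

    The dye intensity is linear in exposed membrane area, so
    I~(t) = I(t)/I(0) and the percentage increase is 100 (I~ - 1).
    """
    corrected = trace.intensity - trace.background
    if corrected[0] <= 0:
        raise ValueError("initial background-corrected intensity must be > 0")
    norm = corrected / corrected[0]
    return SurfaceAreaResult(t_s=trace.t_s.copy(), normalized=norm,
                             area_increase_pct=100.0 * (norm - 1.0))
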