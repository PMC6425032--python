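"""FRAP trace correction, normalization and single-exponential fitting.

A bleached region-of-interest trace is corrected for background and
acquisition bleaching with a control ROI, normalized so the pre-bleach
intensity maps to one (double normalization), and fitted with the
single-exponential recovery model

    y(t) = y0 + a * (1 - exp(-b t))

from which the half time of recovery t_1/2 = ln 0.5 / (-b) and the mobile
fraction X_m = F_inf / F_i (fitted plateau over normalized pre-bleach
intensity) follow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "RecoveryCurve",
    "FrapFit",
    "correct_normalize",
    "fit_recovery",
    "half_life",
    "mobile_fraction",
    "analyze_curve",
    "analyze_curves",
]


@dataclass
class RecoveryCurve:
    """Raw FRAP intensities: bleached ROI, background and control ROI over
    post-bleach time (typically 1 s spacing) plus >= 1 pre-bleach frame."""

    t_s: np.ndarray
    roi: np.ndarray
    background: np.ndarray
    control: np.ndarray
    prebleach_roi: np.ndarray
    prebleach_background: np.ndarray
    prebleach_control: np.ndarray

    def __post_init__(self):
        for name in ("t_s", "roi", "background", "control",
                     "prebleach_roi", "prebleach_background", "prebleach_control"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.t_s)
        if not (len(self.roi) == len(self.background) == len(self.control) == n):
            raise ValueError("t, roi, background and control must have equal lengths")
        if len(self.prebleach_roi) < 1:
            raise ValueError("at least one pre-bleach frame is required")
        if self.prebleach_roi.mean() <= 0:
            raise ValueError("pre-bleach ROI mean must be > 0")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RecoveryCurve":
        """Build from a tidy table with columns t, roi, background, control,
        prebleach (boolean flag marking pre-bleach rows)."""
        pre = df[df["prebleach"].astype(bool)]
        post = df[~df["prebleach"].astype(bool)]
        return cls(post["t"].values, post["roi"].values, post["background"].values,
                   post["control"].values, pre["roi"].values,
                   pre["background"].values, pre["control"].values)


@dataclass
class FrapFit:
    """Fitted recovery parameters (on the normalized scale)."""

    y0: float
    a: float
    b: float
    se: tuple = (np.nan, np.nan, np.nan)
    cov: np.ndarray = None
    flagged: bool = False
    flag_reason: str = ""

    @property
    def plateau(self) -> float:
        return self.y0 + self.a

    @property
    def t_half_s(self) -> float:
        return half_life(self)


def _recovery_model(t, y0, a, b):
    return y0 + a * (1.0 - np.exp(-b * t))


def correct_normalize(curve: RecoveryCurve, anchor_postbleach: bool = False):
    """Double-normalize a FRAP trace.

    y(t) = [(roi - bg) / (ctrl - bg)] / [(pre_roi - pre_bg) / (pre_ctrl - pre_bg)]

    The control ROI cancels acquisition bleaching and the pre-bleach ratio
    anchors the pre-bleach intensity at 1.  With ``anchor_postbleach`` the
    first post-bleach value is additionally mapped to 0 (single-parameter
    rescale), a convention some packages use; default off.

    Returns ``(t_s, y)``.
    """
    ctrl = curve.control - curve.background
    if np.any(ctrl <= 0):
        bad = np.flatnonzero(ctrl <= 0)
        raise ValueError(f"control ROI dips below background at frames {bad.tolist()}")
    pre_ctrl = curve.prebleach_control - curve.prebleach_background
    if np.any(pre_ctrl <= 0):
        raise ValueError("pre-bleach control ROI at or below background")
    num = (curve.roi - curve.background) / ctrl
    pre = np.mean((curve.prebleach_roi - curve.prebleach_background) / pre_ctrl)
    if pre <= 0:
        raise ValueError("normalized pre-bleach intensity must be > 0")
    y = num / pre
    if anchor_postbleach:
        if y[0] >= 1:
            raise ValueError("cannot anchor: first post-bleach value is >= pre-bleach")
        y = (y - y[0]) / (1.0 - y[0])
    return curve.t_s.copy(), y


def fit_recovery(t, y, n_restarts: int = 5) -> FrapFit:
    """Nonlinear least-squares fit of y(t) = y0 + a (1 - e^{-bt}).

    Initialized from the data (y0 = first value, a = last - first, b from
    the time of half rise); up to ``n_restarts`` perturbed re-initializations
    before raising.  Near-flat traces fit but come back ``flagged`` because
    the amplitude and rate are then unidentifiable.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 10:
        raise ValueError("need at least 10 post-bleach points to fit")
    if not np.all(np.isfinite(y)):
        raise ValueError("trace contains non-finite values")

    y0_init = float(y[0])
    a_init = float(y[-1] - y[0])
    half = y0_init + 0.5 * a_init
    rise = np.flatnonzero(y >= half) if a_init > 0 else np.array([])
    t_half_rise = t[rise[0]] if len(rise) and t[rise[0]] > 0 else max(t[-1] / 4, t[1] - t[0])
    b_init = 1.0 / t_half_rise
    p0 = np.array([y0_init, max(a_init, 1e-6), max(b_init, 1e-6)])

    rng = np.random.default_rng(0)
    last_err = None
    for trial in range(n_restarts + 1):
        trial_p0 = p0 if trial == 0 else p0 * rng.lognormal(0.0, 0.3, size=3)
        try:
            popt, pcov = curve_fit(_recovery_model, t, y, p0=trial_p0,
                                   bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
                                   maxfev=10000)
            break
        except RuntimeError as err:  # pragma: no cover - rare
            last_err = err
    else:
        raise RuntimeError(f"recovery fit failed after {n_restarts} restarts "
                           f"(p0={p0.tolist()}): {last_err}")

    se = tuple(np.sqrt(np.maximum(np.diag(pcov), 0.0)))
    fit = FrapFit(y0=float(popt[0]), a=float(popt[1]), b=float(popt[2]),
                  se=se, cov=pcov)
    if fit.b * (t[-1] - t[0]) < 0.05 or abs(fit.a) < 1e-8 * max(1.0, abs(fit.y0)):
        fit.flagged, fit.flag_reason = True, "near-flat trace: rate and amplitude unidentifiable"
    elif np.isfinite(se[1]) and abs(fit.a) > 0 and se[1] > 10 * abs(fit.a):
        fit.flagged, fit.flag_reason = True, "amplitude uncertainty exceeds 10x its value"
    return fit


def half_life(fit: FrapFit | float) -> float:
    """t_1/2 = ln 0.5 / (-b) (equivalently ln 2 / b); requires b > 0."""
    b = fit.b if isinstance(fit, FrapFit) else float(fit)
    if b <= 0:
        raise ValueError("half-life requires b > 0")
    return np.log(0.5) / (-b)


def mobile_fraction(fit: FrapFit, f_i: float = 1.0) -> float:
    """Mobile fraction X_m = F_inf / F_i.

    F_inf is the fitted plateau (y0 + a); F_i is the normalized pre-bleach
    mean, which is 1 after :func:`correct_normalize`.  Values above 1 are
    physically suspect and emit a warning.
    """
    if f_i <= 0:
        raise ValueError("pre-bleach intensity F_i must be > 0")
    xm = fit.plateau / f_i
    if xm > 1.05:
        warnings.warn(f"mobile fraction {xm:.3f} exceeds 1; check normalization",
                      stacklevel=2)
    return xm


def analyze_curve(curve: RecoveryCurve, anchor_postbleach: bool = False) -> dict:
    """Full per-trace analysis: normalize, fit, half-life, mobile fraction."""
    t, y = correct_normalize(curve, anchor_postbleach=anchor_postbleach)
    fit = fit_recovery(t, y)
    out = {"y0": fit.y0, "a": fit.a, "b": fit.b,
           "se_y0": fit.se[0], "se_a": fit.se[1], "se_b": fit.se[2],
           "flagged": fit.flagged}
    out["t_half_s"] = half_life(fit) if fit.b > 0 else np.nan
    out["mobile_fraction"] = mobile_fraction(fit)
    return out


def analyze_curves(curves, **kwargs) -> pd.DataFrame:
    """One row of fit results per trace."""
    return pd.DataFrame([analyze_curve(c, **kwargs) for c in curves])
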