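"""Actin-wave boundary kinematics and speed-intensity coupling.

During frustrated phagocytosis macrophages form circular actin waves on the
ventral membrane.  This module measures, per integer angle theta = 0..359
around the wave centre:

* the boundary radius r(theta, t) (outermost ray crossing of the wave
  edge, subpixel by linear interpolation),
* the boundary speed v(theta, t) = (r_{t+1} - r_t) * pixel_size /
  frame_interval in um/min, positive for expansion and negative for
  contraction,
* the mean actin intensity in a band from the boundary to ``band_depth_px``
  pixels inward (default 30 px, ~4 um).

Per-cell intensities are normalized to 1 at null boundary speed (local
linear regression around v = 0) so cells with different expression levels
can be pooled, and the binned speed-intensity relation is tabulated as
mean +/- SD per speed bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .core import ImageStack

__all__ = [
    "WaveOutline",
    "subtract_background",
    "outline_wave",
    "boundary_speed",
    "band_intensity",
    "track_movie",
    "normalize_at_null_speed",
    "speed_intensity_relation",
]

N_ANGLES = 360
_THETA_RAD = np.deg2rad(np.arange(N_ANGLES))


@dataclass
class WaveOutline:
    """Per-frame wave boundary: radius (px) at each of 360 integer degrees.

    Missing angles (ray without a boundary crossing) are NaN.
    """

    frame_index: int
    center_px: tuple  # (x, y)
    r_px: np.ndarray
    source: str = "provided_mask"

    def __post_init__(self):
        self.r_px = np.asarray(self.r_px, dtype=float)
        if self.r_px.shape != (N_ANGLES,):
            raise ValueError(f"outline must have exactly {N_ANGLES} radial samples")
        if np.any(self.r_px[np.isfinite(self.r_px)] <= 0):
            raise ValueError("boundary radii must be > 0")

    @property
    def missing_fraction(self) -> float:
        return float(np.isnan(self.r_px).mean())


def subtract_background(stack: ImageStack, method: str = "rolling_percentile",
                        value: float | None = None, percentile: float = 10.0,
                        window_px: int = 64) -> ImageStack:
    """Subtract the signal background from every frame, clipping at zero.

    ``constant`` subtracts a fixed value; ``rolling_percentile`` estimates a
    smooth per-frame background surface from block-wise low percentiles
    (bilinearly re-expanded), which tracks slowly varying illumination.
    """
    data = np.asarray(stack.data, dtype=float)
    out = np.empty_like(data)
    if method == "constant":
        if value is None:
            raise ValueError("constant method requires a value")
        for t, frame in enumerate(data):
            if value > frame.max() and frame.max() > 0:
                import warnings
                warnings.warn(f"background constant {value} exceeds frame {t} maximum; "
                              "frame becomes all zero", stacklevel=2)
            out[t] = np.clip(frame - value, 0, None)
    elif method == "rolling_percentile":
        for t, frame in enumerate(data):
            h, w = frame.shape
            by, bx = max(1, h // window_px), max(1, w // window_px)
            blocks = np.array([
                [np.percentile(frame[j * h // by:(j + 1) * h // by,
                                     i * w // bx:(i + 1) * w // bx], percentile)
                 for i in range(bx)] for j in range(by)])
            bg = ndimage.zoom(blocks, (h / blocks.shape[0], w / blocks.shape[1]), order=1)
            out[t] = np.clip(frame - bg[:h, :w], 0, None)
    else:
        raise ValueError(f"unknown background method {method!r}")
    return ImageStack(out, stack.pixel_size_um, stack.frame_interval_s,
                      channel=stack.channel, meta=dict(stack.meta))


def _sample_rays(img: np.ndarray, center_px, radii: np.ndarray) -> np.ndarray:
    """Bilinear image samples at (360, n_radii) polar points."""
    cx, cy = center_px
    xs = cx + np.cos(_THETA_RAD)[:, None] * radii[None, :]
    ys = cy + np.sin(_THETA_RAD)[:, None] * radii[None, :]
    return ndimage.map_coordinates(img, [ys.ravel(), xs.ravel()], order=1,
                                   mode="constant", cval=0.0).reshape(N_ANGLES, len(radii))


def outline_wave(frame: np.ndarray, center_px, mask: np.ndarray | None = None,
                 threshold: float | None = None, step_px: float = 0.25,
                 max_missing_fraction: float = 0.25,
                 frame_index: int = 0) -> WaveOutline:
    """Radial outline of the wave boundary at 360 integer degrees.

    For each angle a ray is cast from the centre and the OUTERMOST
    crossing of the boundary (mask edge, or ``threshold`` on the intensity
    image) is recorded with subpixel precision.  Multiple crossings can
    occur for punctate waves; the outermost one is the expanding front.
    """
    if mask is not None:
        img = np.asarray(mask, dtype=float)
        thr, source = 0.5, "provided_mask"
    else:
        if threshold is None:
            raise ValueError("provide either a mask or an intensity threshold")
        img = np.asarray(frame, dtype=float)
        thr, source = float(threshold), "threshold_segmentation"
    cx, cy = center_px
    h, w = img.shape
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError("center lies outside the image")
    centre_val = ndimage.map_coordinates(img, [[cy], [cx]], order=1)[0]
    if mask is not None and centre_val < thr:
        raise ValueError("center lies outside the provided mask")

    r_max = min(cx, cy, w - 1 - cx, h - 1 - cy)
    radii = np.arange(step_px, r_max, step_px)
    vals = _sample_rays(img, center_px, radii)
    above = vals >= thr
    r = np.full(N_ANGLES, np.nan)
    # outermost downward crossing: last sample index i with above[i] (and a
    # sample after it, guaranteed below threshold at the frame border)
    for a in range(N_ANGLES):
        idx = np.flatnonzero(above[a])
        if len(idx) == 0:
            continue
        i = idx[-1]
        if i == len(radii) - 1:
            r[a] = radii[i]  # boundary clipped at the sampling range
            continue
        v0, v1 = vals[a, i], vals[a, i + 1]
        frac = (v0 - thr) / (v0 - v1) if v0 != v1 else 0.0
        r[a] = radii[i] + frac * step_px
    outline = WaveOutline(frame_index=frame_index, center_px=(float(cx), float(cy)),
                          r_px=r, source=source)
    if outline.missing_fraction > max_missing_fraction:
        raise ValueError(f"{outline.missing_fraction:.0%} of rays found no boundary "
                         "crossing; not a closed wave")
    return outline


def boundary_speed(first: WaveOutline, second: WaveOutline,
                   frame_interval_s: float, pixel_size_um: float) -> np.ndarray:
    """Signed boundary speed v(theta) in um/min between consecutive frames.

    Positive where the wave boundary expands, negative where it contracts.
    Missing radii propagate as NaN.
    """
    if not np.allclose(first.center_px, second.center_px, atol=1e-6):
        raise ValueError("outlines have different centres; speeds are undefined")
    return (second.r_px - first.r_px) * pixel_size_um * 60.0 / frame_interval_s


def band_intensity(frame: np.ndarray, outline: WaveOutline, depth_px: int = 30,
                   step_px: float = 0.5):
    """Mean intensity from the boundary to ``depth_px`` pixels inward.

    Samples each ray from r(theta) down to max(r - depth, 1) px with
    bilinear interpolation.  ``depth_px = 0`` returns the boundary pixel
    value itself.  Returns ``(intensity, truncated)`` where ``truncated``
    flags angles whose band hit the 1 px inner limit.
    """
    img = np.asarray(frame, dtype=float)
    intens = np.full(N_ANGLES, np.nan)
    truncated = np.zeros(N_ANGLES, dtype=bool)
    cx, cy = outline.center_px
    for a in range(N_ANGLES):
        r = outline.r_px[a]
        if not np.isfinite(r):
            continue
        inner = max(r - depth_px, 1.0)
        truncated[a] = (r - depth_px) < 1.0 and depth_px > 0
        rs = np.arange(inner, r + step_px / 2, step_px) if r > inner else np.array([r])
        xs = cx + np.cos(_THETA_RAD[a]) * rs
        ys = cy + np.sin(_THETA_RAD[a]) * rs
        intens[a] = ndimage.map_coordinates(img, [ys, xs], order=1).mean()
    return intens, truncated


def _threshold_center(frame: np.ndarray, threshold: float):
    """Centroid of the largest connected above-threshold component."""
    lab = measure.label(np.asarray(frame) >= threshold)
    if lab.max() == 0:
        raise ValueError("no above-threshold region to centre on")
    sizes = np.bincount(lab.ravel())[1:]
    biggest = int(np.argmax(sizes)) + 1
    cy, cx = ndimage.center_of_mass(lab == biggest)
    return float(cx), float(cy)


def track_movie(stack: ImageStack, masks: np.ndarray | None = None,
                threshold: float | None = None, center_px=None,
                fixed_center: bool = True, band_depth_px: int = 30,
                cell: str = "cell0") -> pd.DataFrame:
    """Track one wave across a movie into a tidy per-(angle, frame) table.

    Columns: cell, frame, theta_deg, r_px, r_um, v_um_min, i_raw, truncated,
    source.  Speeds pair frame t with t+1 (NaN on the last frame).  The
    centre is the centroid of the first frame's wave, held fixed (the
    manual-outline convention identifies the centre once); ``fixed_center=False``
    re-centres every frame, in which case radii are relative to the moving
    centre and speeds are radius differences between frames.
    """
    data = np.asarray(stack.data, dtype=float)
    if center_px is None:
        if masks is not None:
            cy, cx = ndimage.center_of_mass(np.asarray(masks[0]) > 0)
            center_px = (float(cx), float(cy))
        else:
            center_px = _threshold_center(data[0], threshold)

    outlines = []
    for t in range(stack.n_frames):
        c = center_px
        if not fixed_center and t > 0:
            c = (ndimage.center_of_mass(np.asarray(masks[t]) > 0)[::-1]
                 if masks is not None else _threshold_center(data[t], threshold))
            c = (float(c[0]), float(c[1]))
        outlines.append(outline_wave(data[t], c,
                                     mask=None if masks is None else masks[t],
                                     threshold=threshold, frame_index=t))

    px, dt = stack.pixel_size_um, stack.frame_interval_s
    frames = []
    for t, o in enumerate(outlines):
        if t < len(outlines) - 1:
            if fixed_center:
                v = boundary_speed(o, outlines[t + 1], dt, px)
            else:
                v = (outlines[t + 1].r_px - o.r_px) * px * 60.0 / dt
        else:
            v = np.full(N_ANGLES, np.nan)
        i_raw, trunc = band_intensity(data[t], o, depth_px=band_depth_px)
        frames.append(pd.DataFrame({
            "cell": cell, "frame": t, "theta_deg": np.arange(N_ANGLES),
            "r_px": o.r_px, "r_um": o.r_px * px, "v_um_min": v,
            "i_raw": i_raw, "truncated": trunc, "source": o.source,
        }))
    return pd.concat(frames, ignore_index=True)


def normalize_at_null_speed(df: pd.DataFrame, bandwidth: float | None = None,
                            min_samples: int = 10) -> pd.DataFrame:
    """Per-cell normalization of intensity to 1 at null boundary speed.

    For each cell the intercept I(0) of a local linear regression of i_raw
    on v inside |v| < bandwidth (default: 10 % of that cell's speed range)
    rescales the cell's intensities, making cells with different expression
    levels comparable.  Requires samples on both sides of v = 0.
    """
    df = df.copy()
    df["i_norm"] = np.nan
    for cell, grp in df.groupby("cell"):
        ok = np.isfinite(grp["v_um_min"]) & np.isfinite(grp["i_raw"])
        v = grp.loc[ok, "v_um_min"].to_numpy()
        i = grp.loc[ok, "i_raw"].to_numpy()
        if len(v) == 0 or v.min() >= 0 or v.max() <= 0:
            raise ValueError(f"cell {cell!r}: speed samples do not span v = 0; "
                             "cannot anchor the normalization")
        bw = bandwidth if bandwidth is not None else 0.1 * (v.max() - v.min())
        sel = np.abs(v) < bw
        if sel.sum() < min_samples:
            raise ValueError(f"cell {cell!r}: only {int(sel.sum())} samples within "
                             f"|v| < {bw:.3g} um/min; cannot estimate I(0)")
        slope, intercept = np.polyfit(v[sel], i[sel], 1)
        if intercept <= 0:
            raise ValueError(f"cell {cell!r}: non-positive intensity at null speed")
        df.loc[grp.index, "i_norm"] = grp["i_raw"] / intercept
    return df


def speed_intensity_relation(df: pd.DataFrame, bin_width: float = 0.5,
                             n_min: int = 5, value: str = "i_norm") -> pd.DataFrame:
    """Bin (v, I) samples by speed: per-bin mean, SD and n.

    Bins with fewer than ``n_min`` samples are dropped.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    ok = np.isfinite(df["v_um_min"]) & np.isfinite(df[value])
    if ok.sum() == 0:
        raise ValueError("no retained (speed, intensity) samples")
    v = df.loc[ok, "v_um_min"].to_numpy()
    i = df.loc[ok, value].to_numpy()
    centres = np.round(v / bin_width) * bin_width
    out = (pd.DataFrame({"speed_bin_center": centres, "i": i})
           .groupby("speed_bin_center")["i"]
           .agg(mean_intensity="mean", sd_intensity="std", n="count")
           .reset_index())
    out["sd_intensity"] = out["sd_intensity"].fillna(0.0)
    return out[out["n"] >= n_min].reset_index(drop=True)
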