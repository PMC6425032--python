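"""Adhesion and phagocytic-cup morphometry plus group statistics.

Covers: blob detection of punctate FcR-actin adhesions, averaging of
4 x 4 um windows centred on adhesions across two channels (the assay that
reveals membrane lifting as an annular dip around adhesions), 3-D adhesion
footprint area and height from thresholded volumes, per-voxel cup
intensities, phagocytosis scoring (percentage of cells internalizing or
binding at least one bead, aggregated field-of-view -> experiment ->
genotype), and the two-group / multi-group comparisons used throughout
(unpaired t-test, Welch variant when the SDs differ markedly, one-way
ANOVA with Tukey's post-hoc test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage import feature, measure
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .core import ImageStack

__all__ = [
    "AveragedAdhesionMap",
    "CupMeasurement",
    "GroupComparison",
    "detect_adhesions",
    "average_adhesion_windows",
    "measure_adhesions_3d",
    "measure_cup",
    "score_phagocytosis",
    "compare_groups",
]


@dataclass
class AveragedAdhesionMap:
    """Mean adhesion-centred windows per channel with radial profiles."""

    actin: np.ndarray
    membrane: np.ndarray
    n_adhesions: int
    pixel_size_um: float
    radial_r_um: np.ndarray
    actin_profile: np.ndarray
    membrane_profile: np.ndarray


@dataclass
class CupMeasurement:
    mean_intensity: float
    integrated_intensity: float
    n_voxels: int


@dataclass
class GroupComparison:
    test: str
    statistic: float
    p_value: float
    significant: bool
    alpha: float = 0.05
    posthoc: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# Adhesion detection and window averaging
# ---------------------------------------------------------------------------

def detect_adhesions(frame: np.ndarray, pixel_size_um: float,
                     min_sigma_um: float = 0.1, max_sigma_um: float = 0.6,
                     threshold: float = 0.1, window_um: float = 4.0) -> pd.DataFrame:
    """Scale-space (Laplacian-of-Gaussian) blob detection of adhesions.

    Returns centroids in micrometres.  Detections whose ``window_um`` square
    would leave the image are excluded so every centroid can be averaged.
    """
    img = np.asarray(frame, dtype=float)
    if img.size == 0 or img.max() <= 0:
        return pd.DataFrame(columns=["x_um", "y_um", "sigma_um"])
    blobs = feature.blob_log(img / img.max(),
                             min_sigma=min_sigma_um / pixel_size_um,
                             max_sigma=max_sigma_um / pixel_size_um,
                             threshold=threshold)
    if len(blobs) == 0:
        return pd.DataFrame(columns=["x_um", "y_um", "sigma_um"])
    half = window_um / 2 / pixel_size_um
    h, w = img.shape
    rows = []
    for cy, cx, sigma in blobs:
        if half <= cx <= w - 1 - half and half <= cy <= h - 1 - half:
            rows.append((cx * pixel_size_um, cy * pixel_size_um, sigma * pixel_size_um))
    return pd.DataFrame(rows, columns=["x_um", "y_um", "sigma_um"])


def _extract_window(img: np.ndarray, cx_px: float, cy_px: float, half_px: float,
                    n_px: int) -> np.ndarray | None:
    """Subpixel-centred square window by bilinear interpolation."""
    h, w = img.shape
    if not (half_px <= cx_px <= w - 1 - half_px and half_px <= cy_px <= h - 1 - half_px):
        return None
    grid = np.linspace(-half_px, half_px, n_px)
    ys, xs = np.meshgrid(cy_px + grid, cx_px + grid, indexing="ij")
    return ndimage.map_coordinates(img, [ys.ravel(), xs.ravel()], order=1).reshape(n_px, n_px)


def average_adhesion_windows(actin, membrane, centroids: pd.DataFrame,
                             pixel_size_um: float, window_um: float = 4.0,
                             normalize_per_window: bool = False) -> AveragedAdhesionMap:
    """Average ``window_um`` squares centred on each adhesion, per channel.

    ``actin``/``membrane`` are single frames (2-D) or stacks indexed by a
    ``frame`` column in ``centroids``.  Windows are extracted with subpixel
    shifts (bilinear interpolation); windows that would leave the image are
    skipped with a warning.  ``normalize_per_window`` divides each window
    by its own mean before averaging (per-adhesion normalization mode).
    The radial mean profile of each averaged channel is included.
    """
    actin = np.asarray(actin, dtype=float)
    membrane = np.asarray(membrane, dtype=float)
    if len(centroids) < 1:
        raise ValueError("need at least one adhesion centroid")
    n_px = int(round(window_um / pixel_size_um)) | 1  # odd size
    half_px = (n_px - 1) / 2
    acc = {"actin": [], "membrane": []}
    skipped = 0
    for _, row in centroids.iterrows():
        cx, cy = row["x_um"] / pixel_size_um, row["y_um"] / pixel_size_um
        t = int(row["frame"]) if "frame" in row else 0
        wins = {}
        for name, chan in (("actin", actin), ("membrane", membrane)):
            img = chan if chan.ndim == 2 else chan[t]
            wins[name] = _extract_window(img, cx, cy, half_px, n_px)
        if any(w is None for w in wins.values()):
            skipped += 1
            continue
        for name, win in wins.items():
            if normalize_per_window and win.mean() > 0:
                win = win / win.mean()
            acc[name].append(win)
    if not acc["actin"]:
        raise ValueError("all adhesion windows fell outside the image")
    if skipped:
        warnings.warn(f"skipped {skipped} adhesion(s) whose window left the image",
                      stacklevel=2)
    mean_actin = np.mean(acc["actin"], axis=0)
    mean_membrane = np.mean(acc["membrane"], axis=0)

    grid = (np.arange(n_px) - half_px) * pixel_size_um
    rr = np.hypot(grid[:, None], grid[None, :])
    nbins = n_px // 2
    edges = np.linspace(0, rr.max() * (nbins / (nbins + 0.5)), nbins + 1)
    which = np.clip(np.digitize(rr.ravel(), edges) - 1, 0, nbins - 1)
    prof = lambda m: np.bincount(which, m.ravel(), minlength=nbins) / np.bincount(which, minlength=nbins)
    return AveragedAdhesionMap(
        actin=mean_actin, membrane=mean_membrane, n_adhesions=len(acc["actin"]),
        pixel_size_um=pixel_size_um,
        radial_r_um=0.5 * (edges[:-1] + edges[1:]),
        actin_profile=prof(mean_actin), membrane_profile=prof(mean_membrane))


# ---------------------------------------------------------------------------
# 3-D adhesion and cup measurements
# ---------------------------------------------------------------------------

def measure_adhesions_3d(volume: ImageStack, threshold: float) -> pd.DataFrame:
    """Footprint area (xy projection, um^2) and height (z extent, um) of
    each 3-D connected component above ``threshold``.

    Emulates the 3D-SIM per-adhesion area/height measurement; requires the
    volume's lateral pixel size and z step to be calibrated.
    """
    if volume.z_step_um is None or volume.z_step_um <= 0:
        raise ValueError("volume needs a calibrated z step")
    vol = np.asarray(volume.data, dtype=float)
    lab = measure.label(vol > threshold)
    px, dz = volume.pixel_size_um, volume.z_step_um
    rows = []
    for region in measure.regionprops(lab, intensity_image=vol):
        zs, ys, xs = region.coords.T
        footprint = len({(y, x) for y, x in zip(ys, xs)})
        rows.append({
            "label": region.label,
            "area_um2": footprint * px * px,
            "height_um": (zs.max() - zs.min() + 1) * dz,
            "mean_intensity": region.intensity_mean,
            "x_um": region.centroid[2] * px,
            "y_um": region.centroid[1] * px,
            "z_um": region.centroid[0] * dz,
        })
    return pd.DataFrame(rows, columns=["label", "area_um2", "height_um",
                                       "mean_intensity", "x_um", "y_um", "z_um"])


def measure_cup(volume, roi_mask) -> CupMeasurement:
    """Mean per-voxel and integrated intensity over a cup-enclosing ROI."""
    vol = np.asarray(volume.data if isinstance(volume, ImageStack) else volume, dtype=float)
    mask = np.asarray(roi_mask, dtype=bool)
    if mask.shape != vol.shape:
        raise ValueError("ROI mask shape does not match the volume")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("ROI mask is empty")
    total = float(vol[mask].sum())
    return CupMeasurement(mean_intensity=total / n, integrated_intensity=total,
                          n_voxels=n)


# ---------------------------------------------------------------------------
# Phagocytosis scoring and group statistics
# ---------------------------------------------------------------------------

def score_phagocytosis(table: pd.DataFrame, value: str = "n_internalized",
                       group_cols=("genotype", "time_min"),
                       experiment_col: str = "experiment",
                       error: str = "sem") -> pd.DataFrame:
    """Percentage of cells positive for ``value`` per genotype x time.

    Per field of view the percentage value/n_cells is computed (FOVs with
    zero cells are dropped with a warning); FOV percentages are averaged
    within each experiment and the mean +/- SEM (or SD) is taken across
    experiments, matching the FOV -> experiment -> genotype hierarchy.
    """
    df = table.copy()
    if {"n_internalized", "n_associated"} <= set(df.columns):
        if (df["n_internalized"] > df["n_associated"]).any() or \
                (df["n_associated"] > df["n_cells"]).any():
            raise ValueError("counts violate internalized <= associated <= cells")
    empty = df["n_cells"] <= 0
    if empty.any():
        warnings.warn(f"dropping {int(empty.sum())} FOV(s) with zero cells", stacklevel=2)
        df = df[~empty]
    df["pct"] = 100.0 * df[value] / df["n_cells"]
    group_cols = list(group_cols)
    if experiment_col in df.columns:
        per_exp = df.groupby(group_cols + [experiment_col])["pct"].mean().reset_index()
    else:
        per_exp = df.rename(columns={}).assign(**{experiment_col: np.arange(len(df))})[
            group_cols + [experiment_col, "pct"]]
    agg = per_exp.groupby(group_cols)["pct"].agg(["mean", "std", "count"]).reset_index()
    agg = agg.rename(columns={"mean": "pct_mean", "std": "pct_sd", "count": "n_experiments"})
    agg["pct_sd"] = agg["pct_sd"].fillna(0.0)
    agg["pct_sem"] = agg["pct_sd"] / np.sqrt(agg["n_experiments"])
    agg["error"] = agg["pct_sem"] if error == "sem" else agg["pct_sd"]
    return agg


def compare_groups(*groups, alpha: float = 0.05,
                   welch_sd_ratio: float = 2.0) -> GroupComparison:
    """Two-group t-test or one-way ANOVA with Tukey's post-hoc test.

    Two groups: pooled-variance unpaired two-tailed t-test, switching to
    Welch's t-test when the sample SDs differ by more than
    ``welch_sd_ratio``-fold ("differed markedly").  More than two groups:
    one-way ANOVA followed by Tukey HSD.  Significance at p < ``alpha``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for i, g in enumerate(groups):
        if len(g) < 2:
            raise ValueError(f"group {i} has fewer than 2 observations")
    if len(groups) == 2:
        a, b = groups
        sa, sb = a.std(ddof=1), b.std(ddof=1)
        if sa == 0 and sb == 0:
            stat, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
            test = "t-test (degenerate: zero variance)"
        else:
            lo, hi = sorted([sa, sb])
            welch = lo == 0 or hi / max(lo, 1e-300) > welch_sd_ratio
            stat, p = stats.ttest_ind(a, b, equal_var=not welch)
            test = "Welch t-test" if welch else "unpaired t-test"
        return GroupComparison(test=test, statistic=float(stat), p_value=float(p),
                               significant=p < alpha, alpha=alpha)
    stat, p = stats.f_oneway(*groups)
    values = np.concatenate(groups)
    labels = np.concatenate([[f"group{i}"] * len(g) for i, g in enumerate(groups)])
    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    posthoc = pd.DataFrame(tukey.summary().data[1:], columns=tukey.summary().data[0])
    return GroupComparison(test="one-way ANOVA + Tukey HSD", statistic=float(stat),
                           p_value=float(p), significant=p < alpha, alpha=alpha,
                           posthoc=posthoc)
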