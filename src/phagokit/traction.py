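"""Traction force microscopy on linearly elastic substrates.

Pipeline: rigid registration of bead images (phase correlation on a
cell-free region), PIV displacement estimation (normalized cross-correlation
with 3-point Gaussian subpixel peaks), universal-outlier filtering plus
ordinary-Kriging interpolation, regularized Fourier Transform Traction
Cytometry (FTTC) on the Boussinesq half-space operator, L-curve selection of
the Tikhonov parameter, and strain energy U = 1/2 * integral(T . u) dA.

Conventions
-----------
* Displacements in micrometres, tractions in pascals, grid spacing in
  micrometres.  Strain energy is returned in joules.
* The substrate is an elastic half-space with shear modulus G and Poisson
  ratio nu; Young's modulus E = 2 G (1 + nu).
* The zero-frequency traction component is set to zero (net-force-free
  gauge), so reconstructed fields are balanced by construction.
* The Tikhonov parameter ``lam`` carries the units of the Green's operator
  (um/Pa); it is the lambda of ``min ||G T - u||^2 + lam^2 ||T||^2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import curve_fit
from scipy.signal import fftconvolve
from scipy.spatial import cKDTree
from skimage.registration import phase_cross_correlation

from .core import ImageStack

__all__ = [
    "ElasticSubstrate",
    "DisplacementField",
    "TractionField",
    "StrainEnergyResult",
    "register_series",
    "piv_displacement",
    "filter_and_krige",
    "forward_displacement",
    "fttc",
    "choose_lambda",
    "strain_energy",
]


@dataclass(frozen=True)
class ElasticSubstrate:
    """Linearly elastic half-space substrate (polyacrylamide gel).

    The study gels have shear modulus 1.5 kPa; nu defaults to 0.5
    (incompressible), giving E = 2 G (1 + nu) = 3 G.
    """

    shear_modulus_pa: float = 1500.0
    poisson_ratio: float = 0.5

    def __post_init__(self):
        if self.shear_modulus_pa <= 0:
            raise ValueError("shear_modulus_pa must be > 0 (singular forward model)")
        if not 0 <= self.poisson_ratio <= 0.5 + 1e-9:
            raise ValueError("poisson_ratio must be in [0, 0.5]")

    @property
    def young_modulus_pa(self) -> float:
        return 2.0 * self.shear_modulus_pa * (1.0 + self.poisson_ratio)


@dataclass
class DisplacementField:
    """Substrate displacement vectors on a regular grid.

    ``u_um[j, i]`` is the (ux, uy) displacement in micrometres at grid node
    ``(y_um[j], x_um[i])``; invalid nodes (failed PIV quality check or
    detected outliers) are flagged False in ``valid``.
    """

    x_um: np.ndarray
    y_um: np.ndarray
    u_um: np.ndarray  # (ny, nx, 2)
    spacing_um: float
    valid: np.ndarray = None
    peak_ratio: np.ndarray = None
    frame_index: int = 0

    def __post_init__(self):
        self.u_um = np.asarray(self.u_um, dtype=float)
        if self.spacing_um <= 0:
            raise ValueError("spacing_um must be > 0")
        if self.valid is None:
            self.valid = np.ones(self.u_um.shape[:2], dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def shape(self):
        return self.u_um.shape[:2]


@dataclass
class TractionField:
    """Traction stress vectors (Pa) on the same grid as the displacements."""

    x_um: np.ndarray
    y_um: np.ndarray
    t_pa: np.ndarray  # (ny, nx, 2)
    spacing_um: float
    regularization_lambda: float = 0.0

    @property
    def shape(self):
        return self.t_pa.shape[:2]


@dataclass
class StrainEnergyResult:
    """Strain energy stored in the substrate by one cell at one time point."""

    u_joules: float
    cell_area_um2: float | None = None

    @property
    def u_per_area(self) -> float | None:
        if self.cell_area_um2 is None or self.cell_area_um2 <= 0:
            return None
        return self.u_joules / self.cell_area_um2


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------

def register_series(stack: ImageStack, reference_roi, upsample_factor: int = 100,
                    min_variance: float = 1e-10):
    """Register a bead time series rigidly to its first frame.

    Drift is estimated by phase correlation restricted to ``reference_roi``
    (a ``(slice_y, slice_x)`` pair over a region devoid of cells) and the
    full frames are translated by the recovered shift (Fourier shift, so
    subpixel drifts are applied exactly up to interpolation).

    Returns ``(aligned_stack, drift)`` where ``drift`` is a DataFrame with
    columns ``frame, dy_px, dx_px`` (shift of each frame relative to frame 0).
    """
    sy, sx = reference_roi
    ref = np.asarray(stack.data[0][sy, sx], dtype=float)
    if np.var(ref) <= min_variance:
        raise ValueError("reference ROI is featureless (variance below threshold); "
                         "registration needs bead texture")
    hann = np.outer(np.hanning(ref.shape[0]), np.hanning(ref.shape[1]))
    wref = (ref - ref.mean()) * hann
    aligned = np.empty_like(np.asarray(stack.data, dtype=float))
    aligned[0] = stack.data[0]
    rows = [(0, 0.0, 0.0)]
    for t in range(1, stack.n_frames):
        frame = np.asarray(stack.data[t], dtype=float)
        # coarse integer shift (exact for integer drifts), then subpixel
        # refinement on the integer-aligned frame; the Hann window
        # suppresses ROI edge effects in the phase correlation
        mov = frame[sy, sx]
        coarse, _, _ = phase_cross_correlation(wref, (mov - mov.mean()) * hann,
                                               upsample_factor=1)
        coarse = np.round(coarse).astype(int)
        rolled = np.roll(frame, tuple(coarse), axis=(0, 1))
        mov2 = rolled[sy, sx]
        fine, _, _ = phase_cross_correlation(wref, (mov2 - mov2.mean()) * hann,
                                             upsample_factor=upsample_factor)
        shift = coarse + fine
        f = np.fft.fft2(frame)
        aligned[t] = np.real(np.fft.ifft2(ndimage.fourier_shift(f, shift)))
        rows.append((t, -float(shift[0]), -float(shift[1])))
    drift = pd.DataFrame(rows, columns=["frame", "dy_px", "dx_px"])
    out = ImageStack(aligned, stack.pixel_size_um, stack.frame_interval_s,
                     channel=stack.channel, meta=dict(stack.meta))
    return out, drift


# ---------------------------------------------------------------------------
# PIV
# ---------------------------------------------------------------------------

def _subpixel_peak(c: np.ndarray, py: int, px: int):
    """3-point Gaussian (fallback: parabolic) subpixel peak refinement."""
    def refine(cm, c0, cp):
        if cm > 0 and c0 > 0 and cp > 0 and c0 >= cm and c0 >= cp:
            lm, l0, lp = np.log([cm, c0, cp])
            den = lm - 2 * l0 + lp
            if den < 0:
                return 0.5 * (lm - lp) / den
        den = cm - 2 * c0 + cp
        if den < 0:
            return np.clip(0.5 * (cm - cp) / den, -1, 1)
        return 0.0

    dy = refine(c[py - 1, px], c[py, px], c[py + 1, px]) if 0 < py < c.shape[0] - 1 else 0.0
    dx = refine(c[py, px - 1], c[py, px], c[py, px + 1]) if 0 < px < c.shape[1] - 1 else 0.0
    return dy, dx


def piv_displacement(image, reference, pixel_size_um: float,
                     window_um: float = 3.46, spacing_um: float = 1.73,
                     max_shift_px: int | None = None,
                     min_peak_ratio: float = 1.2,
                     smooth_sigma_px: float = 0.75) -> DisplacementField:
    """PIV displacement of ``image`` relative to ``reference``.

    Interrogation windows of ``window_um`` (study value 3.46 um) are placed
    with a centre-to-centre distance of ``spacing_um`` (1.73 um, i.e. 50 %
    overlap).  Each window is mean-subtracted and cross-correlated against
    the reference window; the correlation peak is refined with a 3-point
    Gaussian fit.  The ratio of the primary to the secondary correlation
    peak is stored and windows below ``min_peak_ratio`` are masked invalid.
    """
    image = np.asarray(image, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if image.shape != reference.shape:
        raise ValueError("image and reference must have the same shape")
    win = int(round(window_um / pixel_size_um))
    win += win % 2  # even window
    step = max(1, int(round(spacing_um / pixel_size_um)))
    h, w = image.shape
    if win > min(h, w):
        raise ValueError(f"PIV window ({win} px) larger than image {image.shape}")
    if max_shift_px is None:
        max_shift_px = win // 3

    ys = np.arange(win // 2, h - win // 2 + 1, step)
    xs = np.arange(win // 2, w - win // 2 + 1, step)
    u = np.zeros((len(ys), len(xs), 2))
    ratio = np.ones((len(ys), len(xs)))
    valid = np.zeros((len(ys), len(xs)), dtype=bool)

    half = win // 2
    for j, yc in enumerate(ys):
        for i, xc in enumerate(xs):
            a = reference[yc - half:yc + half, xc - half:xc + half]
            b = image[yc - half:yc + half, xc - half:xc + half]
            a = a - a.mean()
            b = b - b.mean()
            na, nb = np.sqrt((a ** 2).sum()), np.sqrt((b ** 2).sum())
            if na == 0 or nb == 0:
                continue
            c = fftconvolve(b, a[::-1, ::-1], mode="full") / (na * nb)
            centre = win - 1
            lo, hi = centre - max_shift_px, centre + max_shift_px + 1
            cs = c[lo:hi, lo:hi]
            # correct the triangular overlap envelope of equal-window
            # correlation, which otherwise biases peaks toward zero lag
            lags = np.arange(-max_shift_px, max_shift_px + 1)
            overlap = np.outer(win - np.abs(lags), win - np.abs(lags)) / win ** 2
            cs = cs / overlap
            if smooth_sigma_px > 0:
                # a Gaussian blur keeps the (Gaussian) particle peak shape
                # but damps the random cross-term background that limits
                # subpixel accuracy
                cs = ndimage.gaussian_filter(cs, smooth_sigma_px)
            py, px = np.unravel_index(np.argmax(cs), cs.shape)
            peak = cs[py, px]
            # secondary peak outside a 3x3 exclusion zone around the primary
            masked = cs.copy()
            masked[max(0, py - 1):py + 2, max(0, px - 1):px + 2] = -np.inf
            second = masked.max()
            ratio[j, i] = peak / second if second > 0 else np.inf
            fy, fx = _subpixel_peak(cs, py, px) if 0 < py < cs.shape[0] - 1 and 0 < px < cs.shape[1] - 1 else (0.0, 0.0)
            dy = (py - max_shift_px) + fy
            dx = (px - max_shift_px) + fx
            u[j, i] = (dx * pixel_size_um, dy * pixel_size_um)
            valid[j, i] = np.isfinite(ratio[j, i]) and ratio[j, i] >= min_peak_ratio

    u[~valid] = 0.0
    return DisplacementField(x_um=xs * pixel_size_um, y_um=ys * pixel_size_um,
                             u_um=u, spacing_um=step * pixel_size_um,
                             valid=valid, peak_ratio=ratio)


# ---------------------------------------------------------------------------
# Outlier filtering + ordinary Kriging
# ---------------------------------------------------------------------------

def _normalized_median_outliers(u: np.ndarray, valid: np.ndarray,
                                threshold: float, eps_um: float) -> np.ndarray:
    """Universal (normalized-median) outlier test on a vector field.

    For each node the residual of each component against the median of its
    3x3 neighbourhood, normalized by the median absolute neighbour residual
    plus ``eps_um``, is compared with ``threshold``.
    """
    ny, nx = valid.shape
    out = np.zeros_like(valid)
    uu = np.where(valid[..., None], u, np.nan)
    for j in range(ny):
        for i in range(nx):
            if not valid[j, i]:
                continue
            neigh = uu[max(0, j - 1):j + 2, max(0, i - 1):i + 2].reshape(-1, 2)
            r = np.zeros(2)
            for c in range(2):
                vals = neigh[:, c]
                vals = vals[np.isfinite(vals)]
                if len(vals) < 3:
                    continue
                # exclude the centre value once
                med = np.median(np.delete(vals, np.argmin(np.abs(vals - u[j, i, c]))))
                resid = np.abs(vals - med)
                rm = np.median(resid)
                r[c] = np.abs(u[j, i, c] - med) / (rm + eps_um)
            if r.max() > threshold:
                out[j, i] = True
    return out


def _spherical(h, nugget, sill, rng):
    hr = np.minimum(h / np.maximum(rng, 1e-12), 1.0)
    return nugget + sill * (1.5 * hr - 0.5 * hr ** 3)


def _fit_variogram(coords: np.ndarray, values: np.ndarray, n_bins: int = 12,
                   rng_seed: int = 0):
    """Fit an isotropic spherical variogram by weighted least squares."""
    rng = np.random.default_rng(rng_seed)
    n = len(coords)
    idx = rng.choice(n, size=min(n, 600), replace=False)
    c, v = coords[idx], values[idx]
    d = np.sqrt(((c[:, None] - c[None]) ** 2).sum(-1))
    g = 0.5 * (v[:, None] - v[None]) ** 2
    iu = np.triu_indices(len(c), k=1)
    d, g = d[iu], g[iu]
    dmax = d.max() / 2
    bins = np.linspace(0, dmax, n_bins + 1)
    which = np.digitize(d, bins) - 1
    lags, gamma, counts = [], [], []
    for b in range(n_bins):
        m = which == b
        if m.sum() > 2:
            lags.append(d[m].mean())
            gamma.append(g[m].mean())
            counts.append(m.sum())
    lags, gamma, counts = map(np.asarray, (lags, gamma, counts))
    if len(lags) < 4 or gamma.max() <= 0:
        return (0.0, max(float(np.var(values)), 1e-12), max(dmax, 1e-6))
    p0 = (0.0, float(gamma.max()), float(lags.max()))
    try:
        popt, _ = curve_fit(_spherical, lags, gamma, p0=p0,
                            sigma=1.0 / np.sqrt(counts), maxfev=5000,
                            bounds=([0, 1e-15, 1e-9], [np.inf, np.inf, np.inf]))
        return tuple(float(x) for x in popt)
    except RuntimeError:
        return p0


def _krige_points(coords_known, values, coords_query, variogram, n_neighbors=16):
    """Ordinary Kriging prediction at query points (weights sum to one)."""
    tree = cKDTree(coords_known)
    k = min(n_neighbors, len(coords_known))
    pred = np.empty(len(coords_query))
    _, nn = tree.query(coords_query, k=k)
    nn = np.atleast_2d(nn)
    for q, idx in enumerate(nn):
        pts = coords_known[idx]
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        gam = _spherical(d, *variogram)
        a = np.empty((k + 1, k + 1))
        a[:k, :k] = gam + np.eye(k) * 1e-10
        a[k, :k] = a[:k, k] = 1.0
        a[k, k] = 0.0
        dq = np.sqrt(((pts - coords_query[q]) ** 2).sum(-1))
        b = np.empty(k + 1)
        b[:k] = _spherical(dq, *variogram)
        b[k] = 1.0
        try:
            w = np.linalg.solve(a, b)[:k]
        except np.linalg.LinAlgError:
            w = np.full(k, 1.0 / k)
        pred[q] = w @ values[idx]
    return pred


def filter_and_krige(field: DisplacementField, residual_threshold: float = 2.0,
                     eps_um: float = 0.02, n_neighbors: int = 16) -> DisplacementField:
    """Remove PIV outliers and fill all invalid nodes by ordinary Kriging.

    Outliers are flagged by the normalized-median test (threshold 2.0 by
    default); flagged and previously masked nodes are re-estimated by
    ordinary Kriging with a spherical variogram fitted to the valid vectors.
    Returns a complete (all-valid) field on the same grid.
    """
    valid = field.valid.copy()
    if valid.mean() < 0.5:
        raise ValueError(f"only {valid.mean():.0%} of displacement nodes are valid (< 50%)")
    outliers = _normalized_median_outliers(field.u_um, valid, residual_threshold, eps_um)
    valid &= ~outliers
    if valid.mean() < 0.5:
        raise ValueError("fewer than 50% of nodes remain valid after outlier removal")

    u = field.u_um.copy()
    ny, nx = valid.shape
    gy, gx = np.mgrid[0:ny, 0:nx]
    coords = np.column_stack([gx.ravel() * field.spacing_um, gy.ravel() * field.spacing_um])
    known = valid.ravel()
    missing = ~known
    if missing.any():
        for c in range(2):
            vals = u[..., c].ravel()[known]
            if np.ptp(vals) < 1e-12:
                u[..., c] = np.where(valid, u[..., c], vals.mean())
                continue
            vg = _fit_variogram(coords[known], vals)
            filled = _krige_points(coords[known], vals, coords[missing], vg, n_neighbors)
            comp = u[..., c].ravel()
            comp[missing] = filled
            u[..., c] = comp.reshape(ny, nx)
    return DisplacementField(x_um=field.x_um, y_um=field.y_um, u_um=u,
                             spacing_um=field.spacing_um,
                             valid=np.ones_like(valid), frame_index=field.frame_index)


# ---------------------------------------------------------------------------
# Boussinesq forward model (real-space kernel) and FTTC inversion
# ---------------------------------------------------------------------------

def _real_space_kernel(ny: int, nx: int, h: float, substrate: ElasticSubstrate):
    """Sampled Boussinesq surface Green's tensor times cell area on a padded
    lag grid, with the singular self-cell handled by its analytic integral
    over a square cell."""
    e, nu = substrate.young_modulus_pa, substrate.poisson_ratio
    py, px = 2 * ny, 2 * nx
    ly = ((np.arange(py) + ny) % py - ny)[:, None] * h
    lx = ((np.arange(px) + nx) % px - nx)[None, :] * h
    r2 = lx ** 2 + ly ** 2
    r = np.sqrt(r2)
    with np.errstate(divide="ignore", invalid="ignore"):
        pref = (1.0 + nu) / (np.pi * e * r)
        kxx = pref * ((1 - nu) + nu * lx ** 2 / r2) * h * h
        kyy = pref * ((1 - nu) + nu * ly ** 2 / r2) * h * h
        kxy = pref * (nu * lx * ly / r2) * h * h
    # analytic integral of the kernel over the central square cell:
    # int dA/r over a side-h square = 4 h ln(1+sqrt(2));
    # int (x_i x_j / r^3) dA is diagonal with each term = 2 h ln(1+sqrt(2)).
    diag0 = (1.0 + nu) / (np.pi * e) * ((1 - nu) * 4 + nu * 2) * h * np.log(1 + np.sqrt(2))
    kxx[0, 0] = kyy[0, 0] = diag0
    kxy[0, 0] = 0.0
    return kxx, kxy, kyy


def forward_displacement(traction: np.ndarray, spacing_um: float,
                         substrate: ElasticSubstrate) -> np.ndarray:
    """Displacement field (um) produced by a traction field (Pa).

    Linear convolution of the traction with the sampled real-space
    Boussinesq Green's tensor (FFT-accelerated, zero-padded to 2x so no
    periodic wrap-around enters the result).
    """
    t = np.asarray(traction, dtype=float)
    ny, nx = t.shape[:2]
    kxx, kxy, kyy = _real_space_kernel(ny, nx, spacing_um, substrate)
    tp = np.zeros((2 * ny, 2 * nx, 2))
    tp[:ny, :nx] = t
    ftx = np.fft.fft2(tp[..., 0])
    fty = np.fft.fft2(tp[..., 1])
    ux = np.real(np.fft.ifft2(np.fft.fft2(kxx) * ftx + np.fft.fft2(kxy) * fty))
    uy = np.real(np.fft.ifft2(np.fft.fft2(kxy) * ftx + np.fft.fft2(kyy) * fty))
    return np.stack([ux[:ny, :nx], uy[:ny, :nx]], axis=-1)


def _fourier_greens(py: int, px: int, h: float, substrate: ElasticSubstrate):
    """Analytic Fourier-space Boussinesq tensor on a (py, px) padded grid."""
    e, nu = substrate.young_modulus_pa, substrate.poisson_ratio
    kx = 2 * np.pi * np.fft.fftfreq(px, d=h)[None, :]
    ky = 2 * np.pi * np.fft.fftfreq(py, d=h)[:, None]
    k = np.sqrt(kx ** 2 + ky ** 2)
    k[0, 0] = 1.0  # placeholder; zero-frequency handled by the gauge
    pref = 2.0 * (1.0 + nu) / (e * k ** 3)
    gxx = pref * ((1 - nu) * k ** 2 + nu * ky ** 2)
    gyy = pref * ((1 - nu) * k ** 2 + nu * kx ** 2)
    gxy = pref * (-nu * kx * ky)
    gxx[0, 0] = gyy[0, 0] = gxy[0, 0] = 0.0
    return gxx, gxy, gyy


def _smooth_pad(a: np.ndarray) -> np.ndarray:
    """Pad a 2-D field to twice its extent with a smooth periodic bridge.

    The padding region blends cosine-smoothly from each edge back to the
    opposite edge, so the padded field is continuous under the periodic
    boundary of the FFT.  A hard zero pad would put a step at the crop
    boundary whose high-frequency content the (deconvolving) inverse
    operator amplifies into edge artifacts.
    """
    ny, nx = a.shape
    out = np.zeros((2 * ny, 2 * nx))
    out[:ny, :nx] = a
    sx = 0.5 * (1 - np.cos(np.pi * (np.arange(nx) + 1) / (nx + 1)))
    out[:ny, nx:] = np.outer(a[:, -1], 1 - sx) + np.outer(a[:, 0], sx)
    sy = 0.5 * (1 - np.cos(np.pi * (np.arange(ny) + 1) / (ny + 1)))
    out[ny:, :] = (out[ny - 1, :][None, :] * (1 - sy)[:, None]
                   + out[0, :][None, :] * sy[:, None])
    return out


def _spectral_problem(field: DisplacementField, substrate: ElasticSubstrate):
    """Padded spectral form of the inversion: Green's tensor and u-hat."""
    ny, nx = field.shape
    u = field.u_um - field.u_um.mean(axis=(0, 1), keepdims=True)
    up = np.stack([_smooth_pad(u[..., 0]), _smooth_pad(u[..., 1])], axis=-1)
    greens = _fourier_greens(2 * ny, 2 * nx, field.spacing_um, substrate)
    return greens, (np.fft.fft2(up[..., 0]), np.fft.fft2(up[..., 1]))


def _tikhonov_solve(greens, fux, fuy, lam: float):
    """Per-wavevector 2x2 Tikhonov solve T = (G^2 + lam^2 I)^-1 G u
    (G real symmetric), closed-form inverse; zero-frequency gauged to 0."""
    gxx, gxy, gyy = greens
    axx = gxx * gxx + gxy * gxy + lam ** 2
    ayy = gyy * gyy + gxy * gxy + lam ** 2
    axy = gxy * (gxx + gyy)
    det = axx * ayy - axy ** 2
    det[det == 0] = np.inf
    bx = gxx * fux + gxy * fuy
    by = gxy * fux + gyy * fuy
    ftx = (ayy * bx - axy * by) / det
    fty = (-axy * bx + axx * by) / det
    ftx[0, 0] = fty[0, 0] = 0.0
    return ftx, fty


def fttc(field: DisplacementField, substrate: ElasticSubstrate, lam: float) -> TractionField:
    """Regularized Fourier Transform Traction Cytometry.

    Inverts the Boussinesq operator in Fourier space with zeroth-order
    Tikhonov regularization ``lam`` (>= 0, units um/Pa).  The displacement
    grid must be complete (run :func:`filter_and_krige` first).  The field
    is mean-subtracted and zero-padded to twice its extent before inversion
    to suppress periodic wrap-around; the zero-frequency traction is set to
    zero (net-force-free gauge).
    """
    if lam < 0:
        raise ValueError("regularization lambda must be >= 0")
    if not field.valid.all():
        raise ValueError("displacement grid has invalid nodes; interpolate first")
    ny, nx = field.shape
    greens, (fux, fuy) = _spectral_problem(field, substrate)
    ftx, fty = _tikhonov_solve(greens, fux, fuy, lam)
    tx = np.real(np.fft.ifft2(ftx))[:ny, :nx]
    ty = np.real(np.fft.ifft2(fty))[:ny, :nx]
    # net-force-free gauge on the reported (cropped) field
    tx -= tx.mean()
    ty -= ty.mean()
    return TractionField(x_um=field.x_um, y_um=field.y_um,
                         t_pa=np.stack([tx, ty], axis=-1),
                         spacing_um=field.spacing_um, regularization_lambda=lam)


def choose_lambda(field: DisplacementField, substrate: ElasticSubstrate,
                  lambdas: np.ndarray | None = None):
    """Pick the Tikhonov parameter at the corner of the L-curve.

    Sweeps ``lambdas`` (default 29 points over 6 decades), recording the
    residual norm rho(lam) = ||G T - u|| and solution norm eta(lam) = ||T||.
    The corner is the point of maximum curvature of the (log rho, log eta)
    curve.  Returns ``(lam_star, curve)`` with the full curve as a DataFrame
    for inspection or alternative corner criteria.
    """
    if lambdas is None:
        lambdas = np.logspace(-6, 0, 29)
    lambdas = np.asarray(lambdas, dtype=float)
    if len(lambdas) < 20 or np.log10(lambdas.max() / lambdas.min()) < 3:
        raise ValueError("lambda grid must span >= 3 decades with >= 20 points")
    lambdas = np.sort(lambdas)
    greens, (fux, fuy) = _spectral_problem(field, substrate)
    gxx, gxy, gyy = greens
    npix = fux.size
    rho, eta = [], []
    for lam in lambdas:
        ftx, fty = _tikhonov_solve(greens, fux, fuy, lam)
        rx = gxx * ftx + gxy * fty - fux
        ry = gxy * ftx + gyy * fty - fuy
        rx[0, 0] = ry[0, 0] = 0.0  # zero-frequency is gauged out
        rho.append(np.sqrt((np.abs(rx) ** 2 + np.abs(ry) ** 2).sum() / npix))
        eta.append(np.sqrt((np.abs(ftx) ** 2 + np.abs(fty) ** 2).sum() / npix))
    rho, eta = np.asarray(rho), np.asarray(eta)
    # monotone up to a numerical floor (rho sits at machine precision for
    # tiny lambda on noiseless data)
    if np.any(np.diff(rho) < -1e-6 * rho.max()) or np.any(np.diff(eta) > 1e-6 * eta.max()):
        raise RuntimeError("L-curve norms are not monotone in lambda; numerical failure")
    t = np.log(lambdas)
    x = np.log(np.maximum(rho, 1e-300))
    y = np.log(np.maximum(eta, 1e-300))
    dx, dy = np.gradient(x, t), np.gradient(y, t)
    ddx, ddy = np.gradient(dx, t), np.gradient(dy, t)
    kappa = (dx * ddy - dy * ddx) / np.maximum((dx ** 2 + dy ** 2) ** 1.5, 1e-30)
    # endpoints use one-sided differences; exclude them from the corner search
    interior = slice(2, len(lambdas) - 2)
    lam_star = float(lambdas[interior][int(np.argmax(kappa[interior]))])
    curve = pd.DataFrame({"lam": lambdas, "residual_norm": rho,
                          "solution_norm": eta, "curvature": kappa})
    return lam_star, curve


def strain_energy(traction: TractionField, displacement: DisplacementField,
                  cell_area_um2: float | None = None,
                  cell_mask: np.ndarray | None = None) -> StrainEnergyResult:
    """Strain energy U = 1/2 * sum(T . u) * dA over the grid, in joules.

    ``cell_mask`` (boolean, grid-shaped) restricts the sum to nodes under
    the cell; ``cell_area_um2`` (e.g. from a hand-traced DIC outline)
    enables the per-area value.
    """
    if traction.shape != displacement.shape:
        raise ValueError("traction and displacement grids differ in shape")
    if not np.isclose(traction.spacing_um, displacement.spacing_um):
        raise ValueError("traction and displacement grid spacings differ")
    dot = (traction.t_pa * displacement.u_um).sum(axis=-1)
    if cell_mask is not None:
        if cell_mask.shape != dot.shape:
            raise ValueError("cell_mask shape does not match the grid")
        dot = dot * cell_mask
    da_m2 = (traction.spacing_um * 1e-6) ** 2
    u = 0.5 * float(dot.sum()) * da_m2 * 1e-6  # Pa * um -> Pa * m with dA in m^2
    if cell_area_um2 is None and cell_mask is not None:
        cell_area_um2 = float(cell_mask.sum()) * traction.spacing_um ** 2
    return StrainEnergyResult(u_joules=u, cell_area_um2=cell_area_um2)
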