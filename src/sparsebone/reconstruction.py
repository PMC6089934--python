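"""Reconstruction algorithms and image-quality scoring.

Four routes from a projection set back to a volume:

* :func:`fbp_fdk` — the analytic reference: Hamming-apodized ramp-filtered
  backprojection (exact FBP for parallel beam, Parker-weighted short-scan
  FBP for fan beam, FDK cone weighting for cone3d);
* :func:`cgls` / :func:`cgls_reconstruct` — conjugate gradients on the
  least-squares normal equations, started from zero;
* :func:`tv_bb` — smoothed total-variation regularization minimized by
  gradient descent with Barzilai-Borwein (BB1) step lengths, the
  regularization weight selectable by the L-curve corner
  (:func:`lcurve_select`);
* :func:`dart` — the discrete algebraic reconstruction technique: alternate
  CGLS updates of boundary/free voxels with segmentation to a finite set of
  admissible gray values.

:func:`cnr` scores contrast-to-noise on the middle slice.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import ndimage

from .core import VoxelVolume
from .projection import ProjectionSet, ScanGeometry, TomoOperator

__all__ = [
    "ReconConfig",
    "GrayPrior",
    "LCurvePoint",
    "fbp_fdk",
    "cgls",
    "cgls_reconstruct",
    "tv_bb",
    "total_variation",
    "lcurve_corner",
    "lcurve_select",
    "dart",
    "cnr",
]


@dataclass
class ReconConfig:
    """Tunable constants shared by the reconstruction algorithms.

    ``n_iter`` is the base iteration count for every iterative method;
    ``hamming_alpha`` the apodization window parameter; ``tv_lambda`` /
    ``tv_epsilon`` the TV weight and gradient-smoothing constant (epsilon
    defaults to 1e-4 of the bone attenuation, 1.5 mm^-1); ``dart_fix_prob``
    the probability that a non-boundary voxel stays fixed in a DART pass;
    ``dart_smooth_blend`` the weight of the radius-1 mean smoothing of free
    voxels.
    """

    algorithm: str = "cgls"
    n_iter: int = 25
    hamming_alpha: float = 0.54
    tv_lambda: float = 0.0
    tv_epsilon: float = 1.5e-4
    dart_arm_iters: int = 10
    dart_init_iters: int = 25
    dart_fix_prob: float = 0.99
    dart_smooth_blend: float = 0.1
    dart_return_continuous: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if not (0.5 <= self.hamming_alpha <= 1.0):
            raise ValueError("hamming_alpha must lie in [0.5, 1]")
        if self.tv_lambda < 0:
            raise ValueError("tv_lambda must be >= 0")
        if not (0.0 <= self.dart_fix_prob <= 1.0):
            raise ValueError("dart_fix_prob must lie in [0, 1]")


@dataclass
class GrayPrior:
    """Admissible gray values and the thresholds separating them."""

    gray_values: tuple  # (rho0, rho1, rho2): background, soft tissue, bone
    thresholds: Optional[tuple] = None  # (tau1, tau2); midpoints if omitted

    def __post_init__(self) -> None:
        r = tuple(float(v) for v in self.gray_values)
        if not all(a < b for a, b in zip(r, r[1:])):
            raise ValueError("gray values must be strictly increasing")
        self.gray_values = r
        if self.thresholds is None:
            self.thresholds = tuple((a + b) / 2.0 for a, b in zip(r, r[1:]))
        t = tuple(float(v) for v in self.thresholds)
        ok = all(r[i] < t[i] < r[i + 1] for i in range(len(t)))
        if len(t) != len(r) - 1 or not ok:
            raise ValueError("thresholds must interleave the gray values")
        self.thresholds = t

    def segment(self, image: np.ndarray) -> np.ndarray:
        """Map a continuous image onto the admissible gray values."""
        rho = np.asarray(self.gray_values)
        cls = np.searchsorted(np.asarray(self.thresholds), image, side="right")
        return rho[cls]

    def classes(self, image: np.ndarray) -> np.ndarray:
        return np.searchsorted(np.asarray(self.thresholds), image, side="right")


@dataclass
class LCurvePoint:
    lam: float
    residual_norm: float
    penalty: float


# ---------------------------------------------------------------------------
# filtered backprojection / FDK
# ---------------------------------------------------------------------------

def _ramp_hamming(n: int, pitch_mm: float, alpha: float) -> np.ndarray:
    """Ramp filter |nu| apodized by W(nu) = alpha + (1-alpha) cos(pi nu/nu_N),
    sampled on the rfft frequency grid of a zero-padded signal of length n."""
    freqs = np.fft.rfftfreq(n, d=pitch_mm)
    nyquist = 0.5 / pitch_mm
    window = alpha + (1.0 - alpha) * np.cos(np.pi * freqs / nyquist)
    return freqs * window  # zero at DC by the ramp


def _filter_rows(sino: np.ndarray, pitch_mm: float, alpha: float) -> np.ndarray:
    """Apply the apodized ramp along the last axis with 2x zero padding."""
    n = sino.shape[-1]
    n_pad = int(2 ** np.ceil(np.log2(max(2 * n, 8))))
    H = _ramp_hamming(n_pad, pitch_mm, alpha)
    spec = np.fft.rfft(sino, n=n_pad, axis=-1)
    filt = np.fft.irfft(spec * H, n=n_pad, axis=-1)[..., :n]
    return filt


def _parker_weights(geom: ScanGeometry) -> np.ndarray:
    """Short-scan redundancy weights on the (angle, detector) grid.

    Uses the effective half-fan angle (span - 180 deg)/2, which must be at
    least the detector's physical half-fan angle.
    """
    span = np.deg2rad(geom.span_deg)
    fan = np.deg2rad(geom.fan_angle_deg())
    gamma_m = (span - np.pi) / 2.0
    u = geom.detector_coords_mm()
    gamma = np.arctan2(u, geom.sdd_mm)  # per-element fan angle
    beta = np.deg2rad(geom.angles_deg - geom.angles_deg[0])
    B, G = np.meshgrid(beta, gamma, indexing="ij")
    w = np.ones_like(B)
    with np.errstate(divide="ignore", invalid="ignore"):
        lo = B < 2.0 * (gamma_m - G)
        w_lo = np.sin(np.pi / 4.0 * B / (gamma_m - G)) ** 2
        hi = B > np.pi - 2.0 * G
        w_hi = np.sin(np.pi / 4.0 * (np.pi + 2.0 * gamma_m - B) / (gamma_m + G)) ** 2
    w = np.where(lo, w_lo, w)
    w = np.where(hi, w_hi, w)
    return np.clip(np.nan_to_num(w, nan=0.0), 0.0, 1.0)


def _coverage_check(geom: ScanGeometry, tol_deg: float) -> tuple[bool, float]:
    """Return (is_full_360, required span); raise if coverage is deficient."""
    span = geom.span_deg
    fan = geom.fan_angle_deg()
    if geom.modality == "parallel2d":
        required = 180.0
    else:
        required = 180.0 + fan
    full = span >= 360.0 - tol_deg
    if not full and span + tol_deg < required:
        raise ValueError(
            f"angular span {span:.1f} deg is insufficient for {geom.modality} "
            f"FBP: need at least {required:.1f} deg (deficit "
            f"{required - span:.1f} deg)")
    return full, required


def fbp_fdk(projections: ProjectionSet, config: ReconConfig) -> VoxelVolume:
    """Apodized ramp-filtered backprojection (FBP / short-scan FBP / FDK)."""
    geom = projections.geometry
    if geom.n_angles < 2:
        raise ValueError("FBP needs at least two views")
    steps = np.diff(geom.angles_deg)
    if not np.allclose(steps, steps[0], atol=1e-9):
        raise ValueError("FBP requires uniform angular sampling")
    # one angular step of slack: n views at step d cover a span of n*d
    full_360, _ = _coverage_check(geom, tol_deg=float(steps[0]))
    d_beta = np.deg2rad(steps[0])
    vs = geom.voxel_size_um / 1000.0
    ny, nx = geom.vol_shape[-2:]
    x = (np.arange(nx) - (nx - 1) / 2.0) * vs
    y = (np.arange(ny) - (ny - 1) / 2.0) * vs
    X, Y = np.meshgrid(x, y)  # (ny, nx)

    data = projections.data
    single_slice = (geom.modality != "cone3d") and data.ndim == 2
    if single_slice:
        data = data[:, None, :]  # (n_angles, 1, n_det)

    if geom.modality == "parallel2d":
        angles = np.deg2rad(geom.angles_deg)
        use = np.ones(geom.n_angles, dtype=bool)
        if not full_360 and geom.span_deg > 180.0:
            # drop the redundant tail beyond 180 degrees
            use = (geom.angles_deg - geom.angles_deg[0]) < 180.0
        q = _filter_rows(data, geom.det_pitch_iso_mm, config.hamming_alpha)
        u0 = geom.detector_coords_mm()[0]
        pitch = geom.det_pitch_iso_mm
        recon = np.zeros((data.shape[1], ny, nx))
        for ia in np.nonzero(use)[0]:
            c, s = np.cos(angles[ia]), np.sin(angles[ia])
            uu = X * c + Y * s
            f = (uu - u0) / pitch
            i0 = np.clip(np.floor(f).astype(int), 0, geom.n_det - 2)
            w = np.clip(f - i0, 0.0, 1.0)
            qa = q[ia]  # (nz, n_det)
            vals = (1 - w)[None] * qa[:, i0] + w[None] * qa[:, i0 + 1]
            recon += vals * d_beta
        if full_360:
            recon *= 0.5
    else:
        # fan2d / cone3d with a virtual detector rescaled to the isocentre
        m = geom.magnification
        pitch = geom.det_pitch_iso_mm
        u_iso = geom.detector_coords_mm() / m
        if geom.modality == "cone3d":
            v_iso = geom.detector_row_coords_mm() / m
            wgt = geom.sad_mm / np.sqrt(
                geom.sad_mm ** 2 + u_iso[None, :] ** 2 + v_iso[:, None] ** 2)
            pre = data * wgt[None, :, :]
        else:
            wgt = geom.sad_mm / np.sqrt(geom.sad_mm ** 2 + u_iso ** 2)
            pre = data * wgt[None, None, :]
        if not full_360:
            pw = _parker_weights(geom)  # (n_angles, n_det)
            pre = pre * pw[:, None, :]
        q = _filter_rows(pre, pitch, config.hamming_alpha)
        angles = np.deg2rad(geom.angles_deg)
        if geom.modality == "cone3d":
            nz = geom.vol_shape[0]
            z = (np.arange(nz) - (nz - 1) / 2.0) * vs
        else:
            nz = data.shape[1]
        recon = np.zeros((nz, ny, nx))
        u0, v0 = u_iso[0], (0.0 if geom.modality != "cone3d" else v_iso[0])
        for ia, beta in enumerate(angles):
            c, s = np.cos(beta), np.sin(beta)
            # distance of each voxel from the source along the central ray,
            # relative to SAD: U = (SAD + r . c_hat) / SAD
            proj_c = -X * s + Y * c
            U = (geom.sad_mm + proj_c) / geom.sad_mm
            su = (X * c + Y * s) / U  # transverse iso-detector coordinate
            f = (su - u0) / pitch
            i0 = np.clip(np.floor(f).astype(int), 0, geom.n_det - 2)
            w = np.clip(f - i0, 0.0, 1.0)
            if geom.modality == "cone3d":
                zv = z[:, None, None] / U[None, :, :]
                g = (zv - v0) / pitch
                j0 = np.clip(np.floor(g).astype(int), 0, geom.n_det_rows - 2)
                wv = np.clip(g - j0, 0.0, 1.0)
                qa = q[ia]  # (n_rows, n_det)
                i0b = np.broadcast_to(i0, zv.shape)
                wb = np.broadcast_to(w, zv.shape)
                v00 = qa[j0, i0b]
                v01 = qa[j0, i0b + 1]
                v10 = qa[j0 + 1, i0b]
                v11 = qa[j0 + 1, i0b + 1]
                vals = ((1 - wv) * ((1 - wb) * v00 + wb * v01)
                        + wv * ((1 - wb) * v10 + wb * v11))
            else:
                qa = q[ia]  # (nz, n_det)
                vals = (1 - w)[None] * qa[:, i0] + w[None] * qa[:, i0 + 1]
            recon += vals * (d_beta / U ** 2)[None, :, :]
        if full_360:
            recon *= 0.5
    if single_slice:
        recon = recon[0]
    return VoxelVolume(recon, geom.voxel_size_um)


# ---------------------------------------------------------------------------
# CGLS
# ---------------------------------------------------------------------------

def cgls(b: np.ndarray, forward: Callable, adjoint: Callable, n_iter: int,
         x0: Optional[np.ndarray] = None) -> tuple[np.ndarray, list]:
    """Conjugate gradients on the normal equations A^T A x = A^T b.

    Starts from zero (or ``x0``), runs exactly ``n_iter`` iterations and
    returns (iterate, residual-norm history including the start).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    b = np.asarray(b, dtype=np.float64)
    if not np.all(np.isfinite(b)):
        raise ValueError("projection data contains NaN or Inf")
    if x0 is None:
        r = b.copy()
        x = None
    else:
        x = x0.astype(np.float64).copy()
        r = b - forward(x)
    s = adjoint(r)
    if x is None:
        x = np.zeros_like(s)
    p = s.copy()
    gamma = float(np.vdot(s, s).real)
    history = [float(np.linalg.norm(r))]
    for _ in range(n_iter):
        q = forward(p)
        qq = float(np.vdot(q, q).real)
        if qq == 0.0 or gamma == 0.0:
            history.append(history[-1])
            continue
        alpha = gamma / qq
        x += alpha * p
        r -= alpha * q
        s = adjoint(r)
        gamma_new = float(np.vdot(s, s).real)
        p = s + (gamma_new / gamma) * p
        gamma = gamma_new
        history.append(float(np.linalg.norm(r)))
    return x, history


def _masked_pair(op: TomoOperator, mask: Optional[np.ndarray]):
    if mask is None:
        return op.forward, op.adjoint
    m = mask.astype(np.float64)

    def fwd(x):
        return op.forward(x * m)

    def adj(y):
        return op.adjoint(y) * m

    return fwd, adj


def cgls_reconstruct(projections: ProjectionSet, operator: TomoOperator,
                     config: ReconConfig) -> VoxelVolume:
    """CGLS reconstruction of a projection set (default 25 iterations)."""
    x, _ = cgls(projections.data, operator.forward, operator.adjoint,
                config.n_iter)
    return VoxelVolume(x, projections.geometry.voxel_size_um)


# ---------------------------------------------------------------------------
# total variation with Barzilai-Borwein steps
# ---------------------------------------------------------------------------

def _grad(u: np.ndarray) -> tuple:
    """Forward differences with replicated (zero-flux) boundary."""
    grads = []
    for ax in range(u.ndim):
        g = np.diff(u, axis=ax, append=np.take(u, [-1], axis=ax))
        grads.append(g)
    return tuple(grads)


def total_variation(u: np.ndarray, epsilon: float = 0.0) -> float:
    """Sum over voxels of sqrt(|grad u|^2 + epsilon^2) (isotropic TV)."""
    mag2 = np.zeros_like(u, dtype=np.float64)
    for g in _grad(u):
        mag2 += g * g
    if epsilon > 0:
        return float(np.sum(np.sqrt(mag2 + epsilon ** 2)))
    return float(np.sum(np.sqrt(mag2)))


def _tv_gradient(u: np.ndarray, epsilon: float) -> np.ndarray:
    grads = _grad(u)
    mag = np.sqrt(sum(g * g for g in grads) + epsilon ** 2)
    out = np.zeros_like(u)
    for ax, g in enumerate(grads):
        n = g / mag
        # adjoint of forward difference: negative backward difference
        d = np.diff(n, axis=ax, prepend=np.take(n * 0.0, [0], axis=ax))
        # last element: the append boundary makes the final difference zero,
        # handled implicitly since g there is 0
        out -= d
    return out


def _norm_estimate(op: TomoOperator, shape: tuple, n_power: int = 8) -> float:
    """Power-iteration estimate of ||A||_2^2 for step-length safeguarding."""
    rng = np.random.default_rng(12345)
    x = rng.standard_normal(shape)
    x /= np.linalg.norm(x)
    lam = 1.0
    for _ in range(n_power):
        y = op.adjoint(op.forward(x))
        lam = float(np.linalg.norm(y))
        if lam == 0:
            return 1.0
        x = y / lam
    return lam


def tv_bb(projections: ProjectionSet, operator: TomoOperator,
          config: ReconConfig) -> VoxelVolume:
    """Minimize 0.5 ||Au - b||^2 + lambda * sum sqrt(|grad u|^2 + eps^2)
    by Barzilai-Borwein (BB1) gradient descent from the zero image."""
    if not config.tv_epsilon > 0:
        raise ValueError("tv_epsilon must be positive")
    b = projections.data
    lam = config.tv_lambda
    eps = config.tv_epsilon
    u = np.zeros_like(operator.adjoint(b))

    def objective(v, Av):
        obj = 0.5 * float(np.sum((Av - b) ** 2))
        if lam > 0:
            obj += lam * total_variation(v, eps)
        return obj

    def gradient(v, Av):
        g = operator.adjoint(Av - b)
        if lam > 0:
            g = g + lam * _tv_gradient(v, eps)
        return g

    L = _norm_estimate(operator, u.shape) + (4.0 * u.ndim * lam / eps if lam > 0 else 0.0)
    alpha0 = 1.0 / max(L, 1e-30)
    alpha_min, alpha_max = 1e-8, 1e8

    Au = operator.forward(u)
    f0 = objective(u, Au)
    g = gradient(u, Au)
    best_u, best_f = u.copy(), f0
    alpha = alpha0
    u_prev, g_prev = None, None
    for _ in range(config.n_iter):
        if u_prev is not None:
            s = (u - u_prev).ravel()
            yv = (g - g_prev).ravel()
            sy = float(s @ yv)
            if sy > 0:
                alpha = float(np.clip((s @ s) / sy, alpha_min, alpha_max))
            else:  # negative curvature: fall back to the safe fixed step
                alpha = alpha0
        u_prev, g_prev = u, g
        u = u - alpha * g
        Au = operator.forward(u)
        f = objective(u, Au)
        if f < best_f:
            best_f, best_u = f, u.copy()
        g = gradient(u, Au)
    # guarantee monotone overall descent: never return worse than the start
    result = u if objective(u, operator.forward(u)) <= f0 else best_u
    return VoxelVolume(result, projections.geometry.voxel_size_um)


def lcurve_corner(points: list[LCurvePoint]) -> float:
    """Corner of the (log residual, log penalty) curve by three-point Menger
    curvature; endpoints get curvature zero; ties resolve to the smaller
    lambda."""
    pts = sorted(points, key=lambda p: p.lam)
    if len(pts) < 3:
        warnings.warn("fewer than 3 L-curve points; returning the first lambda")
        return pts[len(pts) // 2].lam if len(pts) else float("nan")
    tiny = 1e-300
    xy = np.array([[np.log(max(p.residual_norm, tiny)),
                    np.log(max(p.penalty, tiny))] for p in pts])
    curv = np.zeros(len(pts))
    for i in range(1, len(pts) - 1):
        a, bb, c = xy[i - 1], xy[i], xy[i + 1]
        area2 = abs((bb[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (bb[1] - a[1]))
        la, lb, lc = (np.linalg.norm(bb - a), np.linalg.norm(c - bb),
                      np.linalg.norm(c - a))
        denom = la * lb * lc
        curv[i] = 2.0 * area2 / denom if denom > 0 else 0.0
    best = np.nonzero(curv == curv.max())[0].min()  # ties -> smaller lambda
    return float(pts[best].lam)


def lcurve_select(projections: ProjectionSet, operator: TomoOperator,
                  lambda_grid, config: ReconConfig) -> float:
    """Run :func:`tv_bb` over a lambda grid and return the L-curve corner."""
    lambda_grid = sorted(float(l) for l in lambda_grid)
    if any(l <= 0 for l in lambda_grid):
        raise ValueError("lambda grid must be positive")
    if len(lambda_grid) < 3:
        warnings.warn("fewer than 3 lambda grid points; skipping the L-curve")
        return lambda_grid[len(lambda_grid) // 2]
    pts = []
    for lam in lambda_grid:
        cfg = ReconConfig(algorithm="tv", n_iter=config.n_iter,
                          tv_lambda=lam, tv_epsilon=config.tv_epsilon,
                          hamming_alpha=config.hamming_alpha)
        u = tv_bb(projections, operator, cfg).data
        res = float(np.linalg.norm(operator.forward(u) - projections.data))
        pts.append(LCurvePoint(lam, res, total_variation(u, config.tv_epsilon)))
    return lcurve_corner(pts)


# ---------------------------------------------------------------------------
# DART
# ---------------------------------------------------------------------------

def _boundary_voxels(classes: np.ndarray) -> np.ndarray:
    """Voxels with at least one face neighbour of a different class."""
    b = np.zeros(classes.shape, dtype=bool)
    for ax in range(classes.ndim):
        d = np.diff(classes, axis=ax) != 0
        sl_lo = [slice(None)] * classes.ndim
        sl_hi = [slice(None)] * classes.ndim
        sl_lo[ax] = slice(0, -1)
        sl_hi[ax] = slice(1, None)
        b[tuple(sl_lo)] |= d
        b[tuple(sl_hi)] |= d
    return b


def dart(projections: ProjectionSet, operator: TomoOperator, prior: GrayPrior,
         config: ReconConfig) -> VoxelVolume:
    """Discrete algebraic reconstruction with a three-value gray prior.

    Initial reconstruction: CGLS with ``dart_init_iters``.  Each DART pass
    segments the current image, fixes interior voxels at their class gray
    value (keeping boundary voxels plus a seeded random fraction
    ``1 - dart_fix_prob`` of the interior free), solves for the free voxels
    with ``dart_arm_iters`` CGLS iterations against the residual data, and
    smooths the free voxels with a radius-1 mean filter at blend
    ``dart_smooth_blend``.  The returned image is segmented (every voxel is
    one of the prior gray values) unless ``dart_return_continuous`` is set.
    """
    b = projections.data
    rng = np.random.default_rng(config.seed)
    x, _ = cgls(b, operator.forward, operator.adjoint, config.dart_init_iters)
    for _ in range(config.n_iter):
        seg = prior.segment(x)
        classes = prior.classes(x)
        boundary = _boundary_voxels(classes)
        free = boundary | (rng.random(x.shape) > config.dart_fix_prob)
        fixed_part = np.where(free, 0.0, seg)
        b_res = b - operator.forward(fixed_part)
        fwd, adj = _masked_pair(operator, free)
        u, _ = cgls(b_res, fwd, adj, config.dart_arm_iters,
                    x0=np.where(free, x, 0.0))
        x = fixed_part + np.where(free, u, 0.0)
        if config.dart_smooth_blend > 0:
            sm = ndimage.uniform_filter(x, size=3, mode="nearest")
            x = np.where(free,
                         (1.0 - config.dart_smooth_blend) * x
                         + config.dart_smooth_blend * sm, x)
    if config.dart_return_continuous:
        return VoxelVolume(x, projections.geometry.voxel_size_um)
    return VoxelVolume(prior.segment(x), projections.geometry.voxel_size_um)


# ---------------------------------------------------------------------------
# image quality
# ---------------------------------------------------------------------------

def cnr(volume: VoxelVolume, bone_roi: np.ndarray,
        background_roi: np.ndarray, slice_index: Optional[int] = None) -> float:
    """Contrast-to-noise ratio (mu_bone - mu_bg) / sigma_bg on one slice.

    ROI masks are 2-D and applied to the volume's middle z-slice (or
    ``slice_index``); they must be disjoint and hold at least 25 voxels
    each.  A constant background (sigma = 0, typical for discrete DART
    output) returns +inf as an "undefined" marker.
    """
    img = volume.data
    if img.ndim == 3:
        idx = img.shape[0] // 2 if slice_index is None else int(slice_index)
        img = img[idx]
    bone_roi = np.asarray(bone_roi, dtype=bool)
    background_roi = np.asarray(background_roi, dtype=bool)
    if bone_roi.shape != img.shape or background_roi.shape != img.shape:
        raise ValueError("ROI masks must match the middle-slice shape")
    if np.count_nonzero(bone_roi) < 25 or np.count_nonzero(background_roi) < 25:
        raise ValueError("each ROI must contain at least 25 voxels")
    if np.any(bone_roi & background_roi):
        raise ValueError("ROIs must be disjoint")
    mu_b = float(img[bone_roi].mean())
    mu_g = float(img[background_roi].mean())
    sigma = float(img[background_roi].std())
    if sigma == 0.0:
        return float("inf")
    return (mu_b - mu_g) / sigma
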