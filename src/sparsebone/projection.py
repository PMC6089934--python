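"""Tomographic forward model.

Scan geometries (parallel 2-D, fan 2-D, small-angle cone 3-D), a Joseph
ray-driven projector with an exact adjoint, Poisson photon noise with frame
averaging, and angular subsampling of projection sets.

Conventions (pinned for reproducibility):

* volume axes are (z, y, x); voxel centres sit at ``(i - (n-1)/2) * vs``
  millimetres from the volume centre along each axis;
* gantry angles are degrees, counter-clockwise, starting at 0 where the
  parallel detector axis is +x (rays travel along +y) and the fan/cone
  source sits at (0, -SAD);
* detector element 0 lies at the negative transverse edge, elements are
  spaced ``det_pitch_um`` apart at the detector plane (fan/cone) or at the
  isocentre (parallel);
* 2-D modalities applied to a 3-D volume project every z-slice with the same
  in-plane geometry; the data layout is then (n_angles, nz, n_det).

The Joseph kernel steps one voxel plane at a time along the ray's dominant
axis and interpolates linearly in the transverse direction(s); its sampling
weights are assembled once per geometry into a sparse system matrix, so the
back projector is the exact transpose of the forward projector.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import sparse

from .core import VoxelVolume

__all__ = [
    "ScanGeometry",
    "ProjectionSet",
    "TomoOperator",
    "build_geometry",
    "forward_project",
    "back_project",
    "add_noise",
    "subsample_projections",
    "siddon_forward_project",
]


@dataclass
class ScanGeometry:
    """Acquisition geometry for one scan."""

    modality: str  # "parallel2d" | "fan2d" | "cone3d"
    angles_deg: np.ndarray
    n_det: int
    det_pitch_um: float
    vol_shape: tuple  # (ny, nx) for 2-D modalities, (nz, ny, nx) for cone3d
    voxel_size_um: float
    sad_mm: float = 50.0
    sdd_mm: float = 100.0
    n_det_rows: int = 1  # cone3d only (v axis)

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=np.float64)
        if self.angles_deg.ndim != 1 or len(self.angles_deg) < 1:
            raise ValueError("angles_deg must be a non-empty 1-D sequence")
        if len(self.angles_deg) > 1 and not np.all(np.diff(self.angles_deg) > 0):
            raise ValueError("angles must be strictly increasing")
        if self.modality not in ("parallel2d", "fan2d", "cone3d"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.modality != "parallel2d" and not (self.sad_mm > 0 and self.sdd_mm > 0):
            raise ValueError("source distances must be positive")

    @property
    def n_angles(self) -> int:
        return len(self.angles_deg)

    @property
    def span_deg(self) -> float:
        return float(self.angles_deg[-1] - self.angles_deg[0])

    @property
    def magnification(self) -> float:
        return 1.0 if self.modality == "parallel2d" else self.sdd_mm / self.sad_mm

    @property
    def det_pitch_iso_mm(self) -> float:
        """Detector pitch rescaled to the isocentre plane, in mm."""
        return self.det_pitch_um / 1000.0 / self.magnification

    def fan_angle_deg(self) -> float:
        """Full fan angle subtended by the detector (0 for parallel beam)."""
        if self.modality == "parallel2d":
            return 0.0
        half_w = 0.5 * self.n_det * self.det_pitch_um / 1000.0
        return float(2.0 * np.degrees(np.arctan2(half_w, self.sdd_mm)))

    def detector_coords_mm(self) -> np.ndarray:
        """Transverse physical detector coordinates (at the detector plane
        for fan/cone, at the isocentre for parallel), element 0 negative."""
        pitch = self.det_pitch_um / 1000.0
        return (np.arange(self.n_det) - (self.n_det - 1) / 2.0) * pitch

    def detector_row_coords_mm(self) -> np.ndarray:
        pitch = self.det_pitch_um / 1000.0
        return (np.arange(self.n_det_rows) - (self.n_det_rows - 1) / 2.0) * pitch


@dataclass
class ProjectionSet:
    """Line-integral readings for every view plus their geometry.

    ``data`` shape: (n_angles, n_det) for a single-slice 2-D scan,
    (n_angles, nz, n_det) for a slice stack, (n_angles, n_det_rows, n_det)
    for cone3d.  ``i0``/``frames`` record applied photon noise (None for
    noiseless data).
    """

    data: np.ndarray
    geometry: ScanGeometry
    i0: Optional[float] = None
    frames: Optional[int] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.shape[0] != self.geometry.n_angles:
            raise ValueError("data leading axis must match the number of angles")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("projection data must be finite")


def build_geometry(modality: str, n_angles: int, step_deg: float,
                   start_deg: float = 0.0, n_det: int = 48,
                   det_pitch_um: float = 50.0,
                   sad_mm: float = 50.0, sdd_mm: float = 100.0,
                   vol_shape: tuple = (32, 32), voxel_size_um: float = 25.0,
                   n_det_rows: int = 1) -> ScanGeometry:
    """Uniform-step geometry; angular span is (n_angles - 1) * step_deg."""
    if n_angles < 1:
        raise ValueError("n_angles must be >= 1")
    if step_deg <= 0:
        raise ValueError("step_deg must be positive")
    angles = start_deg + step_deg * np.arange(n_angles)
    geom = ScanGeometry(modality, angles, n_det, det_pitch_um, tuple(vol_shape),
                        voxel_size_um, sad_mm, sdd_mm, n_det_rows)
    # shadow coverage check: the volume's transverse half-diagonal magnified
    # onto the detector must fit within the detector half-width
    ny, nx = geom.vol_shape[-2:]
    half_diag = 0.5 * np.hypot(ny, nx) * voxel_size_um / 1000.0
    half_det_iso = 0.5 * n_det * geom.det_pitch_iso_mm
    if half_det_iso < half_diag:
        warnings.warn(
            f"detector half-width {half_det_iso:.3f} mm (at isocentre) does not "
            f"cover the volume half-diagonal {half_diag:.3f} mm; corners will "
            "be truncated", stacklevel=2)
    return geom


# ---------------------------------------------------------------------------
# Joseph kernel: sparse system-matrix assembly
# ---------------------------------------------------------------------------

def _rays_2d(geom: ScanGeometry, angle_rad: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-detector-element ray origins and unit directions (x, y) in mm."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    u = geom.detector_coords_mm()
    if geom.modality == "parallel2d":
        # detector axis e_u = (c, s), ray direction (-s, c)
        origins = np.stack([u * c, u * s], axis=1)
        dirs = np.broadcast_to(np.array([-s, c]), (geom.n_det, 2)).copy()
        return origins, dirs
    # fan2d: source at R(beta) (0, -SAD); detector centre at R(beta) (0, SDD-SAD)
    src = np.array([s * geom.sad_mm, -c * geom.sad_mm])
    det_c = np.array([-s * (geom.sdd_mm - geom.sad_mm), c * (geom.sdd_mm - geom.sad_mm)])
    e_u = np.array([c, s])
    pts = det_c[None, :] + u[:, None] * e_u[None, :]
    dirs = pts - src[None, :]
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    origins = np.broadcast_to(src, (geom.n_det, 2)).copy()
    return origins, dirs


def _assemble_2d(geom: ScanGeometry) -> sparse.csr_matrix:
    ny, nx = geom.vol_shape[-2:]
    vs = geom.voxel_size_um / 1000.0
    rows, cols, vals = [], [], []
    for ia, ang in enumerate(np.deg2rad(geom.angles_deg)):
        origins, dirs = _rays_2d(geom, ang)
        major_is_y = np.abs(dirs[:, 1]) >= np.abs(dirs[:, 0])
        for flag, n_major, n_minor in ((True, ny, nx), (False, nx, ny)):
            sel = np.nonzero(major_is_y == flag)[0]
            if len(sel) == 0:
                continue
            o, d = origins[sel], dirs[sel]
            maj, mino = (1, 0) if flag else (0, 1)  # indices into (x, y)
            planes = (np.arange(n_major) - (n_major - 1) / 2.0) * vs
            # t such that o + t d crosses each major plane
            t = (planes[None, :] - o[:, maj, None]) / d[:, maj, None]
            m = o[:, mino, None] + t * d[:, mino, None]
            f = m / vs + (n_minor - 1) / 2.0
            i0 = np.floor(f).astype(np.int64)
            w1 = f - i0
            weight = vs / np.abs(d[:, maj])  # path length per plane step
            for tap, wt in ((i0, 1.0 - w1), (i0 + 1, w1)):
                ok = (tap >= 0) & (tap < n_minor)
                if not ok.any():
                    continue
                ray_idx, plane_idx = np.nonzero(ok)
                if flag:  # major axis y: voxel (iy=plane, ix=tap)
                    col = plane_idx * nx + tap[ok]
                else:     # major axis x: voxel (iy=tap, ix=plane)
                    col = tap[ok] * nx + plane_idx
                rows.append(ia * geom.n_det + sel[ray_idx])
                cols.append(col)
                vals.append(wt[ok] * weight[ray_idx])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    A = sparse.coo_matrix((vals, (rows, cols)),
                          shape=(geom.n_angles * geom.n_det, ny * nx))
    return A.tocsr()


def _assemble_cone3d(geom: ScanGeometry) -> sparse.csr_matrix:
    nz, ny, nx = geom.vol_shape
    vs = geom.voxel_size_um / 1000.0
    u = geom.detector_coords_mm()
    v = geom.detector_row_coords_mm()
    rows, cols, vals = [], [], []
    n_rays_per_angle = geom.n_det_rows * geom.n_det
    for ia, ang in enumerate(np.deg2rad(geom.angles_deg)):
        c, s = np.cos(ang), np.sin(ang)
        src = np.array([s * geom.sad_mm, -c * geom.sad_mm, 0.0])  # (x, y, z)
        det_c = np.array([-s * (geom.sdd_mm - geom.sad_mm),
                          c * (geom.sdd_mm - geom.sad_mm), 0.0])
        e_u = np.array([c, s, 0.0])
        e_v = np.array([0.0, 0.0, 1.0])
        uu, vv = np.meshgrid(u, v)  # (n_rows, n_det)
        pts = (det_c[None, :] + uu.ravel()[:, None] * e_u[None, :]
               + vv.ravel()[:, None] * e_v[None, :])
        dirs = pts - src[None, :]
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        # dominant axis is in-plane (x or y) for small cone angles
        major_is_y = np.abs(dirs[:, 1]) >= np.abs(dirs[:, 0])
        for flag in (True, False):
            sel = np.nonzero(major_is_y == flag)[0]
            if len(sel) == 0:
                continue
            d = dirs[sel]
            maj = 1 if flag else 0
            n_major = ny if flag else nx
            n_minor = nx if flag else ny
            planes = (np.arange(n_major) - (n_major - 1) / 2.0) * vs
            t = (planes[None, :] - src[maj]) / d[:, maj, None]
            m = src[1 - maj] + t * d[:, 1 - maj, None]
            zc = src[2] + t * d[:, 2, None]
            fm = m / vs + (n_minor - 1) / 2.0
            fz = zc / vs + (nz - 1) / 2.0
            im = np.floor(fm).astype(np.int64)
            iz = np.floor(fz).astype(np.int64)
            wm = fm - im
            wz = fz - iz
            weight = vs / np.abs(d[:, maj])
            for tm, pwm in ((im, 1.0 - wm), (im + 1, wm)):
                for tz, pwz in ((iz, 1.0 - wz), (iz + 1, wz)):
                    ok = (tm >= 0) & (tm < n_minor) & (tz >= 0) & (tz < nz)
                    if not ok.any():
                        continue
                    ray_idx, plane_idx = np.nonzero(ok)
                    if flag:
                        iy, ix = plane_idx, tm[ok]
                    else:
                        iy, ix = tm[ok], plane_idx
                    col = (tz[ok] * ny + iy) * nx + ix
                    rows.append(ia * n_rays_per_angle + sel[ray_idx])
                    cols.append(col)
                    vals.append(pwm[ok] * pwz[ok] * weight[ray_idx])
    A = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(geom.n_angles * n_rays_per_angle, nz * ny * nx))
    return A.tocsr()


class TomoOperator:
    """Forward/adjoint projection pair for a fixed geometry.

    The Joseph sampling weights are assembled lazily into a cached sparse
    system matrix; ``adjoint`` applies its exact transpose, so the inner
    product identity <A x, y> = <x, A^T y> holds to rounding error.
    """

    def __init__(self, geometry: ScanGeometry):
        self.geometry = geometry
        self._matrix: Optional[sparse.csr_matrix] = None
        self._matrix_T: Optional[sparse.csr_matrix] = None

    @property
    def matrix(self) -> sparse.csr_matrix:
        if self._matrix is None:
            if self.geometry.modality == "cone3d":
                self._matrix = _assemble_cone3d(self.geometry)
            else:
                self._matrix = _assemble_2d(self.geometry)
            self._matrix_T = self._matrix.T.tocsr()
        return self._matrix

    # -- shape plumbing ----------------------------------------------------
    def _check_volume(self, vol: np.ndarray) -> np.ndarray:
        g = self.geometry
        vol = np.asarray(vol, dtype=np.float64)
        if g.modality == "cone3d":
            if vol.shape != tuple(g.vol_shape):
                raise ValueError(f"volume shape {vol.shape} does not match "
                                 f"geometry lattice {tuple(g.vol_shape)}")
        else:
            if vol.shape[-2:] != tuple(g.vol_shape[-2:]) or vol.ndim not in (2, 3):
                raise ValueError(f"volume shape {vol.shape} does not match "
                                 f"geometry lattice {tuple(g.vol_shape)}")
        return vol

    def forward(self, vol: np.ndarray) -> np.ndarray:
        """Volume -> line integrals (dimensionless for attenuation in mm^-1)."""
        g = self.geometry
        vol = self._check_volume(vol)
        A = self.matrix
        if g.modality == "cone3d":
            out = A @ vol.ravel()
            return out.reshape(g.n_angles, g.n_det_rows, g.n_det)
        if vol.ndim == 2:
            return (A @ vol.ravel()).reshape(g.n_angles, g.n_det)
        nz = vol.shape[0]
        out = A @ vol.reshape(nz, -1).T  # (n_rays, nz)
        return out.reshape(g.n_angles, g.n_det, nz).transpose(0, 2, 1)

    def adjoint(self, proj: np.ndarray) -> np.ndarray:
        """Exact transpose of :meth:`forward` (not a filtered backprojection)."""
        g = self.geometry
        proj = np.asarray(proj, dtype=np.float64)
        self.matrix  # ensure assembled
        AT = self._matrix_T
        if g.modality == "cone3d":
            if proj.shape != (g.n_angles, g.n_det_rows, g.n_det):
                raise ValueError("projection shape does not match geometry")
            return (AT @ proj.ravel()).reshape(g.vol_shape)
        ny, nx = g.vol_shape[-2:]
        if proj.shape == (g.n_angles, g.n_det):
            return (AT @ proj.ravel()).reshape(ny, nx)
        if proj.ndim == 3 and proj.shape[0] == g.n_angles and proj.shape[2] == g.n_det:
            nz = proj.shape[1]
            flat = proj.transpose(0, 2, 1).reshape(-1, nz)  # (n_rays, nz)
            return (AT @ flat).T.reshape(nz, ny, nx)
        raise ValueError(f"projection shape {proj.shape} does not match geometry")


def forward_project(volume: VoxelVolume, geometry: ScanGeometry,
                    operator: Optional[TomoOperator] = None) -> ProjectionSet:
    """Ray integrals of attenuation for every view; linear in the volume."""
    if abs(volume.voxel_size_um - geometry.voxel_size_um) > 1e-9:
        raise ValueError("volume voxel size does not match geometry lattice")
    op = operator if operator is not None else TomoOperator(geometry)
    return ProjectionSet(op.forward(volume.data), geometry)


def back_project(projections: ProjectionSet,
                 operator: Optional[TomoOperator] = None) -> VoxelVolume:
    """Exact adjoint of :func:`forward_project` (unfiltered)."""
    geom = projections.geometry
    op = operator if operator is not None else TomoOperator(geom)
    return VoxelVolume(op.adjoint(projections.data), geom.voxel_size_um)


# ---------------------------------------------------------------------------
# photon noise and subsampling
# ---------------------------------------------------------------------------

def add_noise(projections: ProjectionSet, i0: float, frames_m: int = 2,
              seed: int = 0) -> ProjectionSet:
    """Poisson transmitted-count noise with frame averaging.

    For every detector reading p, ``frames_m`` independent Poisson counts
    with mean ``i0 * exp(-p)`` are averaged, clipped at one count to keep the
    logarithm finite, and re-logged to a line integral.
    """
    if not i0 > 0:
        raise ValueError("i0 must be positive")
    if frames_m < 1:
        raise ValueError("frames_m must be >= 1")
    rng = np.random.default_rng(seed)
    lam = i0 * np.exp(-projections.data)
    counts = rng.poisson(lam, size=(frames_m,) + projections.data.shape).astype(np.float64)
    mean_counts = np.clip(counts.mean(axis=0), 1.0, None)
    noisy = np.log(i0 / mean_counts)
    return ProjectionSet(noisy, projections.geometry, i0=float(i0), frames=int(frames_m))


def subsample_projections(projections: ProjectionSet, k: int) -> ProjectionSet:
    """Keep every k-th view starting from the first; ceil(n/k) views remain."""
    if k < 1 or int(k) != k:
        raise ValueError("k must be a positive integer")
    n = projections.geometry.n_angles
    if k > n:
        raise ValueError(f"k={k} exceeds the number of views ({n})")
    if k == 1:
        return ProjectionSet(projections.data.copy(), projections.geometry,
                             projections.i0, projections.frames)
    geom = replace(projections.geometry,
                   angles_deg=projections.geometry.angles_deg[::k].copy())
    return ProjectionSet(projections.data[::k].copy(), geom,
                         projections.i0, projections.frames)


# ---------------------------------------------------------------------------
# Siddon cross-check projector (oracle, not the default kernel)
# ---------------------------------------------------------------------------

def siddon_forward_project(volume: VoxelVolume, geometry: ScanGeometry) -> ProjectionSet:
    """Exact voxel-intersection-length (Siddon) projector, 2-D modalities only.

    Slow (pure Python per ray); retained as an independent cross-check for
    the Joseph kernel on smooth phantoms.
    """
    if geometry.modality not in ("parallel2d", "fan2d"):
        raise ValueError("siddon oracle supports 2-D modalities only")
    vol = volume.data
    if vol.ndim != 2:
        raise ValueError("siddon oracle expects a single 2-D slice")
    ny, nx = geometry.vol_shape[-2:]
    vs = geometry.voxel_size_um / 1000.0
    x_edges = (np.arange(nx + 1) - nx / 2.0) * vs
    y_edges = (np.arange(ny + 1) - ny / 2.0) * vs
    out = np.zeros((geometry.n_angles, geometry.n_det))
    for ia, ang in enumerate(np.deg2rad(geometry.angles_deg)):
        origins, dirs = _rays_2d(geometry, ang)
        for j in range(geometry.n_det):
            o, d = origins[j], dirs[j]
            ts = []
            for edges, oi, di in ((x_edges, o[0], d[0]), (y_edges, o[1], d[1])):
                if abs(di) > 1e-12:
                    ts.append((edges - oi) / di)
            t = np.unique(np.concatenate(ts))
            mid = o[None, :] + 0.5 * (t[:-1] + t[1:])[:, None] * d[None, :]
            ix = np.floor(mid[:, 0] / vs + nx / 2.0).astype(int)
            iy = np.floor(mid[:, 1] / vs + ny / 2.0).astype(int)
            seg = np.diff(t)
            ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny) & (seg > 0)
            out[ia, j] = np.sum(vol[iy[ok], ix[ok]] * seg[ok])
    return ProjectionSet(out, geometry)
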