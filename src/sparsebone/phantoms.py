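"""Synthetic three-material bone phantoms.

The package replaces ex-vivo subchondral bone scans with synthetic volumes
built from three materials: background (air), soft tissue (water-like) and
mineralized bone.  Two families of phantoms are provided:

* analytic primitives (parallel plates, rod lattices) with exactly known
  morphometry, used as oracles for the measurement operators, and
* stochastic trabecular phantoms: an anisotropic Gaussian random field
  thresholded at the quantile that yields a prescribed bone volume fraction,
  with an optional porous subchondral plate on one face.

Cohorts of trabecular phantoms are sampled against per-group morphometric
targets (mean +- SD of BV/TV, Tb.Th, Tb.S, Pl.Th); the mapping from a target
trabecular thickness to the field's correlation length is read from a
calibration table shipped with the package (built once by
``scripts/build_calibration.py``).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
from scipy import ndimage

from .core import VoxelVolume

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "CohortSpec",
    "DEFAULT_GRAY_VALUES",
    "ACLT_TARGETS",
    "CONTROL_TARGETS",
    "make_plate_phantom",
    "make_rod_phantom",
    "make_trabecular_phantom",
    "sample_cohort",
    "corr_len_for_thickness",
]

# Attenuation (mm^-1) of air, water-like soft tissue and mineralized bone at
# a ~50 kVp micro-CT spectrum; the exact values only set image contrast.
DEFAULT_GRAY_VALUES = (0.0, 0.25, 1.5)

# Reference group statistics (mean, SD) used as cohort calibration targets:
# bone volume fraction (%), trabecular thickness (um), trabecular separation
# (um) and subchondral plate thickness (um) for the operated (ACLT) and
# unoperated control groups of the rabbit osteoarthritis model.
ACLT_TARGETS = {
    "bvtv_pct": (47.7, 4.4),
    "tbth_um": (202.9, 18.2),
    "tbs_um": (311.6, 45.0),
    "plth_um": (531.8, 90.7),
}
CONTROL_TARGETS = {
    "bvtv_pct": (51.9, 3.4),
    "tbth_um": (214.7, 16.1),
    "tbs_um": (285.6, 25.9),
    "plth_um": (485.0, 99.7),
}

# Fraction of the transverse field of view occupied by the cylindrical
# sample; the rest is air so that every phantom contains all three classes.
_CYLINDER_RADIUS_FRACTION = 0.42
_MIN_THICKNESS_VOXELS = 3


@dataclass
class PhantomSpec:
    """Parameters of a synthetic phantom.

    ``structure_params`` keys used by the trabecular generator:
    ``bvtv_pct`` (target bone volume fraction, %), ``corr_um`` (structural
    wavelength of the field's oscillatory covariance, um — the Tb.Th + Tb.S
    scale), ``anisotropy`` (z-to-transverse correlation ratio; < 0.8 gives
    transverse plates, > 1.25 gives rods along z, else an isotropic sponge).
    """

    grid_shape: tuple = (64, 32, 32)
    voxel_size_um: float = 25.0
    gray_values: tuple = DEFAULT_GRAY_VALUES
    structure: str = "trabecular"
    structure_params: dict = field(default_factory=dict)
    plate_layer: Optional[dict] = None  # {"thickness_um":..., "pore_fraction":...}
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be three positive voxel counts")
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be positive")
        g = tuple(float(v) for v in self.gray_values)
        if not (g[0] < g[1] < g[2]):
            raise ValueError("gray_values must be strictly increasing")
        self.gray_values = g
        if self.structure not in ("plate", "rod_lattice", "sphere", "trabecular"):
            raise ValueError(f"unknown structure {self.structure!r}")
        bvtv = self.structure_params.get("bvtv_pct")
        if bvtv is not None and not (0.0 < bvtv < 100.0):
            raise ValueError("target BV/TV must lie strictly inside (0, 100) %")


@dataclass
class GroundTruth:
    """Exact per-voxel classes and known morphometry of a phantom.

    ``label_volume`` holds 0 = background, 1 = soft tissue, 2 = bone.
    ``region_masks`` carries the trabecular VOI mask (``"trabecular"``) and,
    when a plate layer exists, the plate mask (``"plate"``).
    ``known_morphometry`` stores values that are exact by construction
    (always BV/TV; Tb.Th/Tb.S for analytic phantoms; the expected EF sign for
    rod/plate lattices).
    """

    label_volume: np.ndarray
    region_masks: dict
    known_morphometry: dict = field(default_factory=dict)

    def bone_mask(self) -> np.ndarray:
        return self.label_volume == 2


@dataclass
class CohortSpec:
    """A group of trabecular phantoms drawn against morphometric targets."""

    group: str  # "aclt" | "control"
    n: int
    targets: dict  # parameter -> (mean, sd)
    base_seed: int = 0
    grid_shape: tuple = (64, 32, 32)
    voxel_size_um: float = 25.0
    gray_values: tuple = DEFAULT_GRAY_VALUES
    anisotropy: float = 0.5
    pore_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        for name, (mean, sd) in self.targets.items():
            if sd < 0:
                raise ValueError(f"SD of {name} must be >= 0")

    @classmethod
    def aclt(cls, n: int = 12, base_seed: int = 0, **kw) -> "CohortSpec":
        return cls("aclt", n, dict(ACLT_TARGETS), base_seed, **kw)

    @classmethod
    def control(cls, n: int = 16, base_seed: int = 1, **kw) -> "CohortSpec":
        return cls("control", n, dict(CONTROL_TARGETS), base_seed, **kw)


# ---------------------------------------------------------------------------
# analytic primitives
# ---------------------------------------------------------------------------

def _to_voxels(um: float, voxel_size_um: float) -> int:
    return int(round(um / voxel_size_um))


def make_plate_phantom(thickness_um: float, spacing_um: float,
                       spec: PhantomSpec) -> tuple[VoxelVolume, GroundTruth]:
    """Parallel bone slabs (normal to z) separated by soft tissue.

    The periodic region [bone, soft] * m starts two voxels above the bottom
    face; the remaining z range is air so all three classes are present.
    The VOI covers exactly the m whole periods, so the ground-truth bone
    volume fraction is thickness / (thickness + spacing) up to voxelization.
    """
    vs = spec.voxel_size_um
    th = _to_voxels(thickness_um, vs)
    sp = _to_voxels(spacing_um, vs)
    if th < _MIN_THICKNESS_VOXELS:
        raise ValueError(
            f"slab thickness {thickness_um} um is below the resolution floor "
            f"of {_MIN_THICKNESS_VOXELS} voxels ({_MIN_THICKNESS_VOXELS * vs} um)")
    if sp < 1:
        raise ValueError("spacing must be at least one voxel")
    nz, ny, nx = spec.grid_shape
    period = th + sp
    z0 = 2
    m = (nz - z0 - 1) // period
    if m < 1:
        raise ValueError("grid too small for one slab period")
    labels = np.zeros(spec.grid_shape, dtype=np.uint8)
    voi = np.zeros(spec.grid_shape, dtype=bool)
    z = z0
    for _ in range(m):
        labels[z:z + th] = 2
        labels[z + th:z + period] = 1
        z += period
    voi[z0:z0 + m * period] = True
    volume = VoxelVolume(np.asarray(spec.gray_values, dtype=np.float64)[labels], vs)
    bvtv = 100.0 * np.count_nonzero(labels[voi] == 2) / np.count_nonzero(voi)
    gt = GroundTruth(
        label_volume=labels,
        region_masks={"trabecular": voi},
        known_morphometry={
            "bvtv_pct": bvtv,
            "tbth_um": th * vs,
            "tbs_um": sp * vs,
            "ef_sign": -1.0,  # slabs are oblate
        },
    )
    return volume, gt


def make_rod_phantom(radius_um: float, pitch_um: float, axis: int,
                     spec: PhantomSpec) -> tuple[VoxelVolume, GroundTruth]:
    """Square lattice of parallel bone cylinders in soft tissue.

    ``axis`` is the rod direction (0 = z, 1 = y, 2 = x).  The VOI covers
    whole lattice cells so the analytic fill fraction pi r^2 / pitch^2 holds
    up to voxelization of the circular cross-section.
    """
    vs = spec.voxel_size_um
    r = radius_um / vs
    p = _to_voxels(pitch_um, vs)
    if r < 2:
        raise ValueError(f"rod radius {radius_um} um is below 2 voxels")
    if pitch_um < 2 * radius_um:
        raise ValueError("pitch smaller than the rod diameter: rods would overlap")
    nz, ny, nx = spec.grid_shape
    # transverse axes (those not along the rods)
    tr = [a for a in range(3) if a != axis]
    n_u, n_v = spec.grid_shape[tr[0]], spec.grid_shape[tr[1]]
    m_u, m_v = n_u // p, n_v // p
    if m_u < 1 or m_v < 1:
        raise ValueError("grid too small for one lattice cell")
    iu = np.arange(n_u)
    iv = np.arange(n_v)
    # offset of each transverse voxel centre to the nearest rod centre;
    # rods are centred on voxel centres (mid-cell) so the discrete inscribed
    # sphere matches the nominal diameter
    du = iu % p - p / 2.0
    dv = iv % p - p / 2.0
    cross = (du[:, None] ** 2 + dv[None, :] ** 2) <= r ** 2
    # tr is in increasing axis order, so expanding at `axis` aligns the
    # cross-section with the transverse axes
    labels = np.where(np.broadcast_to(np.expand_dims(cross, axis), spec.grid_shape),
                      2, 1).astype(np.uint8)
    # air border on a face parallel to the rods keeps three classes without
    # capping the rods (caps would truncate the thickness measure)
    sl = [slice(None)] * 3
    sl[tr[1]] = slice(-1, None)
    border = labels[tuple(sl)]
    border[border == 1] = 0
    voi = np.zeros(spec.grid_shape, dtype=bool)
    voi_slices = [slice(None)] * 3
    voi_slices[tr[0]] = slice(0, m_u * p)
    voi_slices[tr[1]] = slice(0, m_v * p)
    voi[tuple(voi_slices)] = True
    volume = VoxelVolume(np.asarray(spec.gray_values, dtype=np.float64)[labels], vs)
    bvtv = 100.0 * np.count_nonzero(labels[voi] == 2) / np.count_nonzero(voi)
    gt = GroundTruth(
        label_volume=labels,
        region_masks={"trabecular": voi},
        known_morphometry={
            "bvtv_pct": bvtv,
            "bvtv_analytic_pct": 100.0 * np.pi * radius_um ** 2 / pitch_um ** 2,
            "tbth_um": 2.0 * radius_um,
            "ef_sign": +1.0,  # rods are prolate
        },
    )
    return volume, gt


# ---------------------------------------------------------------------------
# stochastic trabecular phantoms
# ---------------------------------------------------------------------------

def _cylinder_mask(shape: tuple) -> np.ndarray:
    nz, ny, nx = shape
    radius = _CYLINDER_RADIUS_FRACTION * min(ny, nx)
    yy = np.arange(ny) - (ny - 1) / 2.0
    xx = np.arange(nx) - (nx - 1) / 2.0
    disc = (yy[:, None] ** 2 + xx[None, :] ** 2) <= radius ** 2
    return np.broadcast_to(disc, shape).copy()


def _punch_pores(slab: np.ndarray, pore_fraction: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Remove random spherical voids until the pore volume fraction is met."""
    if pore_fraction <= 0:
        return slab
    slab = slab.copy()
    target = pore_fraction * np.count_nonzero(slab)
    idx = np.argwhere(slab)
    zz, yy, xx = np.indices(slab.shape, sparse=True)
    removed = 0
    guard = 0
    while removed < target and guard < 10000 and len(idx):
        guard += 1
        c = idx[rng.integers(len(idx))]
        r = rng.uniform(1.0, 2.5)
        ball = ((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2) <= r ** 2
        removed += np.count_nonzero(slab & ball)
        slab[ball] = False
    return slab


def _gabor_kernel(wavelength_vox: float, length: int,
                  env_factor: float = 1.5) -> np.ndarray:
    """Cosine of the given period under a Gaussian envelope, unit L2 norm."""
    half = length // 2
    z = np.arange(-half, length - half)
    env = np.exp(-0.5 * (z / (env_factor * wavelength_vox)) ** 2)
    kern = env * np.cos(2.0 * np.pi * z / wavelength_vox)
    return kern / np.linalg.norm(kern)


def make_trabecular_phantom(spec: PhantomSpec) -> tuple[VoxelVolume, GroundTruth]:
    """Thresholded anisotropic Gaussian random field inside a cylindrical sample.

    The texture model is built from zero-mean stationary Gaussian fields:
    white noise filtered with kernels whose covariance is oscillatory (a
    Gabor kernel of wavelength ``corr_um``) along the structural axes.  The
    ``anisotropy`` ratio selects the architecture:

    * ``anisotropy < 0.8`` — layered plates normal to z (oscillatory
      covariance along z, smooth in-plane) tied together by a sparse set of
      vertical struts from a second, independent rod field; this is the
      plate-and-strut architecture of subchondral trabecular bone and its
      ellipsoid factor comes out negative (oblate-dominant);
    * ``anisotropy > 1.25`` — the mirror image: rods along z (oscillatory
      covariance along both transverse axes) plus sparse connecting plates;
      ellipsoid factor positive (prolate-dominant);
    * otherwise — an isotropic sponge (plain Gaussian smoothing).

    The secondary (strut/connector) component is fixed at 10 % of the bone
    volume; the primary field's threshold is then solved so the union hits
    the target bone volume fraction within the trabecular region exactly
    (up to voxel discretization), which also keeps the network connected —
    isolated layers would otherwise be swept away by the despeckling step
    of the segmentation chain.  An optional porous subchondral plate slab
    occupies the low-z face of the cylinder.
    """
    if spec.structure != "trabecular":
        raise ValueError("spec.structure must be 'trabecular'")
    params = spec.structure_params
    bvtv = float(params.get("bvtv_pct", 50.0))
    if not (0.0 < bvtv < 100.0):
        raise ValueError("target BV/TV is unreachable; must be inside (0, 100) %")
    corr_um = float(params.get("corr_um", 550.0))
    anis = float(params.get("anisotropy", 0.5))
    vs = spec.voxel_size_um
    rng = np.random.default_rng(spec.seed)

    cyl = _cylinder_mask(spec.grid_shape)
    plate = np.zeros(spec.grid_shape, dtype=bool)
    plate_region = np.zeros(spec.grid_shape, dtype=bool)
    z_plate = 0
    if spec.plate_layer is not None:
        z_plate = _to_voxels(spec.plate_layer["thickness_um"], vs)
        if z_plate >= spec.grid_shape[0] - 8:
            raise ValueError("plate layer leaves too little trabecular volume")
        plate_region = cyl.copy()
        plate_region[z_plate:] = False
        plate = _punch_pores(plate_region,
                             spec.plate_layer.get("pore_fraction", 0.05), rng)
    trab_region = cyl.copy()
    trab_region[:z_plate] = False

    lam = corr_um / vs  # structural wavelength in voxels
    target = bvtv / 100.0

    def plate_field(noise: np.ndarray) -> np.ndarray:
        f = ndimage.gaussian_filter(noise, sigma=(0.0, 0.45 * lam, 0.45 * lam),
                                    mode="wrap")
        kern = _gabor_kernel(lam, min(spec.grid_shape[0], int(8 * lam) + 1))
        f = ndimage.convolve1d(f, kern, axis=0, mode="wrap")
        return f / f.std()

    def rod_field(noise: np.ndarray) -> np.ndarray:
        f = ndimage.gaussian_filter(noise, sigma=(0.45 * lam, 0.0, 0.0),
                                    mode="wrap")
        for ax in (1, 2):
            kern = _gabor_kernel(lam, min(spec.grid_shape[ax],
                                          int(8 * lam) + 1))
            f = ndimage.convolve1d(f, kern, axis=ax, mode="wrap")
        return f / f.std()

    n1 = rng.standard_normal(spec.grid_shape)
    n2 = rng.standard_normal(spec.grid_shape)
    if anis < 0.8:  # plates + connecting struts
        primary, secondary = plate_field(n1), rod_field(n2)
    elif anis > 1.25:  # rods + connecting plates
        primary, secondary = rod_field(n1), plate_field(n2)
    else:  # isotropic sponge, no secondary component
        primary = ndimage.gaussian_filter(n1, sigma=0.25 * lam, mode="wrap")
        secondary = None

    if secondary is None:
        thr = np.quantile(primary[trab_region], 1.0 - target)
        bone = trab_region & (primary >= thr)
    else:
        sec_fill = 0.10 * target  # struts take 10 % of the bone volume
        sec = secondary >= np.quantile(secondary[trab_region], 1.0 - sec_fill)
        # bisect the primary fill so the union hits the target exactly
        lo, hi = 0.0, 1.0
        vals = primary[trab_region]
        for _ in range(30):
            mid = 0.5 * (lo + hi)
            cand = sec | (primary >= np.quantile(vals, 1.0 - mid))
            if cand[trab_region].mean() < target:
                lo = mid
            else:
                hi = mid
        bone = trab_region & cand
    bone |= plate

    labels = np.zeros(spec.grid_shape, dtype=np.uint8)
    labels[cyl] = 1
    labels[bone] = 2
    volume = VoxelVolume(np.asarray(spec.gray_values, dtype=np.float64)[labels], vs)
    achieved = 100.0 * np.count_nonzero(labels[trab_region] == 2) / np.count_nonzero(trab_region)
    gt = GroundTruth(
        label_volume=labels,
        # the plate region is the solid slab; the punched pores live only in
        # the label volume (the cleaning chain is expected to refill them)
        region_masks={"trabecular": trab_region, "plate": plate_region},
        known_morphometry={"bvtv_pct": achieved},
    )
    return volume, gt


# ---------------------------------------------------------------------------
# cohort sampling against group targets
# ---------------------------------------------------------------------------

def _load_calibration() -> dict:
    text = resources.files("sparsebone").joinpath("calibration.json").read_text()
    return json.loads(text)


_CALIBRATION_CACHE: Optional[dict] = None


def corr_len_for_thickness(tbth_um: float, bvtv_pct: float) -> float:
    """Invert the shipped calibration table: target Tb.Th -> field correlation
    length (um), interpolated bilinearly over the (BV/TV, corr) sweep grid."""
    global _CALIBRATION_CACHE
    if _CALIBRATION_CACHE is None:
        _CALIBRATION_CACHE = _load_calibration()
    cal = _CALIBRATION_CACHE
    bv_grid = np.asarray(cal["bvtv_grid"], dtype=float)
    corr_grid = np.asarray(cal["corr_grid_um"], dtype=float)
    tbth = np.asarray(cal["tbth_um"], dtype=float)  # shape (n_bv, n_corr)
    bv = float(np.clip(bvtv_pct, bv_grid[0], bv_grid[-1]))
    j = int(np.clip(np.searchsorted(bv_grid, bv) - 1, 0, len(bv_grid) - 2))
    w = (bv - bv_grid[j]) / (bv_grid[j + 1] - bv_grid[j])
    row = (1 - w) * tbth[j] + w * tbth[j + 1]
    # row is monotone increasing in corr; invert by interpolation
    t = float(np.clip(tbth_um, row[0], row[-1]))
    return float(np.interp(t, row, corr_grid))


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float = -np.inf, hi: float = np.inf) -> float:
    """Normal draw truncated at +-3 SD and the physical bounds [lo, hi]."""
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    lo = max(lo, mean - 3 * sd)
    hi = min(hi, mean + 3 * sd)
    for _ in range(100):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def sample_cohort(cohort: CohortSpec) -> list[tuple[VoxelVolume, GroundTruth]]:
    """Draw ``cohort.n`` trabecular phantoms with per-sample morphometric
    parameters from the group's (mean, SD) targets; deterministic under
    ``cohort.base_seed``."""
    ss = np.random.SeedSequence(cohort.base_seed)
    draw_rng = np.random.default_rng(ss)
    phantom_seeds = np.random.SeedSequence(cohort.base_seed + 1).generate_state(cohort.n) % (2 ** 31)
    vs = cohort.voxel_size_um
    out = []
    for i in range(cohort.n):
        bv_m, bv_s = cohort.targets["bvtv_pct"]
        th_m, th_s = cohort.targets["tbth_um"]
        pl_m, pl_s = cohort.targets.get("plth_um", (0.0, 0.0))
        bv = _truncated_normal(draw_rng, bv_m, bv_s, 5.0, 95.0)
        th = _truncated_normal(draw_rng, th_m, th_s, 3 * vs, 20 * vs)
        plate = None
        if pl_m > 0:
            pl = _truncated_normal(draw_rng, pl_m, pl_s, 4 * vs,
                                   (cohort.grid_shape[0] - 12) * vs)
            plate = {"thickness_um": pl, "pore_fraction": cohort.pore_fraction}
        corr = corr_len_for_thickness(th, bv)
        spec = PhantomSpec(
            grid_shape=cohort.grid_shape,
            voxel_size_um=vs,
            gray_values=cohort.gray_values,
            structure="trabecular",
            structure_params={"bvtv_pct": bv, "corr_um": corr,
                              "anisotropy": cohort.anisotropy},
            plate_layer=plate,
            seed=int(phantom_seeds[i]),
        )
        out.append(make_trabecular_phantom(spec))
    return out
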