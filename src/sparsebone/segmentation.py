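"""Grayscale volume -> analysis-ready binary masks.

The processing chain mirrors a standard micro-CT bone workflow: median and
unsharp-mask prefiltering, global 3-D Otsu thresholding, despeckling to the
largest connected object, and — for the subchondral plate — pore filling
plus morphological closing.  Region masks (trabecular VOI and plate) come
from the phantom ground truth for synthetic data, or from user-drawn masks
for external volumes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import VoxelVolume

__all__ = [
    "SegmentationConfig",
    "prefilter",
    "otsu3d",
    "despeckle_keep_largest",
    "clean_plate",
    "segment",
]


@dataclass
class SegmentationConfig:
    median_radius: int = 1
    unsharp_radius: int = 1
    unsharp_amount_pct: float = 50.0
    connectivity: int = 26  # 6 = faces only, 26 = faces+edges+corners
    closing_radius: int = 2
    n_otsu_bins: int = 256

    def __post_init__(self) -> None:
        if self.median_radius < 0 or self.unsharp_radius < 0:
            raise ValueError("filter radii must be >= 0")
        if self.unsharp_amount_pct < 0:
            raise ValueError("unsharp amount must be >= 0")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")


def _structure(ndim: int, connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3,) * ndim, dtype=bool)
    return ndimage.generate_binary_structure(ndim, 1)


def prefilter(volume: VoxelVolume, config: SegmentationConfig) -> VoxelVolume:
    """Median filter (cubic neighbourhood) followed by an unsharp mask.

    The unsharp mask is v + (amount/100) * (v - blur(v)) with a uniform mean
    blur of the same radius.
    """
    data = np.asarray(volume.data, dtype=np.float64)
    if config.median_radius > 0:
        data = ndimage.median_filter(data, size=2 * config.median_radius + 1,
                                     mode="nearest")
    if config.unsharp_radius > 0 and config.unsharp_amount_pct > 0:
        blur = ndimage.uniform_filter(data, size=2 * config.unsharp_radius + 1,
                                      mode="nearest")
        data = data + (config.unsharp_amount_pct / 100.0) * (data - blur)
    return VoxelVolume(data, volume.voxel_size_um)


def otsu3d(volume: VoxelVolume | np.ndarray, n_bins: int = 256) -> float:
    """Global threshold maximizing between-class variance over an n_bins
    histogram of the full volume; ties resolve to the lowest threshold.

    Returns the threshold on the intensity scale (upper edge of the chosen
    cut bin); voxels strictly above it are foreground.
    """
    data = volume.data if isinstance(volume, VoxelVolume) else np.asarray(volume)
    flat = data.ravel().astype(np.float64)
    lo, hi = float(flat.min()), float(flat.max())
    if lo == hi:
        raise ValueError("cannot threshold a constant volume")
    hist, edges = np.histogram(flat, bins=n_bins, range=(lo, hi))
    p = hist.astype(np.float64) / flat.size
    omega = np.cumsum(p)
    mu = np.cumsum(p * np.arange(n_bins))
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b = np.nan_to_num(sigma_b, nan=0.0, posinf=0.0)
    # cut after bin k: classes are bins [0..k] and [k+1..]; argmax ties -> lowest
    k = int(np.argmax(sigma_b[:-1]))
    return float(edges[k + 1])


def despeckle_keep_largest(mask: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Keep only the largest connected foreground component ("sweep").

    Ties resolve to the component containing the first foreground voxel in
    lexicographic (z, y, x) scan order.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("despeckle of an empty mask")
    labels, n = ndimage.label(mask, structure=_structure(mask.ndim, connectivity))
    if n == 1:
        return mask.copy()
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    best = sizes.max()
    candidates = np.nonzero(sizes == best)[0]
    if len(candidates) == 1:
        keep = candidates[0]
    else:
        # earliest voxel in scan order among the tied components
        flat = labels.ravel()
        hits = np.nonzero(np.isin(flat, candidates))[0]
        keep = int(flat[hits.min()])
    return labels == keep


def _ball(radius: int) -> np.ndarray:
    """Discrete ball with the blunted bound d^2 <= r^2 + r.

    The plain Euclidean ball (d^2 <= r^2) has single-voxel tips along the
    axes, which slip into one-voxel surface pits so a closing never fills
    them; the +r slack blunts the tips.
    """
    if radius < 1:
        return np.ones((1, 1, 1), dtype=bool)
    r = int(radius)
    zz, yy, xx = np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1]
    return (zz ** 2 + yy ** 2 + xx ** 2) <= r * (r + 1)


def clean_plate(mask: np.ndarray, config: SegmentationConfig) -> np.ndarray:
    """Fill interior pores, then close edge pores with a ball structuring
    element of ``closing_radius``.

    Interior pores are background components not connected to the volume
    border (scipy's hole filling); the closing then removes notches along
    the plate edges that are smaller than the ball radius.
    """
    mask = np.asarray(mask, dtype=bool)
    filled = ndimage.binary_fill_holes(mask)
    if config.closing_radius > 0:
        selem = _ball(config.closing_radius) if mask.ndim == 3 else None
        if selem is None:
            r = config.closing_radius
            yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
            selem = (yy ** 2 + xx ** 2) <= r ** 2
        filled = ndimage.binary_closing(filled, structure=selem)
        # closing with scipy erodes at the array border; re-add the fill
        filled |= ndimage.binary_fill_holes(mask)
    return filled


def segment(volume: VoxelVolume, region_masks: dict,
            config: SegmentationConfig | None = None
            ) -> tuple[np.ndarray, np.ndarray | None]:
    """Full chain: prefilter -> Otsu -> binarize -> despeckle -> regions.

    ``region_masks`` must hold a nonempty ``"trabecular"`` mask and may hold
    a ``"plate"`` mask.  Each region is despeckled within its own VOI (the
    largest object of the analyzed region, as a per-region sweep) and the
    plate mask is additionally pore-filled and closed.
    """
    config = config or SegmentationConfig()
    trab_region = np.asarray(region_masks.get("trabecular"), dtype=bool)
    if trab_region is None or not trab_region.any():
        raise ValueError("empty or missing trabecular region mask")
    filtered = prefilter(volume, config)
    thr = otsu3d(filtered, config.n_otsu_bins)
    binary = filtered.data > thr
    trab = binary & trab_region
    if trab.any():
        trab = despeckle_keep_largest(trab, config.connectivity)
    plate_out = None
    plate_region = region_masks.get("plate")
    if plate_region is not None and np.asarray(plate_region).any():
        plate_region = np.asarray(plate_region, dtype=bool)
        plate_bin = binary & plate_region
        if plate_bin.any():
            plate_bin = despeckle_keep_largest(plate_bin, config.connectivity)
        plate_out = clean_plate(plate_bin, config) & plate_region
    return trab, plate_out
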