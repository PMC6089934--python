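"""File formats and provenance.

Volumes travel as multi-page TIFF stacks (z-major pages) or NIfTI; the voxel
size (um) rides in a JSON sidecar for TIFF and in the header zooms (mm) for
NIfTI.  Sinograms are HDF5 with the geometry stored as attributes of the
``projections`` dataset.  A :class:`Manifest` records seeds, configuration
and content hashes so any output can be traced and re-run.
"""
from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import tifffile

from .core import VoxelVolume
from .projection import ProjectionSet, ScanGeometry

__all__ = [
    "read_volume",
    "write_volume",
    "read_sinogram",
    "write_sinogram",
    "Manifest",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(volume: VoxelVolume, path) -> Path:
    """Write a volume as TIFF stack (+ JSON sidecar) or NIfTI, by extension."""
    path = Path(path)
    data = volume.data if volume.data.ndim == 3 else volume.data[None]
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, np.ascontiguousarray(data),
                         photometric="minisblack")
        _sidecar(path).write_text(json.dumps(
            {"voxel_size_um": volume.voxel_size_um, "axes": "zyx"}))
    elif path.suffix.lower() == ".nii" or path.name.lower().endswith(".nii.gz"):
        vs_mm = volume.voxel_size_um / 1000.0
        affine = np.diag([vs_mm, vs_mm, vs_mm, 1.0])
        # nibabel expects (x, y, z); our arrays are (z, y, x)
        img = nib.Nifti1Image(np.ascontiguousarray(data.T), affine)
        nib.save(img, path)
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")
    return path


def read_volume(path) -> VoxelVolume:
    """Read a TIFF stack or NIfTI volume; errors if the voxel size is absent."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = np.asarray(tifffile.imread(path))
        side = _sidecar(path)
        if not side.exists():
            raise ValueError(
                f"no voxel-size metadata for {path}: expected sidecar {side}")
        meta = json.loads(side.read_text())
        if "voxel_size_um" not in meta:
            raise ValueError(f"sidecar {side} lacks 'voxel_size_um'")
        return VoxelVolume(data, float(meta["voxel_size_um"]))
    if path.suffix.lower() == ".nii" or path.name.lower().endswith(".nii.gz"):
        img = nib.load(path)
        zooms = img.header.get_zooms()[:3]
        if not zooms or zooms[0] <= 0:
            raise ValueError(f"NIfTI {path} lacks voxel-size zooms")
        data = np.asarray(img.dataobj).T  # back to (z, y, x)
        return VoxelVolume(data, float(zooms[0]) * 1000.0)
    raise ValueError(f"unsupported volume format: {path.suffix}")


_GEOM_ATTRS = ["modality", "n_det", "det_pitch_um", "voxel_size_um",
               "sad_mm", "sdd_mm", "n_det_rows"]


def write_sinogram(projections: ProjectionSet, path) -> Path:
    """HDF5 layout: dataset ``projections`` with geometry/noise attributes."""
    import h5py
    path = Path(path)
    g = projections.geometry
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("projections", data=projections.data)
        ds.attrs["angles_deg"] = g.angles_deg
        ds.attrs["vol_shape"] = np.asarray(g.vol_shape)
        for name in _GEOM_ATTRS:
            ds.attrs[name] = getattr(g, name)
        if projections.i0 is not None:
            ds.attrs["i0"] = projections.i0
            ds.attrs["frames"] = projections.frames
    return path


def read_sinogram(path) -> ProjectionSet:
    import h5py
    with h5py.File(Path(path), "r") as f:
        if "projections" not in f:
            raise ValueError(f"{path} has no 'projections' dataset")
        ds = f["projections"]
        missing = [a for a in _GEOM_ATTRS + ["angles_deg", "vol_shape"]
                   if a not in ds.attrs]
        if missing:
            raise ValueError(f"{path} lacks geometry attributes: {missing}")
        attrs = dict(ds.attrs)
        data = ds[()]
    modality = attrs["modality"]
    if isinstance(modality, bytes):
        modality = modality.decode()
    geom = ScanGeometry(
        modality=str(modality),
        angles_deg=np.asarray(attrs["angles_deg"]),
        n_det=int(attrs["n_det"]),
        det_pitch_um=float(attrs["det_pitch_um"]),
        vol_shape=tuple(int(v) for v in attrs["vol_shape"]),
        voxel_size_um=float(attrs["voxel_size_um"]),
        sad_mm=float(attrs["sad_mm"]),
        sdd_mm=float(attrs["sdd_mm"]),
        n_det_rows=int(attrs["n_det_rows"]),
    )
    i0 = float(attrs["i0"]) if "i0" in attrs else None
    frames = int(attrs["frames"]) if "frames" in attrs else None
    return ProjectionSet(data, geom, i0=i0, frames=frames)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class Manifest:
    """Provenance record for a pipeline run."""

    tool_version: str
    master_seed: int
    config: dict = field(default_factory=dict)
    stage_seeds: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)   # path -> sha256
    outputs: dict = field(default_factory=dict)  # path -> sha256
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(
            datetime.timezone.utc).isoformat())

    def add_input(self, path) -> None:
        self.inputs[str(path)] = _hash_file(Path(path))

    def add_output(self, path) -> None:
        self.outputs[str(path)] = _hash_file(Path(path))

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1,
                                   default=str))
        return path

    @classmethod
    def read(cls, path) -> "Manifest":
        return cls(**json.loads(Path(path).read_text()))
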