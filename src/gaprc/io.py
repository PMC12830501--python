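"""File I/O: NIfTI volumes, kernel archives, sinogram containers.

Volumes are stored as NIfTI with a diagonal mm affine (voxel size on the
diagonal, origin in the translation column); round-trips preserve data and
grid metadata exactly. Kernels and sinograms go into numpy ``.npz`` archives
with JSON-encoded metadata; kernels additionally get a plain-text radial
profile CSV.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .kernels import MaterialSpec, PositronKernel, radial_profile
from .petmodel import ScannerGeometry, Sinogram
from .volumes import ActivityVolume, CTVolume

__all__ = [
    "write_volume", "read_volume", "read_ct", "read_activity",
    "read_volume_pair",
    "write_kernel", "read_kernel", "write_sinogram", "read_sinogram",
    "kernel_hash",
]


def write_volume(path, vol) -> Path:
    path = Path(path)
    affine = np.diag(list(vol.voxel_size) + [1.0])
    affine[:3, 3] = vol.origin
    # NIfTI-2: float64 affine fields, so voxel size and origin round-trip
    # exactly (NIfTI-1 srows are float32)
    img = nib.Nifti2Image(vol.data.astype(np.float64), affine)
    img.header.set_zooms(vol.voxel_size)
    nib.save(img, path)
    return path


def _read(path):
    img = nib.load(str(path))
    affine = img.affine
    data = np.asarray(img.dataobj, dtype=np.float64)
    voxel_size = tuple(float(abs(affine[i, i])) for i in range(3))
    origin = tuple(float(affine[i, 3]) for i in range(3))
    return data, voxel_size, origin


def read_volume(path):
    """Read a NIfTI volume; returns (data, voxel_size, origin)."""
    return _read(path)


def read_ct(path) -> CTVolume:
    return CTVolume(*_read(path))


def read_volume_pair(ct_path, activity_path) -> tuple[CTVolume, "ActivityVolume"]:
    """Read a co-registered CT + activity pair; error if the grids differ."""
    ct = read_ct(ct_path)
    act = read_activity(activity_path)
    if not ct.grid.congruent(act.grid):
        raise ValueError(
            f"paired volumes are on different grids: {ct.grid} vs {act.grid}")
    return ct, act


def read_activity(path) -> ActivityVolume:
    return ActivityVolume(*_read(path))


def kernel_hash(kernel: PositronKernel) -> str:
    return hashlib.sha256(np.ascontiguousarray(kernel.weights).tobytes()).hexdigest()[:16]


def write_kernel(path, kernel: PositronKernel, profile_csv: bool = True) -> Path:
    """Array archive (weights + metadata) plus a radial-profile CSV."""
    path = Path(path)
    meta = {
        "material": {"name": kernel.material.name,
                     "density": kernel.material.density,
                     "hu_ref": kernel.material.hu_ref},
        "voxel_size": list(kernel.voxel_size),
        "half_width": list(kernel.half_width),
        "max_range_mm": kernel.max_range,
        "n_events": kernel.n_events,
        "seed": kernel.seed,
        "sha256_16": kernel_hash(kernel),
        **kernel.meta,
    }
    np.savez(path, weights=kernel.weights, meta=json.dumps(meta))
    if profile_csv:
        prof = radial_profile(kernel)
        prof.to_csv(path.with_suffix(".profile.csv"), index=False)
    return path


def read_kernel(path) -> PositronKernel:
    with np.load(path, allow_pickle=False) as z:
        weights = z["weights"]
        meta = json.loads(str(z["meta"]))
    mat = MaterialSpec(**meta.pop("material"))
    return PositronKernel(
        weights=weights,
        half_width=tuple(meta.pop("half_width")),
        voxel_size=tuple(meta.pop("voxel_size")),
        material=mat,
        max_range=meta.pop("max_range_mm"),
        n_events=meta.pop("n_events"),
        seed=meta.pop("seed"),
        meta=meta,
    )


def write_sinogram(path, sino: Sinogram) -> Path:
    path = Path(path)
    g = sino.geometry
    meta = {
        "geometry": {"n_angles": g.n_angles, "n_radial": g.n_radial,
                     "radial_pitch": g.radial_pitch, "n_planes": g.n_planes},
        "is_noisy": sino.is_noisy,
        "duration_s": sino.duration_s,
        "scale": sino.scale,
        **sino.meta,
    }
    np.savez(path, counts=sino.counts, meta=json.dumps(meta))
    return path


def read_sinogram(path) -> Sinogram:
    with np.load(path, allow_pickle=False) as z:
        counts = z["counts"]
        meta = json.loads(str(z["meta"]))
    g = ScannerGeometry(**meta.pop("geometry"))
    return Sinogram(counts, g, is_noisy=meta.pop("is_noisy"),
                    duration_s=meta.pop("duration_s"),
                    scale=meta.pop("scale"), meta=meta)
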