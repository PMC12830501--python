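"""CT resampling to the PET grid and nearest-neighbour HU tissue classification.

Each PET voxel is assigned to the material whose reference Hounsfield unit is
closest to the voxel's HU (defaults: water 3, lung -695, bone 1226), yielding
mutually exclusive, collectively exhaustive binary tissue masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .kernels import DEFAULT_MATERIALS, MaterialSpec
from .volumes import CTVolume, Grid

__all__ = ["TissueMaskSet", "resample_ct_to_pet", "classify_tissue"]


@dataclass
class TissueMaskSet:
    """Ordered per-tissue binary masks forming a partition of the grid.

    Materials are stored sorted by ascending reference HU (lung, water, bone
    for the defaults) for reproducible serialisation; ``label`` holds the
    per-voxel index into ``materials``.
    """

    materials: tuple[MaterialSpec, ...]
    label: np.ndarray  # int indices into materials
    grid: Grid
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.label = np.asarray(self.label)
        if self.label.shape != tuple(self.grid.shape):
            raise ValueError("label shape does not match grid")
        if self.label.min() < 0 or self.label.max() >= len(self.materials):
            raise ValueError("label values out of range")

    def mask(self, name: str) -> np.ndarray:
        for i, m in enumerate(self.materials):
            if m.name == name:
                return self.label == i
        raise KeyError(name)

    def masks(self):
        """Yield (material, binary mask) pairs in stored order."""
        for i, m in enumerate(self.materials):
            yield m, self.label == i

    @property
    def n(self) -> int:
        return len(self.materials)


def resample_ct_to_pet(ct: CTVolume, pet_grid: Grid) -> CTVolume:
    """Resample the CT volume onto the PET grid.

    If the grids already coincide the data are returned unchanged. When the
    CT is an integer factor finer than the PET grid with aligned extents, HU
    are volume-weighted block-averaged (limits aliasing at tissue boundaries
    before the nearest-neighbour decision); otherwise trilinear interpolation
    on voxel-centre world coordinates is used.
    """
    if ct.grid.congruent(pet_grid):
        return CTVolume(ct.hu.copy(), pet_grid.voxel_size, pet_grid.origin,
                        dict(ct.meta))

    factors = []
    aligned = True
    for a in range(3):
        f = pet_grid.voxel_size[a] / ct.voxel_size[a]
        fi = int(round(f))
        if fi >= 1 and abs(f - fi) < 1e-6 and ct.grid.shape[a] == pet_grid.shape[a] * fi:
            # block start alignment: first pet voxel covers first fi ct voxels
            start_ok = np.isclose(
                pet_grid.origin[a],
                ct.origin[a] + (fi - 1) / 2.0 * ct.voxel_size[a], atol=1e-6)
            aligned = aligned and start_ok
            factors.append(fi)
        else:
            aligned = False
            factors.append(1)
    if aligned and any(f > 1 for f in factors):
        data = ct.hu
        sh = []
        for a in range(3):
            sh.extend([pet_grid.shape[a], factors[a]])
        block = data.reshape(sh).mean(axis=(1, 3, 5))
        return CTVolume(block, pet_grid.voxel_size, pet_grid.origin, dict(ct.meta))

    # general case: trilinear sampling at PET voxel centres
    coords = []
    for a in range(3):
        w = pet_grid.axis_coords(a)
        coords.append((w - ct.origin[a]) / ct.voxel_size[a])
    mesh = np.meshgrid(*coords, indexing="ij")
    out = ndimage.map_coordinates(ct.hu, np.stack(mesh), order=1, mode="nearest")
    return CTVolume(out, pet_grid.voxel_size, pet_grid.origin, dict(ct.meta))


def classify_tissue(
    ct_on_pet: CTVolume,
    materials=DEFAULT_MATERIALS,
) -> TissueMaskSet:
    """Assign each voxel to the material with the nearest reference HU.

    Exact HU midpoints between two references go to the lower-HU material
    (deterministic tie rule; ties are measure-zero on real data).
    """
    mats = tuple(sorted(materials, key=lambda m: m.hu_ref))
    if len(mats) < 1:
        raise ValueError("need at least one material")
    refs = np.array([m.hu_ref for m in mats], dtype=np.float64)
    if len(np.unique(refs)) != len(refs):
        raise ValueError("duplicate hu_ref values")
    dist = np.abs(ct_on_pet.hu[..., None] - refs)
    # argmin returns the first minimum -> with ascending refs the lower-HU
    # material wins exact ties
    label = np.argmin(dist, axis=-1).astype(np.int16)
    return TissueMaskSet(mats, label, ct_on_pet.grid,
                         meta={"hu_refs": {m.name: m.hu_ref for m in mats}})
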