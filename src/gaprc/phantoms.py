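"""Synthetic torso phantom: co-registered CT (HU) and activity (Bq/mL) volumes.

The phantom is an elliptical body with two lung fields, a spine analog and a
liver sub-region, plus spherical lesions reproducing the seven artificial
lesion configurations (tissue type, host region and lesion-to-background
activity ratio) used for the range-correction evaluation. Geometry is defined
relative to the field of view so the same construction works for small test
grids and the full default grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .kernels import BONE, LUNG, WATER, MaterialSpec
from .volumes import ActivityVolume, CTVolume, centered_grid, voxel_centers

__all__ = [
    "REGION_CODES",
    "LesionSpec",
    "TorsoPhantom",
    "make_torso_phantom",
    "table1_lesion_set",
    "rasterize_lesion",
]

REGION_CODES = {"air": 0, "soft": 1, "lung": 2, "bone": 3, "liver": 4}

# Background activity concentration per region (Bq/mL): liver is the
# high-uptake background, lung the low-uptake one.
_REGION_ACTIVITY = {"air": 0.0, "soft": 1000.0, "lung": 300.0, "bone": 600.0,
                    "liver": 3000.0}
_REGION_HU = {"air": -1000.0, "soft": 30.0, "lung": -700.0, "bone": 1200.0,
              "liver": 40.0}
_REGION_HU_JITTER = {"air": 0.0, "soft": 12.0, "lung": 18.0, "bone": 30.0,
                     "liver": 12.0}

_LESION_MATERIALS = {"water": WATER, "lung": LUNG, "bone": BONE}


@dataclass(frozen=True)
class LesionSpec:
    """Spherical lesion: its own tissue type, host region, centre and contrast."""

    name: str
    lesion_tissue: str  # water | lung | bone
    host_region: str    # liver | soft | bone | lung | lung_liver_boundary
    center: tuple[float, float, float]  # mm, world coordinates
    radius: float = 5.0
    activity_ratio: float = 1.0

    def __post_init__(self):
        if not (self.radius > 0):
            raise ValueError("radius must be positive")
        if not (self.activity_ratio > 0):
            raise ValueError("activity_ratio must be positive")
        if self.lesion_tissue not in _LESION_MATERIALS:
            raise ValueError(f"unknown lesion tissue {self.lesion_tissue!r}")

    @property
    def material(self) -> MaterialSpec:
        return _LESION_MATERIALS[self.lesion_tissue]


@dataclass
class TorsoPhantom:
    ct: CTVolume
    activity: ActivityVolume
    labels: np.ndarray  # integer region codes, same grid
    seed: int
    meta: dict = field(default_factory=dict)

    def region_mask(self, name: str) -> np.ndarray:
        return self.labels == REGION_CODES[name]


def make_torso_phantom(
    shape: tuple[int, int, int] = (128, 128, 96),
    voxel_size: tuple[float, float, float] = (2.73, 2.73, 2.80),
    seed: int = 0,
    inhomogeneity: float = 0.10,
) -> TorsoPhantom:
    """Build the torso analog.

    Regions partition the grid (air outside the body). Activity carries a
    smooth +-``inhomogeneity`` multiplicative field so that half-split noise
    subtraction has realistic structure to cancel. Deterministic under seed.
    """
    grid = centered_grid(shape, voxel_size)
    x, y, z = voxel_centers(grid)
    fov = [shape[a] * voxel_size[a] for a in range(3)]
    zn = (z - z.min()) / max(fov[2], 1e-9)  # normalized axial coordinate 0..1

    # body ellipse (in-plane), full axial extent
    ax_body = 0.44 * fov[0]
    ay_body = 0.34 * fov[1]
    body = (x / ax_body) ** 2 + (y / ay_body) ** 2 <= 1.0

    labels = np.zeros(shape, dtype=np.int16)
    labels[body] = REGION_CODES["soft"]

    # two lung fields, upper part of the torso; large relative to the lung
    # positron-range kernel so interior regions exist (as in a real thorax)
    lung_a = (0.17 * fov[0], 0.20 * fov[1], 0.38)
    for sx in (-1.0, 1.0):
        cx = sx * 0.22 * fov[0]
        lungs = ((x - cx) / lung_a[0]) ** 2 + ((y + 0.04 * fov[1]) / lung_a[1]) ** 2 \
            + ((zn - 0.68) / lung_a[2]) ** 2 <= 1.0
        labels[lungs & body] = REGION_CODES["lung"]

    # liver: ellipsoid under the right lung, sharing a boundary with it
    liver = ((x - 0.20 * fov[0]) / (0.21 * fov[0])) ** 2 + (
        (y + 0.02 * fov[1]) / (0.24 * fov[1])) ** 2 + ((zn - 0.26) / 0.30) ** 2 <= 1.0
    labels[liver & body & (labels != REGION_CODES["lung"])] = REGION_CODES["liver"]

    # spine analog: posterior cylinder, full axial extent
    spine = (x ** 2 + (y - 0.24 * fov[1]) ** 2) <= (0.047 * fov[0]) ** 2
    labels[spine & body] = REGION_CODES["bone"]

    rng = np.random.default_rng(seed)
    smooth = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=4.0)
    smooth /= max(np.abs(smooth).max(), 1e-12)

    hu = np.full(shape, _REGION_HU["air"])
    act = np.zeros(shape)
    for name, code in REGION_CODES.items():
        m = labels == code
        hu[m] = _REGION_HU[name] + _REGION_HU_JITTER[name] * smooth[m]
        act[m] = _REGION_ACTIVITY[name] * (1.0 + inhomogeneity * smooth[m])
    act = np.maximum(act, 0.0)

    ct = CTVolume(hu, voxel_size, grid.origin)
    activity = ActivityVolume(act, voxel_size, grid.origin)
    return TorsoPhantom(ct, activity, labels, seed,
                        meta={"fov_mm": fov, "inhomogeneity": inhomogeneity})


# ---------------------------------------------------------------------------
# Lesion placement
# ---------------------------------------------------------------------------

def _interior_point(phantom: TorsoPhantom, mask: np.ndarray,
                    taken: list, min_sep: float) -> tuple[float, float, float]:
    """Deepest interior voxel of ``mask`` at >= min_sep mm from taken centres,
    preferring points near the axial centre of the grid."""
    grid = phantom.ct.grid
    mask = mask.copy()
    # treat the volume border as background so lesions stay off the FOV edge
    for a in range(3):
        sl = [slice(None)] * 3
        sl[a] = 0
        mask[tuple(sl)] = False
        sl[a] = -1
        mask[tuple(sl)] = False
    dist = ndimage.distance_transform_edt(mask, sampling=grid.voxel_size)
    x, y, z = voxel_centers(grid)
    zc = 0.5 * (z.min() + z.max())
    score = dist - 0.02 * np.abs(z - zc)
    score[~mask] = -np.inf
    for c in taken:
        d = np.sqrt((x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2)
        score[d < min_sep] = -np.inf
    idx = np.unravel_index(np.argmax(score), mask.shape)
    if not np.isfinite(score[idx]):
        raise ValueError("no admissible lesion centre in host region")
    return (float(x[idx]), float(y[idx]), float(z[idx]))


def _boundary_point(phantom: TorsoPhantom, region_a: str, region_b: str,
                    taken: list, min_sep: float):
    """Point on the interface between two regions (for the lung-liver lesion)."""
    grid = phantom.ct.grid
    a = phantom.region_mask(region_a)
    b = phantom.region_mask(region_b)
    da = ndimage.distance_transform_edt(~a, sampling=grid.voxel_size)
    db = ndimage.distance_transform_edt(~b, sampling=grid.voxel_size)
    x, y, z = voxel_centers(grid)
    score = -(da + db)
    for c in taken:
        d = np.sqrt((x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2)
        score[d < min_sep] = -np.inf
    idx = np.unravel_index(np.argmax(score), score.shape)
    if not np.isfinite(score[idx]):
        raise ValueError("no admissible boundary lesion centre")
    return (float(x[idx]), float(y[idx]), float(z[idx]))


def table1_lesion_set(
    phantom: TorsoPhantom,
    radius: float = 5.0,
    min_separation: float = 30.0,
) -> list[LesionSpec]:
    """The seven artificial lesion configurations.

    Soft-tissue lesion in liver (3:1), soft-tissue lesion in low-uptake soft
    tissue (16:1), bone lesion in bone (16:1), soft-tissue lesion in bone
    (16:1), soft-tissue lesion inside lung (16:1), soft-tissue lesion between
    lung and liver (10:1), low-contrast soft-tissue lesion inside lung (3:1).
    Centres are chosen at interior maxima of each host region's distance
    transform, at least ``min_separation`` mm apart.
    """
    specs = [
        ("soft_tissue_1", "water", "liver", 3.0),
        ("soft_tissue_2", "water", "soft", 16.0),
        ("bone_1", "bone", "bone", 16.0),
        ("bone_2", "water", "bone", 16.0),
        ("lung_1", "water", "lung", 16.0),
        ("lung_2", "water", "lung_liver_boundary", 10.0),
        ("lung_3", "water", "lung", 3.0),
    ]
    taken: list = []
    lesions = []
    # exclude a margin near the liver for "other soft tissue" hosts
    soft_only = phantom.region_mask("soft")
    soft_only = ndimage.binary_erosion(soft_only, iterations=2)
    for name, tissue, host, ratio in specs:
        if host == "lung_liver_boundary":
            center = _boundary_point(phantom, "lung", "liver", taken, min_separation)
        else:
            mask = soft_only if host == "soft" else phantom.region_mask(host)
            center = _interior_point(phantom, mask, taken, min_separation)
        taken.append(center)
        lesions.append(LesionSpec(name, tissue, host, center, radius, ratio))
    return lesions


def rasterize_lesion(
    lesion: LesionSpec,
    ct: CTVolume,
    act: ActivityVolume,
    background_mean: float | None = None,
) -> tuple[ActivityVolume, CTVolume]:
    """Voxelise a spherical lesion by centre inclusion.

    Voxels whose centres fall inside the sphere receive a homogeneous lesion
    activity of ``activity_ratio`` times the local background mean (the mean
    pre-insertion activity in a 5-10 mm shell around the sphere unless given
    explicitly), and their CT value is set to the lesion tissue's reference
    HU so that the tissue masks update at the lesion location. Returns the
    lesion-only activity volume and the updated CT.
    """
    grid = ct.grid
    if not act.grid.congruent(grid):
        raise ValueError("CT and activity grids differ")
    x, y, z = voxel_centers(grid)
    d = np.sqrt((x - lesion.center[0]) ** 2 + (y - lesion.center[1]) ** 2
                + (z - lesion.center[2]) ** 2)
    inside = d <= lesion.radius
    if not inside.any():
        raise ValueError(f"lesion {lesion.name} contains no voxel centres")
    if (ct.hu[inside] <= -900).all():
        raise ValueError(f"lesion {lesion.name} lies fully outside the body")

    if background_mean is None:
        shell = (d > lesion.radius) & (d <= lesion.radius + 10.0) & (ct.hu > -900)
        if not shell.any():
            raise ValueError(f"no background around lesion {lesion.name}")
        background_mean = float(act.activity[shell].mean())
    lesion_val = lesion.activity_ratio * background_mean

    lesion_act = np.zeros(grid.shape)
    lesion_act[inside] = lesion_val
    new_hu = ct.hu.copy()
    new_hu[inside] = lesion.material.hu_ref
    return (
        ActivityVolume(lesion_act, grid.voxel_size, grid.origin,
                       {"lesion": lesion.name, "background_mean": background_mean,
                        "true_activity": lesion_val}),
        CTVolume(new_hu, grid.voxel_size, grid.origin, dict(ct.meta)),
    )
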