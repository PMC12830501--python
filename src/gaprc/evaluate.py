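"""Lesion quantification: VOIs, SUV_max, CNR, activity recovery, noise.

CNR = (Mean_Lesion - Mean_Background) / SD_Background and activity recovery
= Mean_Lesion / True_Activity * 100%. Noise across reconstructions is
compared with the half-split method: two half-count reconstructions are
subtracted (cancelling spatial uptake structure) and the SD of the
difference is taken over a spherical VOI; no sqrt(2) correction is applied
since values are only compared across reconstructions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import ActivityVolume, Grid, voxel_centers

__all__ = [
    "VOI",
    "LesionMeasurement",
    "gaussian_postfilter",
    "spherical_voi",
    "isocontour_voi",
    "background_voi",
    "lesion_metrics",
    "half_split_noise_sd",
    "filter_lesions",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class VOI:
    """Volume of interest: explicit voxel index set on a grid."""

    kind: str  # sphere | isocontour | freeform
    indices: np.ndarray  # (n, 3) integer voxel indices
    grid: Grid
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.indices.ndim != 2 or self.indices.shape[1] != 3:
            raise ValueError("indices must have shape (n, 3)")
        if self.indices.shape[0] == 0:
            raise ValueError("VOI is empty")
        shp = np.array(self.grid.shape)
        if (self.indices < 0).any() or (self.indices >= shp).any():
            raise ValueError("VOI indices outside grid")

    @property
    def n_voxels(self) -> int:
        return self.indices.shape[0]

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.grid.voxel_volume_mm3

    def as_tuple(self):
        return tuple(self.indices.T)

    def values(self, img: ActivityVolume) -> np.ndarray:
        return img.data[self.as_tuple()]

    def mask(self) -> np.ndarray:
        m = np.zeros(self.grid.shape, dtype=bool)
        m[self.as_tuple()] = True
        return m


@dataclass
class LesionMeasurement:
    """Per-lesion quantification for one reconstruction/filter."""

    lesion_id: str
    tissue_class: str  # soft | bone | lung
    suv_max: float
    mean_lesion: float
    mean_background: float
    sd_background: float
    cnr: float
    volume_cm3: float
    recon_id: str = ""
    filter_fwhm: float = float("nan")
    activity_recovery: float = float("nan")  # %
    patient_id: str = ""


def gaussian_postfilter(img: ActivityVolume, fwhm: float) -> ActivityVolume:
    """Isotropic 3D Gaussian post-filter; sigma = FWHM / (2 sqrt(2 ln 2)) per
    axis in mm, converted to voxels per axis. FWHM 0 is the identity."""
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm == 0:
        return img
    sig = tuple(fwhm * _FWHM_TO_SIGMA / v for v in img.voxel_size)
    out = ndimage.gaussian_filter(img.data, sig, mode="constant", cval=0.0)
    return img.with_data(np.maximum(out, 0.0))


def spherical_voi(center: tuple[float, float, float], radius: float,
                  grid: Grid) -> VOI:
    """Voxels whose centres lie within ``radius`` mm of ``center`` (world mm)."""
    for a in range(3):
        lo = grid.origin[a] - grid.voxel_size[a] / 2.0
        hi = lo + grid.shape[a] * grid.voxel_size[a]
        if not (lo <= center[a] <= hi):
            raise ValueError(f"centre {center} outside grid along axis {a}")
    x, y, z = voxel_centers(grid)
    d2 = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
    idx = np.argwhere(d2 <= radius ** 2)
    return VOI("sphere", idx, grid, {"center": tuple(center), "radius": radius})


def isocontour_voi(img: ActivityVolume, seed_point: tuple[float, float, float],
                   threshold_fraction: float = 0.5) -> VOI:
    """Connected 50%-of-maximum isocontour VOI.

    From the seed point (world mm) a greedy 26-neighbourhood ascent finds the
    local maximum; the VOI is the 26-connected component of voxels >=
    threshold_fraction * that maximum containing it. No background
    correction is applied.
    """
    grid = img.grid
    idx = tuple(
        int(round((seed_point[a] - grid.origin[a]) / grid.voxel_size[a]))
        for a in range(3))
    shp = np.array(grid.shape)
    if any(i < 0 or i >= s for i, s in zip(idx, shp)):
        raise ValueError("seed point outside grid")
    if img.data[idx] <= 0:
        raise ValueError("seed point not inside a positive region")
    # hill climb to the local maximum
    data = img.data
    cur = idx
    while True:
        lo = [max(c - 1, 0) for c in cur]
        hi = [min(c + 2, s) for c, s in zip(cur, shp)]
        patch = data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        best = np.unravel_index(np.argmax(patch), patch.shape)
        nxt = tuple(l + b for l, b in zip(lo, best))
        if data[nxt] <= data[cur]:
            break
        cur = nxt
    peak = data[cur]
    above = data >= threshold_fraction * peak
    labels, _ = ndimage.label(above, structure=np.ones((3, 3, 3)))
    comp = labels == labels[cur]
    return VOI("isocontour", np.argwhere(comp), grid,
               {"seed_point": tuple(seed_point), "threshold": threshold_fraction,
                "peak": float(peak)})


def background_voi(lesion_voi: VOI, tissue_mask: np.ndarray,
                   min_volume_mm3: float = 10.0,
                   min_distance_mm: float = 5.0) -> VOI:
    """Background shell: same-tissue voxels beyond ``min_distance_mm`` from
    the lesion VOI, accumulated nearest-first until ``min_volume_mm3``."""
    grid = lesion_voi.grid
    lesion = lesion_voi.mask()
    dist = ndimage.distance_transform_edt(~lesion, sampling=grid.voxel_size)
    eligible = tissue_mask & ~lesion & (dist > min_distance_mm)
    idx = np.argwhere(eligible)
    if idx.shape[0] == 0:
        raise ValueError("no eligible background voxels")
    order = np.argsort(dist[eligible], kind="stable")
    need = max(1, int(np.ceil(min_volume_mm3 / grid.voxel_volume_mm3)))
    take = idx[order[:need]]
    return VOI("freeform", take, grid,
               {"role": "background", "min_volume_mm3": min_volume_mm3,
                "min_distance_mm": min_distance_mm})


def lesion_metrics(
    img: ActivityVolume,
    lesion_voi: VOI,
    bg_voi: VOI,
    true_activity: float | None = None,
    lesion_id: str = "",
    tissue_class: str = "",
    recon_id: str = "",
    filter_fwhm: float = float("nan"),
    patient_id: str = "",
) -> LesionMeasurement:
    """SUV_max, CNR and (if the true inserted activity is given) recovery."""
    lesion_vals = lesion_voi.values(img)
    bg_vals = bg_voi.values(img)
    mean_l = float(lesion_vals.mean())
    mean_b = float(bg_vals.mean())
    sd_b = float(bg_vals.std(ddof=1)) if bg_vals.size > 1 else float("nan")
    cnr = (mean_l - mean_b) / sd_b if sd_b and np.isfinite(sd_b) and sd_b > 0 \
        else float("nan")
    recovery = float("nan")
    if true_activity is not None:
        if true_activity == 0:
            raise ValueError("true_activity must be nonzero")
        recovery = 100.0 * mean_l / true_activity
    return LesionMeasurement(
        lesion_id=lesion_id,
        tissue_class=tissue_class,
        suv_max=float(lesion_vals.max()),
        mean_lesion=mean_l,
        mean_background=mean_b,
        sd_background=sd_b,
        cnr=float(cnr),
        volume_cm3=lesion_voi.volume_mm3 / 1000.0,
        recon_id=recon_id,
        filter_fwhm=filter_fwhm,
        activity_recovery=recovery,
        patient_id=patient_id,
    )


def half_split_noise_sd(recon_half1: ActivityVolume, recon_half2: ActivityVolume,
                        voi: VOI) -> float:
    """SD of (half1 - half2) over the VOI (no sqrt(2) correction)."""
    if not recon_half1.grid.congruent(recon_half2.grid):
        raise ValueError("half reconstructions are on different grids")
    if voi.n_voxels < 2:
        raise ValueError("SD undefined on a VOI of fewer than 2 voxels")
    diff = recon_half1.data - recon_half2.data
    return float(diff[voi.as_tuple()].std(ddof=1))


def filter_lesions(measurements: list[LesionMeasurement],
                   max_volume_cm3: float = 10.0,
                   max_per_tissue: int = 5) -> list[LesionMeasurement]:
    """Inclusion rules: drop lesions larger than ``max_volume_cm3``; keep at
    most the ``max_per_tissue`` largest per (patient, tissue class)."""
    if not measurements:
        return []
    df = pd.DataFrame(
        {"i": range(len(measurements)),
         "patient": [m.patient_id for m in measurements],
         "tissue": [m.tissue_class for m in measurements],
         "volume": [m.volume_cm3 for m in measurements]})
    df = df[df["volume"] <= max_volume_cm3]
    keep = (
        df.sort_values("volume", ascending=False, kind="stable")
        .groupby(["patient", "tissue"], sort=False)
        .head(max_per_tissue)["i"]
    )
    keep_set = set(keep.tolist())
    return [m for i, m in enumerate(measurements) if i in keep_set]
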