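"""Static-image construction, VOI definition and static SUV biomarkers.

The static biomarkers of amino-acid PET neuro-oncology are computed here:

* ``SUVmax`` — hottest voxel of the 20-40-min summed image within a search
  region;
* ``SUVmean_bg`` — mean SUV of a crescent-shaped background VOI over the
  contralateral, unaffected hemisphere (white + grey matter);
* ``SUVmean_tumor`` — mean SUV of the tumour auto-contour: the 26-connected
  voxel component, seeded at the SUVmax voxel, of all voxels at or above
  ``tbr_cutoff`` times the background mean (default cutoff 1.6);
* ``TBRmax = SUVmax / SUVmean_bg`` and ``TBRmean = SUVmean_tumor / SUVmean_bg``.

An empty auto-contour (lesion max below the cutoff) is a valid outcome and is
reported as ``TBRmean = 0``, ``tumour volume = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .images import DynamicSeries, StaticImage, VoiMask

__all__ = [
    "StaticBiomarkers",
    "sum_static_image",
    "find_suv_max",
    "spherical_voi",
    "crescent_background_voi",
    "suv_mean",
    "autocontour_tumor",
    "static_biomarkers",
]

#: 26-neighbourhood structuring element for 3-D connected components
_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class StaticBiomarkers:
    """Static SUV/TBR biomarkers of one lesion."""

    suv_max: float
    suv_mean_bg: float
    suv_mean_tumor: float  # 0 when the tumour VOI is empty
    tbr_max: float
    tbr_mean: float  # 0 when the tumour VOI is empty
    tumor_volume_ml: float


def sum_static_image(
    series: DynamicSeries, window: tuple[float, float] = (1200.0, 2400.0)
) -> StaticImage:
    """Duration-weighted mean of all frames overlapping ``window`` (seconds).

    Frames partially overlapping the window contribute their overlapping
    duration.  Raises if no frame overlaps the window.
    """
    sched = series.schedule
    lo, hi = float(window[0]), float(window[1])
    overlap = np.minimum(sched.frame_end, hi) - np.maximum(sched.frame_start, lo)
    weights = np.clip(overlap, 0.0, None)
    if weights.sum() <= 0:
        raise ValueError(f"no frame overlaps the window {window}")
    data = np.tensordot(weights, series.voxels, axes=(0, 0)) / weights.sum()
    return StaticImage(data, series.voxel_size, (lo, hi))


def find_suv_max(image: StaticImage, search_mask: VoiMask | None = None):
    """Maximum SUV (and its voxel index) within ``search_mask``.

    Ties are broken toward the lexicographically smallest index.  With no
    mask the whole grid is searched.
    """
    vox = image.voxels
    if search_mask is None:
        masked = vox
    else:
        if search_mask.empty:
            raise ValueError("search mask is empty")
        masked = np.where(search_mask.voxels, vox, -np.inf)
    flat = int(np.argmax(masked))  # first occurrence = lexicographically smallest
    loc = np.unravel_index(flat, vox.shape)
    return float(vox[loc]), tuple(int(i) for i in loc)


def spherical_voi(
    image: StaticImage, center: tuple[int, int, int], diameter_mm: float
) -> VoiMask:
    """Sphere of voxels whose centres lie within ``diameter_mm/2`` of the
    centre voxel's centre (world mm); clipped at the grid edges."""
    if diameter_mm <= 0:
        raise ValueError("diameter must be > 0")
    shape = image.voxels.shape
    if not all(0 <= c < s for c, s in zip(center, shape)):
        raise ValueError("center must lie inside the grid")
    vs = np.asarray(image.voxel_size, float)
    idx = np.indices(shape, dtype=float)
    r2 = sum(((idx[a] - center[a]) * vs[a]) ** 2 for a in range(3))
    return VoiMask(r2 <= (diameter_mm / 2.0) ** 2, kind="sphere")


def crescent_background_voi(
    image: StaticImage,
    hemisphere: str,
    inner_radius_mm: float = 15.0,
    outer_radius_mm: float = 45.0,
    angular_span_deg: float = 90.0,
) -> VoiMask:
    """Crescent background VOI in the stated hemisphere.

    Voxels of the brain volume (SUV > 0) lying between two concentric
    spherical shells centred on the brain-volume centroid, restricted to a
    cone of half-angle ``angular_span_deg / 2`` about the lateral axis of the
    hemisphere (``left`` = -x, ``right`` = +x on axis 0).  Deterministic for
    fixed parameters; raises if the resulting mask is empty.
    """
    if hemisphere not in ("left", "right"):
        raise ValueError("hemisphere must be 'left' or 'right'")
    if not 0 < inner_radius_mm < outer_radius_mm:
        raise ValueError("need 0 < inner_radius < outer_radius")
    if not 0 < angular_span_deg <= 360:
        raise ValueError("angular_span_deg must be in (0, 360]")
    brain = image.voxels > 0
    if not brain.any():
        raise ValueError("image has no brain volume (all voxels zero)")
    vs = np.asarray(image.voxel_size, float)
    centroid = np.asarray(ndimage.center_of_mass(brain), float)
    idx = np.indices(image.voxels.shape, dtype=float)
    delta = [(idx[a] - centroid[a]) * vs[a] for a in range(3)]
    r = np.sqrt(delta[0] ** 2 + delta[1] ** 2 + delta[2] ** 2)
    axis_sign = -1.0 if hemisphere == "left" else 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_angle = np.where(r > 0, axis_sign * delta[0] / np.maximum(r, 1e-12), -1.0)
    half_angle = np.deg2rad(angular_span_deg / 2.0)
    mask = (
        brain
        & (r >= inner_radius_mm)
        & (r <= outer_radius_mm)
        & (cos_angle >= np.cos(half_angle))
    )
    if not mask.any():
        raise ValueError("crescent VOI is empty for these parameters")
    return VoiMask(mask, kind="crescent")


def suv_mean(image: StaticImage, mask: VoiMask) -> float:
    """Arithmetic mean SUV over a non-empty mask."""
    if mask.empty:
        raise ValueError("mask is empty")
    return float(image.voxels[mask.voxels].mean())


def autocontour_tumor(
    image: StaticImage,
    seed_voxel: tuple[int, int, int],
    suv_mean_bg: float,
    tbr_cutoff: float = 1.6,
) -> VoiMask:
    """Threshold-and-grow tumour contour.

    The 26-connected component containing ``seed_voxel`` (normally the SUVmax
    voxel) of the voxel set ``{SUV >= tbr_cutoff * suv_mean_bg}``.  If the
    seed itself is below threshold the contour is empty — a valid outcome.
    """
    if suv_mean_bg <= 0:
        raise ValueError("suv_mean_bg must be > 0")
    above = image.voxels >= tbr_cutoff * suv_mean_bg
    if not above[tuple(seed_voxel)]:
        return VoiMask(np.zeros_like(above), kind="tumor_autocontour")
    labels, _ = ndimage.label(above, structure=_CONN26)
    return VoiMask(labels == labels[tuple(seed_voxel)], kind="tumor_autocontour")


def static_biomarkers(
    image: StaticImage,
    tumor: VoiMask,
    suv_max: float,
    suv_mean_bg: float,
) -> StaticBiomarkers:
    """Assemble SUV/TBR biomarkers from the static image and tumour contour."""
    if suv_mean_bg <= 0:
        raise ValueError("suv_mean_bg must be > 0")
    if tumor.empty:
        suv_mean_tumor = 0.0
    else:
        # mean over a region containing the max voxel cannot exceed the max;
        # clip the last-ulp overshoot pairwise summation produces on
        # constant regions
        suv_mean_tumor = min(suv_mean(image, tumor), float(suv_max))
    return StaticBiomarkers(
        suv_max=float(suv_max),
        suv_mean_bg=float(suv_mean_bg),
        suv_mean_tumor=suv_mean_tumor,
        tbr_max=float(suv_max) / suv_mean_bg,
        tbr_mean=suv_mean_tumor / suv_mean_bg,
        tumor_volume_ml=tumor.volume_ml(image.voxel_size),
    )
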