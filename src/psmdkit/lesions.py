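"""Threshold-based white matter hyperintensity (WMH) quantification.

WMH appear as bright voxels on FLAIR images.  Segmentation is threshold
based: a voxel belongs to the lesion map iff its intensity is strictly
greater than ``k`` times the modal in-brain intensity (default k = 1.40).
Lesions are then partitioned into periventricular (PVH, within a Euclidean
distance of the ventricles) and deep (DWMH) components and into lobar
regions, and volumes are normalised by total intracranial volume (TIV, as a
percentage) and square-root transformed to tame right skew.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt

from .exceptions import EmptyMaskError, ShapeMismatchError
from .skeleton import LabelAtlas

logger = logging.getLogger("psmdkit")

DEFAULT_THRESHOLD_FACTOR = 1.40
DEFAULT_PV_DISTANCE_MM = 10.0
DEFAULT_N_BINS = 256


@dataclass
class LesionQuantResult:
    """WMH segmentation output: mask, threshold provenance and volumes (mm³)."""

    lesion_mask: np.ndarray
    modal_intensity: float
    threshold: float
    total_volume: float
    voxel_volume_mm3: float
    pvh_volume: float | None = None
    dwmh_volume: float | None = None
    lobar_volumes: dict[str, float] | None = None
    unassigned_volume: float | None = None
    normalized_total: float | None = None
    transformed_total: float | None = None
    n_manual_edits: int = field(default=0)


def estimate_modal_intensity(
    image: np.ndarray,
    brain_mask: np.ndarray,
    n_bins: int = DEFAULT_N_BINS,
) -> float:
    """Modal intensity of in-mask voxels via a fixed-bin histogram.

    Bins span the in-mask [min, max]; the mode is the centre of the most
    populated bin, ties broken toward the lower bin.  A constant image returns
    that constant.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    mask = np.asarray(brain_mask) > 0
    if not mask.any():
        raise EmptyMaskError("brain mask is empty")
    values = np.asarray(image, dtype=float)[mask]
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        return vmin
    counts, edges = np.histogram(values, bins=n_bins, range=(vmin, vmax))
    idx = int(np.argmax(counts))  # argmax takes the first (lower) bin on ties
    return float(0.5 * (edges[idx] + edges[idx + 1]))


def segment_wmh(
    image: np.ndarray,
    brain_mask: np.ndarray,
    k: float = DEFAULT_THRESHOLD_FACTOR,
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    n_bins: int = DEFAULT_N_BINS,
) -> LesionQuantResult:
    """Segment WMH as in-mask voxels with intensity > k × modal intensity.

    The inequality is strict: a voxel at exactly ``k`` times the mode is
    excluded.
    """
    if k <= 0:
        raise ValueError("threshold factor k must be positive")
    mask = np.asarray(brain_mask) > 0
    if not mask.any():
        raise EmptyMaskError("brain mask is empty")
    img = np.asarray(image, dtype=float)
    if img.shape != mask.shape:
        raise ShapeMismatchError("image and brain mask shapes differ")
    mode = estimate_modal_intensity(img, mask, n_bins=n_bins)
    threshold = k * mode
    lesion_mask = mask & (img > threshold)
    voxel_volume = float(np.prod(voxel_size_mm))
    return LesionQuantResult(
        lesion_mask=lesion_mask,
        modal_intensity=mode,
        threshold=float(threshold),
        total_volume=float(lesion_mask.sum()) * voxel_volume,
        voxel_volume_mm3=voxel_volume,
    )


def partition_wmh(
    result: LesionQuantResult,
    ventricle_mask: np.ndarray,
    lobar_atlas: LabelAtlas,
    pv_distance_mm: float = DEFAULT_PV_DISTANCE_MM,
    voxel_size_mm: tuple[float, float, float] | None = None,
) -> LesionQuantResult:
    """Split the lesion mask into PVH/DWMH and lobar components (in place).

    A lesion voxel is periventricular iff its Euclidean distance to the
    nearest ventricle voxel is <= ``pv_distance_mm``; an empty ventricle mask
    therefore yields zero PVH.  Lobar volumes follow the atlas label of each
    lesion voxel; label-0 lesion voxels accumulate under ``unassigned_volume``
    with a logged warning.
    """
    vent = np.asarray(ventricle_mask) > 0
    lesion = result.lesion_mask
    if vent.shape != lesion.shape:
        raise ShapeMismatchError("ventricle mask and lesion mask shapes differ")
    lobar_atlas.validate_against(lesion.shape)
    if not lobar_atlas.legend:
        raise ValueError("lobar atlas has an empty legend")

    vv = result.voxel_volume_mm3
    if voxel_size_mm is None:
        # recover isotropic edge length from the stored voxel volume
        edge = vv ** (1.0 / 3.0)
        voxel_size_mm = (edge, edge, edge)

    if vent.any():
        dist = distance_transform_edt(~vent, sampling=voxel_size_mm)
        pvh = lesion & (dist <= pv_distance_mm)
    else:
        pvh = np.zeros_like(lesion)
    dwmh = lesion & ~pvh
    result.pvh_volume = float(pvh.sum()) * vv
    result.dwmh_volume = float(dwmh.sum()) * vv

    labels = lobar_atlas.labels
    lobar: dict[str, float] = {}
    for lab, name in lobar_atlas.legend.items():
        lobar[name] = float((lesion & (labels == lab)).sum()) * vv
    unassigned = float((lesion & (labels == 0)).sum()) * vv
    if unassigned > 0:
        logger.warning(
            "%.1f mm³ of lesion falls outside the lobar atlas (label 0)", unassigned
        )
    result.lobar_volumes = lobar
    result.unassigned_volume = unassigned
    return result


def normalize_and_transform(volume_mm3: float, tiv_mm3: float) -> tuple[float, float]:
    """Normalize a volume to percent of TIV and square-root transform it.

    Returns ``(normalized, transformed)`` with ``normalized = 100 * v / tiv``
    and ``transformed = sqrt(normalized)``.
    """
    if tiv_mm3 <= 0:
        raise ValueError("TIV must be positive")
    if volume_mm3 < 0:
        raise ValueError("volume must be nonnegative")
    normalized = 100.0 * volume_mm3 / tiv_mm3
    return normalized, math.sqrt(normalized)


def apply_manual_edits(
    result: LesionQuantResult,
    add_mask: np.ndarray | None = None,
    remove_mask: np.ndarray | None = None,
) -> LesionQuantResult:
    """Apply expert edit masks by voxelwise override, logging the edit count.

    Mirrors the manual-correction step of expert review: ``add_mask`` voxels
    are forced into the lesion map, ``remove_mask`` voxels forced out.
    Partition and normalisation fields are reset and must be recomputed.
    """
    mask = result.lesion_mask.copy()
    n_edits = 0
    if add_mask is not None:
        add = (np.asarray(add_mask) > 0) & ~mask
        n_edits += int(add.sum())
        mask |= add
    if remove_mask is not None:
        rem = (np.asarray(remove_mask) > 0) & mask
        n_edits += int(rem.sum())
        mask &= ~rem
    logger.info("applied %d manual lesion-mask edits", n_edits)
    result.lesion_mask = mask
    result.total_volume = float(mask.sum()) * result.voxel_volume_mm3
    result.n_manual_edits += n_edits
    result.pvh_volume = result.dwmh_volume = None
    result.lobar_volumes = None
    result.normalized_total = result.transformed_total = None
    return result
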