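"""Peak width of skeletonized mean diffusivity (PSMD).

PSMD summarises the dispersion of mean diffusivity (MD) over the core of the
cerebral white matter: MD values are read off a binary white-matter skeleton,
the skeleton is masked at fractional anisotropy (FA) >= 0.2 to exclude voxels
contaminated by cerebrospinal fluid, and the statistic is the difference
between the 95th and the 5th percentile of the surviving MD values.  A wide
peak indicates heterogeneous, diffusely damaged white matter and is a
candidate marker of cerebral small vessel disease.

The functions here operate on template-space volumes that already share a
grid (the registration and skeleton-projection steps of a TBSS pipeline are
upstream of this package).  Percentiles use linear interpolation between
order statistics at rank ``1 + (n - 1) * q`` — numpy's default — and the
standard deviation uses the n−1 denominator; both conventions are fixed here
because published descriptions of the statistic leave them implicit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .exceptions import EmptySkeletonError, ShapeMismatchError

logger = logging.getLogger("psmdkit")

#: Default FA cutoff below which skeleton voxels are considered CSF-contaminated.
DEFAULT_FA_THRESHOLD = 0.2

#: Default minimum voxel count for a regional peak-width estimate.
DEFAULT_MIN_REGION_VOXELS = 100


@dataclass
class SkeletonBundle:
    """Co-registered MD and FA volumes plus a binary white-matter skeleton.

    Parameters
    ----------
    md : ndarray
        Mean diffusivity in mm²/s, 3-D.
    fa : ndarray
        Fractional anisotropy (dimensionless, in [0, 1] on the skeleton), 3-D.
    skeleton_mask : ndarray
        Binary skeleton, same shape as ``md``.
    voxel_size_mm : tuple of float
        Physical voxel edge lengths in mm.
    """

    md: np.ndarray
    fa: np.ndarray
    skeleton_mask: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        self.md = np.asarray(self.md, dtype=float)
        self.fa = np.asarray(self.fa, dtype=float)
        self.skeleton_mask = np.asarray(self.skeleton_mask) > 0
        if not (self.md.shape == self.fa.shape == self.skeleton_mask.shape):
            raise ShapeMismatchError(
                f"MD {self.md.shape}, FA {self.fa.shape} and skeleton "
                f"{self.skeleton_mask.shape} must share a shape"
            )
        if not self.skeleton_mask.any():
            raise EmptySkeletonError("skeleton mask has no foreground voxels")
        on_skel = self.fa[self.skeleton_mask]
        if on_skel.size and (np.nanmin(on_skel) < 0 or np.nanmax(on_skel) > 1):
            raise ValueError("FA values on the skeleton must lie within [0, 1]")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.md.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))


@dataclass
class LabelAtlas:
    """Integer label volume with a legend mapping label -> region name.

    Label 0 means "unassigned" and must not appear in the legend.
    """

    labels: np.ndarray
    legend: Mapping[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if 0 in self.legend:
            raise ValueError("label 0 is reserved for unassigned voxels")

    def validate_against(self, shape: tuple[int, ...]) -> None:
        if self.labels.shape != tuple(shape):
            raise ShapeMismatchError(
                f"atlas shape {self.labels.shape} does not match volume shape {shape}"
            )
        present = set(np.unique(self.labels).tolist())
        missing = [name for lab, name in self.legend.items() if lab not in present]
        if missing:
            logger.warning("atlas legend regions absent from volume: %s", missing)


@dataclass
class PsmdResult:
    """Peak-width and companion summary statistics of the masked skeleton MD.

    ``psmd = p95 - p5``; mean/SD of MD and FA are computed on the same masked
    voxel multiset (SD with the n−1 denominator).
    """

    psmd: float
    p95: float
    p5: float
    n_voxels: int
    mean_md: float
    sd_md: float
    mean_fa: float
    sd_fa: float

    def as_dict(self) -> dict[str, float]:
        return {
            "psmd": self.psmd,
            "p95": self.p95,
            "p5": self.p5,
            "n_voxels": self.n_voxels,
            "mean_md": self.mean_md,
            "sd_md": self.sd_md,
            "mean_fa": self.mean_fa,
            "sd_fa": self.sd_fa,
        }


@dataclass
class InsufficientRegion:
    """Placeholder for a region with too few surviving skeleton voxels."""

    n_voxels: int
    min_voxels: int = field(default=DEFAULT_MIN_REGION_VOXELS)


def _masked_indices(bundle: SkeletonBundle, fa_threshold: float) -> np.ndarray:
    if not 0 < fa_threshold < 1:
        raise ValueError("fa_threshold must lie in (0, 1)")
    return bundle.skeleton_mask & (bundle.fa >= fa_threshold)


def mask_skeleton(
    bundle: SkeletonBundle, fa_threshold: float = DEFAULT_FA_THRESHOLD
) -> np.ndarray:
    """Return the multiset of MD values on the FA-masked skeleton.

    Voxels enter iff they are on the skeleton AND have FA >= ``fa_threshold``
    (inclusive, following TBSS convention).  Non-finite MD values are excluded
    with a logged count; negative MD values are retained with a warning so the
    masked multiset stays as defined while surfacing data problems.

    Raises
    ------
    EmptySkeletonError
        If no voxel survives masking.
    """
    mask = _masked_indices(bundle, fa_threshold)
    values = bundle.md[mask]
    finite = np.isfinite(values)
    n_dropped = int(values.size - finite.sum())
    if n_dropped:
        logger.warning("excluded %d non-finite MD voxels from the skeleton", n_dropped)
        values = values[finite]
    if values.size == 0:
        raise EmptySkeletonError(
            f"no skeleton voxels survive FA >= {fa_threshold} masking"
        )
    n_negative = int((values < 0).sum())
    if n_negative:
        logger.warning("retaining %d negative MD voxels on the skeleton", n_negative)
    return values


def _psmd_from_values(md_values: np.ndarray, fa_values: np.ndarray) -> PsmdResult:
    p95, p5 = np.percentile(md_values, [95.0, 5.0])
    n = md_values.size
    sd_md = float(np.std(md_values, ddof=1)) if n > 1 else 0.0
    sd_fa = float(np.std(fa_values, ddof=1)) if n > 1 else 0.0
    return PsmdResult(
        psmd=float(p95 - p5),
        p95=float(p95),
        p5=float(p5),
        n_voxels=int(n),
        mean_md=float(np.mean(md_values)),
        sd_md=sd_md,
        mean_fa=float(np.mean(fa_values)),
        sd_fa=sd_fa,
    )


def compute_psmd(
    bundle: SkeletonBundle, fa_threshold: float = DEFAULT_FA_THRESHOLD
) -> PsmdResult:
    """Compute the global peak width of skeletonized mean diffusivity.

    The 95th and 5th percentiles are computed by linear interpolation between
    order statistics at rank ``1 + (n - 1) * q``; ``psmd`` is their
    difference.  Mean and SD of MD and FA are computed over the same masked
    voxel set.
    """
    mask = _masked_indices(bundle, fa_threshold)
    md = bundle.md[mask]
    fa = bundle.fa[mask]
    finite = np.isfinite(md)
    if not finite.all():
        logger.warning("excluded %d non-finite MD voxels", int((~finite).sum()))
        md, fa = md[finite], fa[finite]
    if md.size == 0:
        raise EmptySkeletonError(
            f"no skeleton voxels survive FA >= {fa_threshold} masking"
        )
    if (md < 0).any():
        logger.warning("retaining %d negative MD voxels", int((md < 0).sum()))
    return _psmd_from_values(md, fa)


def compute_regional_psmd(
    bundle: SkeletonBundle,
    atlas: LabelAtlas,
    fa_threshold: float = DEFAULT_FA_THRESHOLD,
    min_voxels: int = DEFAULT_MIN_REGION_VOXELS,
) -> dict[str, PsmdResult | InsufficientRegion]:
    """Peak-width analysis restricted to each atlas region.

    For every legend region the global computation is re-run on the skeleton
    voxels carrying that label.  Regions with fewer than ``min_voxels``
    surviving voxels are reported as :class:`InsufficientRegion` carrying the
    observed count rather than a (noisy) estimate.
    """
    atlas.validate_against(bundle.shape)
    base = _masked_indices(bundle, fa_threshold)
    out: dict[str, PsmdResult | InsufficientRegion] = {}
    for label, name in atlas.legend.items():
        mask = base & (atlas.labels == label)
        md = bundle.md[mask]
        fa = bundle.fa[mask]
        finite = np.isfinite(md)
        md, fa = md[finite], fa[finite]
        if md.size < min_voxels:
            out[name] = InsufficientRegion(n_voxels=int(md.size), min_voxels=min_voxels)
        else:
            out[name] = _psmd_from_values(md, fa)
    return out
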