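"""Synthetic template-space phantoms for the imaging pipeline.

A phantom supplies every volume the downstream stages consume — an MD map,
an FA map, a binary white-matter skeleton, a FLAIR-like image with planted
hyperintense lesions, a brain mask, a ventricle mask and an eight-lobe label
atlas — all on one grid and fully determined by a spec and a seed.

Deliberate simplifications (the statistic under test depends only on the
masked value multiset, not on anatomy):

* the skeleton is a union of axis-aligned one-voxel-thick sheets inside the
  brain mask, not a registered tract skeleton;
* skeleton MD values are Gaussian with ``sigma = target_psmd / (2 * z_95)``
  (z_95 = 1.6449), truncated at zero, so the 95th−5th percentile spread of
  the generating distribution equals ``target_psmd`` exactly;
* FLAIR lesions are spheres in mm space rasterized by centre-of-voxel
  inclusion, with intensity strictly above ``multiplier × background_mode``;
  the background is a clipped Gaussian whose mode is ``background_mode``,
  bounded away from the 1.40× segmentation threshold so planted masks are
  recoverable voxel-exactly;
* the lobar atlas partitions the brain mask into octants labelled
  left/right × frontal/parietal/temporal/occipital.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .exceptions import PlacementError
from .skeleton import LabelAtlas, SkeletonBundle

#: 95th percentile of the standard normal: PSMD of N(mu, s) = 2 * Z95 * s.
Z95 = float(sps.norm.ppf(0.95))

#: legend for the octant atlas; anterior/superior octants are "frontal" etc.
LOBE_LEGEND = {
    1: "left_frontal",
    2: "left_parietal",
    3: "left_temporal",
    4: "left_occipital",
    5: "right_frontal",
    6: "right_parietal",
    7: "right_temporal",
    8: "right_occipital",
}


@dataclass
class PhantomSpec:
    """Parameters of one synthetic phantom.

    ``target_psmd`` and ``md_center`` are in mm²/s; the defaults (peak width
    5.51e-4, centre 7.7e-4) sit at typical memory-clinic cohort means.
    ``lesion_blobs`` is a list of
    ``(center_voxel, radius_mm, intensity_multiplier)``.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    target_psmd: float = 5.51e-4
    md_center: float = 7.7e-4
    skeleton_fraction: float = 0.05
    csf_contamination: float = 0.02
    lesion_blobs: list[tuple[tuple[int, int, int], float, float]] = field(
        default_factory=list
    )
    background_mode: float = 100.0
    seed: int = 0

    def validate(self) -> None:
        if any(s < 16 for s in self.grid_shape):
            raise ValueError("grid_shape axes must all be >= 16")
        if not 0 < self.skeleton_fraction < 0.5:
            raise ValueError("skeleton_fraction must lie in (0, 0.5)")
        if self.target_psmd <= 0:
            raise ValueError("target_psmd must be positive")
        if not 0 <= self.csf_contamination < 1:
            raise ValueError("csf_contamination must lie in [0, 1)")
        for i, (_, radius, mult) in enumerate(self.lesion_blobs):
            if radius <= 0:
                raise ValueError(f"lesion blob {i}: radius must be positive")
            if mult <= 0:
                raise ValueError(f"lesion blob {i}: intensity multiplier must be > 0")


@dataclass
class PhantomVolumes:
    """All volumes generated from one :class:`PhantomSpec`."""

    bundle: SkeletonBundle
    flair: np.ndarray
    brain_mask: np.ndarray
    ventricle_mask: np.ndarray
    atlas: LabelAtlas
    planted_lesion_mask: np.ndarray
    spec: PhantomSpec


def _ellipsoid_mask(shape, center, semiaxes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, c, a in zip(grids, center, semiaxes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def _build_skeleton(brain: np.ndarray, fraction: float, rng) -> np.ndarray:
    """Union of axis-aligned 1-voxel sheets through the brain until the target
    in-brain fraction is reached."""
    shape = brain.shape
    target = int(round(fraction * brain.sum()))
    skel = np.zeros(shape, dtype=bool)
    axes = rng.permutation([0, 1, 2]).tolist()
    # deterministic cycle over shuffled plane indices per axis
    plane_order = {ax: rng.permutation(np.arange(2, shape[ax] - 2)).tolist() for ax in axes}
    i = 0
    while skel.sum() < target:
        ax = axes[i % 3]
        if not plane_order[ax]:
            break
        idx = plane_order[ax].pop()
        sl = [slice(None)] * 3
        sl[ax] = idx
        sheet = np.zeros(shape, dtype=bool)
        sheet[tuple(sl)] = True
        skel |= sheet & brain
        i += 1
    return skel


def generate_phantom(spec: PhantomSpec) -> PhantomVolumes:
    """Generate all template-space volumes for one phantom.

    Identical spec + seed reproduces bit-identical volumes.  Raises
    :class:`PlacementError` naming any lesion blob whose sphere does not fit
    inside the brain mask (outside the ventricles).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.grid_shape)
    center = tuple((s - 1) / 2.0 for s in shape)

    brain = _ellipsoid_mask(shape, center, tuple(0.45 * s for s in shape))
    ventricles = _ellipsoid_mask(
        shape, center, (0.08 * shape[0], 0.18 * shape[1], 0.10 * shape[2])
    )
    ventricles &= brain
    parenchyma = brain & ~ventricles

    skeleton = _build_skeleton(parenchyma, spec.skeleton_fraction, rng)

    # --- FA ---------------------------------------------------------------
    fa = np.zeros(shape)
    fa[brain] = rng.uniform(0.05, 0.6, size=int(brain.sum()))
    n_skel = int(skeleton.sum())
    fa_skel = rng.uniform(0.25, 0.75, size=n_skel)
    n_contam = int(round(spec.csf_contamination * n_skel))
    if n_contam:
        contam_idx = rng.choice(n_skel, size=n_contam, replace=False)
        fa_skel[contam_idx] = rng.uniform(0.02, 0.15, size=n_contam)
    fa[skeleton] = fa_skel
    fa[ventricles] = rng.uniform(0.0, 0.1, size=int(ventricles.sum()))

    # --- MD ---------------------------------------------------------------
    sigma = spec.target_psmd / (2.0 * Z95)
    md = np.zeros(shape)
    md[parenchyma] = np.clip(
        rng.normal(8.0e-4, 1.0e-4, size=int(parenchyma.sum())), 0, None
    )
    md[ventricles] = rng.normal(3.0e-3, 2.0e-4, size=int(ventricles.sum()))
    md[skeleton] = np.clip(rng.normal(spec.md_center, sigma, size=n_skel), 0, None)

    # --- FLAIR ------------------------------------------------------------
    mode = spec.background_mode
    flair = np.zeros(shape)
    # clipped so no background voxel approaches the 1.40 x mode threshold
    flair[brain] = np.clip(
        rng.normal(mode, 0.05 * mode, size=int(brain.sum())),
        0.70 * mode,
        1.30 * mode,
    )
    flair[ventricles] = rng.uniform(0.30 * mode, 0.45 * mode, size=int(ventricles.sum()))

    planted = np.zeros(shape, dtype=bool)
    coords = np.indices(shape).astype(float)
    for i, (blob_center, radius_mm, mult) in enumerate(spec.lesion_blobs):
        d2 = np.zeros(shape)
        for ax in range(3):
            d2 += ((coords[ax] - blob_center[ax]) * spec.voxel_size_mm[ax]) ** 2
        sphere = d2 <= radius_mm**2
        if not sphere.any():
            raise PlacementError(
                f"lesion blob {i} at {blob_center} (r={radius_mm} mm) covers no voxel"
            )
        if (sphere & ~parenchyma).any():
            raise PlacementError(
                f"lesion blob {i} at {blob_center} (r={radius_mm} mm) does not fit"
                " inside the brain parenchyma"
            )
        flair[sphere] = mult * mode * (1.0 + rng.uniform(0.02, 0.08, size=int(sphere.sum())))
        planted |= sphere

    # --- lobar atlas (octants of the brain mask) ---------------------------
    labels = np.zeros(shape, dtype=np.int16)
    x, y, z = np.indices(shape)
    right = x > center[0]
    posterior = y > center[1]
    inferior = z <= center[2]
    octant = np.zeros(shape, dtype=np.int16)
    #  frontal: anterior-superior; parietal: posterior-superior;
    #  temporal: anterior-inferior; occipital: posterior-inferior
    octant[~posterior & ~inferior] = 1
    octant[posterior & ~inferior] = 2
    octant[~posterior & inferior] = 3
    octant[posterior & inferior] = 4
    labels[brain] = (octant + 4 * right.astype(np.int16))[brain]
    atlas = LabelAtlas(labels=labels, legend=dict(LOBE_LEGEND))

    bundle = SkeletonBundle(
        md=md, fa=fa, skeleton_mask=skeleton, voxel_size_mm=spec.voxel_size_mm
    )
    return PhantomVolumes(
        bundle=bundle,
        flair=flair,
        brain_mask=brain,
        ventricle_mask=ventricles,
        atlas=atlas,
        planted_lesion_mask=planted,
        spec=spec,
    )
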