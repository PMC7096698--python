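"""NIfTI and YAML I/O helpers."""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np
import yaml

from .phantom import PhantomVolumes
from .skeleton import LabelAtlas, SkeletonBundle


def save_volume(path: str, data: np.ndarray, voxel_size_mm=(1.0, 1.0, 1.0)) -> None:
    affine = np.diag(list(voxel_size_mm) + [1.0])
    arr = data.astype(np.uint8) if data.dtype == bool else data
    nib.save(nib.Nifti1Image(np.asanyarray(arr), affine), path)


def load_volume(path: str) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, voxel_size


def load_bundle(md_path: str, fa_path: str, skeleton_path: str) -> SkeletonBundle:
    md, vs = load_volume(md_path)
    fa, _ = load_volume(fa_path)
    skel, _ = load_volume(skeleton_path)
    return SkeletonBundle(md=md, fa=fa, skeleton_mask=skel, voxel_size_mm=vs)


def load_atlas(path: str, legend: dict[int, str] | None = None) -> LabelAtlas:
    labels, _ = load_volume(path)
    labels = labels.astype(int)
    if legend is None:
        from .phantom import LOBE_LEGEND

        present = set(np.unique(labels).tolist()) - {0}
        legend = {k: v for k, v in LOBE_LEGEND.items() if k in present}
        legend.update({k: f"region_{k}" for k in present if k not in legend})
    return LabelAtlas(labels=labels, legend=legend)


def save_phantom(out_dir: str, volumes: PhantomVolumes) -> dict[str, str]:
    """Write all phantom volumes as .nii.gz under out_dir; return the paths."""
    os.makedirs(out_dir, exist_ok=True)
    vs = volumes.spec.voxel_size_mm
    paths = {}
    for name, data in [
        ("md", volumes.bundle.md),
        ("fa", volumes.bundle.fa),
        ("skeleton", volumes.bundle.skeleton_mask),
        ("flair", volumes.flair),
        ("brain_mask", volumes.brain_mask),
        ("ventricles", volumes.ventricle_mask),
        ("lobes", volumes.atlas.labels.astype(np.int16)),
        ("planted_lesions", volumes.planted_lesion_mask),
    ]:
        path = os.path.join(out_dir, f"{name}.nii.gz")
        save_volume(path, data, vs)
        paths[name] = path
    return paths


def load_yaml(path: str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(obj: dict, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
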