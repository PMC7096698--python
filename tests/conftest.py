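import numpy as np
import pytest

from psmdkit import (
    CohortSimParams,
    PhantomSpec,
    SkeletonBundle,
    generate_cohort,
    generate_phantom,
)

# two lesion spheres: one close to the ventricles (periventricular), one far (deep)
TWO_BLOBS = [((40, 32, 32), 4.0, 1.6), ((52, 32, 32), 4.0, 1.8)]


@pytest.fixture(scope="session")
def phantom():
    """64³ phantom with two planted lesions."""
    return generate_phantom(PhantomSpec(lesion_blobs=list(TWO_BLOBS), seed=11))


@pytest.fixture(scope="session")
def cohort():
    """Default 145-subject synthetic cohort."""
    return generate_cohort(CohortSimParams(seed=5))


@pytest.fixture()
def make_bundle():
    """Factory: SkeletonBundle of shape (n, 1, 1) from a 1-D MD value array."""

    def _make(md_values, fa=0.5):
        md = np.asarray(md_values, dtype=float).reshape(-1, 1, 1)
        fa_vol = np.full_like(md, fa, dtype=float)
        skel = np.ones_like(md, dtype=bool)
        return SkeletonBundle(md=md, fa=fa_vol, skeleton_mask=skel)

    return _make


def interp_percentile(values, q):
    """Independent brute-force percentile at rank 1 + (n-1) q (sort + interpolate)."""
    v = sorted(values)
    n = len(v)
    h = (n - 1) * q
    lo = int(np.floor(h))
    frac = h - lo
    hi = min(lo + 1, n - 1)
    return v[lo] + (v[hi] - v[lo]) * frac
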