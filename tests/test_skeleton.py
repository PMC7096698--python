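"""Peak-width statistic: masking contract, percentile convention, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import interp_percentile
from psmdkit import (
    EmptySkeletonError,
    LabelAtlas,
    ShapeMismatchError,
    SkeletonBundle,
    compute_psmd,
    compute_regional_psmd,
    mask_skeleton,
)
from psmdkit.skeleton import InsufficientRegion


def _bundle_of(md_values, fa=0.5):
    md = np.asarray(md_values, dtype=float).reshape(-1, 1, 1)
    return SkeletonBundle(
        md=md, fa=np.full_like(md, fa), skeleton_mask=np.ones_like(md, bool)
    )


class TestMaskSkeleton:
    def test_no_exclusion_when_fa_above_threshold(self, make_bundle):
        bundle = make_bundle(np.full(100, 1e-3), fa=0.5)
        assert mask_skeleton(bundle).size == 100

    def test_threshold_partitions_exactly(self):
        md = np.concatenate([np.full(50, 1e-3), np.full(50, 9e-3)]).reshape(-1, 1, 1)
        fa = np.concatenate([np.full(50, 0.5), np.full(50, 0.1)]).reshape(-1, 1, 1)
        bundle = SkeletonBundle(md=md, fa=fa, skeleton_mask=np.ones_like(md, bool))
        values = mask_skeleton(bundle, 0.2)
        assert values.size == 50 and np.all(values == 1e-3)

    def test_matches_voxel_loop_oracle(self):
        rng = np.random.default_rng(42)
        shape = (9, 8, 7)
        md = rng.uniform(1e-4, 2e-3, shape)
        fa = rng.uniform(0, 1, shape)
        skel = rng.random(shape) < 0.5
        bundle = SkeletonBundle(md=md, fa=np.clip(fa, 0, 1), skeleton_mask=skel)
        expected = sum(
            1
            for i in range(shape[0])
            for j in range(shape[1])
            for k in range(shape[2])
            if skel[i, j, k] and fa[i, j, k] >= 0.2
        )
        assert mask_skeleton(bundle, 0.2).size == expected

    def test_empty_after_masking_raises(self, make_bundle):
        bundle = make_bundle(np.full(10, 1e-3), fa=0.1)
        with pytest.raises(EmptySkeletonError):
            mask_skeleton(bundle, 0.2)

    def test_inclusive_fa_boundary(self, make_bundle):
        bundle = make_bundle(np.full(10, 1e-3), fa=0.2)
        assert mask_skeleton(bundle, 0.2).size == 10


class TestComputePsmd:
    def test_constant_field(self, make_bundle):
        res = compute_psmd(make_bundle(np.full(64, 8e-4)))
        assert res.psmd == 0.0
        assert res.mean_md == pytest.approx(8e-4)
        assert res.sd_md == pytest.approx(0.0, abs=1e-15)

    def test_interpolated_order_statistics(self, make_bundle):
        res = compute_psmd(make_bundle(np.arange(1.0, 101.0)))
        assert res.p95 == pytest.approx(95.05)
        assert res.p5 == pytest.approx(5.95)
        assert res.psmd == pytest.approx(89.1)

    def test_oracle_equivalence_small_instances(self, make_bundle):
        rng = np.random.default_rng(7)
        for n in (2, 3, 17, 250, 1000):
            values = rng.lognormal(-7.2, 0.3, n)
            res = compute_psmd(make_bundle(values))
            expected = interp_percentile(values, 0.95) - interp_percentile(values, 0.05)
            assert res.psmd == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        values=st.lists(
            st.floats(1e-5, 1e-2, allow_nan=False), min_size=2, max_size=60
        ),
        c=st.floats(0.1, 10.0),
    )
    def test_scale_equivariance_and_translation(self, values, c):
        base = compute_psmd(_bundle_of(values))
        scaled = compute_psmd(_bundle_of(np.asarray(values) * c))
        assert scaled.psmd == pytest.approx(c * base.psmd, rel=1e-9, abs=1e-15)
        assert scaled.p95 == pytest.approx(c * base.p95, rel=1e-9)
        assert scaled.mean_md == pytest.approx(c * base.mean_md, rel=1e-9)
        assert scaled.sd_md == pytest.approx(c * base.sd_md, rel=1e-9, abs=1e-15)
        shifted = compute_psmd(_bundle_of(np.asarray(values) + c))
        assert shifted.psmd == pytest.approx(base.psmd, rel=1e-9, abs=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        values=st.lists(
            st.floats(1e-4, 1e-2, allow_nan=False), min_size=3, max_size=60
        ),
        c=st.floats(1.0, 5.0),
    )
    def test_mean_preserving_dilation_does_not_shrink_width(self, values, c):
        v = np.asarray(values)
        dilated = v.mean() + c * (v - v.mean())
        assert (
            compute_psmd(_bundle_of(dilated)).psmd
            >= compute_psmd(_bundle_of(v)).psmd - 1e-15
        )

    def test_negative_md_retained_with_warning(self, make_bundle, caplog):
        values = np.array([-1e-4, 2e-4, 3e-4, 4e-4, 5e-4])
        with caplog.at_level("WARNING", logger="psmdkit"):
            res = compute_psmd(make_bundle(values))
        assert res.n_voxels == 5
        assert "negative" in caplog.text

    def test_nonfinite_md_excluded(self, make_bundle):
        values = np.array([np.nan, 2e-4, 3e-4, 4e-4, np.inf, 5e-4])
        assert compute_psmd(make_bundle(values)).n_voxels == 4


class TestRegionalPsmd:
    def _bundle_with_atlas(self, md_a, md_b):
        md = np.concatenate([md_a, md_b]).reshape(-1, 1, 1)
        labels = np.concatenate(
            [np.full(len(md_a), 1), np.full(len(md_b), 2)]
        ).reshape(-1, 1, 1)
        bundle = SkeletonBundle(
            md=md, fa=np.full_like(md, 0.5), skeleton_mask=np.ones_like(md, bool)
        )
        atlas = LabelAtlas(labels=labels, legend={1: "A", 2: "B"})
        return bundle, atlas

    def test_single_label_equals_global(self, make_bundle):
        rng = np.random.default_rng(3)
        bundle = make_bundle(rng.normal(7e-4, 1e-4, 500))
        atlas = LabelAtlas(
            labels=np.ones(bundle.shape, dtype=int), legend={1: "all"}
        )
        regional = compute_regional_psmd(bundle, atlas, min_voxels=1)
        assert regional["all"].psmd == compute_psmd(bundle).psmd

    def test_equal_multisets_give_equal_psmd(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(7e-4, 1e-4, 300)
        bundle, atlas = self._bundle_with_atlas(vals, vals[::-1].copy())
        regional = compute_regional_psmd(bundle, atlas, min_voxels=1)
        assert regional["A"].psmd == pytest.approx(regional["B"].psmd, rel=1e-12)

    def test_uniform_quantile_spread(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(6e-4, 8e-4, 100_000)
        b = rng.uniform(6e-4, 1.2e-3, 100_000)
        bundle, atlas = self._bundle_with_atlas(a, b)
        regional = compute_regional_psmd(bundle, atlas)
        assert regional["A"].psmd == pytest.approx(0.9 * 2e-4, rel=0.02)
        assert regional["B"].psmd == pytest.approx(0.9 * 6e-4, rel=0.02)

    def test_small_region_reported_missing_with_count(self):
        rng = np.random.default_rng(6)
        bundle, atlas = self._bundle_with_atlas(
            rng.normal(7e-4, 1e-4, 500), rng.normal(7e-4, 1e-4, 30)
        )
        regional = compute_regional_psmd(bundle, atlas, min_voxels=100)
        assert isinstance(regional["B"], InsufficientRegion)
        assert regional["B"].n_voxels == 30

    def test_restriction_consistency(self, phantom):
        """Per-region masked multisets over the atlas partition re-assemble the
        global multiset (up to ordering)."""
        bundle, atlas = phantom.bundle, phantom.atlas
        global_vals = np.sort(mask_skeleton(bundle, 0.2))
        pieces = []
        base = bundle.skeleton_mask & (bundle.fa >= 0.2)
        for lab in atlas.legend:
            pieces.append(bundle.md[base & (atlas.labels == lab)])
        pieces.append(bundle.md[base & (atlas.labels == 0)])
        assert np.allclose(np.sort(np.concatenate(pieces)), global_vals)

    def test_shape_mismatch_raises(self, make_bundle):
        bundle = make_bundle(np.full(10, 1e-3))
        atlas = LabelAtlas(labels=np.ones((3, 1, 1), int), legend={1: "A"})
        with pytest.raises(ShapeMismatchError):
            compute_regional_psmd(bundle, atlas)
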