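"""Voxel-wise statistics: t-maps, BH FDR, Z conversion, cluster filtering,
effect sizes and ROI summaries, each against an independent oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from phenopet.petsim import build_atlas
from phenopet.voxelstats import (bh_fdr, classify_d, cluster_extent_filter,
                                 cohens_d_map, roi_summarize, significance_map,
                                 t_to_z, voxelwise_ttest)
from phenopet.volume import LabelAtlas, MaskVolume, VolumeImage


def _vols(arr):
    """(n, x, y, z) array -> list of VolumeImage."""
    return [VolumeImage(a) for a in arr]


def _full_mask(shape):
    return MaskVolume(np.ones(shape, dtype=np.uint8))


class TestVoxelwiseTTest:
    def test_identical_groups_give_t0_p1(self):
        rng = np.random.default_rng(0)
        arr = rng.normal(size=(3, 4, 4, 4))
        stat = voxelwise_ttest(_vols(arr), _vols(arr.copy()),
                               _full_mask((4, 4, 4)))
        np.testing.assert_allclose(stat.t, 0.0, atol=1e-12)
        np.testing.assert_allclose(stat.p, 1.0, atol=1e-12)

    def test_single_voxel_hand_computation(self):
        a = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1, 1)
        b = np.array([3.0, 4.0, 5.0]).reshape(3, 1, 1, 1)
        stat = voxelwise_ttest(_vols(a), _vols(b), _full_mask((1, 1, 1)))
        assert stat.t[0] == pytest.approx(-np.sqrt(6), abs=1e-3)  # -2.449
        assert stat.df == 4

    def test_contrast_swap_flips_t_and_preserves_p(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(4, 3, 3, 3)), rng.normal(1, 1, size=(5, 3, 3, 3))
        m = _full_mask((3, 3, 3))
        ab = voxelwise_ttest(_vols(a), _vols(b), m)
        ba = voxelwise_ttest(_vols(b), _vols(a), m)
        np.testing.assert_allclose(ab.t, -ba.t, rtol=1e-12)
        np.testing.assert_allclose(ab.p, ba.p, rtol=1e-12)

    def test_matches_scipy_per_voxel_loop(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(6, 8, 8, 8))
        b = rng.normal(0.3, 1.2, size=(7, 8, 8, 8))
        stat = voxelwise_ttest(_vols(a), _vols(b), _full_mask((8, 8, 8)))
        t_map = stat.volume("t").data
        p_map = stat.volume("p", background=1.0).data
        flat_a = a.reshape(6, -1)
        flat_b = b.reshape(7, -1)
        for v in range(0, 512, 7):
            ref = stats.ttest_ind(flat_a[:, v], flat_b[:, v])
            assert t_map.ravel()[v] == pytest.approx(ref.statistic, rel=1e-10)
            assert p_map.ravel()[v] == pytest.approx(ref.pvalue, rel=1e-10)

    def test_degenerate_voxels_flagged_not_dropped(self):
        a = np.ones((3, 2, 2, 2))
        b = np.ones((3, 2, 2, 2)) * 1.0
        stat = voxelwise_ttest(_vols(a), _vols(b), _full_mask((2, 2, 2)))
        assert stat.degenerate.all()
        np.testing.assert_allclose(stat.p, 1.0)

    def test_geometry_mismatch_and_small_groups_raise(self):
        a = _vols(np.zeros((2, 3, 3, 3)))
        with pytest.raises(ValueError):
            voxelwise_ttest(a, _vols(np.zeros((2, 4, 4, 4))),
                            _full_mask((3, 3, 3)))
        with pytest.raises(ValueError):
            voxelwise_ttest(a[:1], a, _full_mask((3, 3, 3)))


class TestBHFDR:
    def test_step_up_by_hand(self):
        q = bh_fdr(np.array([0.005, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.015, 0.04, 0.04], atol=1e-12)

    def test_single_p_unchanged(self):
        assert bh_fdr(np.array([0.02]))[0] == pytest.approx(0.02)

    def test_matches_explicit_step_up_on_random_input(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(1e-6, 1, size=500)
        q = bh_fdr(p)
        # independent step-up oracle
        order = np.argsort(p)
        m = p.size
        ranked = p[order] * m / np.arange(1, m + 1)
        expected = np.minimum.accumulate(ranked[::-1])[::-1].clip(max=1)
        np.testing.assert_allclose(q[order], expected, atol=1e-12)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, derandomize=True)
    def test_adjustment_dominates_p_and_is_monotone(self, seed):
        p = np.random.default_rng(seed).uniform(1e-9, 1, size=60)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all() and (q <= 1).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.0, 0.5]))
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.2]))


class TestTtoZ:
    def test_zero_maps_to_zero_and_sign_preserved(self):
        z = t_to_z(np.array([-2.0, 0.0, 2.0]), df=10)
        assert z[1] == 0.0
        assert z[0] == -z[2] < 0

    def test_large_df_limit(self):
        assert t_to_z(np.array([1.96]), df=10_000)[0] == pytest.approx(
            1.96, abs=5e-3)

    def test_against_numeric_integration_of_t_density(self):
        t, df = 2.0, 58
        cdf, _ = integrate.quad(lambda x: stats.t.pdf(x, df), -np.inf, t)
        expected = stats.norm.ppf(cdf)
        assert t_to_z(np.array([t]), df)[0] == pytest.approx(expected, rel=1e-8)

    def test_strictly_increasing(self):
        grid = np.linspace(-6, 6, 101)
        assert (np.diff(t_to_z(grid, df=12)) > 0).all()


class TestClusterFilter:
    def test_49_voxel_component_dropped_50_retained(self):
        sig = np.zeros((20, 20, 20), dtype=np.int8)
        sig[1:8, 1:8, 1] = 1          # 49 voxels, face-connected
        sig[10:15, 10:15, 10:12] = 1  # 50 voxels
        cs = cluster_extent_filter(sig, min_extent=50)
        assert len(cs.clusters) == 1
        assert cs.clusters[0].size == 50

    def test_empty_map_gives_empty_set(self):
        cs = cluster_extent_filter(np.zeros((6, 6, 6), dtype=np.int8))
        assert cs.clusters == []

    def test_opposite_signs_break_contiguity(self):
        sig = np.zeros((10, 10, 10), dtype=np.int8)
        sig[0:5, :6, :2] = 1
        sig[5:10, :6, :2] = -1
        cs = cluster_extent_filter(sig, min_extent=50)
        assert sorted((c.sign, c.size) for c in cs.clusters) == [(-1, 60), (1, 60)]

    def test_filter_never_adds_voxels(self):
        rng = np.random.default_rng(4)
        sig = rng.choice([-1, 0, 1], size=(12, 12, 12),
                         p=[0.1, 0.8, 0.1]).astype(np.int8)
        cs = cluster_extent_filter(sig, min_extent=5)
        mask = cs.voxel_mask(sig.shape)
        assert (sig[mask] != 0).all()
        assert mask.sum() <= (sig != 0).sum()

    def test_unknown_connectivity_rejected(self):
        with pytest.raises(ValueError):
            cluster_extent_filter(np.zeros((3, 3, 3), dtype=np.int8),
                                  connectivity=10)

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, connectivity):
        offsets = _neighbour_offsets(connectivity)
        rng = np.random.default_rng(5)
        for _ in range(20):
            sig = rng.choice([-1, 0, 1], size=(12, 12, 12),
                             p=[0.15, 0.7, 0.15]).astype(np.int8)
            cs = cluster_extent_filter(sig, min_extent=8,
                                       connectivity=connectivity)
            got = {(c.sign, frozenset(map(tuple, c.indices)))
                   for c in cs.clusters}
            expected = _flood_fill_components(sig, offsets, min_size=8)
            assert got == expected


def _neighbour_offsets(connectivity):
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if (connectivity == 6 and order == 1) or \
                   (connectivity == 18 and order <= 2) or connectivity == 26:
                    offs.append((dx, dy, dz))
    return offs


def _flood_fill_components(sig, offsets, min_size):
    """Brute-force BFS connected components of each sign."""
    shape = sig.shape
    seen = np.zeros(shape, dtype=bool)
    comps = set()
    for sign in (1, -1):
        for start in map(tuple, np.argwhere((sig == sign) & ~seen)):
            if seen[start]:
                continue
            stack, comp = [start], set()
            seen[start] = True
            while stack:
                v = stack.pop()
                comp.add(v)
                for o in offsets:
                    w = (v[0] + o[0], v[1] + o[1], v[2] + o[2])
                    if all(0 <= w[i] < shape[i] for i in range(3)) \
                            and sig[w] == sign and not seen[w]:
                        seen[w] = True
                        stack.append(w)
            if len(comp) >= min_size:
                comps.add((sign, frozenset(comp)))
    return comps


class TestEffectSizes:
    def test_formula_and_classes(self):
        assert cohens_d_map(np.array([0.0]), 3, 3)[0] == 0.0
        assert classify_d(0.0) == "moderate"
        d = cohens_d_map(np.array([2.449]), 3, 3)[0]
        assert d == pytest.approx(2.0, abs=1e-3)
        assert classify_d(d) == "very large"
        assert classify_d(1.00) == "large"
        assert classify_d(0.80) == "large"
        assert classify_d(1.20) == "large"
        assert classify_d(-1.5) == "very large"

    def test_linear_in_t(self):
        t = np.linspace(-3, 3, 7)
        np.testing.assert_allclose(cohens_d_map(2 * t, 10, 12),
                                   2 * cohens_d_map(t, 10, 12), rtol=1e-12)

    def test_bad_group_sizes_raise(self):
        with pytest.raises(ValueError):
            cohens_d_map(np.array([1.0]), 0, 3)


class TestROISummary:
    def _atlas_and_stat(self):
        labels = np.zeros((10, 10, 10), dtype=np.int32)
        labels[:5, :5, :4] = 1   # 100 voxels
        labels[6:, 6:, :4] = 2   # 64 voxels
        atlas = LabelAtlas(labels, {1: "A", 2: "B"})
        rng = np.random.default_rng(6)
        a = rng.normal(size=(20, 10, 10, 10))
        b = rng.normal(size=(20, 10, 10, 10))
        b[:, :5, :5, :4] += 2.0  # strong effect confined to ROI A
        from phenopet.preproc import whole_brain_mask
        wbm = whole_brain_mask(atlas)
        stat = voxelwise_ttest(_vols(b), _vols(a), wbm, contrast=("X", "Y"))
        return atlas, wbm, stat

    def test_effect_roi_summarised_null_roi_omitted(self):
        atlas, wbm, stat = self._atlas_and_stat()
        sig = significance_map(stat, alpha=0.05)
        cs = cluster_extent_filter(sig, z=stat.volume("z").data, min_extent=50)
        table = roi_summarize(stat, cs, atlas)
        assert list(table["roi"]) == ["A"]
        row = table.iloc[0]
        assert row["mean_z"] > 0 and row["contrast"] == "X vs Y"
        assert row["n_voxels"] <= 100
        assert row["d_class"] in ("large", "very large")

    def test_constant_z_yields_zero_sd(self):
        labels = np.zeros((8, 8, 8), dtype=np.int32)
        labels[:4, :4, :4] = 1
        atlas = LabelAtlas(labels, {1: "A"})
        mask = MaskVolume((labels > 0).astype(np.uint8))
        from phenopet.voxelstats import StatMap
        n = int(mask.data.sum())
        stat = StatMap(contrast=("X", "Y"), mask=mask,
                       t=np.full(n, 3.0), df=10, p=np.full(n, 0.01),
                       q=np.full(n, 0.02), z=np.full(n, 2.6),
                       d=np.full(n, 1.0), n_a=6, n_b=6,
                       degenerate=np.zeros(n, dtype=bool))
        sig = significance_map(stat, alpha=0.05)
        cs = cluster_extent_filter(sig, min_extent=50)
        table = roi_summarize(stat, cs, atlas)
        assert table.iloc[0]["mean_z"] == pytest.approx(2.6)
        assert table.iloc[0]["sd_z"] == pytest.approx(0.0, abs=1e-12)
        assert table.iloc[0]["d_class"] == "large"

    def test_no_surviving_clusters_gives_empty_table(self):
        atlas, wbm, stat = self._atlas_and_stat()
        cs = cluster_extent_filter(np.zeros(atlas.shape, dtype=np.int8))
        assert roi_summarize(stat, cs, atlas).empty
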