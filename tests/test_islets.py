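"""Islet morphometrics, GTV split, filtering, and Kolmogorov distance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import ks_2samp

from isletsim.islets import (
    EmpiricalDistribution,
    Islet,
    IsletSet,
    ball_volume,
    connected_components,
    equivalent_diameter,
    filter_islets,
    islet_summary,
    kolmogorov_distance,
    split_gtv_islets,
)


def flood_fill_components(mask):
    """Independent 6-connectivity labelling oracle (BFS)."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    comps = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        comp, queue = [], [start]
        seen[start] = True
        while queue:
            v = queue.pop()
            comp.append(v)
            for d in range(3):
                for s in (-1, 1):
                    nb = list(v)
                    nb[d] += s
                    nb = tuple(nb)
                    if (
                        0 <= nb[d] < mask.shape[d]
                        and mask[nb]
                        and not seen[nb]
                    ):
                        seen[nb] = True
                        queue.append(nb)
        comps.append(frozenset(comp))
    return set(comps)


def make_islet(diameter_mm: float) -> Islet:
    vol = ball_volume(diameter_mm)
    return Islet(
        voxels=np.zeros((1, 3), int), volume_mm3=vol, diameter_mm=diameter_mm,
        caliper_mm=diameter_mm, centroid_mm=(0, 0, 0),
    )


class TestConnectedComponents:
    def test_empty_mask(self):
        out = connected_components(np.zeros((4, 4, 4), bool), spacing=0.25)
        assert len(out) == 0

    def test_diagonal_voxels_are_separate(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[0, 0, 0] = mask[1, 1, 0] = True
        assert len(connected_components(mask, spacing=0.25)) == 2

    def test_solid_cube_morphometrics(self):
        mask = np.zeros((6, 6, 6), bool)
        mask[1:5, 1:5, 1:5] = True
        out = connected_components(mask, spacing=0.25)
        assert len(out) == 1
        islet = out.islets[0]
        assert islet.volume_mm3 == pytest.approx(1.0)
        assert islet.diameter_mm == pytest.approx((6 / np.pi) ** (1 / 3))
        assert islet.diameter_mm == pytest.approx(1.2407, abs=1e-4)
        assert islet.caliper_mm == pytest.approx(1.0)
        assert islet.centroid_mm == pytest.approx((0.75, 0.75, 0.75))

    def test_agrees_with_flood_fill(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            mask = rng.random((5, 5, 5)) < 0.4
            out = connected_components(mask, spacing=1.0)
            got = {frozenset(map(tuple, i.voxels)) for i in out}
            assert got == flood_fill_components(mask)

    def test_requires_spacing(self):
        with pytest.raises(ValueError):
            connected_components(np.zeros((2, 2, 2), bool))


class TestGTVSplit:
    def test_large_component_becomes_gtv(self):
        comps = IsletSet([make_islet(6.0), make_islet(2.0)], spacing=0.25)
        gtv, islets = split_gtv_islets(comps)
        assert gtv is not None
        assert [i.diameter_mm for i in islets] == [2.0]

    def test_all_small_gives_empty_gtv(self):
        comps = IsletSet([make_islet(2.0), make_islet(4.9)], spacing=0.25)
        gtv, islets = split_gtv_islets(comps)
        assert gtv is None
        assert len(islets) == 2

    def test_threshold_is_strict(self):
        # exactly 5 mm stays an islet ("above" the threshold means strictly)
        comps = IsletSet([make_islet(5.0)], spacing=0.25)
        gtv, islets = split_gtv_islets(comps)
        assert gtv is None
        assert len(islets) == 1

    def test_no_components_warns(self):
        with pytest.warns(UserWarning, match="no connected component"):
            split_gtv_islets(IsletSet([], spacing=0.25))


class TestFilter:
    def make_component_set(self, voxel_counts, spacing=0.25):
        mask = np.zeros((100, 10, 10), bool)
        x = 0
        for c in voxel_counts:  # one snaking rod per component, gaps between
            for i in range(c):
                mask[x + i // 8, i % 8, 0] = True
            x += c // 8 + 3
        return connected_components(mask, spacing=spacing)

    def test_single_voxel_removed_34_kept(self):
        comps = self.make_component_set([1, 34, 33])
        kept = filter_islets(comps)
        assert sorted(i.voxel_count for i in kept) == [34]
        # 34 * 0.25^3 = 0.53125 >= pi/6 ~ 0.5236; 33 voxels fall short
        assert ball_volume(1.0) == pytest.approx(0.5235987756, abs=1e-9)

    def test_idempotent_and_monotone(self):
        comps = self.make_component_set([1, 20, 34, 40, 60])
        once = filter_islets(comps)
        twice = filter_islets(once)
        assert [i.voxel_count for i in once] == [i.voxel_count for i in twice]
        assert len(once) <= len(comps)

    def test_empty_input(self):
        assert len(filter_islets(IsletSet([], spacing=0.25))) == 0


class TestSummary:
    def test_odd_count(self):
        s = IsletSet([make_islet(d) for d in (1.0, 2.0, 4.0)], 0.25)
        assert islet_summary(s) == (3, 2.0)

    def test_even_count_mean_of_central(self):
        s = IsletSet([make_islet(d) for d in (1.0, 3.0)], 0.25)
        assert islet_summary(s) == (2, 2.0)

    def test_empty(self):
        count, median = islet_summary(IsletSet([], 0.25))
        assert count == 0 and median is None


class TestKolmogorovDistance:
    def test_identical_samples(self):
        assert kolmogorov_distance([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_disjoint_supports(self):
        assert kolmogorov_distance([0.0], [1.0]) == 1.0

    def test_half_overlap(self):
        assert kolmogorov_distance([1.0, 2.0], [2.0, 3.0]) == pytest.approx(0.5)

    def test_matches_scipy(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            a = rng.normal(size=rng.integers(2, 40))
            b = rng.normal(0.3, 1.2, size=rng.integers(2, 40))
            assert kolmogorov_distance(a, b) == pytest.approx(
                ks_2samp(a, b).statistic
            )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            EmpiricalDistribution(np.array([]))

    @settings(derandomize=True, max_examples=60)
    @given(
        a=st.lists(st.floats(-5, 5), min_size=1, max_size=15),
        b=st.lists(st.floats(-5, 5), min_size=1, max_size=15),
        c=st.lists(st.floats(-5, 5), min_size=1, max_size=15),
    )
    def test_metric_properties(self, a, b, c):
        dab = kolmogorov_distance(a, b)
        assert 0.0 <= dab <= 1.0
        assert dab == pytest.approx(kolmogorov_distance(b, a))
        assert dab <= kolmogorov_distance(a, c) + kolmogorov_distance(c, b) + 1e-12

    def test_cdf_step_conventions(self):
        d = EmpiricalDistribution([1.0, 1.0, 2.0, 5.0])
        assert d.cdf(0.5) == 0.0
        assert d.cdf(1.0) == 0.5  # right-continuous at atoms
        assert d.cdf(10.0) == 1.0
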