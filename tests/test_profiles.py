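"""Profile map construction, sorting, orientation, resampling, collectives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rodquant as rq
from rodquant.profiles import ProfileColumn, ProfileMap

SCALE = 14.98


def _make_map(vectors, diameters=None, qualified=None):
    cols = []
    for i, vec in enumerate(vectors):
        fluor = {1: np.asarray(vec[0], dtype=float)}
        if len(vec) > 1:
            fluor[2] = np.asarray(vec[1], dtype=float)
        d = (
            np.asarray(diameters[i], dtype=float)
            if diameters
            else np.ones_like(fluor[1])
        )
        cols.append(
            ProfileColumn(
                cell_id=i + 1,
                fluor=fluor,
                diameter=d,
                qualified=True if qualified is None else qualified[i],
            )
        )
    return ProfileMap(cols, list(range(len(cols))), SCALE)


class TestBuildProfileMap:
    def test_total_signal_matches_pixel_sum_oracle(
        self, clean_scene, clean_cells, clean_pmap
    ):
        """Σ over all profile vectors = Σ pixels inside the dilated contours."""
        from scipy import ndimage

        fl = rq.subtract_modal_background(clean_scene.hyperstack[1])
        union = np.zeros(fl.shape, dtype=bool)
        for c in clean_cells:
            y0, x0, y1, x1 = c.bbox
            union[y0:y1, x0:x1] |= c.mask
        union = ndimage.binary_dilation(union, iterations=4)
        oracle = float(fl[union].sum())
        total = sum(
            col.fluor[1].sum() for col in clean_pmap.columns
        )
        assert total == pytest.approx(oracle, rel=1e-9)
        # and that captures essentially all rendered fluorescence
        assert total == pytest.approx(float(fl.sum()), rel=0.01)

    def test_fluortotal_within_one_percent_of_truth(
        self, clean_scene, clean_cells, clean_pmap
    ):
        # match detected cells to truth rows by axis-midpoint position
        truth = clean_scene.truth
        pos = truth[["x_px", "y_px"]].to_numpy()
        totals = {c.cell_id: c.fluor[1].sum() for c in clean_pmap.columns}
        for c in clean_cells:
            mid = c.axis[len(c.axis) // 2]
            k = int(np.argmin(np.hypot(*(pos - mid).T)))
            expected = truth["molecules_ch1"].iloc[k] * 20.0
            assert totals[c.id] == pytest.approx(expected, rel=0.01)

    def test_ring_profile_peaks_at_axis_midpoint(self, ring_analysis):
        _, _, pmap, results = ring_analysis
        ages = dict(zip(results["cell"], results["age_pct"]))
        checked = 0
        for col in pmap.columns:
            if ages.get(col.cell_id, 0) < 60:
                continue
            peak = int(np.argmax(col.fluor[1]))
            assert abs(peak - (col.length - 1) / 2) <= 2.0
            checked += 1
        assert checked > 5

    def test_zero_channel_gives_zero_vectors(self, clean_cells, clean_scene):
        blank = np.zeros(clean_scene.hyperstack[1].shape)
        pmap = rq.build_profile_map(clean_cells, {1: blank}, SCALE)
        for col in pmap.columns:
            assert np.all(col.fluor[1] == 0.0)

    def test_vector_length_equals_axis_samples(self, clean_cells, clean_pmap):
        by_id = {c.id: c for c in clean_cells}
        for col in clean_pmap.columns:
            assert col.length == len(by_id[col.cell_id].axis)


class TestSortMap:
    def test_sorted_ascending_by_length(self):
        pmap = _make_map([[np.ones(3)], [np.ones(1)], [np.ones(2)]])
        out = rq.sort_map(pmap)
        assert [c.cell_id for c in out.ordered_columns()] == [2, 3, 1]

    def test_stable_for_equal_keys(self):
        pmap = _make_map([[np.ones(2)], [np.ones(2)], [np.ones(2)]])
        out = rq.sort_map(pmap)
        assert [c.cell_id for c in out.ordered_columns()] == [1, 2, 3]

    def test_qualified_only_drops_flagged(self):
        pmap = _make_map(
            [[np.ones(3)], [np.ones(1)], [np.ones(2)]],
            qualified=[True, False, True],
        )
        out = rq.sort_map(pmap, qualified_only=True)
        assert len(out) == 2

    def test_sort_by_results_column(self):
        pmap = _make_map([[np.ones(2)], [np.ones(2)]])
        out = rq.sort_map(pmap, key={1: 5.0, 2: 1.0})
        assert [c.cell_id for c in out.ordered_columns()] == [2, 1]


class TestOrientByLeader:
    def test_coflip_of_follower(self):
        pmap = _make_map([[[1, 2, 3], [9, 0, 0]]])
        out = rq.orient_by_leader(pmap, 1)
        col = out.columns[0]
        np.testing.assert_array_equal(col.fluor[1], [3, 2, 1])
        np.testing.assert_array_equal(col.fluor[2], [0, 0, 9])
        assert col.flipped

    def test_symmetric_tie_keeps_orientation(self):
        pmap = _make_map([[[1, 2, 1]]])
        out = rq.orient_by_leader(pmap, 1)
        np.testing.assert_array_equal(out.columns[0].fluor[1], [1, 2, 1])
        assert not out.columns[0].flipped

    def test_idempotent(self):
        rng = np.random.default_rng(51)
        pmap = _make_map([[rng.random(7)] for _ in range(10)])
        once = rq.orient_by_leader(pmap, 1)
        twice = rq.orient_by_leader(once, 1)
        for a, b in zip(once.columns, twice.columns):
            np.testing.assert_array_equal(a.fluor[1], b.fluor[1])

    def test_independent_follower_stays_symmetric(self):
        """Polar leader + independent symmetric follower: after orienting by
        the leader, the collective follower profile keeps its symmetry."""
        rng = np.random.default_rng(52)
        vectors = []
        n = 400
        for _ in range(n):
            m = 50
            x = np.arange(m) / (m - 1)
            leader = np.exp(-x / 0.15)  # bright pole
            if rng.random() < 0.5:
                leader = leader[::-1]  # random acquisition orientation
            follower = np.exp(-((x - 0.5) ** 2) / 0.02) + 0.1 * rng.random(m)
            vectors.append([leader, follower])
        pmap = _make_map(vectors)
        out = rq.orient_by_leader(pmap, 1)
        mean_follower = np.mean(
            [c.fluor[2] for c in out.columns], axis=0
        )
        asym = np.abs(mean_follower - mean_follower[::-1]).max()
        assert asym < 0.05 * mean_follower.max()
        # while the leader is now asymmetric by construction
        mean_leader = np.mean([c.fluor[1] for c in out.columns], axis=0)
        assert mean_leader[:10].sum() > 2 * mean_leader[-10:].sum()


class TestResampleToNorm:
    def test_small_profile_conserves_total(self):
        out = rq.resample_to_norm(np.array([2.0, 2.0, 4.0]), 100)
        assert out.shape == (100,)
        assert out.sum() == pytest.approx(8.0, abs=1e-12)

    def test_constant_profile_stays_constant(self):
        out = rq.resample_to_norm(np.full(7, 3.0), 100)
        np.testing.assert_allclose(out, out[0])

    def test_delta_mass_confined_to_adjacent_bins(self):
        v = np.zeros(10)
        v[4] = 5.0
        out = rq.resample_to_norm(v, 100)
        hot = np.nonzero(out > 1e-12)[0]
        assert len(hot) <= int(np.ceil(100 / 10)) + 1
        assert np.all(np.diff(hot) == 1)
        assert out.sum() == pytest.approx(5.0)

    def test_degenerate_length_raises(self):
        with pytest.raises(ValueError):
            rq.resample_to_norm(np.array([1.0]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0, max_value=1e6, allow_nan=False),
            min_size=2,
            max_size=300,
        ),
        st.integers(min_value=2, max_value=250),
    )
    def test_conservation_property(self, values, npoints):
        v = np.asarray(values)
        out = rq.resample_to_norm(v, npoints)
        assert len(out) == npoints
        assert out.sum() == pytest.approx(v.sum(), rel=1e-12, abs=1e-9)

    def test_mean_commutes_with_resampling_for_equal_lengths(self):
        rng = np.random.default_rng(53)
        profs = rng.random((20, 37))
        a = rq.resample_to_norm(profs.mean(axis=0), 100)
        b = np.mean([rq.resample_to_norm(p, 100) for p in profs], axis=0)
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestCollectiveProfiles:
    def test_ten_age_groups_yield_ten_profiles(self, ring_analysis):
        _, _, pmap, results = ring_analysis
        ages = dict(zip(results["cell"], results["age_pct"]))
        stack, counts = rq.collective_profiles(pmap, 1, ages, n_age_groups=10)
        assert stack.shape == (10, 100)
        assert counts.sum() == len(pmap)

    def test_single_group_is_grand_mean(self, ring_analysis):
        _, _, pmap, results = ring_analysis
        ages = dict(zip(results["cell"], results["age_pct"]))
        stack, _ = rq.collective_profiles(pmap, 1, ages, n_age_groups=1)
        expected = np.mean(
            [rq.resample_to_norm(c.fluor[1], 100) for c in pmap.columns],
            axis=0,
        )
        np.testing.assert_allclose(stack[0], expected)

    def test_ring_appears_only_after_programmed_onset(self, ring_analysis):
        """Ring pattern switched on at age 0.5: central peak only in the
        older half of the age groups."""
        _, _, pmap, results = ring_analysis
        ages = dict(zip(results["cell"], results["age_pct"]))
        stack, counts = rq.collective_profiles(pmap, 1, ages, n_age_groups=10)

        def central_fraction(p):
            total = np.nansum(p)
            return np.nansum(p[40:60]) / total if total > 0 else 0.0

        young = [central_fraction(stack[g]) for g in range(4) if counts[g]]
        old = [central_fraction(stack[g]) for g in (6, 7, 8) if counts[g]]
        assert max(young) < 0.35
        assert min(old) > 0.6

    def test_empty_group_is_nan_with_zero_count(self):
        pmap = _make_map([[np.ones(5)]])
        stack, counts = rq.collective_profiles(
            pmap, 1, {1: 10.0}, n_age_groups=10
        )
        assert counts[1] == 1
        assert np.isnan(stack[5]).all()
        assert counts[5] == 0


class TestMapImage:
    def test_columns_vertically_centered(self):
        pmap = _make_map([[np.ones(4)], [np.ones(8)]])
        img, pads = pmap.to_image(1)
        assert img.shape == (8, 2)
        assert pads == [2, 0]
        assert img[:, 1].sum() == 8
        assert img[2:6, 0].sum() == 4
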