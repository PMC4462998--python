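"""Background, registration, ages, FCPlus, calibration, stats, qualifiers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rodquant as rq
from rodquant.quant import estimate_modal_background
from rodquant.synthgen import OpticsSpec, PatternSpec

SCALE = 14.98


class TestModalBackground:
    def test_constant_image_goes_to_zero(self):
        out = rq.subtract_modal_background(np.full((32, 32), 100.0))
        assert np.all(out == 0.0)

    def test_all_zero_image_unchanged(self):
        out = rq.subtract_modal_background(np.zeros((16, 16)))
        assert np.all(out == 0.0)

    def test_recovers_injected_background_level(self, clean_scene):
        # clean fixture has background_level 50 and no noise
        img = clean_scene.hyperstack[1]
        assert estimate_modal_background(img) == pytest.approx(50.0, abs=0.5)
        out = rq.subtract_modal_background(img)
        assert np.median(out) == pytest.approx(0.0, abs=0.5)

    def test_noisy_background_median_near_zero(self):
        rng = np.random.default_rng(61)
        img = rng.normal(80.0, 3.0, (128, 128))
        img[30:40, 30:60] += 500.0  # a bright object
        out = rq.subtract_modal_background(img, clip_negative=False)
        assert abs(np.median(out[60:, :])) < 1.0


@pytest.fixture(scope="module")
def shifted_setup():
    pop = rq.sample_population(12, seed=62)
    scene = rq.render_scene(
        pop, [PatternSpec("cytoplasmic_uniform", 800)],
        OpticsSpec(noise_sd=0.0, channel_shift=(3, -2)), seed=63,
    )
    cells = [
        c for c in rq.detect_cells(scene.hyperstack[0], SCALE)
        if c.accepted
    ]
    fl = rq.subtract_modal_background(scene.hyperstack[1])
    return cells, fl


class TestRegistration:
    def test_programmed_shift_recovered(self, shifted_setup):
        cells, fl = shifted_setup
        assert rq.register_fluorescence(cells, fl, 5) == (-3, 2)

    def test_matches_exhaustive_search_oracle(self, shifted_setup):
        cells, fl = shifted_setup
        mask = np.zeros(fl.shape, dtype=bool)
        for c in cells:
            y0, x0, y1, x1 = c.bbox
            mask[y0:y1, x0:x1] |= c.mask
        best, best_val = None, -np.inf
        for dx in range(-5, 6):
            for dy in range(-5, 6):
                val = rq.apply_shift(fl, (dx, dy))[mask].sum()
                if val > best_val:
                    best, best_val = (dx, dy), val
        assert rq.register_fluorescence(cells, fl, 5) == best

    def test_unshifted_scene_returns_zero(self, clean_scene, clean_cells):
        fl = rq.subtract_modal_background(clean_scene.hyperstack[1])
        assert rq.register_fluorescence(clean_cells, fl, 5) == (0, 0)

    def test_blank_channel_warns_and_returns_zero(self, clean_scene,
                                                  clean_cells):
        blank = np.zeros(clean_scene.hyperstack[1].shape)
        with pytest.warns(UserWarning):
            assert rq.register_fluorescence(clean_cells, blank, 5) == (0, 0)


class TestAssignAges:
    def test_boundary_ranks(self):
        ages = rq.assign_ages([1.0, 2.0, 3.0])
        assert ages[0] == pytest.approx(0.0)
        assert ages[-1] == pytest.approx(100.0)

    def test_middle_rank_of_101(self):
        ages = rq.assign_ages(np.linspace(1, 2, 101))
        assert ages[50] == pytest.approx(
            np.log(0.75) / np.log(0.5) * 100, abs=1e-9
        )
        assert ages[50] == pytest.approx(41.504, abs=1e-3)

    def test_is_inverse_cdf_of_steady_state_distribution(self):
        n = 5000
        u = np.arange(n) / (n - 1)
        closed_form = (1.0 - np.log2(2.0 - u)) * 100.0
        ages = rq.assign_ages(np.sort(np.random.default_rng(64).random(n)))
        np.testing.assert_allclose(ages, closed_form, atol=1e-9)

    def test_recovers_truth_ages_of_sampled_population(self):
        pop = rq.sample_population(20_000, seed=65)
        ages = rq.assign_ages(pop["length_um"].to_numpy())
        mae = np.mean(np.abs(ages / 100.0 - pop["age"].to_numpy()))
        assert mae < 0.005

    def test_monotone_in_length(self):
        rng = np.random.default_rng(66)
        lengths = rng.random(500) * 3 + 2
        ages = rq.assign_ages(lengths)
        order = np.argsort(lengths, kind="stable")
        assert np.all(np.diff(ages[order]) >= 0)

    def test_fewer_than_two_cells_raises(self):
        with pytest.raises(rq.NotComputableError):
            rq.assign_ages([1.5])


class TestFCPlus:
    def test_uniform_cell_is_exactly_zero(self):
        n, step = 400, 0.01
        d = np.full(n, 1.0)
        vols = rq.disk_volumes(d, step)
        profile = vols * 7.5  # uniform concentration
        assert rq.fc_plus(profile, d, step) == pytest.approx(0.0, abs=1e-12)

    def test_worked_example_eight_au(self):
        """4 μm cell, d = 1 μm, 10 AU/μm outside vs 20 AU/μm in the central
        0.8 μm: FCPlus = (16/0.6283 − 32/2.5133)·0.6283 = 8.0 AU."""
        n = 4000
        step = 4.0 / n
        d = np.full(n, 1.0)
        s = (np.arange(n) + 0.5) * step
        density = np.where(np.abs(s - 2.0) <= 0.4, 20.0, 10.0)
        profile = density * step
        v_mid = np.pi * 0.25 * 0.8
        v_rest = np.pi * 0.25 * 3.2
        expected = (16.0 / v_mid - 32.0 / v_rest) * v_mid
        assert expected == pytest.approx(8.0, abs=1e-9)
        assert rq.fc_plus(profile, d, step) == pytest.approx(8.0, abs=1e-6)

    def test_ring_matches_direct_formula_oracle(self):
        n, step = 3000, 0.001
        d = np.full(n, 1.0)
        profile = np.zeros(n)
        profile[n // 2] = 250.0  # all mass at midcell
        vols = rq.disk_volumes(d, step)
        fsplit = rq.midcell_partition(profile, step, 0.4)
        vsplit = rq.midcell_partition(vols, step, 0.4)
        oracle = (
            fsplit.mid / vsplit.mid - fsplit.rest / vsplit.rest
        ) * vsplit.mid
        assert rq.fc_plus(profile, d, step) == pytest.approx(oracle, abs=1e-9)
        assert oracle == pytest.approx(250.0, abs=1e-9)  # no mass outside

    def test_conservation_identity(self):
        """FCPlus == F_mid − conc_rest · V_mid, exactly."""
        rng = np.random.default_rng(67)
        n, step = 300, 0.01
        d = rng.uniform(0.8, 1.0, n)
        profile = rng.random(n)
        vols = rq.disk_volumes(d, step)
        fsplit = rq.midcell_partition(profile, step, 0.4)
        vsplit = rq.midcell_partition(vols, step, 0.4)
        expected = fsplit.mid - fsplit.rest / vsplit.rest * vsplit.mid
        assert rq.fc_plus(profile, d, step) == pytest.approx(
            expected, abs=1e-9
        )

    def test_short_cell_undefined(self):
        assert rq.fc_plus(np.ones(5), np.ones(5), 0.1) is None


class TestCalibration:
    def _results(self, fluortotals):
        return pd.DataFrame(
            {
                "fluortotal_ch1": fluortotals,
                "fcplus_ch1": np.linspace(1, 2, len(fluortotals)),
                "qualified": True,
            }
        )

    def test_f_is_navg_over_mean_fluortotal(self):
        res = self._results([300.0, 367.0])
        calib = rq.calibration_factor(res, n_avg=3335.0, channel=1)
        assert calib.F == pytest.approx(10.0)

    def test_mols_cplus_is_product(self):
        res = self._results([333.5])
        calib = rq.calibration_factor(res, 3335.0, 1)
        assert rq.mols_cplus(8.0, calib) == pytest.approx(80.0)

    def test_scale_invariance_of_molecule_counts(self):
        res = self._results(np.linspace(200, 400, 10))
        calib = rq.calibration_factor(res, 1000.0, 1)
        mols = rq.mols_cplus(res["fcplus_ch1"], calib)
        k = 7.3
        scaled = self._results(np.linspace(200, 400, 10) * k)
        scaled["fcplus_ch1"] *= k
        calib2 = rq.calibration_factor(scaled, 1000.0, 1)
        mols2 = rq.mols_cplus(scaled["fcplus_ch1"], calib2)
        np.testing.assert_allclose(mols, mols2, rtol=1e-12)

    def test_no_qualified_cells_raises(self):
        res = self._results([100.0])
        res["qualified"] = False
        with pytest.raises(rq.NotComputableError):
            rq.calibration_factor(res, 100.0, 1)


class TestResultsTable:
    def test_concentration_identities(self, clean_cells, clean_pmap):
        res = rq.build_results_table(clean_cells, clean_pmap)
        np.testing.assert_allclose(
            res["conctotal_ch1"],
            res["fluortotal_ch1"] / res["volume_um3"],
        )
        np.testing.assert_allclose(
            res["concwall_ch1"],
            res["fluortotal_ch1"] / res["cell_wall_um2"],
        )

    def test_fluortotal_matches_profile_sum_exactly(
        self, clean_cells, clean_pmap
    ):
        res = rq.build_results_table(clean_cells, clean_pmap)
        totals = clean_pmap.fluor_totals(1)
        for _, row in res.iterrows():
            assert row["fluortotal_ch1"] == pytest.approx(
                totals[row["cell"]], abs=1e-9
            )

    def test_age_range_and_monotonicity(self, clean_cells, clean_pmap):
        res = rq.build_results_table(clean_cells, clean_pmap)
        assert res["age_pct"].min() == pytest.approx(0.0)
        assert res["age_pct"].max() == pytest.approx(100.0)
        srt = res.sort_values("axis_length_um")
        assert np.all(np.diff(srt["age_pct"]) >= 0)


class TestAgeBinnedStats:
    def _results(self, n=200, seed=68):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "age_pct": np.linspace(0, 100, n),
                "value": rng.normal(10.0, 1.0, n),
                "qualified": True,
            }
        )

    def test_five_percent_bins_give_twenty_rows(self):
        stats = rq.age_binned_stats(self._results(), "value", bin_pct=5.0)
        assert len(stats) == 20
        assert stats["n"].sum() == 200

    def test_single_cell_bin_has_no_ci(self):
        res = self._results(n=20)  # one cell per 5% bin
        stats = rq.age_binned_stats(res, "value", 5.0)
        assert (stats["n"] == 1).all()
        assert stats["ci_lo"].isna().all()

    def test_ci_shrinks_with_n(self):
        wide = rq.age_binned_stats(self._results(100), "value", 5.0)
        tight = rq.age_binned_stats(self._results(2000), "value", 5.0)
        assert (
            (tight["ci_hi"] - tight["ci_lo"]).mean()
            < (wide["ci_hi"] - wide["ci_lo"]).mean()
        )


class TestQualify:
    def _results(self):
        return pd.DataFrame(
            {
                "cell": np.arange(10),
                "fluortotal_ch1": [0.01, 5, 6, 0.02, 7, 8, 9, 0.05, 10, 11],
                "qualified": True,
            }
        )

    def test_dark_cells_disqualified_by_predicate(self):
        out = rq.qualify(self._results(), "fluortotal_ch1 < 0.1")
        assert (~out["qualified"]).sum() == 3
        assert len(out) == 10  # rows retained

    def test_always_true_predicate_warns(self):
        with pytest.warns(UserWarning):
            out = rq.qualify(self._results(), lambda df: np.ones(10, bool))
        assert not out["qualified"].any()

    def test_clearing_flags_restores_statistics(self):
        res = self._results()
        before = res["fluortotal_ch1"].mean()
        out = rq.clear_qualifiers(rq.qualify(res, "fluortotal_ch1 < 0.1"))
        assert out["qualified"].all()
        assert out["fluortotal_ch1"].mean() == before

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=12.0))
    def test_qualify_then_clear_is_identity(self, threshold):
        res = self._results()
        out = rq.clear_qualifiers(
            rq.qualify(res, f"fluortotal_ch1 < {threshold}")
        )
        pd.testing.assert_frame_equal(out, res)
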