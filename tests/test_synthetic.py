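"""Fixture generators: rendering, trajectories, noise, logs, mass–area."""

import math

import numpy as np
import pandas as pd
import pytest

from thermapheno import synthetic as syn
from thermapheno.core import CalibrationScale
from thermapheno.size import PlateLayout
from thermapheno.thermal import AssayConfig


class TestRenderPlateImage:
    def test_empty_larva_list_matches_reference_exactly(self, cal):
        layout = PlateLayout.grid()
        frame, reference, truth = syn.render_plate_image(layout, [], cal)
        np.testing.assert_array_equal(frame, reference)
        assert truth.empty

    def test_circular_larva_truth_area(self):
        # radius 20 px at 10 px/mm is a 2 mm-radius disk: 4π mm²
        cal10 = CalibrationScale(10.0)
        layout = PlateLayout.grid()
        larva = syn.LarvaSpec(
            well_id="W01",
            center_px=layout.wells[0].center_px,
            semi_axes_px=(20.0, 20.0),
            orientation_rad=0.0,
        )
        _, _, truth = syn.render_plate_image(layout, [larva], cal10)
        assert truth["true_area_mm2"].iloc[0] == pytest.approx(4 * math.pi, rel=1e-12)

    def test_full_plate_truth_matches_closed_form(self, cal):
        plates, _ = syn.simulate_larval_cohort(30, cal, seed=5)
        layout, larvae = plates[0]
        _, _, truth = syn.render_plate_image(layout, larvae, cal)
        assert len(truth) == 30
        for larva, (_, row) in zip(larvae, truth.iterrows()):
            a, b = larva.semi_axes_px
            assert row["true_area_px2"] == pytest.approx(math.pi * a * b, rel=1e-12)

    def test_larva_outside_well_rejected(self, cal):
        layout = PlateLayout.grid()
        w = layout.wells[0]
        larva = syn.LarvaSpec(
            well_id="W01",
            center_px=(w.center_px[0] + w.radius_px, w.center_px[1]),
            semi_axes_px=(10.0, 5.0),
            orientation_rad=0.0,
        )
        with pytest.raises(ValueError, match="fit"):
            syn.render_plate_image(layout, [larva], cal)

    def test_two_larvae_one_well_rejected(self, cal):
        layout = PlateLayout.grid()
        la = syn.LarvaSpec("W01", layout.wells[0].center_px, (5.0, 3.0), 0.0)
        with pytest.raises(ValueError, match="more than one"):
            syn.render_plate_image(layout, [la, la], cal)


class TestMassArea:
    def test_zero_noise_is_collinear(self):
        fix = syn.simulate_mass_area(50, noise_sd=0.0, seed=1)
        assert fix.realized_pearson_r == pytest.approx(1.0, abs=1e-12)

    def test_fixed_seed_reproducible(self):
        a = syn.simulate_mass_area(40, seed=9)
        b = syn.simulate_mass_area(40, seed=9)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert a.realized_pearson_r == b.realized_pearson_r

    def test_default_noise_gives_strong_but_imperfect_correlation(self):
        fix = syn.simulate_mass_area(150, seed=2)
        assert 0.6 < fix.realized_pearson_r < 0.95

    @pytest.mark.parametrize("bad", [dict(n=2), dict(n=10, noise_sd=-1.0)])
    def test_invalid_args_rejected(self, bad):
        with pytest.raises(ValueError):
            syn.simulate_mass_area(**bad)


class TestSimulateTrack:
    def test_heat_agent_is_still_after_knockdown(self, cal, vial, short_static_high):
        params = syn.AgentParams(
            individual_id="F1", assay_type="static_high", knockdown_s=300.0, seed=3
        )
        series, truth = syn.simulate_track(params, short_static_high, vial, cal)
        after = series.time_s >= 300.0
        assert np.all(series.activity[after] == 0)
        assert np.all(series.distance_cm[after] == 0)
        assert truth.last_movement_s < 300.0

    def test_chill_agent_first_moves_at_coma_end(self, cal, vial, short_static_low):
        params = syn.AgentParams(
            individual_id="F1", assay_type="static_low", coma_end_s=900.0, seed=3
        )
        series, truth = syn.simulate_track(params, short_static_low, vial, cal)
        first_nonzero = series.time_s[np.flatnonzero(series.activity > 0)[0]]
        assert first_nonzero == pytest.approx(900.0, abs=1.0 / series.frame_rate_hz)
        assert truth.first_movement_s == first_nonzero
        before = series.time_s < 900.0
        assert np.all(series.activity[before] == 0)

    def test_crosses_place_centroid_in_upper_zone(self, cal, vial, short_static_high):
        params = syn.AgentParams(
            individual_id="F1",
            assay_type="static_high",
            knockdown_s=400.0,
            cross_times_s=(50.0, 200.0),
            seed=7,
        )
        series, truth = syn.simulate_track(params, short_static_high, vial, cal)
        assert truth.first_middle_cross_s == pytest.approx(50.0, abs=0.21)
        assert truth.last_middle_cross_s == pytest.approx(
            200.0 + syn.CROSS_DWELL_S, abs=1.0
        )
        upper = series.zone == "upper"
        assert upper.any()
        assert np.all(series.y_mm[upper] * cal.pixels_per_mm < vial.middle_line_y_px)

    def test_same_seed_identical_trajectory(self, cal, vial, short_static_high):
        params = syn.AgentParams(
            individual_id="F1", assay_type="static_high", knockdown_s=300.0, seed=11
        )
        s1, _ = syn.simulate_track(params, short_static_high, vial, cal)
        s2, _ = syn.simulate_track(params, short_static_high, vial, cal)
        np.testing.assert_array_equal(s1.x_mm, s2.x_mm)
        np.testing.assert_array_equal(s1.activity, s2.activity)

    def test_cross_outside_duration_rejected(self, cal, vial, short_static_high):
        params = syn.AgentParams(
            individual_id="F1",
            assay_type="static_high",
            knockdown_s=300.0,
            cross_times_s=(1000.0,),
            seed=0,
        )
        with pytest.raises(ValueError, match="cross time"):
            syn.simulate_track(params, short_static_high, vial, cal)


class TestInjectNoise:
    def _clean(self, cal, vial, short_static_high):
        params = syn.AgentParams(
            individual_id="F1", assay_type="static_high", knockdown_s=200.0, seed=5
        )
        return syn.simulate_track(params, short_static_high, vial, cal)

    def test_all_zero_injection_is_identity(self, cal, vial, short_static_high):
        series, _ = self._clean(cal, vial, short_static_high)
        noisy, events = syn.inject_noise(series, syn.NoiseInjection(seed=1))
        np.testing.assert_array_equal(noisy.distance_cm, series.distance_cm)
        np.testing.assert_array_equal(noisy.activity, series.activity)
        assert events.empty

    def test_fixed_seed_reproducible_events(self, cal, vial, short_static_high):
        series, _ = self._clean(cal, vial, short_static_high)
        inj = syn.NoiseInjection(bubble_rate_per_s=0.05, seed=4)
        _, ev1 = syn.inject_noise(series, inj)
        _, ev2 = syn.inject_noise(series, inj)
        pd.testing.assert_frame_equal(ev1, ev2)
        assert not ev1.empty

    def test_filter_restores_truth_after_post_knockdown_noise(
        self, cal, vial, short_static_high
    ):
        # noise lands only after knockdown: the unfiltered last movement is
        # dragged late, the filtered one matches truth within one bin
        from thermapheno.signal import apply_noise_filter, bin_series, quantify_noise
        from thermapheno.traits import first_last_movement

        series, truth = self._clean(cal, vial, short_static_high)
        inj = syn.NoiseInjection(bubble_rate_per_s=0.1, flicker_rate_per_s=0.05,
                                 flicker_amplitude=0.01, seed=8)
        noisy, events = syn.inject_noise(series, inj)
        post = events[events["time_s"] > 250.0]
        assert not post.empty, "fixture must contain post-knockdown noise"
        binned = bin_series(noisy)
        unfiltered = first_last_movement(binned, "last")
        assert unfiltered.time_s > truth.last_movement_s + 15.0
        profile = quantify_noise([binned], (250.0, 600.0))
        filtered = first_last_movement(apply_noise_filter(binned, profile), "last")
        assert abs(filtered.time_s - truth.last_movement_s) <= 15.0

    def test_min_spacing_bounds_events_per_bin(self, cal, vial, short_static_high):
        series, _ = self._clean(cal, vial, short_static_high)
        inj = syn.NoiseInjection(bubble_rate_per_s=1.0, min_spacing_s=15.0, seed=2)
        _, events = syn.inject_noise(series, inj)
        bins = (events["time_s"] // 15.0).astype(int)
        assert bins.value_counts().max() == 1


class TestTemperatureLog:
    def test_ramp_reading_at_minute_ten(self, short_dynamic):
        log = syn.make_temperature_log(short_dynamic, jitter_sd_C=0.0)
        assert log.temp_C[10] == pytest.approx(29.0, abs=1e-12)
        assert log.time_s[10] == 600.0

    def test_static_log_constant(self, short_static_high):
        log = syn.make_temperature_log(short_static_high, jitter_sd_C=0.0)
        assert np.all(log.temp_C == 46.5)
        assert np.all(np.diff(log.time_s) == 60.0)

    def test_jitter_reproducible(self, short_dynamic):
        a = syn.make_temperature_log(short_dynamic, jitter_sd_C=0.1, seed=3)
        b = syn.make_temperature_log(short_dynamic, jitter_sd_C=0.1, seed=3)
        np.testing.assert_array_equal(a.temp_C, b.temp_C)

    def test_negative_jitter_rejected(self, short_dynamic):
        with pytest.raises(ValueError):
            syn.make_temperature_log(short_dynamic, jitter_sd_C=-0.1)


class TestCohort:
    def test_cohort_size_and_scheduled_exclusions(self, short_static_high):
        agents = syn.make_assay_cohort(
            short_static_high, n_per_treatment=10, seed=1, n_never_move=2,
            n_never_cross=3,
        )
        assert len(agents) == 30
        never_move = [a for a in agents if a.knockdown_s == 0.0]
        never_cross = [a for a in agents if not a.cross_times_s]
        assert len(never_move) == 6  # 2 per treatment
        assert len(never_cross) == 15  # never-movers never cross either
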