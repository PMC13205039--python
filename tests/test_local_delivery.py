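"""Event referencing, decoupling, dip metrics, ROI integration, mass response."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pemkit import local_delivery as ld
from pemkit import synthetic_data as sd
from pemkit.image_io import ImageStack


def _event_for(stack, truth, conc_uM=1.0, volume_mL=10.0):
    ev = truth.events[0]
    return ld.DeliveryEvent(stack, ev.pump_on_frame, ev.pump_off_frame, conc_uM, volume_mL)


class TestReferenceEvent:
    def test_frame_before_pump_on_is_exactly_zero(self, local_default):
        _, stack, truth = local_default
        event = _event_for(stack, truth)
        ref = ld.reference_event(stack, event)
        np.testing.assert_array_equal(ref.frames[event.pump_on_frame - 1], 0.0)

    def test_static_fringes_cancel_exactly(self):
        # identical fringe patterns difference out bit-for-bit
        base = np.zeros((10, 12, 14), dtype=np.float64)
        fringes = sd.fringe_pattern((12, 14), 1.0, sd.FringeConfig(amplitude_au=5.0))
        stack_a = ImageStack(base + fringes[None], 50.0, 0.94)
        event = ld.DeliveryEvent(stack_a, 2, 5, 1.0, 1.0)
        ref = ld.reference_event(stack_a, event)
        np.testing.assert_array_equal(ref.frames, 0.0)

    def test_pump_on_at_frame_zero_rejected(self):
        stack = ImageStack(np.zeros((6, 4, 4)), 50.0, 0.94)
        with pytest.raises(ValueError):
            ld.reference_event(stack, ld.DeliveryEvent(stack, 0, 3, 1.0, 1.0))

    def test_fringe_amplitude_does_not_change_event_metrics(self, local_default):
        cfg, stack, truth = local_default
        strong = sd.LocalConfig(
            **{
                **cfg.__dict__,
                "fringes": sd.FringeConfig(amplitude_au=10.0, wavelength_um=cfg.fringes.wavelength_um),
            }
        )
        stack_b, truth_b = sd.simulate_local(strong, seed=3)
        ev_a = _event_for(stack, truth)
        ev_b = _event_for(stack_b, truth_b)
        dip_a = ld.quantify_dip(ld.reference_event(stack, ev_a), ev_a)
        dip_b = ld.quantify_dip(ld.reference_event(stack_b, ev_b), ev_b)
        assert dip_a.dip_min == pytest.approx(dip_b.dip_min, abs=1e-3)
        assert dip_a.dip_radius_um == pytest.approx(dip_b.dip_radius_um, abs=1e-9)


class TestProfileStack:
    def test_constant_frame_yields_constant_profiles(self):
        stack = ImageStack(np.full((20, 10, 30), 4.0), 50.0, 1.0)
        prof = ld.profile_stack(
            stack, ld.LineSpec("row", 5), times_s=[0.1, 0.2], window=10, offset_step=0.0
        )
        np.testing.assert_allclose(prof.color_values, 4.0)
        np.testing.assert_allclose(prof.profiles, 4.0)

    def test_identity_settings_return_raw_profile(self, rng):
        frames = rng.normal(size=(5, 6, 12))
        stack = ImageStack(frames, 1.0, 1.0)
        prof = ld.profile_stack(stack, ld.LineSpec("row", 2), [1.0], window=1, offset_step=0.0)
        np.testing.assert_allclose(prof.color_values[0], frames[1, 2, :])

    def test_offsets_are_monotone_and_colors_unoffset(self, rng):
        frames = rng.normal(size=(8, 6, 20))
        stack = ImageStack(frames, 1.0, 1.0)
        prof = ld.profile_stack(stack, ld.LineSpec("row", 3), [0.0, 2.0, 4.0], window=3)
        assert np.all(np.diff(prof.offsets) > 0)
        np.testing.assert_allclose(prof.profiles - prof.offsets[:, None], prof.color_values)

    def test_deposit_peak_position_matches_truth(self, local_default):
        cfg, stack, truth = local_default
        ev = truth.events[0]
        event = _event_for(stack, truth)
        ref = ld.reference_event(stack, event)
        row = int(round(ev.center_rc[0] + cfg.deposit.offset_um[0] / cfg.pixel_size_um))
        prof = ld.profile_stack(
            ref, ld.LineSpec("row", row, band_halfwidth=2), [stack.times_s[-1]], window=10
        )
        peak_um = prof.positions_um[int(np.argmax(prof.color_values[0]))]
        # oracle: same line/smoothing applied to the noise-free truth field
        truth_field = ev.deposit_field_final + ev.halo_field_final
        truth_line = truth_field[row - 2 : row + 3].mean(axis=0)
        from pemkit.image_io import temporal_moving_average

        truth_peak_um = cfg.pixel_size_um * int(
            np.argmax(temporal_moving_average(truth_line, 10))
        )
        assert peak_um == pytest.approx(truth_peak_um, abs=2.0)

    def test_out_of_range_line_rejected(self):
        stack = ImageStack(np.zeros((4, 5, 5)), 1.0, 1.0)
        with pytest.raises(IndexError):
            ld.profile_stack(stack, ld.LineSpec("row", 9), [0.0])


class TestDecouplePhases:
    def test_all_zero_stack_gives_empty_masks(self):
        stack = ImageStack(np.zeros((40, 8, 8)), 50.0, 0.94)
        event = ld.DeliveryEvent(stack, 5, 10, 1.0, 1.0)
        transient, persistent = ld.decouple_phases(stack, event, sigma=1.0)
        assert not transient.any()
        assert not persistent.any()

    def test_pure_persistent_step_pixel_is_chemical(self):
        frames = np.zeros((50, 4, 4))
        frames[20:, 1, 2] = 10.0  # step up, never returns
        stack = ImageStack(frames, 50.0, 0.94)
        event = ld.DeliveryEvent(stack, 5, 10, 1.0, 1.0)
        transient, persistent = ld.decouple_phases(stack, event, sigma=1.0)
        assert persistent[1, 2]
        assert not transient[1, 2]

    def test_pure_transient_pixel_is_physical(self):
        frames = np.zeros((50, 4, 4))
        frames[5:10, 2, 2] = -10.0  # dip during pump, recovers after
        stack = ImageStack(frames, 50.0, 0.94)
        event = ld.DeliveryEvent(stack, 5, 10, 1.0, 1.0)
        transient, persistent = ld.decouple_phases(stack, event, sigma=1.0)
        assert transient[2, 2]
        assert not persistent[2, 2]

    def test_masks_are_disjoint(self, local_default):
        _, stack, truth = local_default
        event = _event_for(stack, truth)
        ref = ld.reference_event(stack, event)
        transient, persistent = ld.decouple_phases(ref, event)
        assert not (transient & persistent).any()

    def test_simulated_event_classification_matches_truth(self, local_default):
        _, stack, truth = local_default
        ev = truth.events[0]
        event = _event_for(stack, truth)
        ref = ld.reference_event(stack, event)
        transient, persistent = ld.decouple_phases(ref, event)

        def balanced_accuracy(pred, true):
            tpr = (pred & true).sum() / max(true.sum(), 1)
            tnr = (~pred & ~true).sum() / max((~true).sum(), 1)
            return 0.5 * (tpr + tnr)

        assert balanced_accuracy(transient, ev.class_masks["transient_physical"]) >= 0.90
        assert balanced_accuracy(persistent, ev.class_masks["persistent_chemical"]) >= 0.90


class TestQuantifyDip:
    def test_dip_radius_matches_truth_half_minimum(self, local_default):
        _, stack, truth = local_default
        ev = truth.events[0]
        event = _event_for(stack, truth)
        dip = ld.quantify_dip(ld.reference_event(stack, event), event)
        assert not dip.no_dip
        assert dip.dip_radius_um == pytest.approx(ev.dip_half_min_radius_um, rel=0.15)

    def test_no_dip_simulation_is_flagged(self):
        cfg = sd.LocalConfig(
            shape=(100, 120),
            duration_s=4.0,
            pump_off_s=2.0,
            dip=sd.DipTruth(amplitude_mdeg=-0.0),
            deposit=sd.DepositTruth(amplitude_mdeg=0.0),
            halo=sd.HaloTruth(amplitude_mdeg=0.0),
            n_scatterers=0,
        )
        stack, truth = sd.simulate_local(cfg, seed=4)
        event = _event_for(stack, truth)
        dip = ld.quantify_dip(ld.reference_event(stack, event), event)
        assert dip.no_dip
        assert dip.dip_min >= -3 * 1.5 * np.sqrt(2)

    def test_doubling_amplitude_doubles_dip_min(self):
        metrics = []
        for amp in (-30.0, -60.0):
            cfg = sd.LocalConfig(
                shape=(160, 200),
                duration_s=5.0,
                dip=sd.DipTruth(amplitude_mdeg=amp),
                deposit=sd.DepositTruth(amplitude_mdeg=0.0),
                halo=sd.HaloTruth(amplitude_mdeg=0.0),
                n_scatterers=0,
                noise_sigma_au=0.0,
            )
            stack, truth = sd.simulate_local(cfg, seed=5)
            event = _event_for(stack, truth)
            metrics.append(ld.quantify_dip(ld.reference_event(stack, event), event, sigma=1.5))
        assert metrics[1].dip_min == pytest.approx(2 * metrics[0].dip_min, rel=0.02)

    def test_symmetric_dip_centroid_matches_configured_center(self):
        cfg = sd.LocalConfig(
            shape=(200, 240),
            duration_s=8.0,
            deposit=sd.DepositTruth(amplitude_mdeg=0.0),
            halo=sd.HaloTruth(amplitude_mdeg=0.0),
            noise_sigma_au=0.0,
            n_scatterers=0,
            mask_threshold_mdeg=4.5,
        )
        stack, truth = sd.simulate_local(cfg, seed=1)
        ev = truth.events[0]
        event = _event_for(stack, truth)
        dip = ld.quantify_dip(ld.reference_event(stack, event), event, sigma=1.5)
        err_um = cfg.pixel_size_um * np.hypot(
            dip.dip_centroid_rc[0] - ev.center_rc[0],
            dip.dip_centroid_rc[1] - ev.center_rc[1],
        )
        assert err_um < 2.0


class TestROI:
    def test_zero_frame_integrates_to_zero(self):
        roi = ld.circular_roi((100.0, 100.0), (201, 201), 0.94)
        assert ld.integrate_roi(np.zeros((201, 201)), roi) == 0.0

    def test_uniform_frame_integrates_to_value_times_count(self):
        roi = ld.circular_roi((50.0, 50.0), (101, 101), 0.94, diameter_um=50.0)
        frame = np.full((101, 101), 3.0)
        assert ld.integrate_roi(frame, roi) == pytest.approx(3.0 * roi.pixel_count)

    def test_pixel_membership_by_center_rule(self):
        roi = ld.circular_roi((2.0, 2.0), (5, 5), 1.0, diameter_um=2.0)
        # radius 1 px: centre pixel plus the 4 orthogonal neighbours
        assert roi.pixel_count == 5

    def test_roi_outside_frame_rejected(self):
        with pytest.raises(ValueError):
            ld.circular_roi((5.0, 5.0), (20, 20), 1.0, diameter_um=166.0)

    @given(
        a=st.floats(-3, 3, allow_nan=False),
        b=st.floats(-3, 3, allow_nan=False),
    )
    def test_integration_is_linear(self, a, b):
        rng = np.random.default_rng(0)
        f = rng.normal(size=(41, 41))
        g = rng.normal(size=(41, 41))
        roi = ld.circular_roi((20.0, 20.0), (41, 41), 1.0, diameter_um=30.0)
        lhs = ld.integrate_roi(a * f + b * g, roi)
        rhs = a * ld.integrate_roi(f, roi) + b * ld.integrate_roi(g, roi)
        assert lhs == pytest.approx(rhs, abs=1e-8)


class TestNominalAmount:
    @pytest.mark.parametrize(
        "conc, volume, expected",
        [(1.0, 3.0, 3.0), (10.0, 2.0, 20.0), (5.0, 0.0, 0.0)],
    )
    def test_product_rule(self, conc, volume, expected):
        assert ld.nominal_amount(conc, volume) == expected

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            ld.nominal_amount(-1.0, 1.0)


class TestMassResponse:
    def _summary(self, conc, vol, signal):
        return ld.DeliverySummary(
            conc_uM=conc,
            pump_volume_mL=vol,
            nominal_amount_au=ld.nominal_amount(conc, vol),
            integrated_signal_au=signal,
            roi_center_rc=(0.0, 0.0),
            roi_pixel_count=100,
            dip_min=-1.0,
            dip_radius_um=10.0,
            dip_recovery_s=None,
            no_dip=False,
            n_transient_px=0,
            n_persistent_px=0,
        )

    def test_single_event_reports_zero_sd_with_n1(self):
        table = ld.mass_response([self._summary(1.0, 3.0, 100.0)])
        assert table.loc[0, "sd_au"] == 0.0
        assert table.loc[0, "n"] == 1

    def test_replicates_grouped_with_sample_sd(self):
        events = [self._summary(10.0, 2.0, s) for s in (90.0, 110.0)]
        table = ld.mass_response(events)
        assert len(table) == 1
        assert table.loc[0, "mean_au"] == pytest.approx(100.0)
        assert table.loc[0, "sd_au"] == pytest.approx(np.sqrt(200.0))

    def test_identical_replicates_have_zero_sd(self):
        events = [self._summary(1.0, 3.0, 55.0), self._summary(1.0, 3.0, 55.0)]
        table = ld.mass_response(events)
        assert table.loc[0, "sd_au"] == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ld.mass_response([])

    def test_loglog_fit_recovers_unit_slope_on_proportional_data(self):
        events = [self._summary(c, 1.0, 500.0 * c) for c in (0.1, 1.0, 10.0)]
        slope, _, r2 = ld.loglog_fit(ld.mass_response(events))
        assert slope == pytest.approx(1.0, abs=1e-9)
        assert r2 == pytest.approx(1.0)


class TestSummarizeEvent:
    def test_summary_integrates_near_truth_chemical_signal(self, local_default):
        cfg, stack, truth = local_default
        ev = truth.events[0]
        event = _event_for(stack, truth)
        summary, transient, persistent = ld.summarize_event(stack, event)
        # linear transduction, slope 1 a.u./mDeg: ROI sum tracks the truth field sum
        assert summary.integrated_signal_au == pytest.approx(
            ev.integrated_chemical_mdeg, rel=0.10
        )
        assert summary.n_persistent_px == persistent.sum()
        assert summary.nominal_amount_au == 10.0
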