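"""Generator ground truth, calibration fidelity and seed determinism."""

import numpy as np
import pandas as pd
import pytest

from swimtag import synth
from swimtag.cardio import burst_to_record, detect_r_peaks
from swimtag.circadian import day_night_summary
from swimtag.kinematics import external_acceleration, odba, split_static_dynamic
from swimtag.respirometry import RespiroConfig, compute_mo2, iter_measure_phases


class TestRespiroGenerator:
    def test_noise_free_round_trip_exact(self):
        trace, truth = synth.gen_respiro_session(
            true_mo2_by_speed={0.30: 213.0}, noise_sd_pct=0.0, n_replicates=1)
        _, _, phase = next(iter_measure_phases(trace))
        rec = compute_mo2(phase, truth["cfg"])
        assert rec.mo2 == pytest.approx(213.0, abs=1e-8)

    def test_default_truth_recovered_within_5pct(self):
        trace, truth = synth.gen_respiro_session(seed=7)
        cfg = truth["cfg"]
        by_speed: dict = {}
        for speed, _, phase in iter_measure_phases(trace):
            by_speed.setdefault(speed, []).append(compute_mo2(phase, cfg).mo2)
        for speed, vals in by_speed.items():
            assert np.mean(vals) == pytest.approx(truth["true_mo2"][speed], rel=0.05)

    def test_body_mass_scaling(self):
        trace, truth = synth.gen_respiro_session(
            true_mo2_by_speed={0.30: 213.0}, noise_sd_pct=0.0, n_replicates=1)
        _, _, phase = next(iter_measure_phases(trace))
        heavy = RespiroConfig(body_mass_kg=truth["cfg"].body_mass_kg * 2)
        assert compute_mo2(phase, heavy).mo2 == pytest.approx(213.0 / 2, abs=1e-8)

    def test_protocol_structure(self):
        trace, _ = synth.gen_respiro_session(n_replicates=2, seed=0)
        assert set(trace["phase"]) == {"acclimation", "measure", "flush"}
        speeds = sorted(trace["speed_mps"].unique())
        assert speeds == [0.30, 0.45, 0.60, 0.75, 0.90]
        assert np.all(np.diff(trace["time_s"]) > 0)


class TestEcgGenerator:
    def test_peak_geometry(self):
        _, peaks80 = synth.gen_ecg(80.0, seed=0)
        _, peaks48 = synth.gen_ecg(48.0, seed=0)
        assert peaks80.size == 10 and peaks48.size == 6

    def test_full_dropout_maps_to_qi3(self):
        burst, _ = synth.gen_ecg(
            70.0, artifact_prob=1.0, artifact="dropout", artifact_span_s=7.5, seed=0)
        rec = burst_to_record(burst)
        assert rec.qi == 3 and rec.hr_bpm is None

    def test_hr_bounds_enforced(self):
        with pytest.raises(ValueError):
            synth.gen_ecg(20.0)


class TestTriaxialGenerator:
    def test_calibrated_external_accel_at_tank_speed(self):
        trace, truth = synth.gen_triaxial(0.50, "steady", seed=2)
        _, dyn = split_static_dynamic(trace)
        assert external_acceleration(dyn) == pytest.approx(13.04, rel=0.02)
        assert truth["target_ext_accel_mg"] == pytest.approx(13.035, abs=1e-9)

    def test_zero_speed_zero_odba(self):
        trace, _ = synth.gen_triaxial(0.0, noise_sd_g=0.0)
        _, dyn = split_static_dynamic(trace)
        assert odba(dyn) == pytest.approx(0.0, abs=1e-12)

    def test_burst_glide_drop_at_top_speed(self):
        hi, truth_hi = synth.gen_triaxial(0.90, "steady", seed=3)
        mid, _ = synth.gen_triaxial(0.75, "steady", seed=4)
        _, dyn_hi = split_static_dynamic(hi)
        _, dyn_mid = split_static_dynamic(mid)
        assert truth_hi["burst_glide"]
        assert external_acceleration(dyn_hi) < external_acceleration(dyn_mid)


class TestSentinelGenerator:
    def test_noise_free_summary_equals_cells(self):
        data, truth = synth.gen_sentinel(
            n_fish=3, weeks_per_phase=0.5,
            intercept_sd={m: 0.0 for m in synth.SENTINEL_CELL_MEANS},
            resid_sd={m: 0.0 for m in synth.SENTINEL_CELL_MEANS}, seed=0)
        out = day_night_summary(data)
        for _, row in out.iterrows():
            expected = truth["cell_means"][row["metric"]][(row["treatment"], row["period"])]
            assert row["mean"] == pytest.approx(expected, abs=1e-9)

    def test_phase_schedule(self):
        data, _ = synth.gen_sentinel(n_fish=2, weeks_per_phase=1.0, seed=0)
        one = data[data["fish_id"] == "fish01"].sort_values("timestamp")
        switch = one["treatment"].ne(one["treatment"].shift()).to_numpy().nonzero()[0]
        assert list(one["treatment"].unique()) == ["steady", "unsteady"]
        assert switch.size == 2  # start plus the single phase change

    def test_small_treatment_effect_in_truth(self):
        _, truth = synth.gen_sentinel(n_fish=2, weeks_per_phase=0.25, seed=0)
        assert truth["treatment_effect"]["hr_bpm"] == pytest.approx(2.05, abs=0.01)
        assert truth["period_effect"]["hr_bpm"] == pytest.approx(10.65, abs=0.01)


class TestTransmitter:
    def test_detection_count_bounds(self):
        t = np.arange(0, 3600.0, 1.0)
        det = synth.gen_transmitter_stream(t, np.ones_like(t), seed=5)
        assert 72 <= len(det) <= 120

    def test_constant_odba_carried_through(self):
        t = np.arange(0, 600.0, 0.2)
        det = synth.gen_transmitter_stream(t, np.full_like(t, 1.3), seed=6)
        assert np.allclose(det["odba_ms2"], 1.3)

    def test_short_series_rejected(self):
        t = np.arange(0, 40.0, 1.0)
        with pytest.raises(ValueError):
            synth.gen_transmitter_stream(t, np.ones_like(t))


class TestDeterminism:
    def test_identical_seed_identical_output(self):
        for gen in (
            lambda s: synth.gen_respiro_session(true_mo2_by_speed={0.3: 213.0}, seed=s)[0],
            lambda s: pd.DataFrame({"x": synth.gen_ecg(70.0, noise_sd=0.1, seed=s)[0].samples}),
            lambda s: pd.DataFrame({"x": synth.gen_triaxial(0.5, seed=s)[0].ay_g}),
            lambda s: synth.gen_sentinel(n_fish=2, weeks_per_phase=0.1, seed=s)[0],
        ):
            a, b = gen(77), gen(77)
            pd.testing.assert_frame_equal(a, b)
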