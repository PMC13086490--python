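"""Oxygen-consumption, cost-of-transport and swim-speed computations."""

import numpy as np
import pandas as pd
import pytest

from swimtag import synth
from swimtag.respirometry import (
    CotCurve,
    Mo2Record,
    RespiroConfig,
    UcritInput,
    check_solid_blocking,
    compute_cot,
    compute_mo2,
    compute_ucrit,
    fit_cot_curve,
    fulton_k,
    session_summary,
    subtract_background,
)


def linear_trace(delta_pct: float, duration_s: float, dt: float = 2.0) -> pd.DataFrame:
    t = np.arange(0.0, duration_s + dt / 2, dt)
    do = 100.0 - delta_pct * (t - t[0]) / (t[-1] - t[0])
    return pd.DataFrame({"time_s": t, "do_percent": do, "phase": "measure", "speed_mps": 0.3})


class TestComputeMo2:
    cfg = RespiroConfig(chamber_volume_l=30, do_max_mg_l=8, body_mass_kg=0.46)

    def test_hand_arithmetic(self):
        # 5% decline over 15 min: (0.05 * 8 * 30) / (0.46 * 0.25)
        rec = compute_mo2(linear_trace(5.0, 900.0), self.cfg)
        assert rec.mo2 == pytest.approx(104.35, abs=0.01)

    def test_zero_decline(self):
        rec = compute_mo2(linear_trace(0.0, 900.0), self.cfg)
        assert rec.mo2 == pytest.approx(0.0, abs=1e-9)

    def test_noisy_recovery_within_5pct(self):
        trace, _ = synth.gen_respiro_session(
            true_mo2_by_speed={0.30: 213.0}, noise_sd_pct=0.5, seed=7
        )
        table = session_summary(trace, self.cfg)
        assert table["mo2"].iloc[0] == pytest.approx(213.0, rel=0.05)
        assert table["n_replicates"].iloc[0] == 3

    def test_rejects_non_monotone_time(self):
        bad = linear_trace(5.0, 900.0)
        bad.loc[10, "time_s"] = bad.loc[9, "time_s"]
        with pytest.raises(ValueError, match="increasing"):
            compute_mo2(bad, self.cfg)

    def test_rejects_short_phase(self):
        with pytest.raises(ValueError, match="samples"):
            compute_mo2(linear_trace(5.0, 40.0), self.cfg)

    def test_rising_oxygen_flags_zero(self):
        with pytest.warns(UserWarning, match="rose"):
            rec = compute_mo2(linear_trace(-3.0, 900.0), self.cfg)
        assert rec.mo2 == 0.0 and rec.flagged

    @pytest.mark.parametrize("factor", [2.0, 0.5])
    def test_scaling_laws(self, factor):
        """MO2 is linear in dO2 and V, inverse in BM and t."""
        base = compute_mo2(linear_trace(5.0, 900.0), self.cfg).mo2
        assert compute_mo2(linear_trace(5.0 * factor, 900.0), self.cfg).mo2 == pytest.approx(
            base * factor
        )
        cfg_v = RespiroConfig(chamber_volume_l=30 * factor, do_max_mg_l=8, body_mass_kg=0.46)
        assert compute_mo2(linear_trace(5.0, 900.0), cfg_v).mo2 == pytest.approx(base * factor)
        cfg_bm = RespiroConfig(chamber_volume_l=30, do_max_mg_l=8, body_mass_kg=0.46 * factor)
        assert compute_mo2(linear_trace(5.0, 900.0), cfg_bm).mo2 == pytest.approx(base / factor)
        # same total decline over scaled duration
        assert compute_mo2(linear_trace(5.0, 900.0 * factor), self.cfg).mo2 == pytest.approx(
            base / factor
        )


class TestBackground:
    def test_subtraction(self):
        rec = subtract_background(Mo2Record(0.3, 220.0), Mo2Record(0.3, 10.0))
        assert rec.mo2 == 210.0 and rec.background_corrected

    def test_clamps_with_warning(self):
        with pytest.warns(UserWarning, match="clamping"):
            rec = subtract_background(Mo2Record(0.3, 5.0), Mo2Record(0.3, 10.0))
        assert rec.mo2 == 0.0

    def test_zero_background_identity(self):
        assert subtract_background(Mo2Record(0.3, 213.0), Mo2Record(0.3, 0.0)).mo2 == 213.0


class TestCot:
    def test_values(self):
        assert compute_cot(307.0, 0.9) == pytest.approx(94.75, abs=0.01)
        assert compute_cot(123.0, 1.0 / 3.6) == pytest.approx(123.0)
        assert compute_cot(0.0, 0.5) == 0.0

    def test_rejects_nonpositive_speed(self):
        with pytest.raises(ValueError):
            compute_cot(100.0, 0.0)

    def test_cot_of_mo2_is_algebraic_identity(self, rng):
        """COT(MO2(trace), U) equals the closed form dO2*DOmax*V/(100*BM*t*3.6*U)."""
        for _ in range(10):
            delta = rng.uniform(1, 10)
            v, do, bm = rng.uniform(10, 50), rng.uniform(6, 10), rng.uniform(0.2, 1.0)
            u = rng.uniform(0.2, 1.0)
            cfg = RespiroConfig(chamber_volume_l=v, do_max_mg_l=do, body_mass_kg=bm)
            mo2 = compute_mo2(linear_trace(delta, 900.0), cfg).mo2
            expected = (delta / 100) * do * v / (bm * 0.25) / (3.6 * u)
            assert compute_cot(mo2, u) == pytest.approx(expected)


class TestCotCurve:
    speeds = [0.15, 0.3, 0.45, 0.6, 0.75, 0.9]

    def test_exact_parabola(self):
        pts = [(u, 100 + 50 * (u - 0.5) ** 2) for u in self.speeds]
        curve = fit_cot_curve(pts)
        assert curve.valid
        assert curve.u_opt == pytest.approx(0.50, abs=1e-9)
        assert curve.cot_min == pytest.approx(100.0, abs=1e-9)

    def test_uopt_matches_grid_minimizer(self):
        """Vertex of the fit equals a 1e-4 m/s grid search over the polynomial."""
        mo2 = lambda u: 180 + 160 * u**3
        pts = [(u, compute_cot(mo2(u), u)) for u in self.speeds]
        curve = fit_cot_curve(pts)
        c0, c1, c2 = curve.poly_coeffs
        grid = np.arange(self.speeds[0], self.speeds[-1] + 1e-4, 1e-4)
        u_grid = grid[np.argmin(c0 + c1 * grid + c2 * grid**2)]
        assert curve.valid
        assert curve.u_opt == pytest.approx(u_grid, abs=1e-4)

    def test_monotone_decreasing_is_invalid(self):
        pts = [(u, 500 - 300 * u) for u in self.speeds]
        assert not fit_cot_curve(pts).valid

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_cot_curve([(0.3, 100), (0.45, 90), (0.6, 95)])


class TestUcrit:
    def test_prorated(self):
        assert compute_ucrit(UcritInput(0.75, 0.15, 15, 30)) == pytest.approx(0.825)

    def test_boundaries(self):
        assert compute_ucrit(UcritInput(0.75, 0.15, 0, 30)) == 0.75
        assert compute_ucrit(UcritInput(0.75, 0.15, 30, 30)) == pytest.approx(0.90)

    def test_monotone_in_fatigue_time(self):
        vals = [compute_ucrit(UcritInput(0.75, 0.15, t, 30)) for t in range(0, 31, 5)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_invalid_fatigue_time_rejected(self):
        with pytest.raises(ValueError):
            UcritInput(0.75, 0.15, 31, 30)


def test_solid_blocking_check():
    assert check_solid_blocking(50, 625)  # 8% of a 25x25 cm section
    assert not check_solid_blocking(62.5, 625)  # 10% exactly: strict <
    assert check_solid_blocking(6.25, 625)
    with pytest.raises(ValueError):
        check_solid_blocking(700, 625)


def test_fulton_condition_factor():
    assert fulton_k(460, 30) == pytest.approx(1.70, abs=0.005)
    assert fulton_k(1000, 10) == pytest.approx(100.0)
    assert fulton_k(460, 60) == pytest.approx(fulton_k(460, 30) / 8)
    with pytest.raises(ValueError):
        fulton_k(-1, 30)
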