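"""Day/night labelling, hourly aggregation and the random-intercept model."""

import numpy as np
import pandas as pd
import pytest

from swimtag import synth
from swimtag.circadian import (
    day_night_summary,
    fit_lmm,
    hourly_aggregate,
    label_period,
)


class TestLabelPeriod:
    @pytest.mark.parametrize(
        "ts,expected",
        [
            ("2023-10-01 09:00", "day"),     # morning feeding hour
            ("2023-10-01 03:30", "night"),
            ("2023-10-01 17:59", "day"),     # inclusive upper day bin
            ("2023-10-01 18:00", "night"),
            ("2023-10-01 05:59", "night"),
            ("2023-10-01 06:00", "day"),
        ],
    )
    def test_examples(self, ts, expected):
        assert label_period(pd.Timestamp(ts)) == expected

    def test_partition_is_exhaustive(self):
        labels = [label_period(pd.Timestamp(2023, 10, 1, h)) for h in range(24)]
        assert labels.count("day") == 12 and labels.count("night") == 12
        assert all(lab in ("day", "night") for lab in labels)


def _toy(hr_by_fish, hours=range(24)):
    rows = []
    for fish, hr in hr_by_fish.items():
        for h in hours:
            rows.append({"fish_id": fish, "timestamp": pd.Timestamp(2023, 10, 1, h),
                         "treatment": "steady", "hr_bpm": hr})
    return pd.DataFrame(rows)


class TestHourlyAggregate:
    def test_single_fish_constant(self):
        per_fish, group = hourly_aggregate(_toy({"f1": 70.0}))
        assert (per_fish["hr_bpm"] == 70.0).all()
        assert (group["hr_bpm_mean"] == 70.0).all()

    def test_two_fish_sem(self):
        _, group = hourly_aggregate(_toy({"f1": 60.0, "f2": 80.0}))
        assert (group["hr_bpm_mean"] == 70.0).all()
        assert np.allclose(group["hr_bpm_sem"], 10.0)

    def test_order_and_duplication_invariance(self):
        df = _toy({"f1": 60.0, "f2": 80.0})
        shuffled = df.sample(frac=1.0, random_state=0)
        dup = pd.concat([df, df], ignore_index=True)
        base = hourly_aggregate(df)[1]["hr_bpm_mean"]
        assert np.allclose(hourly_aggregate(shuffled)[1]["hr_bpm_mean"], base)
        assert np.allclose(hourly_aggregate(dup)[1]["hr_bpm_mean"], base)

    def test_m_shaped_profile_peaks_at_feedings(self):
        data, _ = synth.gen_sentinel(n_fish=4, weeks_per_phase=1.0, seed=5)
        _, group = hourly_aggregate(data)
        prof = group[group["treatment"] == "steady"].set_index("hour")["hr_bpm_mean"]
        # feeding peaks stand above the midday dip and the night level
        midday = prof.loc[12:13].mean()
        assert prof.loc[9] > midday and prof.loc[16] > midday
        assert prof.loc[[9, 16]].mean() > prof.loc[[1, 2, 3]].mean() + 5


class TestDayNightSummary:
    def test_constant_input_identical_cells(self):
        df = _toy({"f1": 70.0, "f2": 70.0})
        out = day_night_summary(df)
        hr = out[out["metric"] == "hr_bpm"]
        assert np.allclose(hr["mean"], 70.0)

    def test_recovers_generator_cell_within_1bpm(self):
        data, truth = synth.gen_sentinel(seed=11)
        out = day_night_summary(data)
        cell = out[(out["metric"] == "hr_bpm") & (out["treatment"] == "unsteady")
                   & (out["period"] == "day")]["mean"].iloc[0]
        assert cell == pytest.approx(truth["cell_means"]["hr_bpm"][("unsteady", "day")],
                                     abs=1.0)

    def test_var_ordering_preserved(self):
        data, _ = synth.gen_sentinel(n_fish=6, weeks_per_phase=0.5, seed=21)
        out = day_night_summary(data)
        var = out[out["metric"] == "var_mg2"].set_index(["treatment", "period"])["mean"]
        assert var[("unsteady", "day")] > var[("steady", "day")]
        assert var[("unsteady", "night")] > var[("steady", "night")]


class TestLmm:
    def test_single_fish_rejected(self):
        df = _toy({"f1": 70.0})
        df.loc[df.index[:12], "treatment"] = "unsteady"
        with pytest.raises(ValueError, match="fish"):
            fit_lmm(df, "hr_bpm")

    def test_period_effect_recovery_with_11bpm_truth(self):
        cells = {"hr_bpm": {("steady", "day"): 71.5, ("steady", "night"): 60.5,
                            ("unsteady", "day"): 73.5, ("unsteady", "night"): 62.5}}
        data, _ = synth.gen_sentinel(cell_means=cells, seed=31)
        fit = fit_lmm(data, "hr_bpm", interaction=False)
        est, se = fit.fe_params["period_day"], fit.fe_se["period_day"]
        assert abs(est - 11.0) <= 2 * se + 1e-9
        assert fit.n_fish == 10 and fit.converged

    def test_recovery_rate_across_replicates(self):
        """Period estimate within 2 SE of truth in >= 18 of 20 replicates."""
        hits = 0
        for seed in range(20):
            data, truth = synth.gen_sentinel(n_fish=6, weeks_per_phase=0.5, seed=200 + seed)
            fit = fit_lmm(data, "hr_bpm", interaction=False)
            est, se = fit.fe_params["period_day"], fit.fe_se["period_day"]
            hits += abs(est - truth["period_effect"]["hr_bpm"]) <= 2 * se
        assert hits >= 18

    def test_balanced_subsampling_stability(self):
        data, _ = synth.gen_sentinel(n_fish=8, weeks_per_phase=1.0, seed=41)
        full = fit_lmm(data, "hr_bpm", interaction=False)
        half = fit_lmm(data.iloc[::2].reset_index(drop=True), "hr_bpm", interaction=False)
        assert half.fe_params["period_day"] == pytest.approx(
            full.fe_params["period_day"], abs=3 * half.fe_se["period_day"])
        assert half.fe_params["treatment_unsteady"] == pytest.approx(
            full.fe_params["treatment_unsteady"], abs=3 * half.fe_se["treatment_unsteady"])

    def test_singular_fit_converges_with_flag(self):
        data, _ = synth.gen_sentinel(
            n_fish=4, weeks_per_phase=0.25, intercept_sd={"hr_bpm": 0.0}, seed=51)
        fit = fit_lmm(data, "hr_bpm", interaction=False)
        assert fit.converged
        assert fit.random_intercept_var < 0.5
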