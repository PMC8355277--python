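"""Value tuning, population binomial test, timecourses, latency, ANOVA."""

import numpy as np
import pandas as pd
import pytest

from vdgradient import DegenerateDataError
from vdgradient.selectivity import (latency_anova, population_selectivity,
                                    response_latency, selectivity_timecourse,
                                    value_tuning)
from vdgradient.task import EPOCHS, SpikeTrainSet


class TestValueTuning:
    def test_perfect_linear_tuning(self, rng):
        ev = rng.uniform(0, 200, size=50)
        res = value_tuning(2.0 * ev[None, :], ev)
        assert res.r[0] == pytest.approx(1.0)
        assert res.p[0] < 1e-12
        assert bool(res.selective[0])

    def test_r_squared_consistency(self, rng):
        # build a neuron with r ~ -0.6 and check r2 = r^2 exactly
        ev = rng.uniform(0, 200, size=5000)
        noise = rng.standard_normal(5000)
        y = -0.6 * (ev - ev.mean()) / ev.std() + 0.8 * noise
        res = value_tuning(y[None, :], ev)
        assert res.r2[0] == pytest.approx(res.r[0] ** 2)
        assert res.r[0] < -0.4

    def test_null_calibration_fraction(self, rng):
        # 1000 untuned neurons: selective fraction ~ alpha
        rates = rng.standard_normal((1000, 80))
        ev = rng.uniform(0, 200, size=80)
        res = value_tuning(rates, ev, alpha=0.05)
        frac = res.selective.mean()
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 1000)

    def test_zero_variance_neuron_flagged_not_raised(self, rng):
        rates = np.vstack([np.full(30, 4.0), rng.standard_normal(30)])
        res = value_tuning(rates, rng.uniform(0, 1, 30))
        assert not res.valid[0] and np.isnan(res.r[0])
        assert res.valid[1]


class TestPopulationSelectivity:
    @pytest.mark.parametrize("k,n,expected", [
        (25, 156, 16.03), (34, 129, 26.36),
    ])
    def test_reported_proportions(self, k, n, expected):
        flags = pd.DataFrame({"selective": [True] * k + [False] * (n - k)})
        prop, p = population_selectivity(flags)
        assert 100 * prop == pytest.approx(expected, abs=0.005)
        assert p < 0.01

    def test_empty_tail_gives_p_one(self):
        flags = pd.DataFrame({"selective": [False] * 100})
        prop, p = population_selectivity(flags, null_rate=0.05)
        assert prop == 0.0
        assert p == pytest.approx(1.0)


class TestTimecourse:
    def test_step_equal_window_partitions_span(self, tuned_dataset):
        tc = selectivity_timecourse(
            tuned_dataset.spikes, tuned_dataset.trials,
            tuned_dataset.trials.ev1.to_numpy(),
            window_ms=500.0, step_ms=500.0, span_ms=(-500.0, 2500.0))
        assert len(tc) == 6
        assert np.allclose(np.diff(tc.center_ms), 500.0)

    def test_tuning_peaks_in_its_epoch(self, tuned_dataset):
        tc = selectivity_timecourse(
            tuned_dataset.spikes, tuned_dataset.trials,
            tuned_dataset.trials.ev1.to_numpy(),
            window_ms=500.0, step_ms=100.0, span_ms=(-500.0, 1000.0))
        # ev1 tuning exists only in epoch 1 ([0, 500) ms): the fully
        # overlapping window (center 250 ms) must beat the baseline window
        at_peak = tc.loc[(tc.center_ms - 250).abs().idxmin(), "prop_selective"]
        baseline = tc.loc[tc.center_ms < 0, "prop_selective"].mean()
        assert at_peak > baseline + 0.2


def _psth_spikeset(psth_counts, n_trials=40):
    """SpikeTrainSet whose epoch-1 PSTH equals the requested per-bin counts."""
    times, ni, ti = [], [], []
    for b, c in enumerate(psth_counts):
        for k in range(n_trials):
            reps = int(c)
            t = 0.0205 * 0 + b * 0.020 + 0.010 + np.zeros(reps)
            times.append(t)
            ni.append(np.zeros(reps, int))
            ti.append(np.full(reps, k))
    return SpikeTrainSet(np.concatenate(times), np.concatenate(ni),
                         np.concatenate(ti), 1, n_trials, (-2.0, 3.2))


class TestLatency:
    def test_peak_latency_at_bin_center(self):
        from vdgradient.synth import generate_trials
        trials = generate_trials(40, seed=0)
        counts = np.ones(25)
        counts[13] = 5.0  # bin [260, 280) ms, center 270 ms
        spikes = _psth_spikeset(counts)
        lat = response_latency(spikes, trials, EPOCHS["epoch1"], method="peak")
        assert lat.latency_ms[0] == pytest.approx(270.0)

    def test_flat_psth_ties_to_earliest_bin(self):
        from vdgradient.synth import generate_trials
        trials = generate_trials(40, seed=0)
        spikes = _psth_spikeset(np.ones(25))
        lat = response_latency(spikes, trials, EPOCHS["epoch1"], method="peak")
        assert lat.latency_ms[0] == pytest.approx(10.0)  # first bin center

    def test_first_change_precedes_peak_change(self, tuned_dataset):
        pc = response_latency(tuned_dataset.spikes, tuned_dataset.trials,
                              EPOCHS["epoch1"], method="peak_change")
        fc = response_latency(tuned_dataset.spikes, tuned_dataset.trials,
                              EPOCHS["epoch1"], method="first_change_2sd")
        both = (~pc.latency_ms.isna()) & (~fc.latency_ms.isna())
        assert both.any()
        assert (pc.latency_ms[both] >= fc.latency_ms[both]).all()

    def test_sig_methods_require_values(self, tuned_dataset):
        with pytest.raises(DegenerateDataError, match="values"):
            response_latency(tuned_dataset.spikes, tuned_dataset.trials,
                             EPOCHS["epoch1"], method="onset_to_sig")


class TestLatencyAnova:
    def _frame(self, rng, shift=None):
        rows = []
        for i, area in enumerate(("a1", "a2", "a3", "a4")):
            for offer in (1, 2):
                mu = 250.0 + (shift if (shift and i == 3) else 0.0)
                for v in rng.normal(mu, 40.0, size=50):
                    rows.append({"area": area, "offer": offer,
                                 "latency_ms": v})
        return pd.DataFrame(rows)

    def test_detects_shifted_area(self, rng):
        f_a, p_a, _, _ = latency_anova(self._frame(rng, shift=100.0))
        assert p_a < 0.001

    def test_null_rejects_rarely(self):
        rejections = 0
        for s in range(30):
            r = np.random.default_rng(s)
            _, p_a, _, _ = latency_anova(self._frame(r))
            rejections += p_a < 0.05
        assert rejections <= 5

    def test_degenerate_constant_latencies_raise(self):
        df = pd.DataFrame({"area": ["a", "a", "b", "b"] * 2,
                           "offer": [1, 1, 1, 1, 2, 2, 2, 2],
                           "latency_ms": 100.0})
        with pytest.raises(DegenerateDataError, match="constant"):
            latency_anova(df)

    def test_empty_cell_named(self, rng):
        df = self._frame(rng)
        df = df[~((df.area == "a2") & (df.offer == 2))]
        with pytest.raises(DegenerateDataError, match="a2"):
            latency_anova(df)
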