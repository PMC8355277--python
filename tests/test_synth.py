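"""Synthetic-data generator: determinism, behavior, ground-truth structure."""

import numpy as np
import pandas as pd
import pytest

from vdgradient import ConfigError
from vdgradient.synth import (AreaSpec, BehaviorSpec, CORE_WEIGHTS,
                              calibrate_choice_temperature, generate_trials,
                              generate_gradient_dataset, higher_ev_choice_rate,
                              simulate_area, _draw_neuron_specs)
from vdgradient._rng import substream
from vdgradient.task import EPOCHS, bin_spikes, epoch_rates


class TestGenerateTrials:
    def test_deterministic_under_seed(self):
        a = generate_trials(200, seed=42)
        b = generate_trials(200, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self):
        a = generate_trials(200, seed=42)
        b = generate_trials(200, seed=43)
        assert not a.equals(b)

    def test_infinite_beta_always_picks_higher_ev(self):
        t = generate_trials(2000, behavior=BehaviorSpec(beta=1e6), seed=1)
        assert higher_ev_choice_rate(t) == 1.0

    def test_zero_beta_is_indifferent(self):
        t = generate_trials(8000, behavior=BehaviorSpec(beta=0.0), seed=1)
        assert abs(higher_ev_choice_rate(t) - 0.5) < 0.02

    def test_calibration_hits_target(self):
        beta = calibrate_choice_temperature(target=0.80, n_trials=10_000, seed=9)
        t = generate_trials(10_000, behavior=BehaviorSpec(beta=beta), seed=123)
        assert abs(higher_ev_choice_rate(t) - 0.80) < 0.02

    def test_reward_follows_chosen_probability(self):
        t = generate_trials(20_000, seed=8)
        chosen_p = np.where(t.chosen_offer == 1, t.offer1_prob, t.offer2_prob)
        hi = chosen_p > 0.8
        lo = chosen_p < 0.2
        assert t.rewarded[hi].mean() > 0.8
        assert t.rewarded[lo].mean() < 0.2


class TestSimulateArea:
    def test_deterministic_under_seed(self, trials120):
        area = AreaSpec("a", 1, 5, 1.0, 200.0)
        s1, _ = simulate_area(trials120, area, seed=3, time_range=(-0.2, 0.7))
        s2, _ = simulate_area(trials120, area, seed=3, time_range=(-0.2, 0.7))
        np.testing.assert_array_equal(s1.times, s2.times)
        np.testing.assert_array_equal(s1.neuron_index, s2.neuron_index)

    def test_poisson_fano_near_one(self, poisson_dataset):
        tensor = bin_spikes(poisson_dataset.spikes, EPOCHS["epoch1"],
                            poisson_dataset.trials)
        counts = tensor.counts.sum(axis=2).astype(float)
        ff = counts.var(axis=1, ddof=1) / counts.mean(axis=1)
        assert abs(ff.mean() - 1.0) < 0.1

    def test_strong_tuning_correlates_with_ev(self, trials120):
        # injected ground truth: a huge ev1 weight in epoch 1, low noise
        from vdgradient.synth import NeuronSpec
        area = AreaSpec("a", 1, 2, 1.0, 200.0)
        specs = [NeuronSpec(baseline_rate=150.0, beta_ev1_e1=60.0,
                            ou_tau=200.0, ou_sigma=0.5),
                 NeuronSpec(baseline_rate=150.0, beta_ev1_e1=-60.0,
                            ou_tau=200.0, ou_sigma=0.5)]
        spikes, _ = simulate_area(trials120, area, seed=2, specs=specs,
                                  time_range=(-0.2, 0.7))
        rates = epoch_rates(bin_spikes(spikes, EPOCHS["epoch1"], trials120)).rates
        ev = trials120.ev1.to_numpy()
        assert np.corrcoef(rates[0], ev)[0, 1] > 0.9
        assert np.corrcoef(rates[1], ev)[0, 1] < -0.9

    def test_weight_population_correlations_realized(self):
        area = AreaSpec("a", 1, 2000, 1.0, 200.0)
        specs = _draw_neuron_specs(area, substream(0, "w"))
        w = {name: np.array([getattr(s, f"beta_{name}") for s in specs])
             for name in CORE_WEIGHTS}
        se = 1.0 / np.sqrt(2000)
        assert abs(np.corrcoef(w["prob1"], w["mag1"])[0, 1] - 0.5) < 4 * se
        assert abs(np.corrcoef(w["ev1_e1"], w["ev2_e2"])[0, 1] - 0.5) < 4 * se
        assert abs(np.corrcoef(w["ev1_e2"], w["ev2_e2"])[0, 1] + 0.5) < 4 * se

    def test_non_psd_correlation_rejected(self, trials120):
        area = AreaSpec("a", 1, 5, 1.0, 200.0, weight_correlations={
            ("prob1", "mag1"): 0.9, ("prob1", "ev1_e1"): 0.9,
            ("mag1", "ev1_e1"): -0.9})
        with pytest.raises(ConfigError, match="positive"):
            simulate_area(trials120, area, seed=1, time_range=(-0.2, 0.7))

    def test_seed_isolation_of_substreams(self, trials120):
        # weights depend only on the weight substream: identical across
        # different spike realisations forced by different time ranges
        area = AreaSpec("a", 1, 8, 1.0, 200.0)
        _, sp1 = simulate_area(trials120, area, seed=6, time_range=(-0.2, 0.7))
        _, sp2 = simulate_area(trials120, area, seed=6, time_range=(-2.0, 3.2))
        assert [s.beta_ev1_e1 for s in sp1] == [s.beta_ev1_e1 for s in sp2]


class TestMonotonePower:
    def test_selective_fraction_rises_with_snr(self):
        # a 4-point SNR ladder: tuned fraction must be non-decreasing
        from vdgradient.selectivity import value_tuning
        trials = generate_trials(250, seed=13)
        fracs = []
        for snr in (0.0, 0.7, 1.4, 2.8):
            area = AreaSpec("p", 1, 100, snr, 200.0)
            spikes, _ = simulate_area(trials, area, seed=13,
                                      time_range=(-0.1, 0.6))
            rates = epoch_rates(bin_spikes(spikes, EPOCHS["epoch1"], trials))
            res = value_tuning(rates, trials.ev1.to_numpy())
            fracs.append(res.selective.mean())
        assert all(b >= a - 0.02 for a, b in zip(fracs, fracs[1:]))
        assert fracs[-1] > fracs[0] + 0.2


class TestGradientDataset:
    def test_default_preset_shapes_and_order(self):
        small = [AreaSpec(f"a{i}", i, 4, 0.5 * i, 100.0 + 50 * i)
                 for i in (1, 2, 3, 4)]
        ds = generate_gradient_dataset(seed=0, n_trials=20, areas=small,
                                       time_range=(-0.2, 0.7))
        assert [d.order_index for d in ds] == [1, 2, 3, 4]
        assert all(d.spikes.n_trials == 20 for d in ds)
        assert all(d.spikes.n_neurons == 4 for d in ds)

    def test_duplicate_order_rejected(self):
        bad = [AreaSpec("x", 1, 4, 1.0, 100.0), AreaSpec("y", 1, 4, 1.0, 100.0)]
        with pytest.raises(ConfigError, match="distinct"):
            generate_gradient_dataset(seed=0, n_trials=5, areas=bad)
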