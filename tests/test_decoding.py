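"""Pseudo-population construction, SVM decoding, controls, gradient tests."""

import numpy as np
import pytest

from vdgradient import DegenerateDataError
from vdgradient.decoding import (DEFAULT_LABELS, battery_frame,
                                 binarize_label, build_pseudopopulation,
                                 decode_label, decoder_battery,
                                 gradient_order_test, label_values,
                                 multinomial_ev_control,
                                 _train_test_split_classes)


class TestLabels:
    def test_all_twelve_labels_derivable(self, trials120):
        for spec in DEFAULT_LABELS:
            vals, valid = label_values(trials120, spec.source)
            y = binarize_label(vals, spec.continuous, valid)
            assert np.unique(y[valid]).size == 2

    def test_prev_labels_invalid_on_first_trial(self, trials120):
        _, valid = label_values(trials120, "prev_chosen_offer")
        assert not valid[0] and valid[1:].all()

    def test_mean_split_ties_go_low(self):
        y = binarize_label(np.array([1.0, 2.0, 3.0]), continuous=True)
        assert list(y) == [0, 0, 1]  # the mean itself is "low"


class TestPseudoPopulation:
    def test_one_matrix_per_level_with_requested_shape(self, rng):
        rates = rng.standard_normal((3, 40))
        labels = np.repeat([0, 1], 20)
        pp = build_pseudopopulation(rates, labels, 1000, rng)
        assert set(pp.matrices) == {0, 1}
        assert pp.matrices[0].shape == (3, 1000)
        assert pp.matrices[1].shape == (3, 1000)

    def test_constant_neuron_rows_constant(self, rng):
        rates = np.vstack([np.full(40, 7.0), rng.standard_normal(40)])
        labels = np.repeat([0, 1], 20)
        pp = build_pseudopopulation(rates, labels, 100, rng)
        assert np.all(pp.matrices[0][0] == 7.0)
        assert np.all(pp.matrices[1][0] == 7.0)

    def test_draw_frequencies_match_empirical(self, rng):
        vals = np.array([1.0, 2.0, 4.0, 8.0])
        rates = np.concatenate([vals, [0.0] * 4])[None, :]
        labels = np.repeat([0, 1], 4)
        pp = build_pseudopopulation(rates, labels, 100_000, rng)
        for v in vals:
            f = np.mean(pp.matrices[0][0] == v)
            assert abs(f - 0.25) < 0.01

    def test_missing_level_raises(self, rng):
        with pytest.raises(DegenerateDataError):
            build_pseudopopulation(rng.standard_normal((2, 10)),
                                   np.zeros(10, int), 10, rng,
                                   valid=np.zeros(10, bool))

    def test_train_test_disjoint_within_repeat(self, rng):
        rates = rng.standard_normal((2, 30))
        labels = np.repeat([0, 1], 15)
        pp = build_pseudopopulation(rates, labels, 100, rng)
        # tag pseudo-trials with unique ids to track the split
        for lev in pp.matrices:
            pp.matrices[lev] = np.vstack([pp.matrices[lev],
                                          np.arange(100)[None, :] + 1000 * lev])
        Xtr, _, Xte, _ = _train_test_split_classes(pp, rng)
        assert not set(Xtr[:, -1]) & set(Xte[:, -1])


class TestDecodeLabel:
    def test_separable_limit(self, rng):
        rates = np.concatenate([rng.normal(0, 1, (20, 50)),
                                rng.normal(10, 1, (20, 50))], axis=1)
        labels = np.repeat([0, 1], 50)
        res = decode_label(rates, labels, n_reps=10, seed=0, shuffle_reps=5,
                           n_pseudotrials=200)
        assert res.mean > 0.999

    def test_single_neuron_gaussian_oracle(self, rng):
        # one neuron, class means 0 and 1, unit noise: optimal accuracy is
        # Phi(1/2) ~ 0.691; many trials keep resampling bias negligible
        n = 4000
        rates = np.concatenate([rng.normal(0, 1, n),
                                rng.normal(1, 1, n)])[None, :]
        labels = np.repeat([0, 1], n)
        res = decode_label(rates, labels, n_reps=30, seed=0, shuffle_reps=5,
                           n_pseudotrials=500)
        from scipy.stats import norm
        assert abs(res.mean - norm.cdf(0.5)) < 0.02

    def test_shuffle_mean_at_chance(self, rng):
        rates = np.concatenate([rng.normal(0, 1, (30, 60)),
                                rng.normal(1, 1, (30, 60))], axis=1)
        labels = np.repeat([0, 1], 60)
        res = decode_label(rates, labels, n_reps=2, seed=0, shuffle_reps=60,
                           n_pseudotrials=400)
        assert 0.45 < res.shuffle_mean < 0.55

    def test_single_level_raises(self, rng):
        with pytest.raises(DegenerateDataError, match="two label levels"):
            decode_label(rng.standard_normal((2, 10)), np.zeros(10, int),
                         n_reps=2, seed=0)


class TestBattery:
    @pytest.fixture(scope="class")
    def battery(self, tuned_dataset):
        return decoder_battery(tuned_dataset, n_reps=6, n_pseudotrials=200,
                               seed=0, shuffle_reps=4)

    def test_all_twelve_run_and_beat_shuffle(self, battery):
        assert len(battery) == 12
        assert not any(r.skipped for r in battery)
        for r in battery:
            assert r.mean > r.shuffle_mean

    def test_frame_schema(self, battery):
        f = battery_frame(battery)
        assert set(f.columns) >= {"area", "label", "mean_acc", "se",
                                  "shuffle_mean", "n_reps", "n_neurons"}
        assert len(f) == 12

    def test_decimation_uses_exact_count(self, tuned_dataset):
        res = decoder_battery(tuned_dataset, n_reps=2, n_pseudotrials=100,
                              seed=0, shuffle_reps=1, decimate_to=20,
                              labels=DEFAULT_LABELS[:1])
        assert res[0].n_neurons == 20
        assert "20 neurons" in res[0].note

    def test_decimation_beyond_population_raises(self, tuned_dataset):
        with pytest.raises(DegenerateDataError, match="decimate"):
            decoder_battery(tuned_dataset, n_reps=1, seed=0, decimate_to=500)


class TestMultinomialControl:
    def test_untuned_rates_near_chance(self, rng):
        # few neurons + many trials keep the resampling bias negligible
        rates = rng.standard_normal((5, 3000))
        ev = rng.uniform(0, 240, size=3000)
        overall, per_class = multinomial_ev_control(
            rates, ev, n_reps=6, seed=0, n_pseudotrials=300)
        assert abs(overall.mean() - 1 / 6) < 0.05
        assert per_class.shape[1] == 6

    def test_strongly_tuned_rates_beat_chance(self, rng):
        ev = rng.uniform(0, 240, size=600)
        rates = np.vstack([ev + rng.normal(0, 5, 600) for _ in range(8)])
        overall, _ = multinomial_ev_control(rates, ev, n_reps=4, seed=0,
                                            n_pseudotrials=200)
        assert overall.mean() > 0.5


class TestGradientOrderTest:
    def test_printed_mean_accuracies_perfectly_ordered(self):
        rho, p = gradient_order_test([63.4, 67.1, 69.8, 71.9])
        assert rho == pytest.approx(1.0)
        assert p < 0.05

    def test_printed_baseline_rates(self):
        rho, _ = gradient_order_test([3.11, 3.69, 0.75, 5.06])
        assert rho == pytest.approx(0.4)

    def test_point_mass_distributions(self):
        dists = [np.full(50, v) for v in (0.6, 0.65, 0.7, 0.75)]
        rho, p = gradient_order_test(dists)
        assert rho == pytest.approx(1.0)

    def test_all_tied_values_raise(self):
        with pytest.raises(DegenerateDataError, match="tied"):
            gradient_order_test([1.0, 1.0, 1.0, 1.0])
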