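# vdgradient

Analysis pipeline for asking whether brain areas recorded in a two-offer
risky-choice task form a **functional gradient**: trial-aligned spike
trains from four areas, each tagged with a hypothesized order 1–4, are
characterized by per-neuron value selectivity, population signatures of
the choice computation, intrinsic timescales, pseudo-population decoding,
and intrinsic-property controls — then compared across areas with
rank-order statistics.  It is written for systems/computational
neuroscientists who have per-trial spike times plus a task table and want
the full battery, and it ships a synthetic spiking-data generator so every
stage is testable end to end without any recordings.

## The quantities at the core

* **Expected value.** An offer of magnitude *m* (µL) at probability *p*
  has EV = *m·p*; choice behavior is summarized by the higher-EV choice
  proportion and a logistic fit of P(choose offer 1) against EV₁ − EV₂.
* **Value selectivity.** Per neuron, Pearson correlation of 500-ms epoch
  firing rates with offer EV (two-sided, α = 0.05); per area, a one-sided
  exact binomial test of the selective proportion against the 5% false
  positive rate; five response-latency definitions with 4 (area) × 2
  (offer) ANOVAs.
* **Choice-process signatures.** OLS weights of z-scored epoch rates on
  task variables, correlated across the population: integration
  (probability vs magnitude weights, +), attentional alignment (EV₁ weight
  in epoch 1 vs EV₂ weight in epoch 2, +), mutual inhibition (EV₁ vs EV₂
  weights within epoch 2, −), and unsigned variants indexing population
  overlap.
* **Intrinsic timescale.** Across-trial spike-count autocorrelation in a
  2-s task-free pre-offer window (20-ms bins, lags 20–720 ms), fitted with
  R(kΔ) = A·[exp(−kΔ/τ) + B]; τ is the area's intrinsic timescale.
* **Decoding battery.** Twelve binary label/epoch decoders on
  pseudo-populations (per-neuron resampling, 1000 pseudo-trials per class),
  linear SVM with half/half cross-validation, a shuffle null calibrated at
  50%, a decimation-to-125-neurons control and a six-bin multinomial EV
  control.
* **Gradient-order statistics.** Spearman correlation of per-area decoding
  accuracies (or any control statistic) against the order 1–4, and Pearson
  correlation for the four τs.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
from vdgradient import (AreaSpec, generate_trials, simulate_area,
                        pretrial_autocorrelation, fit_exponential_decay,
                        timescale_gradient, decode_label, EPOCHS,
                        bin_spikes, epoch_rates)
from vdgradient.decoding import (label_values, binarize_label,
                                 gradient_order_test)

areas = [AreaSpec("vmPFC", 1, 156, 0.50, 110.0),
         AreaSpec("sgACC", 2, 146, 0.75, 150.0),
         AreaSpec("pgACC", 3, 213, 1.00, 320.0),
         AreaSpec("dACC",  4, 129, 1.60, 450.0)]

taus, accs = [], []
for area in areas:
    trials = generate_trials(500, seed=area.order_index)
    spikes, _ = simulate_area(trials, area, seed=1)

    fit = fit_exponential_decay(pretrial_autocorrelation(spikes, trials))
    taus.append(fit.tau_ms)

    rates = epoch_rates(bin_spikes(spikes, EPOCHS["epoch1"], trials))
    vals, valid = label_values(trials, "ev1")
    y = binarize_label(vals, True, valid)
    res = decode_label(rates, y, n_reps=100, seed=1, shuffle_reps=50,
                       label_name="ev1_epoch1", area=area.name)
    accs.append(res.mean)
    print(f"{area.name:>5}: tau = {fit.tau_ms:6.1f} ms   "
          f"EV1 decoding = {100*res.mean:.1f}%  "
          f"(shuffle {100*res.shuffle_mean:.1f}%)")

r, p = timescale_gradient(taus)
rho, sp = gradient_order_test(accs)
print(f"timescale gradient: Pearson r = {r:.2f} (p = {p:.3f})")
print(f"decoding  gradient: Spearman rho = {rho:.1f} (p = {sp:.3f})")
```

Output:

```
vmPFC: tau =  113.3 ms   EV1 decoding = 71.3%  (shuffle 49.9%)
sgACC: tau =  161.5 ms   EV1 decoding = 76.4%  (shuffle 50.3%)
pgACC: tau =  319.4 ms   EV1 decoding = 82.1%  (shuffle 50.0%)
 dACC: tau =  427.6 ms   EV1 decoding = 89.5%  (shuffle 50.1%)
timescale gradient: Pearson r = 0.98 (p = 0.017)
decoding  gradient: Spearman rho = 1.0 (p = 0.000)
```

The fitted timescales recover each area's Ornstein–Uhlenbeck ground truth
(110/150/320/450 ms), EV decoding accuracy rises with the preset's
signal-to-noise ladder while the shuffle null sits at 50%, and both
gradient statistics come out perfectly ordered — the same analyses one
would run on recorded data, validated here against known ground truth.

The same pipeline runs from the shell:

```bash
vdgradient simulate --seed 1 --out data/          # trials.csv, spikes.csv per area
vdgradient analyze  --seed 1 --data data/ --out results/
vdgradient report   --out results/
```

`analyze` writes tidy CSVs (tuning, latency, signatures, acf,
timescale_fits, decoding, gradient_tests, controls, behavior) plus a
`report.json` embedding the config hash and seed; a rerun with the same
config and seed reproduces it.

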