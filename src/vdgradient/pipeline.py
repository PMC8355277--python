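"""End-to-end orchestration: simulate → analyze → machine-readable report.

``run_pipeline`` executes every analysis stage on a four-area dataset
(simulated by default) and assembles a :class:`RunReport`; ``write_report``
serializes it as ``report.json`` plus tidy per-stage CSVs.  A single master
seed spawns named substreams per stage, so a rerun with identical config
and seed reproduces the report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import VDGradientError
from .config import (areas_from_config, behavior_from_config, config_hash,
                     load_config, task_from_config, validate_config)
from .decoding import (battery_frame, decoder_battery, gradient_order_test)
from .popstats import (baseline_rates, behavior_summary, fano_factor,
                       pca_dimensionality)
from .selectivity import (latency_anova, population_selectivity,
                          response_latency, selectivity_timecourse,
                          value_tuning)
from .signatures import compute_signatures
from .synth import generate_gradient_dataset
from .task import EPOCHS, bin_spikes, epoch_rates
from .timescale import (fit_exponential_decay, pretrial_autocorrelation,
                        timescale_gradient)

log = logging.getLogger("vdgradient")

__all__ = ["RunReport", "run_pipeline", "write_report", "read_report"]


@dataclass
class RunReport:
    """All per-area tables plus the cross-area gradient tests."""

    config: dict
    seed: int
    tables: dict = field(default_factory=dict)       # name -> DataFrame
    scalars: dict = field(default_factory=dict)      # name -> jsonable
    errors: list = field(default_factory=list)       # (stage, message)

    @property
    def hash(self) -> str:
        return config_hash(self.config)


def _stage(report, name):
    """Decorator-ish context: run fn, record failure, keep partial outputs."""
    class _Ctx:
        def __enter__(self):
            log.info("stage %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                report.errors.append((name, f"{exc_type.__name__}: {exc}"))
                log.error("stage %s failed: %s", name, exc)
                return True
            return False
    return _Ctx()


def _selectivity_stage(report, datasets, alpha=0.05):
    tune_rows, pop_rows, lat_rows, tc_rows = [], [], [], []
    for ds in datasets:
        rates = {e: epoch_rates(bin_spikes(ds.spikes, EPOCHS[e], ds.trials))
                 for e in ("epoch1", "epoch2")}
        combos = [("ev1", "epoch1"), ("ev2", "epoch2"), ("ev1", "epoch2")]
        for var, ep in combos:
            t = value_tuning(rates[ep], ds.trials[var].to_numpy(),
                             alpha=alpha, variable=var, epoch=ep)
            t.insert(0, "area", ds.name)
            tune_rows.append(t)
            prop, p = population_selectivity(t, alpha=alpha)
            pop_rows.append({"area": ds.name, "variable": var, "epoch": ep,
                             "prop_selective": prop, "binomial_p": p,
                             "n_neurons": len(t)})
        for offer, ep, var in ((1, "epoch1", "ev1"), (2, "epoch2", "ev2")):
            for method in ("peak", "first_change_2sd"):
                lat = response_latency(ds.spikes, ds.trials, EPOCHS[ep],
                                       method=method,
                                       values=ds.trials[var].to_numpy())
                lat.insert(0, "area", ds.name)
                lat.insert(1, "offer", offer)
                lat_rows.append(lat)
        for var in ("ev1", "ev2"):
            tc = selectivity_timecourse(ds.spikes, ds.trials,
                                        ds.trials[var].to_numpy(),
                                        span_ms=(-500.0, 2500.0))
            tc.insert(0, "area", ds.name)
            tc.insert(1, "variable", var)
            tc_rows.append(tc)
    report.tables["tuning"] = pd.concat(tune_rows, ignore_index=True)
    report.tables["population_selectivity"] = pd.DataFrame(pop_rows)
    lat = pd.concat(lat_rows, ignore_index=True)
    report.tables["latency"] = lat
    report.tables["timecourse"] = pd.concat(tc_rows, ignore_index=True)

    peak = lat[lat["method"] == "peak"]
    f_a, p_a, f_o, p_o = latency_anova(peak)
    report.scalars["latency_anova"] = {
        "F_area": f_a, "p_area": p_a, "F_offer": f_o, "p_offer": p_o}
    means = peak.groupby("area", observed=True)["latency_ms"].mean()
    report.scalars["peak_latency_grand_mean_ms"] = float(means.mean())


def _signatures_stage(report, datasets):
    rows = []
    for ds in datasets:
        r1 = epoch_rates(bin_spikes(ds.spikes, EPOCHS["epoch1"], ds.trials),
                         zscore=True)
        r2 = epoch_rates(bin_spikes(ds.spikes, EPOCHS["epoch2"], ds.trials),
                         zscore=True)
        sig = compute_signatures(r1, r2, ds.trials)
        sig.insert(0, "area", ds.name)
        rows.append(sig)
    report.tables["signatures"] = pd.concat(rows, ignore_index=True)


def _timescale_stage(report, datasets, cfg):
    acf_rows, fit_rows, fits, taus = [], [], [], []
    for ds in datasets:
        acf = pretrial_autocorrelation(
            ds.spikes, ds.trials,
            delta_ms=float(cfg["timescale"]["delta_ms"]),
            max_lag_ms=float(cfg["timescale"]["max_lag_ms"]))
        acf_rows.append(pd.DataFrame({
            "area": ds.name, "lag_ms": acf.lags_ms, "R": acf.R, "se": acf.se}))
        fit = fit_exponential_decay(acf)
        fits.append(fit)
        taus.append(fit.tau_ms)
        fit_rows.append({"area": ds.name, "order_index": ds.order_index,
                         "A": fit.A, "tau_ms": fit.tau_ms, "B": fit.B,
                         "sse": fit.sse, "converged": fit.converged,
                         "n_neurons_used": acf.n_neurons_used,
                         "n_neurons_excluded": acf.n_neurons_excluded})
    report.tables["acf"] = pd.concat(acf_rows, ignore_index=True)
    report.tables["timescale_fits"] = pd.DataFrame(fit_rows)
    order = [ds.order_index for ds in datasets]
    r, p = timescale_gradient(taus, order, fits=fits)
    report.scalars["timescale_gradient"] = {"pearson_r": r, "p": p}


def _decoding_stage(report, datasets, cfg, seed):
    dec = cfg["decoding"]
    frames, grad_rows = [], []
    per_label_dists, area_means, orders = {}, [], []
    for ds in datasets:
        results = decoder_battery(
            ds, n_reps=int(dec["n_reps"]),
            n_pseudotrials=int(dec["n_pseudotrials"]), seed=seed,
            shuffle_reps=int(dec["shuffle_reps"]))
        frames.append(battery_frame(results))
        means = [r.mean for r in results if not r.skipped]
        area_means.append(float(np.mean(means)))
        orders.append(ds.order_index)
        for r in results:
            if not r.skipped:
                per_label_dists.setdefault(r.label, []).append(
                    (ds.order_index, r.accuracies))
    report.tables["decoding"] = pd.concat(frames, ignore_index=True)

    for label, dists in per_label_dists.items():
        dists.sort(key=lambda t: t[0])
        rho, p = gradient_order_test([d for _, d in dists],
                                     order=[o for o, _ in dists])
        grad_rows.append({"label": label, "rho": rho, "p": p,
                          "mode": "distribution"})
    rho, p = gradient_order_test(area_means, order=orders)
    grad_rows.append({"label": "battery_mean", "rho": rho, "p": p,
                      "mode": "scalar"})
    report.scalars["decoding_area_means"] = dict(
        zip([ds.name for ds in datasets], area_means))

    if dec.get("run_decimation", False):
        dec_means = []
        dec_frames = []
        for ds in datasets:
            results = decoder_battery(
                ds, n_reps=int(dec["n_reps"]),
                n_pseudotrials=int(dec["n_pseudotrials"]), seed=seed,
                shuffle_reps=int(dec["shuffle_reps"]),
                decimate_to=int(dec["decimate_to"]))
            f = battery_frame(results)
            f["control"] = "decimated"
            dec_frames.append(f)
            dec_means.append(float(np.mean(
                [r.mean for r in results if not r.skipped])))
        report.tables["decoding_decimated"] = pd.concat(dec_frames,
                                                        ignore_index=True)
        rho, p = gradient_order_test(dec_means, order=orders)
        grad_rows.append({"label": "battery_mean_decimated", "rho": rho,
                          "p": p, "mode": "scalar"})
    report.tables["gradient_tests"] = pd.DataFrame(grad_rows)


def _controls_stage(report, datasets):
    rows, grads = [], {}
    base, ff1, ff2 = [], [], []
    pca12 = {"epoch1": [], "epoch2": []}
    for ds in datasets:
        b, _ = baseline_rates(ds.spikes, ds.trials)
        base.append(b)
        rows.append({"area": ds.name, "metric": "baseline_rate",
                     "epoch": "pretrial", "value": b, "sem": np.nan})
        for ep, acc in (("epoch1", ff1), ("epoch2", ff2)):
            fr = fano_factor(ds.spikes, ds.trials, EPOCHS[ep])
            acc.append(fr.mean_ff)
            rows.append({"area": ds.name, "metric": "fano_factor",
                         "epoch": ep, "value": fr.mean_ff, "sem": fr.sem})
        for ep in ("epoch1", "epoch2"):
            dim = pca_dimensionality(ds.spikes, ds.trials, EPOCHS[ep])
            pca12[ep].append(dim.slope_12)
            rows.append({"area": ds.name, "metric": "pca_slope_12",
                         "epoch": ep, "value": dim.slope_12, "sem": np.nan})
            rows.append({"area": ds.name, "metric": "pca_slope_23",
                         "epoch": ep, "value": dim.slope_23, "sem": np.nan})
    order = [ds.order_index for ds in datasets]
    for name, vals in (("baseline_rate", base), ("fano_epoch1", ff1),
                       ("fano_epoch2", ff2),
                       ("pca_slope12_epoch1", pca12["epoch1"]),
                       ("pca_slope12_epoch2", pca12["epoch2"])):
        try:
            rho, p = gradient_order_test(vals, order=order)
            grads[name] = {"rho": rho, "p": p}
        except VDGradientError as e:
            grads[name] = {"error": str(e)}
    report.tables["controls"] = pd.DataFrame(rows)
    report.scalars["control_gradients"] = grads


def _behavior_stage(report, datasets):
    summ = behavior_summary([ds.trials for ds in datasets])
    report.tables["behavior"] = pd.DataFrame({
        "session": [ds.name for ds in datasets],
        "prop_higher_ev": summ.proportions,
    })
    report.scalars["behavior_fit"] = {
        "t_stat": summ.t_stat, "p_value": summ.p_value,
        "logistic_slope": summ.logistic_slope,
        "logistic_bias": summ.logistic_bias,
    }


def run_pipeline(config=None, seed: int = 0, out_dir=None,
                 datasets=None) -> RunReport:
    """Run simulate → selectivity → signatures → timescale → decoding →
    controls → behavior, returning (and optionally writing) the report.

    ``config`` may be a path, a dict, or None (defaults).  Pass ``datasets``
    to analyze pre-loaded :class:`~vdgradient.synth.AreaDataset` objects
    instead of simulating.
    """
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    elif isinstance(config, dict):
        cfg = validate_config(config)
    else:
        cfg = load_config(None)
    report = RunReport(config=cfg, seed=int(seed))

    if datasets is None:
        datasets = generate_gradient_dataset(
            seed=seed, n_trials=int(cfg["task"]["n_trials"]),
            areas=areas_from_config(cfg), task=task_from_config(cfg),
            behavior=behavior_from_config(cfg))
    datasets = sorted(datasets, key=lambda d: d.order_index)
    report.scalars["areas"] = {
        ds.name: {"order_index": ds.order_index,
                  "n_neurons": ds.spikes.n_neurons,
                  "n_trials": ds.spikes.n_trials}
        for ds in datasets}

    with _stage(report, "behavior"):
        _behavior_stage(report, datasets)
    with _stage(report, "selectivity"):
        _selectivity_stage(report, datasets)
    with _stage(report, "signatures"):
        _signatures_stage(report, datasets)
    with _stage(report, "timescale"):
        _timescale_stage(report, datasets, cfg)
    with _stage(report, "decoding"):
        _decoding_stage(report, datasets, cfg, seed)
    with _stage(report, "controls"):
        _controls_stage(report, datasets)

    if out_dir is not None:
        write_report(report, out_dir)
    return report


def write_report(report: RunReport, out_dir) -> list:
    """Write report.json and one CSV per table; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, table in report.tables.items():
        p = out / f"{name}.csv"
        table.to_csv(p, index=False)
        paths.append(p)
    if "timescale_fits" in report.tables:
        p = out / "timescale_fits.json"
        p.write_text(report.tables["timescale_fits"].to_json(
            orient="records", indent=1))
        paths.append(p)
    if "behavior_fit" in report.scalars:
        p = out / "behavior_fit.json"
        p.write_text(json.dumps(report.scalars["behavior_fit"], indent=1))
        paths.append(p)
    payload = {
        "config_hash": report.hash,
        "seed": report.seed,
        "config": report.config,
        "scalars": report.scalars,
        "errors": report.errors,
        "tables": sorted(report.tables),
    }
    p = out / "report.json"
    p.write_text(json.dumps(payload, indent=1, default=float))
    paths.append(p)
    return paths


def read_report(out_dir) -> dict:
    """Load report.json and the per-stage CSVs back into memory."""
    out = Path(out_dir)
    payload = json.loads((out / "report.json").read_text())
    payload["tables"] = {name: pd.read_csv(out / f"{name}.csv")
                         for name in payload["tables"]}
    return payload
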