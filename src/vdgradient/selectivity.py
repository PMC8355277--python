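"""Per-neuron value coding: tuning, population tests, timecourses, latency.

A neuron is "value selective" in an epoch when its mean epoch firing rate
correlates with the offer's expected value (two-sided Pearson test at
α = 0.05).  Whether a significant *proportion* of neurons is selective is
assessed with a one-sided exact binomial test against the per-neuron false
positive rate.  Response latency is computed under five definitions (peak
rate, first significant value correlation, significant-to-peak, peak rate
change, first 2-SD rate change) and compared across areas × offers with a
two-way ANOVA.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.formula.api import ols

from ._errors import DegenerateDataError
from .task import (BIN_WIDTH_MS, Epoch, EpochRates, SpikeTrainSet,
                   bin_spikes, epoch_rates)

__all__ = [
    "value_tuning",
    "population_selectivity",
    "selectivity_timecourse",
    "response_latency",
    "latency_anova",
    "LATENCY_METHODS",
]

LATENCY_METHODS = ("peak", "onset_to_sig", "sig_to_peak",
                   "peak_change", "first_change_2sd")


# --------------------------------------------------------------------------
# tuning
# --------------------------------------------------------------------------

def _pearson_rows(X: np.ndarray, y: np.ndarray):
    """Vectorized Pearson r and two-sided p of each row of X against y.

    Rows (or y) with zero variance yield NaN.
    """
    n = y.size
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((Xc ** 2).sum(axis=1))
    sy = np.sqrt((yc ** 2).sum())
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, Xc @ yc / np.where(denom > 0, denom, 1.0), np.nan)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(np.maximum(n - 2, 1) / np.maximum(1.0 - r ** 2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=max(n - 2, 1))
    p = np.where(np.isnan(r), np.nan, p)
    return r, p


def value_tuning(rates, values, alpha: float = 0.05,
                 variable: str = "ev", epoch: str = "") -> pd.DataFrame:
    """Pearson correlation of each neuron's epoch rates with a trial regressor.

    Returns a frame with one row per neuron: r, r², two-sided p, and the
    selectivity flag (p < α).  Zero-variance neurons get NaN results and
    ``valid = False`` rather than raising.
    """
    X = rates.rates if isinstance(rates, EpochRates) else np.asarray(rates, float)
    y = np.asarray(values, dtype=float)
    if X.shape[1] != y.size:
        raise DegenerateDataError("rates and values trial counts differ")
    if y.size < 3:
        raise DegenerateDataError("value tuning requires >= 3 trials")
    if y.std() == 0:
        raise DegenerateDataError("regressor has zero variance")
    r, p = _pearson_rows(X, y)
    valid = ~np.isnan(r)
    return pd.DataFrame({
        "neuron": np.arange(X.shape[0]),
        "variable": variable,
        "epoch": epoch,
        "r": r,
        "r2": r ** 2,
        "p": p,
        "selective": valid & (p < alpha),
        "valid": valid,
    })


def population_selectivity(tuning: pd.DataFrame, alpha: float = 0.05,
                           null_rate: float = 0.05):
    """Proportion selective and one-sided exact binomial tail P(X ≥ k).

    ``tuning`` is a frame from :func:`value_tuning` (or anything with a
    boolean ``selective`` column); all neurons, valid or not, count toward
    the denominator, mirroring reporting of proportions out of the full
    sample.
    """
    sel = tuning["selective"].to_numpy(dtype=bool)
    n = sel.size
    if n < 1:
        raise DegenerateDataError("population test requires >= 1 neuron")
    k = int(sel.sum())
    res = stats.binomtest(k, n, null_rate, alternative="greater")
    return k / n, float(res.pvalue)


# --------------------------------------------------------------------------
# time-resolved selectivity
# --------------------------------------------------------------------------

def selectivity_timecourse(spikes: SpikeTrainSet, trials, values,
                           window_ms: float = 500.0, step_ms: float = 20.0,
                           span_ms=(-500.0, 2500.0), anchor: str = "offer1",
                           alpha: float = 0.05) -> pd.DataFrame:
    """Sliding-window tuning: per-window proportion selective and mean r².

    Windows of ``window_ms`` advance by ``step_ms`` over ``span_ms``
    (relative to ``anchor``); outputs are aligned to window centers.
    """
    starts = np.arange(span_ms[0], span_ms[1] - window_ms + 1e-9, step_ms)
    rows = []
    for s in starts:
        ep = Epoch("win", anchor, float(s), float(window_ms))
        tensor = bin_spikes(spikes, ep, trials, bin_width_ms=float(window_ms))
        tune = value_tuning(epoch_rates(tensor), values, alpha=alpha)
        rows.append({
            "center_ms": s + window_ms / 2.0,
            "prop_selective": tune["selective"].mean(),
            "mean_r2": tune["r2"].mean(skipna=True),
            "n_valid": int(tune["valid"].sum()),
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# latency
# --------------------------------------------------------------------------

def response_latency(spikes: SpikeTrainSet, trials, epoch: Epoch,
                     method: str = "peak", values=None,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Per-neuron response latency (ms from epoch onset) under one definition.

    peak            time of the maximal trial-averaged rate bin
    onset_to_sig    first bin whose rates correlate significantly with value
    sig_to_peak     elapsed time from that first significant bin to the peak
    peak_change     time of the maximal |rate − epoch-mean rate|
    first_change_2sd  first bin beyond mean ± 2 SD of the binned rates

    Latencies are reported at 20-ms bin centers with ties broken to the
    earliest bin; neurons with no qualifying bin get NaN (excluded from
    means downstream).  Negative sig-to-peak intervals (peak precedes the
    first significant bin) are reported missing.
    """
    if method not in LATENCY_METHODS:
        raise DegenerateDataError(f"unknown latency method {method!r}")
    tensor = bin_spikes(spikes, epoch, trials)
    psth = tensor.counts.mean(axis=1) / (BIN_WIDTH_MS / 1000.0)  # neurons × bins
    n_neurons, n_bins = psth.shape
    centers = BIN_WIDTH_MS * np.arange(n_bins) + BIN_WIDTH_MS / 2.0

    peak_bin = psth.argmax(axis=1)  # argmax ties -> earliest
    lat = np.full(n_neurons, np.nan)
    if method == "peak":
        lat = centers[peak_bin]
    elif method in ("onset_to_sig", "sig_to_peak"):
        if values is None:
            raise DegenerateDataError(f"method {method!r} requires values")
        y = np.asarray(values, dtype=float)
        sig_first = np.full(n_neurons, -1)
        for b in range(n_bins):
            rates_b = tensor.counts[:, :, b] / (BIN_WIDTH_MS / 1000.0)
            _, p = _pearson_rows(rates_b, y)
            newly = (sig_first < 0) & ~np.isnan(p) & (p < alpha)
            sig_first[newly] = b
        has = sig_first >= 0
        if method == "onset_to_sig":
            lat[has] = centers[sig_first[has]]
        else:
            dt = centers[peak_bin[has]] - centers[sig_first[has]]
            lat[has] = np.where(dt >= 0, dt, np.nan)
    elif method in ("peak_change", "first_change_2sd"):
        dev = np.abs(psth - psth.mean(axis=1, keepdims=True))
        if method == "peak_change":
            lat = centers[dev.argmax(axis=1)]
        else:
            sd = psth.std(axis=1, ddof=0)
            beyond = dev > 2.0 * sd[:, None]
            any_cross = beyond.any(axis=1) & (sd > 0)
            first = beyond.argmax(axis=1)
            lat[any_cross] = centers[first[any_cross]]
    return pd.DataFrame({
        "neuron": np.arange(n_neurons),
        "method": method,
        "latency_ms": lat,
    })


def latency_anova(latencies: pd.DataFrame):
    """4 (area) × 2 (offer) ANOVA on neuron-level latencies.

    Expects columns ``latency_ms``, ``area``, ``offer``; missing latencies
    are dropped listwise.  Returns (F_area, p_area, F_offer, p_offer).
    Raises on empty cells or degenerate (zero-variance) data.
    """
    df = latencies.dropna(subset=["latency_ms"]).copy()
    counts = df.groupby(["area", "offer"], observed=True).size()
    areas = df["area"].unique()
    offers = df["offer"].unique()
    for a in areas:
        for o in offers:
            if counts.get((a, o), 0) < 2:
                raise DegenerateDataError(
                    f"ANOVA cell (area={a}, offer={o}) has < 2 observations")
    if df["latency_ms"].std() == 0:
        raise DegenerateDataError("latencies are constant; ANOVA undefined")
    model = ols("latency_ms ~ C(area) + C(offer)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    return (float(table.loc["C(area)", "F"]), float(table.loc["C(area)", "PR(>F)"]),
            float(table.loc["C(offer)", "F"]), float(table.loc["C(offer)", "PR(>F)"]))
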