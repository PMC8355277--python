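"""Intrinsic-timescale estimation from pre-offer spike-count autocorrelation.

Spike counts in 20-ms bins over the 2-s window preceding offer 1 (a
task-free period) are correlated across trials between every ordered bin
pair; the autocorrelation at lag kΔ is the mean correlation over all pairs
(i, j) with |i − j| = k, for lags 20–720 ms.  Per-neuron curves are
averaged within an area and the area curve is fitted with the exponential
decay model

    R(kΔ) = A · [exp(−kΔ / τ) + B]

whose decay constant τ is the area's intrinsic timescale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import pearsonr

from ._errors import DegenerateDataError
from .task import BIN_WIDTH_MS, Epoch, SpikeTrainSet, bin_spikes

__all__ = [
    "ACFCurve",
    "TimescaleFit",
    "pretrial_autocorrelation",
    "fit_exponential_decay",
    "timescale_gradient",
]

PRETRIAL_EPOCH = Epoch("pretrial", "offer1", -2000.0, 2000.0)

TAU_BOUNDS = (1.0, 5000.0)
A_BOUNDS = (0.0, 2.0)
B_BOUNDS = (-1.0, 1.0)
TAU_STARTS = (50.0, 100.0, 300.0, 600.0)


@dataclass
class ACFCurve:
    """Across-trial spike-count autocorrelation vs lag, averaged over neurons."""

    lags_ms: np.ndarray          # strictly increasing multiples of the bin width
    R: np.ndarray                # mean autocorrelation per lag
    se: np.ndarray               # SE across neurons per lag
    per_neuron: np.ndarray       # neurons × lags (NaN where undefined)
    n_neurons_used: int
    n_neurons_excluded: int      # silent neurons (no spikes in the window)


@dataclass
class TimescaleFit:
    """Parameters of R(kΔ) = A[exp(−kΔ/τ) + B] with fit diagnostics."""

    A: float
    tau_ms: float
    B: float
    sse: float
    converged: bool


def _neuron_acf(counts: np.ndarray, max_lag_bins: int) -> np.ndarray:
    """ACF for one neuron from its bins × trials count matrix.

    Bin pairs where either bin has zero across-trial variance are skipped
    (their correlation is undefined); a lag with no valid pair is NaN.
    """
    sd = counts.std(axis=1)
    valid = sd > 0
    corr = np.full((counts.shape[0], counts.shape[0]), np.nan)
    if valid.sum() >= 2:
        sub = np.corrcoef(counts[valid])
        ij = np.nonzero(valid)[0]
        corr[np.ix_(ij, ij)] = sub
    out = np.empty(max_lag_bins)
    n_bins = counts.shape[0]
    for k in range(1, max_lag_bins + 1):
        diag = np.diagonal(corr, offset=k)
        out[k - 1] = np.nanmean(diag) if np.any(~np.isnan(diag)) else np.nan
    return out


def pretrial_autocorrelation(spikes: SpikeTrainSet, trials,
                             epoch: Epoch = PRETRIAL_EPOCH,
                             delta_ms: float = BIN_WIDTH_MS,
                             max_lag_ms: float = 720.0) -> ACFCurve:
    """Across-trial spike-count autocorrelation in a task-free window.

    By construction R depends only on |i − j|: the correlation matrix is
    symmetric, so averaging the k-th superdiagonal equals averaging over
    both (i, j) and (j, i).
    """
    if spikes.n_trials < 2:
        raise DegenerateDataError("autocorrelation requires at least 2 trials")
    tensor = bin_spikes(spikes, epoch, trials, bin_width_ms=delta_ms)
    max_lag_bins = int(round(max_lag_ms / delta_ms))
    lags = delta_ms * np.arange(1, max_lag_bins + 1)

    total = tensor.counts.sum(axis=(1, 2))
    silent = total == 0
    curves = np.full((spikes.n_neurons, max_lag_bins), np.nan)
    for n in np.nonzero(~silent)[0]:
        curves[n] = _neuron_acf(tensor.counts[n].T, max_lag_bins)
    used = ~silent & ~np.all(np.isnan(curves), axis=1)
    if not used.any():
        raise DegenerateDataError("no neuron has a defined autocorrelation")
    sub = curves[used]
    R = np.nanmean(sub, axis=0)
    n_per_lag = np.sum(~np.isnan(sub), axis=0)
    se = np.full(max_lag_bins, np.nan)
    multi = n_per_lag > 1
    if multi.any():
        se[multi] = (np.nanstd(sub[:, multi], axis=0, ddof=1)
                     / np.sqrt(n_per_lag[multi]))
    return ACFCurve(lags_ms=lags, R=R, se=se, per_neuron=curves,
                    n_neurons_used=int(used.sum()),
                    n_neurons_excluded=int(spikes.n_neurons - used.sum()))


def fit_exponential_decay(acf: ACFCurve) -> TimescaleFit:
    """Bounded nonlinear least squares of the exponential-decay model.

    Multi-start over τ0 ∈ {50, 100, 300, 600} ms, best SSE kept.
    ``converged`` is False when the optimizer fails, the solution sits on a
    bound, or the curve is flat (τ unidentifiable); values are still
    reported.
    """
    ok = ~np.isnan(acf.R)
    lags = np.asarray(acf.lags_ms, dtype=float)[ok]
    R = np.asarray(acf.R, dtype=float)[ok]
    if lags.size < 4:
        raise DegenerateDataError("exponential fit requires >= 4 lag points")

    def resid(p):
        A, tau, B = p
        return A * (np.exp(-lags / tau) + B) - R

    flat = R.std() < 1e-6
    best = None
    for tau0 in TAU_STARTS:
        A0 = max(R[0] - R[-1], 1e-3)
        B0 = float(np.clip(R[-1] / A0 if A0 > 0 else 0.0, *B_BOUNDS))
        p0 = (float(np.clip(A0, *A_BOUNDS)), tau0, B0)
        sol = least_squares(
            resid, p0,
            bounds=([A_BOUNDS[0], TAU_BOUNDS[0], B_BOUNDS[0]],
                    [A_BOUNDS[1], TAU_BOUNDS[1], B_BOUNDS[1]]),
        )
        if best is None or sol.cost < best.cost:
            best = sol
    A, tau, B = best.x
    sse = float(2.0 * best.cost)
    at_bound = (
        np.isclose(tau, TAU_BOUNDS[0]) or np.isclose(tau, TAU_BOUNDS[1])
        or np.isclose(A, A_BOUNDS[0]) or np.isclose(A, A_BOUNDS[1])
    )
    converged = bool(best.success) and not at_bound and not flat
    return TimescaleFit(A=float(A), tau_ms=float(tau), B=float(B),
                        sse=sse, converged=converged)


def timescale_gradient(taus, order=(1, 2, 3, 4), fits=None):
    """Pearson correlation of per-area intrinsic timescales with gradient order.

    If ``fits`` is given, any unconverged area raises an error naming it.
    """
    taus = np.asarray(taus, dtype=float)
    order = np.asarray(order, dtype=float)
    if fits is not None:
        bad = [i for i, f in enumerate(fits) if not f.converged]
        if bad:
            raise DegenerateDataError(f"unconverged timescale fits for areas {bad}")
    if np.std(taus) == 0:
        raise DegenerateDataError("timescales constant across areas; r undefined")
    r, p = pearsonr(taus, order)
    return float(r), float(p)
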