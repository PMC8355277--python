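"""Intrinsic-property controls and behavior summary.

Baseline firing rates in a task-free pre-offer window, trial-to-trial
spike-count variability (Fano factor, 100-ms bins), PCA dimensionality of
trial-averaged epoch responses, and the sigmoidal higher-EV choice
behavior.  These are the analyses that should *not* show a gradient when
the gradient is functional rather than a trivial consequence of firing
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from ._errors import DegenerateDataError, DomainError
from .task import BIN_WIDTH_MS, Epoch, SpikeTrainSet, bin_spikes
from .synth import higher_ev_choice_rate

__all__ = [
    "baseline_rates",
    "fano_factor",
    "FanoResult",
    "pca_dimensionality",
    "DimensionalityResult",
    "behavior_summary",
    "BehaviorSummary",
]

#: Default baseline window, seconds relative to offer-1 onset.  Chosen not
#: to overlap the final second of the 2-s timescale window; configurable.
BASELINE_WINDOW = (-2.0, -1.0)


def baseline_rates(spikes: SpikeTrainSet, trials,
                   window=BASELINE_WINDOW):
    """Mean pre-offer firing rate: per neuron across trials, then over neurons.

    Returns ``(area_mean_sp_s, per_neuron_rates)``.
    """
    t0, t1 = window
    ep = Epoch("baseline", "offer1", t0 * 1000.0, (t1 - t0) * 1000.0)
    tensor = bin_spikes(spikes, ep, trials, bin_width_ms=(t1 - t0) * 1000.0)
    per_neuron = tensor.counts[:, :, 0].mean(axis=1) / (t1 - t0)
    return float(per_neuron.mean()), per_neuron


@dataclass
class FanoResult:
    """Fano factor of 100-ms spike counts, per bin and summarized."""

    mean_ff: float               # mean over bins of the across-neuron means
    sem: float                   # SEM across neurons of per-neuron mean FF
    per_bin: np.ndarray          # across-neuron mean FF per 100-ms bin
    per_neuron: np.ndarray       # neurons × bins (NaN where mean count = 0)
    n_neurons_used: int
    n_neurons_excluded: int


def fano_factor(spikes: SpikeTrainSet, trials, epoch: Epoch,
                bin_ms: float = 100.0) -> FanoResult:
    """Across-trial variance / mean of spike counts in ``bin_ms`` bins.

    Bins with zero mean count are skipped; a neuron with no usable bin is
    excluded (counted in the report).  FF is 1 for a homogeneous Poisson
    process; latent rate fluctuations push it above 1.
    """
    if spikes.n_trials < 2:
        raise DegenerateDataError("Fano factor requires >= 2 trials")
    tensor = bin_spikes(spikes, epoch, trials, bin_width_ms=bin_ms)
    counts = tensor.counts.astype(float)           # neurons × trials × bins
    mean = counts.mean(axis=1)
    var = counts.var(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ff = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), np.nan)
    usable = ~np.all(np.isnan(ff), axis=1)
    if not usable.any():
        raise DegenerateDataError("no neuron has a nonzero-mean bin")
    ff_used = ff[usable]
    per_bin = np.nanmean(ff_used, axis=0)
    per_neuron_mean = np.nanmean(ff_used, axis=1)
    sem = float(np.std(per_neuron_mean, ddof=1) / np.sqrt(per_neuron_mean.size)) \
        if per_neuron_mean.size > 1 else float("nan")
    return FanoResult(
        mean_ff=float(np.nanmean(per_bin)), sem=sem, per_bin=per_bin,
        per_neuron=ff, n_neurons_used=int(usable.sum()),
        n_neurons_excluded=int((~usable).sum()),
    )


@dataclass
class DimensionalityResult:
    """Explained-variance fractions of leading PCs and successive changes."""

    fractions: np.ndarray        # full spectrum, sums to 1
    pc_fractions: tuple          # first three (NaN-padded if rank < 3)
    slope_12: float              # fraction(PC2) − fraction(PC1)
    slope_23: float


def pca_dimensionality(spikes: SpikeTrainSet, trials, epoch: Epoch,
                       normalize: bool = True) -> DimensionalityResult:
    """PCA of trial-averaged 20-ms rate time courses (time × neurons).

    Each neuron's time course is z-scored across time bins (its own mean
    and SD), then the explained-variance spectrum of the time × neurons
    matrix is computed.  Successive slopes are simple differences of the
    explained-variance fractions of adjacent PCs.
    """
    if spikes.n_neurons < 3:
        raise DegenerateDataError("PCA dimensionality requires >= 3 neurons")
    tensor = bin_spikes(spikes, epoch, trials)
    psth = tensor.counts.mean(axis=1) / (BIN_WIDTH_MS / 1000.0)  # neurons × bins
    M = psth.T.astype(float)                                      # time × neurons
    if normalize:
        sd = M.std(axis=0)
        M = (M - M.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    else:
        M = M - M.mean(axis=0)
    s = np.linalg.svd(M, compute_uv=False)
    ev = s ** 2
    if ev.sum() == 0:
        raise DegenerateDataError("response matrix has no variance")
    frac = ev / ev.sum()
    first3 = tuple(frac[i] if i < frac.size else float("nan") for i in range(3))
    slope_12 = first3[1] - first3[0] if frac.size >= 2 else float("nan")
    slope_23 = first3[2] - first3[1] if frac.size >= 3 else float("nan")
    return DimensionalityResult(fractions=frac, pc_fractions=first3,
                                slope_12=float(slope_12), slope_23=float(slope_23))


@dataclass
class BehaviorSummary:
    proportions: np.ndarray      # per-session higher-EV choice proportions
    t_stat: float
    p_value: float
    logistic_slope: float        # logit units per µL of ΔEV
    logistic_bias: float
    curve: pd.DataFrame          # binned P(choose offer 1) vs ΔEV
    n_sessions_skipped: int


def behavior_summary(sessions, null: float = 0.0,
                     n_curve_bins: int = 9) -> BehaviorSummary:
    """Higher-EV choice proportions with a one-sample t-test, plus the
    fitted logistic choice curve of P(choose offer 1) against EV1 − EV2.

    ``sessions`` is a list of trial tables.  Sessions with no unequal-EV
    trials are skipped (counted).  The t-test compares the session
    proportions against ``null`` (0 as conventionally reported for this
    task; pass 0.5 for a chance-level test).
    """
    props, skipped = [], 0
    pooled = []
    for t in sessions:
        try:
            props.append(higher_ev_choice_rate(t))
        except DomainError:
            skipped += 1
            continue
        pooled.append(t)
    if len(props) < 2:
        raise DegenerateDataError("t-test requires >= 2 usable sessions")
    props = np.asarray(props)
    tt = stats.ttest_1samp(props, null)

    allt = pd.concat(pooled, ignore_index=True)
    dv = (allt["ev1"] - allt["ev2"]).to_numpy(dtype=float)
    y = (allt["chosen_offer"].to_numpy() == 1).astype(float)
    X = sm.add_constant(dv)
    fit = sm.Logit(y, X).fit(disp=0)
    bias, slope = float(fit.params[0]), float(fit.params[1])

    edges = np.linspace(dv.min(), dv.max(), n_curve_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    which = np.clip(np.searchsorted(edges, dv, side="right") - 1, 0,
                    n_curve_bins - 1)
    curve = pd.DataFrame({
        "ev_diff": centers,
        "p_choose1": [y[which == b].mean() if (which == b).any() else np.nan
                      for b in range(n_curve_bins)],
        "n_trials": [int((which == b).sum()) for b in range(n_curve_bins)],
    })
    return BehaviorSummary(
        proportions=props, t_stat=float(tt.statistic), p_value=float(tt.pvalue),
        logistic_slope=slope, logistic_bias=bias, curve=curve,
        n_sessions_skipped=skipped,
    )
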