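"""Trial/epoch data model: expected value, spike binning, epoch rates.

Conventions used throughout the package
---------------------------------------
* Time origin: offer-1 onset is t = 0 for every trial.  Spike times are
  stored in seconds relative to that origin; window arithmetic is done in
  milliseconds internally.
* All analysis windows are half-open ``[start, start + duration)``.
* Firing rates are analyzed in 20-ms bins but usually reduced to 500-ms
  epochs locked to offer 1, offer 2, the choice fixation, and the period
  after choice resolution.  A 2-s pre-offer window ("pretrial") serves the
  baseline and intrinsic-timescale analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import CoverageError, DomainError, DegenerateDataError

__all__ = [
    "BIN_WIDTH_MS",
    "Epoch",
    "EPOCHS",
    "SpikeTrainSet",
    "RateTensor",
    "EpochRates",
    "expected_value",
    "bin_spikes",
    "epoch_rates",
    "validate_trial_table",
    "anchor_times",
    "boxcar_smooth",
]

BIN_WIDTH_MS = 20.0

TRIAL_COLUMNS = [
    "trial_id", "offer1_mag", "offer1_prob", "offer1_side",
    "offer2_mag", "offer2_prob", "offer2_side", "ev1", "ev2",
    "chosen_offer", "chosen_side", "rewarded",
    "prev_chosen_offer", "prev_rewarded",
    "t_offer1", "t_offer2", "t_choice",
]


# --------------------------------------------------------------------------
# expected value
# --------------------------------------------------------------------------

def expected_value(magnitude, probability):
    """Expected value of an offer: reward magnitude (µL) × reward probability.

    Accepts scalars or arrays; raises :class:`DomainError` for a probability
    outside [0, 1] or a negative magnitude.
    """
    magnitude = np.asarray(magnitude, dtype=float)
    probability = np.asarray(probability, dtype=float)
    if np.any(probability < 0.0) or np.any(probability > 1.0):
        raise DomainError("reward probability must lie in [0, 1]")
    if np.any(magnitude < 0.0):
        raise DomainError("reward magnitude must be non-negative")
    out = magnitude * probability
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# epochs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Epoch:
    """A half-open analysis window locked to a named trial event.

    ``anchor`` is one of ``offer1`` / ``offer2`` / ``choice``; the window is
    ``[anchor + offset_ms, anchor + offset_ms + duration_ms)``.
    """

    name: str
    anchor: str
    offset_ms: float
    duration_ms: float

    def __post_init__(self):
        if self.duration_ms <= 0:
            raise DomainError("epoch duration must be positive")

    def n_bins(self, bin_width_ms: float = BIN_WIDTH_MS) -> int:
        n = self.duration_ms / bin_width_ms
        if abs(n - round(n)) > 1e-9:
            raise DomainError(
                f"epoch duration {self.duration_ms} ms is not a multiple of "
                f"the {bin_width_ms} ms bin width"
            )
        return int(round(n))


#: The standard analysis epochs.  ``postchoice`` follows choice resolution,
#: i.e. the 500 ms after the choice epoch ends; ``pretrial`` is the 2-s
#: task-free window preceding offer 1 used by the baseline and timescale
#: analyses.
EPOCHS: dict[str, Epoch] = {
    "epoch1": Epoch("epoch1", "offer1", 0.0, 500.0),
    "epoch2": Epoch("epoch2", "offer2", 0.0, 500.0),
    "choice": Epoch("choice", "choice", 0.0, 500.0),
    "postchoice": Epoch("postchoice", "choice", 500.0, 500.0),
    "pretrial": Epoch("pretrial", "offer1", -2000.0, 2000.0),
}


def anchor_times(trials: pd.DataFrame, anchor: str) -> np.ndarray:
    """Per-trial anchor event time in seconds relative to offer-1 onset."""
    col = {"offer1": "t_offer1", "offer2": "t_offer2", "choice": "t_choice"}
    if anchor not in col:
        raise DomainError(f"unknown epoch anchor {anchor!r}")
    return trials[col[anchor]].to_numpy(dtype=float)


# --------------------------------------------------------------------------
# spike container
# --------------------------------------------------------------------------

class SpikeTrainSet:
    """Sorted spike times per (neuron, trial), aligned to offer-1 onset.

    Stored flat (times + integer neuron/trial indices) so binning reduces to
    one ``bincount``.  Every (neuron, trial) pair is implicitly present;
    empty trains simply contribute no spikes.  ``time_range`` is the recorded
    span (seconds) common to every trial and must include at least
    ``[-2.0, ...]`` for the pretrial analyses.
    """

    def __init__(self, times, neuron_index, trial_index, n_neurons, n_trials,
                 time_range):
        times = np.asarray(times, dtype=float)
        neuron_index = np.asarray(neuron_index, dtype=np.int64)
        trial_index = np.asarray(trial_index, dtype=np.int64)
        if not (times.shape == neuron_index.shape == trial_index.shape):
            raise DomainError("times / neuron_index / trial_index must align")
        if times.size and (neuron_index.min() < 0 or neuron_index.max() >= n_neurons):
            raise DomainError("neuron index out of range")
        if times.size and (trial_index.min() < 0 or trial_index.max() >= n_trials):
            raise DomainError("trial index out of range")
        order = np.lexsort((times, trial_index, neuron_index))
        self.times = times[order]
        self.neuron_index = neuron_index[order]
        self.trial_index = trial_index[order]
        self.n_neurons = int(n_neurons)
        self.n_trials = int(n_trials)
        self.time_range = (float(time_range[0]), float(time_range[1]))

    @classmethod
    def from_trains(cls, trains, time_range) -> "SpikeTrainSet":
        """Build from a nested list ``trains[neuron][trial] -> spike times (s)``."""
        t, ni, ti = [], [], []
        n_trials = max((len(row) for row in trains), default=0)
        for n, row in enumerate(trains):
            for k, tr in enumerate(row):
                tr = np.asarray(tr, dtype=float)
                t.append(tr)
                ni.append(np.full(tr.size, n, dtype=np.int64))
                ti.append(np.full(tr.size, k, dtype=np.int64))
        cat = (np.concatenate(x) if x else np.empty(0) for x in (t, ni, ti))
        return cls(*cat, n_neurons=len(trains), n_trials=n_trials,
                   time_range=time_range)

    def train(self, neuron: int, trial: int) -> np.ndarray:
        """Ascending spike times (s) of one neuron on one trial."""
        m = (self.neuron_index == neuron) & (self.trial_index == trial)
        return self.times[m]

    def subset_neurons(self, neurons) -> "SpikeTrainSet":
        neurons = np.asarray(neurons, dtype=np.int64)
        remap = -np.ones(self.n_neurons, dtype=np.int64)
        remap[neurons] = np.arange(neurons.size)
        keep = remap[self.neuron_index] >= 0
        return SpikeTrainSet(
            self.times[keep], remap[self.neuron_index[keep]],
            self.trial_index[keep], neurons.size, self.n_trials,
            self.time_range,
        )

    def __repr__(self):  # pragma: no cover - cosmetic
        return (f"SpikeTrainSet(n_neurons={self.n_neurons}, "
                f"n_trials={self.n_trials}, n_spikes={self.times.size}, "
                f"time_range={self.time_range})")


# --------------------------------------------------------------------------
# binning and epoch rates
# --------------------------------------------------------------------------

@dataclass
class RateTensor:
    """Spike counts, neurons × trials × bins, for one epoch."""

    counts: np.ndarray
    epoch: Epoch
    bin_width_ms: float = BIN_WIDTH_MS

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[0]

    @property
    def n_trials(self) -> int:
        return self.counts.shape[1]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]


@dataclass
class EpochRates:
    """Mean firing rate (sp/s) per neuron × trial within one epoch.

    When ``zscored`` each neuron is standardized across trials; neurons with
    zero across-trial variance are set to 0 and flagged in ``zero_variance``.
    """

    rates: np.ndarray
    epoch: Epoch
    zscored: bool = False
    zero_variance: np.ndarray = field(default=None)
    mean: np.ndarray = field(default=None)
    sd: np.ndarray = field(default=None)


def bin_spikes(spikes: SpikeTrainSet, epoch: Epoch, trials: pd.DataFrame,
               bin_width_ms: float = BIN_WIDTH_MS) -> RateTensor:
    """Count spikes in ``bin_width_ms`` bins tiling ``epoch`` on every trial.

    Bins are half-open: a spike exactly at a bin's right edge belongs to the
    next bin, and a spike exactly at the epoch end is excluded.  Raises
    :class:`CoverageError` (naming the offending trials) if the epoch window
    falls outside the recorded span on any trial.
    """
    n_bins = epoch.n_bins(bin_width_ms)
    anchors_s = anchor_times(trials, epoch.anchor)
    if anchors_s.size != spikes.n_trials:
        raise DomainError("trial table does not match the spike set")
    start_s = anchors_s + epoch.offset_ms / 1000.0
    end_s = start_s + epoch.duration_ms / 1000.0
    lo, hi = spikes.time_range
    bad = np.nonzero((start_s < lo - 1e-9) | (end_s > hi + 1e-9))[0]
    if bad.size:
        ids = trials["trial_id"].to_numpy()[bad][:10].tolist()
        raise CoverageError(
            f"epoch {epoch.name!r} not covered by the recorded span "
            f"{spikes.time_range} on {bad.size} trial(s), e.g. trial_id {ids}"
        )

    rel_ms = (spikes.times - start_s[spikes.trial_index]) * 1000.0
    # half-open bins; relative fuzz absorbs float error at exact edges
    # without reclassifying genuinely out-of-window times
    b = np.floor(rel_ms / bin_width_ms * (1.0 + 1e-12)).astype(np.int64)
    ok = (b >= 0) & (b < n_bins)
    flat = (spikes.neuron_index[ok] * spikes.n_trials
            + spikes.trial_index[ok]) * n_bins + b[ok]
    counts = np.bincount(flat, minlength=spikes.n_neurons * spikes.n_trials * n_bins)
    counts = counts.reshape(spikes.n_neurons, spikes.n_trials, n_bins)
    return RateTensor(counts=counts, epoch=epoch, bin_width_ms=bin_width_ms)


def epoch_rates(tensor: RateTensor, zscore: bool = False) -> EpochRates:
    """Reduce a binned tensor to mean firing rates (sp/s) per neuron × trial."""
    dur_s = tensor.epoch.duration_ms / 1000.0
    rates = tensor.counts.sum(axis=2) / dur_s
    if not zscore:
        return EpochRates(rates=rates.astype(float), epoch=tensor.epoch)
    mean = rates.mean(axis=1)
    sd = rates.std(axis=1, ddof=0)
    zero_var = sd == 0.0
    safe_sd = np.where(zero_var, 1.0, sd)
    z = (rates - mean[:, None]) / safe_sd[:, None]
    z[zero_var] = 0.0
    return EpochRates(rates=z, epoch=tensor.epoch, zscored=True,
                      zero_variance=zero_var, mean=mean, sd=sd)


# --------------------------------------------------------------------------
# trial-table validation
# --------------------------------------------------------------------------

def validate_trial_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Check the trial-table invariants; returns the table unchanged.

    Verifies column presence, EV = magnitude × probability, probability
    domain, complementary offer sides, and that the previous-trial lag
    columns equal the preceding trial's choice/reward (missing on the first
    trial).
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise DomainError(f"trial table missing columns: {missing}")
    for c in ("offer1_prob", "offer2_prob"):
        p = trials[c].to_numpy(dtype=float)
        if np.any(p < 0) or np.any(p > 1):
            raise DomainError(f"{c} outside [0, 1]")
    for i in (1, 2):
        ev = expected_value(trials[f"offer{i}_mag"].to_numpy(dtype=float),
                            trials[f"offer{i}_prob"].to_numpy(dtype=float))
        if not np.allclose(ev, trials[f"ev{i}"].to_numpy(dtype=float)):
            raise DomainError(f"ev{i} != offer{i}_mag * offer{i}_prob")
    s1 = trials["offer1_side"].astype(str)
    s2 = trials["offer2_side"].astype(str)
    if not ((s1 != s2) & s1.isin(["left", "right"]) & s2.isin(["left", "right"])).all():
        raise DomainError("offer sides must be complementary left/right")
    prev_c = trials["prev_chosen_offer"].to_numpy(dtype=object)
    prev_r = trials["prev_rewarded"].to_numpy(dtype=object)
    if not (pd.isna(prev_c[0]) and pd.isna(prev_r[0])):
        raise DomainError("prev_* fields must be missing on the first trial")
    cur_c = trials["chosen_offer"].to_numpy()
    cur_r = trials["rewarded"].to_numpy()
    for k in range(1, len(trials)):
        if int(prev_c[k]) != int(cur_c[k - 1]) or bool(prev_r[k]) != bool(cur_r[k - 1]):
            raise DomainError(f"prev_* lag mismatch at trial index {k}")
    return trials


# --------------------------------------------------------------------------
# display smoothing
# --------------------------------------------------------------------------

def boxcar_smooth(x: np.ndarray, window_ms: float = 200.0,
                  bin_width_ms: float = BIN_WIDTH_MS, axis: int = -1) -> np.ndarray:
    """Running-boxcar smoothing of a binned time course, for display only."""
    w = max(1, int(round(window_ms / bin_width_ms)))
    kernel = np.ones(w) / w
    x = np.asarray(x, dtype=float)

    def _smooth(v):
        return np.convolve(np.pad(v, (w // 2, w - 1 - w // 2), mode="edge"),
                           kernel, mode="valid")

    return np.apply_along_axis(_smooth, axis, x)


def require_min_trials(n: int, minimum: int, what: str) -> None:
    if n < minimum:
        raise DegenerateDataError(f"{what} requires at least {minimum} trials, got {n}")
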