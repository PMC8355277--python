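"""Pseudo-population decoding and cross-area gradient-order statistics.

For each binary task label, per-neuron epoch rates are resampled with
replacement within label level to build two ``n_neurons × n_pseudotrials``
class matrices (a *pseudo-population*; independent draws per neuron destroy
noise correlations by construction).  Each repeat splits both classes in
half, trains a linear SVM on one half-pair (features z-scored with
training-half statistics) and reports held-out accuracy; the shuffle
control repeats the identical procedure with the class assignment of the
pseudo-trials permuted.  Twelve label/epoch decoders form the battery; per-area accuracy
distributions are compared against the hypothesized area order 1–4 with a
Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

from ._errors import DegenerateDataError
from ._rng import substream
from .task import EPOCHS, EpochRates, bin_spikes, epoch_rates

__all__ = [
    "LabelSpec",
    "DEFAULT_LABELS",
    "PseudoPopulation",
    "DecoderResult",
    "label_values",
    "binarize_label",
    "build_pseudopopulation",
    "decode_label",
    "decoder_battery",
    "multinomial_ev_control",
    "gradient_order_test",
]


@dataclass(frozen=True)
class LabelSpec:
    """One decoding analysis: a task label read out in one epoch.

    Continuous labels are binarized by a mean split (value strictly greater
    than the across-trial mean → high class; ties go low); categorical
    labels are used directly.
    """

    name: str
    epoch: str
    source: str          # column / derived quantity of the trial table
    continuous: bool


DEFAULT_LABELS = (
    LabelSpec("ev1_epoch1", "epoch1", "ev1", True),
    LabelSpec("ev1_epoch2", "epoch2", "ev1", True),
    LabelSpec("ev2_epoch2", "epoch2", "ev2", True),
    LabelSpec("ev_diff_epoch2", "epoch2", "ev_diff", True),
    LabelSpec("offer1_side_epoch1", "epoch1", "offer1_side", False),
    LabelSpec("choice_epoch", "choice", "chosen_offer", False),
    LabelSpec("chosen_side_choice", "choice", "chosen_side", False),
    LabelSpec("chosen_value_choice", "choice", "chosen_value", True),
    LabelSpec("unchosen_value_choice", "choice", "unchosen_value", True),
    LabelSpec("prev_choice_choice", "choice", "prev_chosen_offer", False),
    LabelSpec("prev_reward_choice", "choice", "prev_rewarded", False),
    LabelSpec("chosen_side_postchoice", "postchoice", "chosen_side", False),
)


def label_values(trials: pd.DataFrame, source: str):
    """Per-trial raw label values and a validity mask for one label source."""
    n = len(trials)
    valid = np.ones(n, dtype=bool)
    ev1 = trials["ev1"].to_numpy(dtype=float)
    ev2 = trials["ev2"].to_numpy(dtype=float)
    chose1 = trials["chosen_offer"].to_numpy() == 1
    if source in ("ev1", "ev2"):
        vals = trials[source].to_numpy(dtype=float)
    elif source == "ev_diff":
        vals = ev1 - ev2
    elif source == "chosen_value":
        vals = np.where(chose1, ev1, ev2)
    elif source == "unchosen_value":
        vals = np.where(chose1, ev2, ev1)
    elif source in ("offer1_side", "chosen_side"):
        vals = (trials[source].to_numpy() == "right").astype(float)
    elif source == "chosen_offer":
        vals = chose1.astype(float)
    elif source == "prev_chosen_offer":
        raw = trials[source].to_numpy(dtype=float, na_value=np.nan)
        valid = ~np.isnan(raw)
        vals = np.where(valid & (raw == 1), 1.0, 0.0)
    elif source == "prev_rewarded":
        raw = trials[source].to_numpy(dtype=float, na_value=np.nan)
        valid = ~np.isnan(raw)
        vals = np.where(valid & (raw > 0), 1.0, 0.0)
    else:
        raise DegenerateDataError(f"unknown label source {source!r}")
    return vals, valid


def binarize_label(values: np.ndarray, continuous: bool,
                   valid=None) -> np.ndarray:
    """Binary class labels; mean split for continuous values (ties → low)."""
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.ones(values.size, dtype=bool)
    if continuous:
        m = values[valid].mean()
        return (values > m).astype(np.int64)
    return (values > 0.5).astype(np.int64)


# --------------------------------------------------------------------------
# pseudo-population
# --------------------------------------------------------------------------

@dataclass
class PseudoPopulation:
    """One ``n_neurons × n_pseudotrials`` matrix per class level."""

    matrices: dict              # {0: ndarray, 1: ndarray, ...}
    n_pseudotrials: int


@dataclass
class DecoderResult:
    label: str
    area: str
    accuracies: np.ndarray
    shuffle_accuracies: np.ndarray
    n_neurons: int
    epoch: str = ""
    degenerate: bool = False
    skipped: bool = False
    note: str = ""

    @property
    def mean(self):
        return float(np.mean(self.accuracies)) if self.accuracies.size else np.nan

    @property
    def se(self):
        a = self.accuracies
        return float(np.std(a, ddof=1) / np.sqrt(a.size)) if a.size > 1 else np.nan

    @property
    def shuffle_mean(self):
        s = self.shuffle_accuracies
        return float(np.mean(s)) if s.size else np.nan


def build_pseudopopulation(rates, labels, n_pseudotrials: int,
                           rng: np.random.Generator,
                           valid=None) -> PseudoPopulation:
    """Resample each neuron's trials within label level, with replacement.

    Draws are independent across neurons, which destroys cross-neuron noise
    correlations by construction.  Every class level must have at least one
    valid trial.
    """
    R = rates.rates if isinstance(rates, EpochRates) else np.asarray(rates, float)
    labels = np.asarray(labels)
    if valid is None:
        valid = np.ones(labels.size, dtype=bool)
    n_neurons = R.shape[0]
    if not valid.any():
        raise DegenerateDataError("no valid trials to resample")
    matrices = {}
    for lev in np.unique(labels[valid]):
        idx = np.nonzero(valid & (labels == lev))[0]
        if idx.size == 0:
            raise DegenerateDataError(f"label level {lev} has no trials")
        draws = rng.integers(0, idx.size, size=(n_neurons, n_pseudotrials))
        matrices[int(lev)] = R[np.arange(n_neurons)[:, None], idx[draws]]
    return PseudoPopulation(matrices=matrices, n_pseudotrials=n_pseudotrials)


def _train_test_split_classes(pp: PseudoPopulation, rng, shuffle=False):
    """Disjoint half splits per class, concatenated across classes.

    With ``shuffle=True`` the class assignment of the pooled pseudo-trial
    columns is permuted before splitting, so any relation between features
    and labels is destroyed while the per-repeat procedure (sample sizes,
    split, classifier) stays identical; expected accuracy is then 50%.
    """
    if shuffle:
        levels = sorted(pp.matrices)
        pooled = np.concatenate([pp.matrices[v] for v in levels], axis=1)
        pooled = pooled[:, rng.permutation(pooled.shape[1])]
        sizes = np.cumsum([pp.matrices[v].shape[1] for v in levels])[:-1]
        parts = np.split(pooled, sizes, axis=1)
        pp = PseudoPopulation(matrices=dict(zip(levels, parts)),
                              n_pseudotrials=pp.n_pseudotrials)
    Xtr, ytr, Xte, yte = [], [], [], []
    for lev, M in pp.matrices.items():
        P = M.shape[1]
        perm = rng.permutation(P)
        tr, te = perm[: P // 2], perm[P // 2:]
        Xtr.append(M[:, tr].T)
        Xte.append(M[:, te].T)
        ytr.append(np.full(tr.size, lev))
        yte.append(np.full(te.size, lev))
    return (np.vstack(Xtr), np.concatenate(ytr),
            np.vstack(Xte), np.concatenate(yte))


def _fit_score(Xtr, ytr, Xte, yte, clf):
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    clf.fit((Xtr - mu) / sd, ytr)
    return float(np.mean(clf.predict((Xte - mu) / sd) == yte))


def decode_label(rates, labels, n_reps: int = 1000, seed: int = 0,
                 n_pseudotrials: int = 1000, valid=None,
                 shuffle_reps: int = None, C: float = 1.0,
                 label_name: str = "", area: str = "") -> DecoderResult:
    """Cross-validated linear-SVM decoding of a binary label with shuffle null.

    Each repeat rebuilds the pseudo-trials, splits each class in half,
    trains on one half-pair and tests on the other.  The shuffle control
    runs the identical procedure with the class assignment of the pooled
    pseudo-trials permuted, which by construction yields 50% expected
    accuracy.
    """
    labels = np.asarray(labels, dtype=np.int64)
    if valid is None:
        valid = np.ones(labels.size, dtype=bool)
    levels = np.unique(labels[valid])
    if levels.size < 2:
        raise DegenerateDataError("decoding requires two label levels")
    rng = substream(seed, "decode", area, label_name)
    if shuffle_reps is None:
        shuffle_reps = n_reps
    R = rates.rates if isinstance(rates, EpochRates) else np.asarray(rates, float)
    clf = LinearSVC(C=C, dual=False)

    accs = np.empty(n_reps)
    degenerate = False
    for rep in range(n_reps):
        pp = build_pseudopopulation(R, labels, n_pseudotrials, rng, valid=valid)
        Xtr, ytr, Xte, yte = _train_test_split_classes(pp, rng)
        if np.all(Xtr.std(axis=0) == 0):
            degenerate = True
        accs[rep] = _fit_score(Xtr, ytr, Xte, yte, clf)

    sh = np.empty(shuffle_reps)
    for rep in range(shuffle_reps):
        pp = build_pseudopopulation(R, labels, n_pseudotrials, rng,
                                    valid=valid)
        Xtr, ytr, Xte, yte = _train_test_split_classes(pp, rng, shuffle=True)
        sh[rep] = _fit_score(Xtr, ytr, Xte, yte, clf)

    return DecoderResult(label=label_name, area=area, accuracies=accs,
                         shuffle_accuracies=sh, n_neurons=R.shape[0],
                         degenerate=degenerate)


# --------------------------------------------------------------------------
# battery
# --------------------------------------------------------------------------

def area_epoch_rates(dataset, epoch_names=None) -> dict:
    """Mean epoch rates (sp/s) per analysis epoch for one area dataset."""
    if epoch_names is None:
        epoch_names = ("epoch1", "epoch2", "choice", "postchoice")
    out = {}
    for name in epoch_names:
        tensor = bin_spikes(dataset.spikes, EPOCHS[name], dataset.trials)
        out[name] = epoch_rates(tensor)
    return out


def decoder_battery(dataset, n_reps: int = 1000, n_pseudotrials: int = 1000,
                    seed: int = 0, labels=DEFAULT_LABELS,
                    shuffle_reps: int = None, decimate_to: int = None,
                    C: float = 1.0) -> list:
    """Run the 12-decoder battery on one area.

    ``decimate_to`` subsamples the area to that many neurons (without
    replacement, seeded) before decoding — the sample-size control.  A
    label observed at a single level is skipped with a note rather than
    failing the battery.  Returns a list of :class:`DecoderResult`.
    """
    spikes = dataset.spikes
    note = ""
    if decimate_to is not None:
        if decimate_to > spikes.n_neurons:
            raise DegenerateDataError(
                f"cannot decimate {spikes.n_neurons} neurons to {decimate_to}")
        keep = np.sort(substream(seed, "decimate", dataset.order_index)
                       .choice(spikes.n_neurons, size=decimate_to, replace=False))
        spikes = spikes.subset_neurons(keep)
        note = f"decimated to {decimate_to} neurons"
        dataset = type(dataset)(dataset.name, dataset.order_index,
                                dataset.trials, spikes, dataset.neuron_specs,
                                getattr(dataset, "area_spec", None))
    rates = area_epoch_rates(dataset)
    results = []
    for spec in labels:
        vals, valid = label_values(dataset.trials, spec.source)
        y = binarize_label(vals, spec.continuous, valid=valid)
        if np.unique(y[valid]).size < 2:
            results.append(DecoderResult(
                label=spec.name, area=dataset.name,
                accuracies=np.empty(0), shuffle_accuracies=np.empty(0),
                n_neurons=spikes.n_neurons, epoch=spec.epoch, skipped=True,
                note="single label level observed"))
            continue
        res = decode_label(rates[spec.epoch], y, n_reps=n_reps, seed=seed,
                           n_pseudotrials=n_pseudotrials, valid=valid,
                           shuffle_reps=shuffle_reps, C=C,
                           label_name=spec.name, area=dataset.name)
        res.epoch = spec.epoch
        res.note = note
        results.append(res)
    return results


def battery_frame(results: list) -> pd.DataFrame:
    """Summarize a list of DecoderResults as a tidy frame."""
    rows = []
    for r in results:
        rows.append({
            "area": r.area, "label": r.label, "epoch": r.epoch,
            "mean_acc": r.mean, "se": r.se, "shuffle_mean": r.shuffle_mean,
            "n_reps": r.accuracies.size, "n_neurons": r.n_neurons,
            "skipped": r.skipped, "degenerate": r.degenerate,
            "note": r.note,
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# multinomial EV control
# --------------------------------------------------------------------------

def multinomial_ev_control(rates, ev_values, n_bins: int = 6,
                           n_reps: int = 20, seed: int = 0,
                           n_pseudotrials: int = 250,
                           binning: str = "quantile",
                           classifier: str = "logistic", area: str = ""):
    """Multiclass EV decoding control: EV split into consecutive bins.

    ``binning="quantile"`` uses equal-count consecutive bins (every class
    keeps a usable number of trials); ``"width"`` uses equal-width bins.
    The classifier is multinomial logistic regression by default, with a
    linear multiclass SVM option.  Returns (overall accuracy per repeat,
    per-class accuracy matrix repeats × classes).
    """
    ev = np.asarray(ev_values, dtype=float)
    if binning == "quantile":
        edges = np.quantile(ev, np.linspace(0, 1, n_bins + 1))
        edges = np.unique(edges)
    elif binning == "width":
        edges = np.linspace(ev.min(), ev.max(), n_bins + 1)
    else:
        raise DegenerateDataError(f"unknown binning {binning!r}")
    classes = np.clip(np.searchsorted(edges, ev, side="right") - 1,
                      0, len(edges) - 2)
    k = np.unique(classes).size
    if k < 2:
        raise DegenerateDataError("EV binning produced fewer than 2 classes")
    rng = substream(seed, "multinomial", area)
    if classifier == "logistic":
        clf = LogisticRegression(max_iter=500)
    elif classifier == "svm":
        clf = LinearSVC(C=1.0, dual=False)
    else:
        raise DegenerateDataError(f"unknown classifier {classifier!r}")
    R = rates.rates if isinstance(rates, EpochRates) else np.asarray(rates, float)

    overall = np.empty(n_reps)
    per_class = np.full((n_reps, k), np.nan)
    for rep in range(n_reps):
        pp = build_pseudopopulation(R, classes, n_pseudotrials, rng)
        Xtr, ytr, Xte, yte = _train_test_split_classes(pp, rng)
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        clf.fit((Xtr - mu) / sd, ytr)
        pred = clf.predict((Xte - mu) / sd)
        overall[rep] = np.mean(pred == yte)
        for j, lev in enumerate(np.unique(yte)):
            m = yte == lev
            per_class[rep, j] = np.mean(pred[m] == lev)
    return overall, per_class


# --------------------------------------------------------------------------
# gradient-order statistics
# --------------------------------------------------------------------------

def gradient_order_test(per_area_values, order=(1, 2, 3, 4)):
    """Spearman rank correlation of per-area statistics against area order.

    ``per_area_values`` is a sequence, one entry per area, each either a
    scalar (scalar mode: 4 points) or an array of repeats (distribution
    mode: all values pooled with their area's order label).
    """
    order = np.asarray(order, dtype=float)
    if len(per_area_values) != order.size:
        raise DegenerateDataError("one value (or distribution) per area required")
    vals, labs = [], []
    for v, o in zip(per_area_values, order):
        v = np.atleast_1d(np.asarray(v, dtype=float))
        vals.append(v)
        labs.append(np.full(v.size, o))
    vals = np.concatenate(vals)
    labs = np.concatenate(labs)
    if np.unique(vals).size == 1:
        raise DegenerateDataError("all values tied; Spearman rho undefined")
    rho, p = stats.spearmanr(vals, labs)
    return float(rho), float(p)
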