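"""Population signatures of the choice process.

Each neuron's z-scored epoch firing rates are regressed (OLS) on
standardized task variables; the resulting coefficient vectors are then
correlated across the population.  Three signatures are read off the
signed correlations, and their unsigned (absolute-weight) counterparts
index overlap of the functional populations:

* integration — epoch-1 rates ~ offer-1 probability + magnitude; a
  positive weight correlation means both value features share a coding
  scheme (an integrated value signal);
* alignment — epoch-1 rates ~ EV1 vs epoch-2 rates ~ EV2; a positive
  correlation means one value filter is reused for whichever offer is
  attended;
* inhibition — epoch-2 rates ~ EV1 + EV2; a negative correlation is the
  signature of value comparison by mutual inhibition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import CollinearityError, DegenerateDataError
from .task import EpochRates

__all__ = [
    "CoefficientVector",
    "SignatureResult",
    "fit_value_regressions",
    "signature_correlation",
    "compute_signatures",
]

#: expected sign of each signed signature correlation
SIGNATURE_EXPECTED_SIGN = {"integration": +1, "alignment": +1, "inhibition": -1}


@dataclass
class CoefficientVector:
    """Per-neuron OLS weight for one (regressor, epoch) pair."""

    weights: np.ndarray        # length n_neurons, NaN for failed fits
    regressor: str
    epoch: str


@dataclass
class SignatureResult:
    signature: str
    mode: str                  # "signed" | "unsigned"
    r: float
    p: float
    ci_lo: float               # Fisher-z 95% CI on r
    ci_hi: float
    slope: float               # regression slope of b on a
    slope_ci_lo: float
    slope_ci_hi: float
    n_neurons: int


def _standardize_columns(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise DegenerateDataError("a regressor has zero variance")
    return (X - X.mean(axis=0)) / sd


def fit_value_regressions(rates, regressors: pd.DataFrame,
                          epoch: str = "") -> dict:
    """OLS weights of each neuron's (z-scored) rates on standardized regressors.

    ``rates`` is an :class:`EpochRates` (ideally z-scored) or an
    neurons × trials array; ``regressors`` a trials × k frame.  Returns
    ``{regressor_name: CoefficientVector}``.  Near-collinear regressors
    raise :class:`CollinearityError` naming the offending pair.
    """
    R = rates.rates if isinstance(rates, EpochRates) else np.asarray(rates, float)
    names = list(regressors.columns)
    X = _standardize_columns(regressors.to_numpy(dtype=float))
    n_trials = X.shape[0]
    if R.shape[1] != n_trials:
        raise DegenerateDataError("rates and regressors trial counts differ")

    if X.shape[1] > 1:
        C = np.corrcoef(X, rowvar=False)
        iu = np.triu_indices_from(C, k=1)
        worst = np.argmax(np.abs(C[iu]))
        if np.abs(C[iu][worst]) > 0.999:
            a, b = iu[0][worst], iu[1][worst]
            raise CollinearityError(
                f"regressors {names[a]!r} and {names[b]!r} are collinear "
                f"(|corr| = {abs(C[iu][worst]):.4f})")

    Xd = np.column_stack([np.ones(n_trials), X])
    coefs, _, rank, _ = np.linalg.lstsq(Xd, R.T, rcond=None)
    if rank < Xd.shape[1]:
        raise CollinearityError("design matrix is rank deficient")
    W = coefs[1:, :]  # k × neurons
    return {name: CoefficientVector(weights=W[j].copy(), regressor=name,
                                    epoch=epoch)
            for j, name in enumerate(names)}


def _fisher_ci(r: float, n: int, level: float = 0.95):
    if n < 4 or abs(r) >= 1.0:
        return float("nan"), float("nan")
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zc = stats.norm.ppf(0.5 + level / 2.0)
    return float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se))


def signature_correlation(a: CoefficientVector, b: CoefficientVector,
                          mode: str = "signed",
                          signature: str = "") -> SignatureResult:
    """Pearson correlation between two coefficient vectors across neurons.

    ``mode="unsigned"`` correlates absolute weights (the overlap analysis).
    Neurons with a missing weight in either vector are excluded pairwise.
    """
    if mode not in ("signed", "unsigned"):
        raise DegenerateDataError(f"unknown mode {mode!r}")
    x = np.asarray(a.weights, dtype=float)
    y = np.asarray(b.weights, dtype=float)
    if x.size != y.size:
        raise DegenerateDataError("coefficient vectors differ in length")
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise DegenerateDataError("signature correlation requires >= 3 neurons")
    if mode == "unsigned":
        x, y = np.abs(x), np.abs(y)
    if x.std() == 0 or y.std() == 0:
        raise DegenerateDataError("zero-variance coefficient vector")
    r, p = stats.pearsonr(x, y)
    ci_lo, ci_hi = _fisher_ci(r, n)
    fit = stats.linregress(x, y)
    tcrit = stats.t.ppf(0.975, n - 2)
    return SignatureResult(
        signature=signature, mode=mode, r=float(r), p=float(p),
        ci_lo=ci_lo, ci_hi=ci_hi, slope=float(fit.slope),
        slope_ci_lo=float(fit.slope - tcrit * fit.stderr),
        slope_ci_hi=float(fit.slope + tcrit * fit.stderr),
        n_neurons=n,
    )


def compute_signatures(rates1, rates2, trials: pd.DataFrame) -> pd.DataFrame:
    """All three signatures in both modes from epoch-1 and epoch-2 rates.

    ``rates1`` / ``rates2`` are (preferably z-scored) rates for epochs 1
    and 2.  Returns one row per (signature, mode).
    """
    w_int = fit_value_regressions(
        rates1, trials[["offer1_prob", "offer1_mag"]], epoch="epoch1")
    w_al1 = fit_value_regressions(rates1, trials[["ev1"]], epoch="epoch1")
    w_al2 = fit_value_regressions(rates2, trials[["ev2"]], epoch="epoch2")
    w_inh = fit_value_regressions(rates2, trials[["ev1", "ev2"]], epoch="epoch2")

    pairs = {
        "integration": (w_int["offer1_prob"], w_int["offer1_mag"]),
        "alignment": (w_al1["ev1"], w_al2["ev2"]),
        "inhibition": (w_inh["ev1"], w_inh["ev2"]),
    }
    rows = []
    for name, (a, b) in pairs.items():
        for mode in ("signed", "unsigned"):
            res = signature_correlation(a, b, mode=mode, signature=name)
            rows.append({
                "signature": name, "mode": mode, "r": res.r, "p": res.p,
                "ci_lo": res.ci_lo, "ci_hi": res.ci_hi,
                "slope": res.slope, "n_neurons": res.n_neurons,
            })
    return pd.DataFrame(rows)
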