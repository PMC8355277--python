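"""Synthetic four-area spiking datasets for the two-offer risky-choice task.

The generator emulates the statistical structure every analysis stage
assumes, so the whole pipeline is testable without access to recordings:

* a trial table with two asynchronous offers (magnitude × probability),
  sigmoidal choice on the expected-value difference, probabilistic reward,
  and previous-trial lag fields;
* four "areas" of doubly-stochastic Poisson neurons whose instantaneous
  rate is ``baseline + epoch-locked linear value tuning + OU(t)``, clipped
  at zero.  The Ornstein–Uhlenbeck latent rate has an exponential
  autocovariance, so the intrinsic-timescale stage estimates a well-posed
  quantity with known ground truth;
* per-area gradients: tuning signal-to-noise (``snr_scale``) and OU
  timescale (``ou_tau_mean``) increase with the area's order index 1–4,
  while population tuning weights realize the target correlations
  (probability↔magnitude positive, offer-1/epoch-1 ↔ offer-2/epoch-2 value
  weights positive, offer-1 ↔ offer-2 weights within epoch 2 negative).

Each trial spans at least ``[-2 s, +3.1 s]`` around offer-1 onset so the
2-s task-free pre-offer window required by the baseline and timescale
analyses exists on every trial.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from ._errors import ConfigError, DomainError
from ._rng import substream
from .task import SpikeTrainSet, expected_value

__all__ = [
    "TaskParams",
    "BehaviorSpec",
    "NeuronSpec",
    "AreaSpec",
    "AreaDataset",
    "DEFAULT_AREAS",
    "DEFAULT_CHOICE_BETA",
    "generate_trials",
    "calibrate_choice_temperature",
    "simulate_area",
    "generate_gradient_dataset",
]

#: Choice temperature (logit units per µL of EV difference) calibrated by
#: bisection so the simulated higher-EV choice rate is ~80% at 10,000 trials,
#: the midpoint of the per-area session range the task produces in practice.
DEFAULT_CHOICE_BETA = 0.0264


@dataclass(frozen=True)
class TaskParams:
    """Timing and offer statistics of the two-offer gambling task.

    Offers appear for 400 ms followed by a 600-ms blank; the choice
    fixation is acquired 100 ms after the second blank ends.  Offer types
    are small/medium/large (125/165/240 µL) with mix (12.5%, 43.75%,
    43.75%) and uniformly drawn reward probabilities.
    """

    offer_duration_s: float = 0.4
    blank_s: float = 0.6
    fixation_s: float = 0.1
    magnitudes: tuple = (125.0, 165.0, 240.0)
    type_probs: tuple = (0.125, 0.4375, 0.4375)
    #: if True the small (gray) offer is a sure thing (p = 1) instead of a
    #: uniform-probability gamble.  Default False keeps probability and
    #: magnitude independent across trials.
    safe_prob_one: bool = False

    @property
    def t_offer2(self) -> float:
        return self.offer_duration_s + self.blank_s

    @property
    def t_choice(self) -> float:
        return 2 * (self.offer_duration_s + self.blank_s) + self.fixation_s

    def validate(self) -> None:
        p = np.asarray(self.type_probs, dtype=float)
        if p.size != 3 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise DomainError("offer type probabilities must be 3 values summing to 1")
        if len(self.magnitudes) != 3 or any(m < 0 for m in self.magnitudes):
            raise DomainError("offer magnitudes must be 3 non-negative values")


@dataclass(frozen=True)
class BehaviorSpec:
    """Sigmoidal choice model: P(choose offer 1) = σ(β·(EV1−EV2) + side terms)."""

    beta: float = DEFAULT_CHOICE_BETA   # logit units per µL of ΔEV
    side_bias: float = 0.0              # logit units, + favors the left offer

    def __post_init__(self):
        if self.beta < 0:
            raise DomainError("choice temperature beta must be non-negative")


#: tuning-weight names drawn jointly with the target population correlations
CORE_WEIGHTS = ("prob1", "mag1", "ev1_e1", "ev1_e2", "ev2_e2", "side", "choice")
#: additional independent weights driving the choice/post-choice decoders
EXTRA_WEIGHTS = ("chosen_side", "chosen_value", "unchosen_value",
                 "prev_choice", "prev_reward")

DEFAULT_WEIGHT_CORRELATIONS = {
    ("prob1", "mag1"): 0.5,       # feature integration
    ("ev1_e1", "ev2_e2"): 0.5,    # attentional alignment
    ("ev1_e2", "ev2_e2"): -0.5,   # mutual inhibition
}


@dataclass
class NeuronSpec:
    """Ground-truth parameters of one simulated neuron.

    Tuning weights are in sp/s per z-unit of the corresponding regressor
    (per unit of the ±1 contrast for categorical regressors) and act only
    inside their epoch; ``ou_tau`` (ms) and ``ou_sigma`` (sp/s) parameterize
    the latent OU rate; the realized rate is clipped at zero.
    """

    baseline_rate: float
    beta_prob1: float = 0.0
    beta_mag1: float = 0.0
    beta_ev1_e1: float = 0.0
    beta_ev1_e2: float = 0.0
    beta_ev2_e2: float = 0.0
    beta_side: float = 0.0
    beta_choice: float = 0.0
    beta_chosen_side: float = 0.0
    beta_chosen_value: float = 0.0
    beta_unchosen_value: float = 0.0
    beta_prev_choice: float = 0.0
    beta_prev_reward: float = 0.0
    ou_tau: float = 200.0
    ou_sigma: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.baseline_rate <= 0 or self.ou_tau <= 0:
            raise DomainError("baseline_rate and ou_tau must be positive")


@dataclass
class AreaSpec:
    """One area of the synthetic gradient.

    ``snr_scale`` multiplies every tuning weight and ``ou_tau_mean`` sets
    the latent-rate timescale; in the default preset both increase strictly
    with ``order_index``.
    """

    name: str
    order_index: int
    n_neurons: int
    snr_scale: float
    ou_tau_mean: float          # ms
    weight_correlations: dict = None
    baseline_mean: float = 5.0  # sp/s, population mean
    baseline_log_sd: float = 0.4
    base_weight_sd: float = 0.2  # sp/s per z-unit before snr scaling
    ou_sigma_frac: float = 1.0 / 3.0  # ou_sigma = frac * baseline (keeps clipping rare)
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.weight_correlations is None:
            self.weight_correlations = dict(DEFAULT_WEIGHT_CORRELATIONS)


#: Default gradient preset: neuron counts match the recorded samples in the
#: four medial-wall areas; SNR and intrinsic timescale increase with order.
DEFAULT_AREAS = (
    AreaSpec("vmPFC", 1, 156, 0.50, 110.0),
    AreaSpec("sgACC", 2, 146, 0.75, 150.0),
    AreaSpec("pgACC", 3, 213, 1.00, 320.0),
    AreaSpec("dACC", 4, 129, 1.60, 450.0),
)


@dataclass
class AreaDataset:
    """One area's simulated session: trials + spikes + ground truth."""

    name: str
    order_index: int
    trials: pd.DataFrame
    spikes: SpikeTrainSet
    neuron_specs: list
    area_spec: AreaSpec = None


# --------------------------------------------------------------------------
# trials
# --------------------------------------------------------------------------

def _draw_offer(rng, task: TaskParams, n):
    kind = rng.choice(3, size=n, p=np.asarray(task.type_probs, dtype=float))
    mag = np.asarray(task.magnitudes, dtype=float)[kind]
    prob = rng.uniform(0.0, 1.0, size=n)
    if task.safe_prob_one:
        prob = np.where(kind == 0, 1.0, prob)
    return mag, prob


def generate_trials(n_trials: int, task: TaskParams = None,
                    behavior: BehaviorSpec = None, seed: int = 0) -> pd.DataFrame:
    """Simulate a session of the two-offer risky-choice task.

    Deterministic under ``seed``.  Choice is Bernoulli on a logistic
    function of the EV difference (plus any side bias); reward is Bernoulli
    on the chosen offer's probability; previous-trial lag fields are filled
    (missing on the first trial).
    """
    if n_trials < 1:
        raise DomainError("n_trials must be >= 1")
    task = task or TaskParams()
    task.validate()
    behavior = behavior or BehaviorSpec()
    rng = substream(seed, "trials")

    m1, p1 = _draw_offer(rng, task, n_trials)
    m2, p2 = _draw_offer(rng, task, n_trials)
    ev1 = expected_value(m1, p1)
    ev2 = expected_value(m2, p2)
    side1 = np.where(rng.uniform(size=n_trials) < 0.5, "left", "right")
    side2 = np.where(side1 == "left", "right", "left")

    from scipy.special import expit
    logit = behavior.beta * (ev1 - ev2)
    logit = logit + behavior.side_bias * np.where(side1 == "left", 1.0, -1.0)
    p_choose1 = expit(logit)
    choose1 = rng.uniform(size=n_trials) < p_choose1
    chosen_offer = np.where(choose1, 1, 2)
    chosen_side = np.where(choose1, side1, side2)
    chosen_prob = np.where(choose1, p1, p2)
    rewarded = rng.uniform(size=n_trials) < chosen_prob

    df = pd.DataFrame({
        "trial_id": np.arange(n_trials, dtype=np.int64),
        "offer1_mag": m1, "offer1_prob": p1, "offer1_side": side1,
        "offer2_mag": m2, "offer2_prob": p2, "offer2_side": side2,
        "ev1": ev1, "ev2": ev2,
        "chosen_offer": chosen_offer.astype(np.int64),
        "chosen_side": chosen_side,
        "rewarded": rewarded,
        "t_offer1": 0.0,
        "t_offer2": task.t_offer2,
        "t_choice": task.t_choice,
    })
    df["prev_chosen_offer"] = pd.array(df["chosen_offer"].shift(1), dtype="Int64")
    df["prev_rewarded"] = pd.array(df["rewarded"].shift(1), dtype="boolean")
    return df


def higher_ev_choice_rate(trials: pd.DataFrame) -> float:
    """Fraction of unequal-EV trials on which the higher-EV offer was chosen."""
    ev1 = trials["ev1"].to_numpy()
    ev2 = trials["ev2"].to_numpy()
    uneq = ev1 != ev2
    if not uneq.any():
        raise DomainError("no unequal-EV trials")
    higher = np.where(ev1 > ev2, 1, 2)
    return float(np.mean(trials["chosen_offer"].to_numpy()[uneq] == higher[uneq]))


def calibrate_choice_temperature(target: float = 0.80, n_trials: int = 10_000,
                                 seed: int = 0, task: TaskParams = None,
                                 lo: float = 1e-4, hi: float = 1.0,
                                 n_iter: int = 40) -> float:
    """Bisect the choice temperature β to a target higher-EV choice rate.

    Uses a fixed simulation seed so the objective is deterministic and
    monotone in β up to Monte-Carlo noise at ``n_trials``.
    """
    def rate(beta):
        t = generate_trials(n_trials, task=task,
                            behavior=BehaviorSpec(beta=beta), seed=seed)
        return higher_ev_choice_rate(t)

    if not (rate(lo) <= target <= rate(hi)):
        raise ConfigError("target choice rate outside the achievable [lo, hi] range")
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        if rate(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# --------------------------------------------------------------------------
# spikes
# --------------------------------------------------------------------------

def _zscore(x):
    x = np.asarray(x, dtype=float)
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _signed(mask):
    return np.where(mask, 1.0, -1.0)


def _correlation_cholesky(corr_targets: dict) -> np.ndarray:
    k = len(CORE_WEIGHTS)
    idx = {n: i for i, n in enumerate(CORE_WEIGHTS)}
    C = np.eye(k)
    for (a, b), r in corr_targets.items():
        if a not in idx or b not in idx:
            raise ConfigError(f"unknown weight name in correlation target ({a}, {b})")
        if not -1.0 <= r <= 1.0:
            raise ConfigError(f"correlation target {r} outside [-1, 1]")
        C[idx[a], idx[b]] = C[idx[b], idx[a]] = r
    try:
        return np.linalg.cholesky(C)
    except np.linalg.LinAlgError as e:
        raise ConfigError("target weight-correlation matrix is not positive "
                          "semidefinite") from e


def _draw_neuron_specs(area: AreaSpec, rng) -> list:
    n = area.n_neurons
    L = _correlation_cholesky(area.weight_correlations)
    w_sd = area.base_weight_sd * area.snr_scale
    core = (L @ rng.standard_normal((len(CORE_WEIGHTS), n))).T * w_sd
    extra = rng.standard_normal((n, len(EXTRA_WEIGHTS))) * w_sd
    log_mu = np.log(area.baseline_mean) - 0.5 * area.baseline_log_sd ** 2
    baseline = np.exp(rng.normal(log_mu, area.baseline_log_sd, size=n))
    specs = []
    for i in range(n):
        kw = {f"beta_{name}": float(core[i, j])
              for j, name in enumerate(CORE_WEIGHTS)}
        kw.update({f"beta_{name}": float(extra[i, j])
                   for j, name in enumerate(EXTRA_WEIGHTS)})
        specs.append(NeuronSpec(
            baseline_rate=float(baseline[i]),
            ou_tau=float(area.ou_tau_mean),
            ou_sigma=float(area.ou_sigma_frac * baseline[i]),
            noise_sd=float(area.noise_sd),
            **kw,
        ))
    return specs


def _epoch_drives(trials: pd.DataFrame, specs: list, task: TaskParams):
    """Per-(neuron, trial) additive rate drive for each analysis epoch."""
    zprob1 = _zscore(trials["offer1_prob"])
    zmag1 = _zscore(trials["offer1_mag"])
    zev1 = _zscore(trials["ev1"])
    zev2 = _zscore(trials["ev2"])
    side1 = _signed(trials["offer1_side"].to_numpy() == "right")
    choice = _signed(trials["chosen_offer"].to_numpy() == 1)
    cside = _signed(trials["chosen_side"].to_numpy() == "right")
    ev1 = trials["ev1"].to_numpy()
    ev2 = trials["ev2"].to_numpy()
    chosen_value = np.where(choice > 0, ev1, ev2)
    unchosen_value = np.where(choice > 0, ev2, ev1)
    zcv, zuv = _zscore(chosen_value), _zscore(unchosen_value)
    pco = trials["prev_chosen_offer"].to_numpy(dtype=float, na_value=np.nan)
    prw = trials["prev_rewarded"].to_numpy(dtype=float, na_value=np.nan)
    prev_choice = np.where(np.isnan(pco), 0.0, np.where(pco == 1, 1.0, -1.0))
    prev_reward = np.where(np.isnan(prw), 0.0, np.where(prw > 0, 1.0, -1.0))

    B = {name: np.array([getattr(s, f"beta_{name}") for s in specs])
         for name in CORE_WEIGHTS + EXTRA_WEIGHTS}
    d_e1 = (np.outer(B["prob1"], zprob1) + np.outer(B["mag1"], zmag1)
            + np.outer(B["ev1_e1"], zev1) + np.outer(B["side"], side1))
    d_e2 = np.outer(B["ev1_e2"], zev1) + np.outer(B["ev2_e2"], zev2)
    d_ch = (np.outer(B["choice"], choice) + np.outer(B["chosen_side"], cside)
            + np.outer(B["chosen_value"], zcv)
            + np.outer(B["unchosen_value"], zuv)
            + np.outer(B["prev_choice"], prev_choice)
            + np.outer(B["prev_reward"], prev_reward))
    d_post = np.outer(B["chosen_side"], cside)
    windows = {
        "epoch1": (0.0, 0.5, d_e1),
        "epoch2": (task.t_offer2, task.t_offer2 + 0.5, d_e2),
        "choice": (task.t_choice, task.t_choice + 0.5, d_ch),
        "postchoice": (task.t_choice + 0.5, task.t_choice + 1.0, d_post),
    }
    return windows


def simulate_area(trials: pd.DataFrame, area: AreaSpec, seed: int = 0,
                  time_range=(-2.0, 3.2), dt: float = 0.01, specs=None):
    """Simulate one area's spike trains for the given trial table.

    Returns ``(SpikeTrainSet, list[NeuronSpec])``.  The instantaneous rate
    per neuron is ``baseline + OU(t) + epoch drive``, clipped at zero, and
    spikes are drawn as an inhomogeneous Poisson process discretized at
    ``dt`` (rate constant within each step, spike times jittered uniformly
    inside the step).  Deterministic under ``seed``.  Pass ``specs`` to
    simulate explicit ground-truth neurons instead of drawing them from the
    area's weight population.
    """
    if len(trials) == 0:
        raise DomainError("trials must be non-empty")
    task = TaskParams()
    n_trials = len(trials)
    n_steps = int(round((time_range[1] - time_range[0]) / dt))
    t0 = time_range[0]

    rng_w = substream(seed, "weights", area.order_index)
    rng_s = substream(seed, "spikes", area.order_index)
    if specs is None:
        specs = _draw_neuron_specs(area, rng_w)
    elif len(specs) != area.n_neurons:
        raise ConfigError("len(specs) must equal area.n_neurons")
    n = area.n_neurons

    windows = _epoch_drives(trials, specs, task)
    # map each time step to its epoch drive (or zero)
    step_t = t0 + dt * np.arange(n_steps)
    drive_of_step = [None] * n_steps
    for _, (w0, w1, d) in windows.items():
        in_w = (step_t >= w0 - 1e-9) & (step_t < w1 - 1e-9)
        for s in np.nonzero(in_w)[0]:
            drive_of_step[s] = d

    baseline = np.array([s.baseline_rate for s in specs])
    sigma = np.array([s.ou_sigma for s in specs])
    tau_s = np.array([s.ou_tau for s in specs]) / 1000.0
    a = np.exp(-dt / tau_s)[:, None]
    innov_sd = (sigma * np.sqrt(1.0 - np.exp(-2.0 * dt / tau_s)))[:, None]

    noise_sd = np.array([s.noise_sd for s in specs])
    trial_noise = (rng_s.standard_normal((n, n_trials)) * noise_sd[:, None]
                   if np.any(noise_sd > 0) else 0.0)

    x = rng_s.standard_normal((n, n_trials)) * sigma[:, None]  # stationary OU start
    times, neuron_idx, trial_idx = [], [], []
    for s in range(n_steps):
        rate = baseline[:, None] + x + trial_noise
        d = drive_of_step[s]
        if d is not None:
            rate = rate + d
        np.clip(rate, 0.0, None, out=rate)
        counts = rng_s.poisson(rate * dt)
        nz = np.nonzero(counts)
        if nz[0].size:
            c = counts[nz]
            ni = np.repeat(nz[0], c)
            ti = np.repeat(nz[1], c)
            ts = t0 + (s + rng_s.uniform(size=ni.size)) * dt
            times.append(ts)
            neuron_idx.append(ni)
            trial_idx.append(ti)
        x = x * a + rng_s.standard_normal((n, n_trials)) * innov_sd

    cat = lambda xs, dt_: (np.concatenate(xs) if xs else np.empty(0, dtype=dt_))
    spikes = SpikeTrainSet(
        cat(times, float), cat(neuron_idx, np.int64), cat(trial_idx, np.int64),
        n_neurons=n, n_trials=n_trials, time_range=time_range,
    )
    return spikes, specs


def generate_gradient_dataset(seed: int = 0, n_trials: int = 500,
                              areas=None, task: TaskParams = None,
                              behavior: BehaviorSpec = None,
                              time_range=(-2.0, 3.2), dt: float = 0.01):
    """Generate the four-area gradient dataset (one session per area).

    The default preset uses the recorded neuron counts (156, 146, 213, 129)
    with SNR and OU timescale strictly increasing along the order 1–4.
    """
    areas = list(areas) if areas is not None else list(DEFAULT_AREAS)
    orders = [a.order_index for a in areas]
    if len(set(orders)) != len(orders):
        raise ConfigError("area order_index values must be distinct")
    datasets = []
    for area in sorted(areas, key=lambda a: a.order_index):
        trials = generate_trials(
            n_trials, task=task, behavior=behavior,
            seed=int(substream(seed, "trialseed", area.order_index).integers(2**31)),
        )
        spikes, specs = simulate_area(trials, area, seed=seed,
                                      time_range=time_range, dt=dt)
        datasets.append(AreaDataset(area.name, area.order_index, trials,
                                    spikes, specs, area))
    return datasets


def neuron_specs_frame(specs: list) -> pd.DataFrame:
    """Ground-truth neuron parameters as a DataFrame (for JSON/CSV export)."""
    return pd.DataFrame([asdict(s) for s in specs])
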