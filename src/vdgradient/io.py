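"""CSV/JSON interchange for trial tables, spike trains and ground truth."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from ._errors import DomainError
from .task import SpikeTrainSet, validate_trial_table
from .synth import AreaDataset, NeuronSpec, neuron_specs_frame

__all__ = [
    "write_trials", "read_trials",
    "write_spikes", "read_spikes",
    "write_area_dataset", "read_area_dataset",
]

SPIKE_COLUMNS = ["session_id", "neuron_id", "trial_id", "spike_time_s"]


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DomainError(f"trial table not found: {path}")
    df = pd.read_csv(path)
    df["prev_chosen_offer"] = pd.array(df["prev_chosen_offer"], dtype="Int64")
    df["prev_rewarded"] = pd.array(df["prev_rewarded"], dtype="boolean")
    return validate_trial_table(df)


def write_spikes(spikes: SpikeTrainSet, path, session_id: str = "s0") -> None:
    pd.DataFrame({
        "session_id": session_id,
        "neuron_id": spikes.neuron_index,
        "trial_id": spikes.trial_index,
        "spike_time_s": spikes.times,
    }).to_csv(path, index=False)


def read_spikes(path, n_neurons: int = None, n_trials: int = None,
                time_range=(-2.0, 3.2)) -> SpikeTrainSet:
    path = Path(path)
    if not path.exists():
        raise DomainError(f"spike file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in SPIKE_COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"spike file missing columns: {missing}")
    if n_neurons is None:
        n_neurons = int(df["neuron_id"].max()) + 1 if len(df) else 0
    if n_trials is None:
        n_trials = int(df["trial_id"].max()) + 1 if len(df) else 0
    return SpikeTrainSet(df["spike_time_s"].to_numpy(),
                         df["neuron_id"].to_numpy(),
                         df["trial_id"].to_numpy(),
                         n_neurons=n_neurons, n_trials=n_trials,
                         time_range=time_range)


def write_area_dataset(dataset: AreaDataset, out_dir) -> None:
    """Write trials.csv, spikes.csv and ground_truth.json for one area."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_trials(dataset.trials, out / "trials.csv")
    write_spikes(dataset.spikes, out / "spikes.csv", session_id=dataset.name)
    meta = {
        "name": dataset.name,
        "order_index": dataset.order_index,
        "n_neurons": dataset.spikes.n_neurons,
        "n_trials": dataset.spikes.n_trials,
        "time_range": list(dataset.spikes.time_range),
        "neurons": neuron_specs_frame(dataset.neuron_specs).to_dict("records"),
    }
    (out / "ground_truth.json").write_text(json.dumps(meta, indent=1))


def read_area_dataset(area_dir) -> AreaDataset:
    area_dir = Path(area_dir)
    meta_path = area_dir / "ground_truth.json"
    if not meta_path.exists():
        raise DomainError(f"ground truth not found: {meta_path}")
    meta = json.loads(meta_path.read_text())
    trials = read_trials(area_dir / "trials.csv")
    spikes = read_spikes(area_dir / "spikes.csv",
                         n_neurons=meta["n_neurons"],
                         n_trials=meta["n_trials"],
                         time_range=tuple(meta["time_range"]))
    specs = [NeuronSpec(**rec) for rec in meta["neurons"]]
    return AreaDataset(meta["name"], int(meta["order_index"]), trials,
                       spikes, specs)
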