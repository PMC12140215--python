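"""Reading and writing trial tables (CSV) and epoch sets (NPZ + JSON sidecar).

Trial-table columns (phases in radians, wrapped to [-pi, pi); times in
seconds from stimulus onset):

    participant_id, session_id, condition, tacs_condition, block, stimulus,
    gap_time, fm_phase, tacs_phase, tacs_lag, response_time, accuracy

``condition`` holds the session/block condition label: modulation depth (%)
in Experiment 1, tACS frequency (Hz, or "sham") in Experiment 2, FM rate (Hz)
in Experiment 3.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import EpochSet


def write_trial_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_trial_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    # condition labels may mix numbers and "sham"; keep numerics numeric
    if "condition" in df.columns and df["condition"].dtype == object:
        def _coerce(v):
            try:
                return float(v)
            except (TypeError, ValueError):
                return v
        df["condition"] = df["condition"].map(_coerce)
    return df


def save_epochs(epochs: EpochSet, prefix) -> None:
    """Write ``<prefix>.npz`` (data array) and ``<prefix>.json`` (metadata)."""
    prefix = Path(prefix)
    np.savez_compressed(prefix.with_suffix(".npz"), data=epochs.data)
    meta = {
        "fs": epochs.fs,
        "condition": epochs.condition,
        "channel_labels": list(epochs.channel_labels),
        "epoch_onset_phase": epochs.epoch_onset_phase,
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_epochs(prefix) -> EpochSet:
    prefix = Path(prefix)
    data = np.load(prefix.with_suffix(".npz"))["data"]
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return EpochSet(
        data=data,
        fs=meta["fs"],
        condition=meta["condition"],
        channel_labels=meta["channel_labels"],
        epoch_onset_phase=meta.get("epoch_onset_phase", 0.0),
    )
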