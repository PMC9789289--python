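"""Spike-train container shared by all model variants."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["SpikeTrain", "spike_trains_to_csv", "spike_trains_from_csv"]

#: Valid generating-model labels.
SOURCE_LABELS = ("ES", "AS", "EAS-uncoupled", "EAS-coupled", "EAS-alt")


@dataclass
class SpikeTrain:
    """Sorted spike times for one fiber and one trial.

    Attributes
    ----------
    spike_times : sorted spike times (s)
    fiber_id : index of the fiber in its population
    trial_id : repetition index
    source_label : generating model ("ES", "AS", "EAS-uncoupled",
        "EAS-coupled", "EAS-alt")
    """

    spike_times: np.ndarray
    fiber_id: int = 0
    trial_id: int = 0
    source_label: str = "ES"

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if np.any(np.diff(self.spike_times) < 0):
            raise ValueError("spike times must be sorted")

    def __len__(self) -> int:
        return len(self.spike_times)

    def in_window(self, start: float, stop: float) -> np.ndarray:
        """Spike times t with start <= t < stop."""
        t = self.spike_times
        return t[(t >= start) & (t < stop)]


def spike_trains_to_csv(trains: Sequence[SpikeTrain], path) -> None:
    rows = [
        {"fiber_id": tr.fiber_id, "trial": tr.trial_id,
         "spike_time_s": t, "source_label": tr.source_label}
        for tr in trains for t in tr.spike_times
    ]
    pd.DataFrame(rows, columns=["fiber_id", "trial", "spike_time_s",
                                "source_label"]).to_csv(path, index=False)


def spike_trains_from_csv(path) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    trains = []
    for (fid, trial, label), grp in df.groupby(
            ["fiber_id", "trial", "source_label"], sort=True):
        trains.append(SpikeTrain(np.sort(grp["spike_time_s"].to_numpy()),
                                 fiber_id=int(fid), trial_id=int(trial),
                                 source_label=str(label)))
    return trains
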