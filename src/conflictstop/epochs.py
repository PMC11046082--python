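"""Epoched multichannel EEG container and its HDF5 serialization.

Epochs are stored per subject and condition as ``trials x channels x
samples`` arrays sharing one time axis and one channel montage.  The time
grid is fixed at 307 samples of a 256 Hz recording, covering -200 ms to
just under +1000 ms relative to the epoching event with the half-open
convention ``t_i = -200 + i * (1000 / 256)`` ms (1200 ms at 256 Hz is not
an integer number of samples, so the final sample falls at +995.3 ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

N_CHANNELS = 60
N_SAMPLES = 307
SFREQ = 256.0
EPOCH_START_MS = -200.0

CONDITIONS = ("congruent", "incongruent")

GENERATOR_VERSION = "conflictstop-0.1.0"


def epoch_times() -> np.ndarray:
    """Return the epoch time axis in milliseconds (307 samples at 256 Hz)."""
    return EPOCH_START_MS + np.arange(N_SAMPLES) * (1000.0 / SFREQ)


def default_channel_names(n_channels: int = N_CHANNELS) -> list[str]:
    return [f"E{i + 1:02d}" for i in range(n_channels)]


@dataclass
class EpochsSet:
    """Per-subject, per-condition stop-trial epochs.

    Parameters
    ----------
    data
        ``data[subject][condition]`` is a ``(n_trials, n_channels,
        n_samples)`` float array.  Trial counts may differ across cells.
    times
        Shared time axis in ms.
    channels
        Channel labels, shared across subjects.
    seed
        Seed recorded by the generator (``None`` for imported data).
    """

    data: dict[str, dict[str, np.ndarray]]
    times: np.ndarray = field(default_factory=epoch_times)
    channels: list[str] = field(default_factory=default_channel_names)
    seed: int | None = None

    @property
    def subjects(self) -> list[str]:
        return sorted(self.data)

    @property
    def conditions(self) -> list[str]:
        first = self.data[self.subjects[0]]
        return [c for c in CONDITIONS if c in first] or sorted(first)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def get(self, subject: str, condition: str) -> np.ndarray:
        return self.data[subject][condition]

    def validate(self) -> None:
        nt = len(self.times)
        for sub, conds in self.data.items():
            for cond, arr in conds.items():
                if arr.ndim != 3 or arr.shape[1] != self.n_channels or arr.shape[2] != nt:
                    raise ValueError(
                        f"epochs for {sub}/{cond} have shape {arr.shape}; expected "
                        f"(trials, {self.n_channels}, {nt})"
                    )


def save_epochs(path, epochs: EpochsSet) -> None:
    """Write an :class:`EpochsSet` to HDF5.

    Layout: ``/sub-<ID>/<condition>/data``, with root datasets ``/times``
    (ms) and ``/channels`` and root attributes ``seed`` and
    ``generator_version``.
    """
    epochs.validate()
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=np.asarray(epochs.times, dtype=np.float64))
        f.create_dataset("channels", data=np.array(epochs.channels, dtype="S"))
        if epochs.seed is not None:
            f.attrs["seed"] = int(epochs.seed)
        f.attrs["generator_version"] = GENERATOR_VERSION
        for sub in epochs.subjects:
            g = f.create_group(sub)
            for cond, arr in epochs.data[sub].items():
                g.create_group(cond).create_dataset(
                    "data", data=np.asarray(arr, dtype=np.float32)
                )


def load_epochs(path) -> EpochsSet:
    data: dict[str, dict[str, np.ndarray]] = {}
    with h5py.File(path, "r") as f:
        times = np.asarray(f["times"])
        channels = [c.decode() for c in f["channels"][()]]
        seed = int(f.attrs["seed"]) if "seed" in f.attrs else None
        for sub in f:
            if not isinstance(f[sub], h5py.Group):
                continue
            data[sub] = {
                cond: np.asarray(f[sub][cond]["data"], dtype=np.float64)
                for cond in f[sub]
            }
    return EpochsSet(data=data, times=times, channels=channels, seed=seed)
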