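"""In-memory containers and on-disk formats.

``EpochSet`` holds trials x channels x samples data with a millisecond time
axis and provenance flags (reference state, baseline interval, CSD).  The
trial table is a plain :class:`pandas.DataFrame`, one row per trial, and is
the single source of truth for condition labels; ``trial_id`` aligns the
two.

On disk, epochs go to HDF5 (data + time axis) with a JSON sidecar for
channel labels and provenance; trial tables are tab-separated text.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import EOG, MASTOIDS

#: columns every trial table carries
TRIAL_COLUMNS = [
    "trial_id", "participant_id", "condition", "block", "block_global",
    "practice", "accuracy", "rt", "timeout", "multiple_response",
    "eval_response", "eval_rt", "certainty", "stimulus_onset_ms",
    "target_key", "response_key",
] + [f"force_k{i}" for i in range(1, 9)]

REFERENCES = ("left_mastoid", "linked_mastoid", "average", "csd")


@dataclass
class EpochSet:
    """Epoched multichannel data, trials x channels x samples.

    Parameters
    ----------
    data
        Array (n_trials, n_channels, n_samples) in µV (µV/cm² after the
        surface-Laplacian transform).
    times
        Sample times in ms relative to the lock event, uniform 2-ms step.
    channels
        Channel labels; scalp sites plus optionally M1/M2 and hEOG/vEOG.
    lock
        Event the epochs are time-locked to: ``"response"`` or
        ``"stimulus"``.
    trial_ids
        One id per trial, unique, matching the trial table.
    """

    data: np.ndarray
    times: np.ndarray
    channels: list[str]
    trial_ids: np.ndarray
    lock: str = "response"
    reference: str = "left_mastoid"
    baseline_interval: tuple[float, float] | None = None
    history: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.times = np.asarray(self.times, float)
        self.trial_ids = np.asarray(self.trial_ids)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        n_tr, n_ch, n_s = self.data.shape
        if len(self.channels) != n_ch:
            raise ValueError("channel list does not match data")
        if self.times.shape != (n_s,):
            raise ValueError("time axis does not match data")
        steps = np.diff(self.times)
        if n_s > 1 and (np.any(steps <= 0) or not np.allclose(steps, steps[0])):
            raise ValueError("times must be strictly increasing with a constant step")
        if len(np.unique(self.trial_ids)) != n_tr:
            raise ValueError("trial_ids must be unique")
        if self.reference not in REFERENCES:
            raise ValueError(f"unknown reference {self.reference!r}")

    # ---- basic geometry ------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def sfreq(self) -> float:
        return 1000.0 / (self.times[1] - self.times[0])

    @property
    def scalp_channels(self) -> list[str]:
        aux = set(MASTOIDS) | set(EOG)
        return [c for c in self.channels if c not in aux]

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not present") from None

    def scalp_picks(self) -> np.ndarray:
        aux = set(MASTOIDS) | set(EOG)
        return np.array([i for i, c in enumerate(self.channels) if c not in aux])

    def time_mask(self, tmin: float, tmax: float) -> np.ndarray:
        """Boolean sample mask for the inclusive window [tmin, tmax] ms."""
        return (self.times >= tmin - 1e-9) & (self.times <= tmax + 1e-9)

    # ---- derived sets --------------------------------------------------
    def copy(self, data: np.ndarray | None = None, **kw) -> "EpochSet":
        out = replace(self)
        out.data = (self.data if data is None else data).copy()
        out.times = self.times.copy()
        out.channels = list(self.channels)
        out.trial_ids = self.trial_ids.copy()
        out.history = list(self.history)
        for k, v in kw.items():
            setattr(out, k, v)
        return out

    def crop(self, tmin: float, tmax: float) -> "EpochSet":
        m = self.time_mask(tmin, tmax)
        if not m.any():
            raise ValueError(f"window ({tmin}, {tmax}) ms outside epoch")
        out = self.copy(data=self.data[:, :, m])
        out.times = self.times[m]
        return out

    def select_trials(self, trial_ids) -> "EpochSet":
        idx = {t: i for i, t in enumerate(self.trial_ids)}
        rows = np.array([idx[t] for t in trial_ids])
        out = self.copy(data=self.data[rows])
        out.trial_ids = np.asarray(list(trial_ids))
        return out

    def log(self, msg: str) -> None:
        self.history.append(msg)

    # ---- I/O -----------------------------------------------------------
    def save(self, path: str | Path) -> None:
        import h5py

        path = Path(path)
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("times", data=self.times)
            ids = self.trial_ids
            if ids.dtype.kind in "OU":
                ids = np.asarray([str(t) for t in ids], dtype="S")
            f.create_dataset("trial_ids", data=ids)
        sidecar = {
            "channels": self.channels,
            "lock": self.lock,
            "reference": self.reference,
            "baseline_interval": self.baseline_interval,
            "history": self.history,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "EpochSet":
        import h5py

        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        with h5py.File(path, "r") as f:
            data = f["data"][()]
            times = f["times"][()]
            ids = f["trial_ids"][()]
        if ids.dtype.kind == "S":
            ids = ids.astype(str)
        bl = meta["baseline_interval"]
        return cls(
            data=data, times=times, channels=meta["channels"], trial_ids=ids,
            lock=meta["lock"], reference=meta["reference"],
            baseline_interval=tuple(bl) if bl else None,
            history=meta.get("history", []),
        )

    def to_mne(self):
        """Export as an :class:`mne.EpochsArray` (volts, seconds)."""
        import mne

        types = ["eog" if c in EOG else "eeg" for c in self.channels]
        info = mne.create_info(self.channels, sfreq=self.sfreq, ch_types=types)
        return mne.EpochsArray(
            self.data * 1e-6, info, tmin=self.times[0] / 1000.0, verbose="error"
        )


def align(epochs: EpochSet, table: pd.DataFrame) -> pd.DataFrame:
    """Rows of ``table`` for the trials present in ``epochs``, epoch order."""
    tab = table.set_index("trial_id")
    missing = [t for t in epochs.trial_ids if t not in tab.index]
    if missing:
        raise KeyError(f"epoch trials missing from table: {missing[:5]} ...")
    return tab.loc[epochs.trial_ids].reset_index()


def write_trial_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_trial_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(TRIAL_COLUMNS) - set(table.columns)
    if missing:
        warnings.warn(f"trial table lacks columns: {sorted(missing)}")
    return table
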