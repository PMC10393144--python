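"""Core containers: paradigm definitions, epoch sets, component windows.

An :class:`EpochSet` is the package's central in-memory object: a
``channels x time x trials`` array in microvolts with the sampling rate, the
montage channel names, a per-trial label table (subject, group, target flag)
and a boolean retention mask updated by artifact rejection. Epoch sets are
serialised to an HDF5 container (arrays + JSON-encoded labels) shared by the
simulator and the preprocessing stage.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

from .montage import CHANNELS_32

COMPONENTS = ("P200", "N200", "P300")
#: Deflection polarity of each component (+1 positive-going, -1 negative).
POLARITY = {"P200": +1, "N200": -1, "P300": +1}


@dataclass(frozen=True)
class ParadigmSpec:
    """Oddball block parameters: stimulus/blank durations and trial counts."""

    name: str
    stimulus_duration: float  # s
    blank_duration: float     # s
    n_targets: int
    n_nontargets: int

    def __post_init__(self):
        if self.n_targets <= 0 or self.n_nontargets <= 0:
            raise ValueError("trial counts must be positive")
        if self.stimulus_duration <= 0 or self.blank_duration <= 0:
            raise ValueError("durations must be positive")


#: The four experiment blocks: a simple blue/red-ball oddball and three
#: game-scene paradigms with decreasing target size.
PARADIGMS: dict[str, ParadigmSpec] = {
    "B/RB": ParadigmSpec("B/RB", 0.25, 0.5, 60, 240),
    "BT": ParadigmSpec("BT", 0.4, 1.0, 40, 260),
    "MT": ParadigmSpec("MT", 0.4, 1.0, 40, 260),
    "ST": ParadigmSpec("ST", 0.8, 1.0, 56, 168),
}


@dataclass(frozen=True)
class EpochSpec:
    """Epoch window and baseline: ms relative to stimulus onset at 0."""

    pre_ms: float
    post_ms: float
    baseline_ms: float = 100.0  # last `baseline_ms` of the pre-stimulus window

    @property
    def total_ms(self) -> float:
        return self.pre_ms + self.post_ms

    def n_samples(self, srate: float) -> int:
        n = self.total_ms * srate / 1000.0
        if abs(n - round(n)) > 1e-9:
            raise ValueError(f"epoch span {self.total_ms} ms is not an integer "
                             f"number of samples at {srate} Hz")
        return int(round(n))

    def times_ms(self, srate: float) -> np.ndarray:
        n = self.n_samples(srate)
        return -self.pre_ms + np.arange(n) * 1000.0 / srate


#: Epoch geometry per paradigm: the simple oddball uses an 800 ms epoch with
#: 200 ms pre-stimulus; the game paradigms a 500 ms pre-stimulus epoch whose
#: last sample falls exactly on +900 ms (351 samples at 250 Hz), so the
#: -100...+900 ms tensor crop keeps its full 251-sample time axis.
EPOCH_SPECS: dict[str, EpochSpec] = {
    "B/RB": EpochSpec(pre_ms=200.0, post_ms=600.0),
    "BT": EpochSpec(pre_ms=500.0, post_ms=904.0),
    "MT": EpochSpec(pre_ms=500.0, post_ms=904.0),
    "ST": EpochSpec(pre_ms=500.0, post_ms=904.0),
}


@dataclass(frozen=True)
class ComponentWindow:
    """Search window for one ERP component, with its polarity."""

    component: str
    polarity: int
    start_ms: float
    end_ms: float

    def __post_init__(self):
        if self.end_ms <= self.start_ms:
            raise ValueError("degenerate component window")


def default_windows(paradigm: str) -> dict[str, ComponentWindow]:
    """Default component search windows.

    The P300 window for the small-target paradigm extends to the end of the
    stimulus (its maximal deflection occurs well after 300 ms when the task
    demands visual search).
    """
    wins = {
        "P200": ComponentWindow("P200", +1, 150.0, 250.0),
        "N200": ComponentWindow("N200", -1, 200.0, 320.0),
        "P300": ComponentWindow("P300", +1, 280.0, 450.0),
    }
    if paradigm == "ST":
        end = PARADIGMS["ST"].stimulus_duration * 1000.0
        wins["P300"] = ComponentWindow("P300", +1, 350.0, end)
    return wins


@dataclass
class EpochSet:
    """Epoched multi-channel EEG with per-trial labels and a retention mask."""

    data: np.ndarray                   # (n_channels, n_times, n_trials), uV
    srate: float
    times_ms: np.ndarray               # (n_times,), stimulus at 0
    channels: tuple[str, ...] = CHANNELS_32
    trials: pd.DataFrame = None        # columns: subject, group, target, index
    retained: np.ndarray = None        # bool (n_trials,)
    paradigm: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be channels x time x trials")
        nc, nt, ntr = self.data.shape
        if nc != len(self.channels):
            raise ValueError("channel count does not match montage length")
        if len(self.times_ms) != nt:
            raise ValueError("times axis does not match data")
        if self.trials is None:
            self.trials = pd.DataFrame({
                "subject": ["s0"] * ntr, "group": ["NA"] * ntr,
                "target": [True] * ntr, "index": np.arange(ntr)})
        if len(self.trials) != ntr:
            raise ValueError("trial labels must match trial count")
        if self.retained is None:
            self.retained = np.ones(ntr, dtype=bool)
        self.retained = np.asarray(self.retained, dtype=bool)

    # -- selection ---------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    def select(self, *, target: bool | None = None, subject=None, group=None,
               retained_only: bool = True) -> "EpochSet":
        """Subset trials by label; returns a new EpochSet (copy of labels)."""
        keep = np.ones(self.n_trials, dtype=bool)
        if retained_only:
            keep &= self.retained
        if target is not None:
            keep &= self.trials["target"].to_numpy() == target
        if subject is not None:
            keep &= self.trials["subject"].to_numpy() == subject
        if group is not None:
            keep &= self.trials["group"].to_numpy() == group
        return replace(
            self,
            data=self.data[:, :, keep],
            trials=self.trials.loc[keep].reset_index(drop=True),
            retained=self.retained[keep],
        )

    def crop(self, start_ms: float, end_ms: float) -> "EpochSet":
        tol = 0.5 * 1000.0 / self.srate
        sel = (self.times_ms >= start_ms - tol) & (self.times_ms <= end_ms + tol)
        return replace(self, data=self.data[:, sel, :], times_ms=self.times_ms[sel])

    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.trials["subject"]))

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data, compression="gzip")
            f.create_dataset("times_ms", data=self.times_ms)
            f.create_dataset("retained", data=self.retained)
            f.attrs["srate"] = self.srate
            f.attrs["paradigm"] = self.paradigm
            f.attrs["channels"] = json.dumps(list(self.channels))
            f.attrs["trials"] = self.trials.to_json(orient="split")
            f.attrs["meta"] = json.dumps(self.meta)

    @classmethod
    def load(cls, path) -> "EpochSet":
        with h5py.File(path, "r") as f:
            trials = pd.read_json(io.StringIO(f.attrs["trials"]),
                                  orient="split")
            return cls(
                data=f["data"][()], srate=float(f.attrs["srate"]),
                times_ms=f["times_ms"][()],
                channels=tuple(json.loads(f.attrs["channels"])),
                trials=trials, retained=f["retained"][()].astype(bool),
                paradigm=str(f.attrs["paradigm"]),
                meta=json.loads(f.attrs["meta"]),
            )
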