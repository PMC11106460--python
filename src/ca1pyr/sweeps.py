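"""Current-clamp sweep containers, stimulus builders and columnar-CSV I/O.

A :class:`Sweep` holds one uniformly sampled recording: time (s), injected
current (pA) and membrane voltage (mV), with the stimulus epoch marked by
onset/offset times.  Sweep families (e.g. a hyperpolarizing step series)
are grouped in a :class:`SweepSet`.

On disk a sweep set is one CSV with columns ``sweep,t_s,i_pa,v_mv`` plus a
JSON header carrying the sampling rate, protocol and epoch markers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

PROTOCOLS = ("step", "chirp")


@dataclass
class Sweep:
    t: np.ndarray          # s, uniform
    i: np.ndarray          # pA
    v: np.ndarray          # mV
    fs: float              # Hz
    onset: float           # stimulus onset, s
    offset: float          # stimulus offset, s
    protocol: str = "step"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (len(self.t) == len(self.i) == len(self.v)):
            raise ValueError("t, i, v must have equal length")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not (self.onset < self.offset <= self.t[-1] + 1.0 / self.fs):
            raise ValueError("require onset < offset <= trace end")
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"unknown protocol {self.protocol!r}")

    def window(self, t0: float, t1: float) -> np.ndarray:
        """Boolean mask selecting samples with t0 <= t < t1."""
        return (self.t >= t0) & (self.t < t1)

    def baseline_voltage(self, pre_s: float = 0.1) -> float:
        """Mean voltage over the final ``pre_s`` seconds before stimulus onset."""
        mask = self.window(max(self.onset - pre_s, 0.0), self.onset)
        return float(np.mean(self.v[mask]))

    def step_amplitude(self) -> float:
        """Injected step amplitude (pA): stimulus mean minus pre-stimulus mean."""
        stim = self.window(self.onset, self.offset)
        pre = self.window(0.0, self.onset)
        base = float(np.mean(self.i[pre])) if pre.any() else 0.0
        return float(np.mean(self.i[stim])) - base


@dataclass
class SweepSet:
    sweeps: list[Sweep]

    def __iter__(self):
        return iter(self.sweeps)

    def __len__(self):
        return len(self.sweeps)

    def hyperpolarizing(self) -> list[Sweep]:
        return [s for s in self.sweeps if s.step_amplitude() < 0]

    def depolarizing(self) -> list[Sweep]:
        return [s for s in self.sweeps if s.step_amplitude() > 0]


# ---------------------------------------------------------------------------
# stimulus builders
# ---------------------------------------------------------------------------

def step_current(
    amp_pa: float,
    fs: float = 20000.0,
    pre_s: float = 0.2,
    dur_s: float = 1.0,
    post_s: float = 0.3,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Square current step; returns (t, i, onset, offset)."""
    n = int(round((pre_s + dur_s + post_s) * fs))
    t = np.arange(n) / fs
    i = np.zeros(n)
    i[(t >= pre_s) & (t < pre_s + dur_s)] = amp_pa
    return t, i, pre_s, pre_s + dur_s


def chirp_current(
    amp_pa: float = 100.0,
    f0_hz: float = 0.5,
    f1_hz: float = 30.0,
    dur_s: float = 10.0,
    fs: float = 20000.0,
    pre_s: float = 0.5,
    post_s: float = 0.2,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Linear frequency sweep (ZAP stimulus); returns (t, i, onset, offset).

    The instantaneous frequency rises linearly from ``f0_hz`` to ``f1_hz``
    over ``dur_s`` (the standard 0.5–30 Hz in 10 s, or 0.5–40 Hz in 20 s).
    """
    n = int(round((pre_s + dur_s + post_s) * fs))
    t = np.arange(n) / fs
    i = np.zeros(n)
    mask = (t >= pre_s) & (t < pre_s + dur_s)
    ts = t[mask] - pre_s
    phase = 2.0 * np.pi * (f0_hz * ts + (f1_hz - f0_hz) * ts**2 / (2.0 * dur_s))
    i[mask] = amp_pa * np.sin(phase)
    return t, i, pre_s, pre_s + dur_s


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def write_sweepset(sweeps: SweepSet, csv_path: str | Path) -> None:
    """Write a sweep set as ``sweep,t_s,i_pa,v_mv`` CSV + JSON header sidecar."""
    csv_path = Path(csv_path)
    frames = []
    header = {"sweeps": []}
    for k, s in enumerate(sweeps):
        frames.append(pd.DataFrame({
            "sweep": k, "t_s": s.t, "i_pa": s.i, "v_mv": s.v,
        }))
        header["sweeps"].append({
            "index": k, "fs_hz": s.fs, "onset_s": s.onset, "offset_s": s.offset,
            "protocol": s.protocol, "meta": s.meta,
        })
    pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False,
                                                float_format="%.6g")
    with open(csv_path.with_suffix(".json"), "w") as fh:
        json.dump(header, fh, indent=1)


def read_sweepset(csv_path: str | Path) -> SweepSet:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    with open(csv_path.with_suffix(".json")) as fh:
        header = json.load(fh)
    by_index = {h["index"]: h for h in header["sweeps"]}
    sweeps = []
    for k, grp in df.groupby("sweep", sort=True):
        h = by_index[int(k)]
        sweeps.append(Sweep(
            t=grp["t_s"].to_numpy(), i=grp["i_pa"].to_numpy(),
            v=grp["v_mv"].to_numpy(), fs=h["fs_hz"],
            onset=h["onset_s"], offset=h["offset_s"],
            protocol=h["protocol"], meta=h.get("meta", {}),
        ))
    return SweepSet(sweeps)
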