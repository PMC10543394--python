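"""Spike-train container shared by every stage of the pipeline.

A :class:`SpikeTrainSet` is a list of per-cell spike-time arrays (seconds,
strictly increasing) together with the stimulus duration and a provenance
dict recording the seeds and stage that produced it.  All stages (EC grid
cells, LEC, DG granule cells, CA3) exchange this one type.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SpikeTrainSet", "jitter_spikes", "save_spikes", "load_spikes"]


@dataclass
class SpikeTrainSet:
    """Per-cell sorted spike times within ``[0, duration]``."""

    trains: list[np.ndarray]
    duration: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.trains = [np.asarray(t, dtype=float) for t in self.trains]
        for i, t in enumerate(self.trains):
            if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0 or t[-1] > self.duration):
                raise ValueError(
                    f"cell {i}: spike times must be strictly increasing within "
                    f"[0, {self.duration}]"
                )

    @property
    def n_cells(self) -> int:
        return len(self.trains)

    @property
    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.trains))

    def counts(self) -> np.ndarray:
        return np.array([t.size for t in self.trains])

    def mean_rate(self) -> float:
        """Population mean firing rate in Hz."""
        return self.n_spikes / (self.n_cells * self.duration)

    def phases(self, theta_freq: float) -> list[np.ndarray]:
        """Theta phase of every spike, phase 0 at each cycle start."""
        return [2.0 * np.pi * np.mod(t * theta_freq, 1.0) for t in self.trains]

    def cycle_indices(self, theta_freq: float) -> list[np.ndarray]:
        return [np.floor(t * theta_freq).astype(int) for t in self.trains]

    def n_cycles(self, theta_freq: float) -> int:
        return int(round(self.duration * theta_freq))

    def pooled(self) -> np.ndarray:
        """All spike times of all cells, concatenated (unsorted by cell)."""
        if not self.trains:
            return np.empty(0)
        return np.concatenate(self.trains)

    def select_cells(self, idx) -> "SpikeTrainSet":
        return SpikeTrainSet([self.trains[i] for i in idx], self.duration,
                             dict(self.provenance))

    def to_frame(self) -> pd.DataFrame:
        cells = np.concatenate(
            [np.full(t.size, i) for i, t in enumerate(self.trains)]
        ) if self.n_spikes else np.empty(0, dtype=int)
        return pd.DataFrame({"cell_id": cells.astype(int),
                             "spike_time_s": self.pooled()})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, n_cells: int, duration: float,
                   provenance: dict | None = None) -> "SpikeTrainSet":
        trains = [np.sort(df.loc[df["cell_id"] == i, "spike_time_s"].to_numpy())
                  for i in range(n_cells)]
        return cls(trains, duration, provenance or {})


def jitter_spikes(spikes: SpikeTrainSet, sigma: float, seed: int) -> SpikeTrainSet:
    """Add Gaussian jitter (SD ``sigma`` seconds) to every spike time.

    Times are clipped to ``[0, duration]`` and re-sorted; exact duplicates
    (probability zero for sigma > 0) are nudged apart by 1 ns.
    """
    rng = np.random.default_rng(seed)
    out = []
    for t in spikes.trains:
        tj = np.sort(np.clip(t + rng.normal(0.0, sigma, t.size), 0.0, spikes.duration))
        bad = np.flatnonzero(np.diff(tj) <= 0)
        while bad.size:
            tj[bad + 1] = np.nextafter(tj[bad], np.inf) + 1e-9
            tj = np.minimum(tj, spikes.duration)
            tj.sort()
            bad = np.flatnonzero(np.diff(tj) <= 0)
        out.append(tj)
    prov = dict(spikes.provenance)
    prov["jitter_sd_s"] = sigma
    return SpikeTrainSet(out, spikes.duration, prov)


def save_spikes(spikes: SpikeTrainSet, path: str | Path) -> None:
    """Write ``cell_id,spike_time_s`` CSV plus a JSON sidecar with metadata."""
    path = Path(path)
    spikes.to_frame().to_csv(path, index=False, float_format="%.17g")
    meta = {"duration_s": spikes.duration, "n_cells": spikes.n_cells}
    meta.update({k: v for k, v in spikes.provenance.items()
                 if isinstance(v, (str, int, float, bool, type(None)))})
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_spikes(path: str | Path) -> SpikeTrainSet:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    meta = json.loads(path.with_suffix(".json").read_text())
    n_cells = int(meta.pop("n_cells"))
    duration = float(meta.pop("duration_s"))
    return SpikeTrainSet.from_frame(df, n_cells, duration, meta)
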