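"""Theta-cycle phase/rate vector codes and their isolation.

Each (cell, theta-cycle) pair is summarized by a "theta-vector" in polar
coordinates: magnitude = firing rate in the 100 ms cycle (Hz), angle =
circular mean theta phase of the spikes in that cycle.  Vectors are
transformed to Cartesian [x, y] so that cycles without spikes are well
defined (as [0, 0]) and can enter correlations and decoders.

Pure codes are isolated by clamping the other coordinate:

* rate-isolated:  angle := pi/4 wherever spikes exist (x = y = r/sqrt(2));
* phase-isolated: magnitude := 1 Hz wherever spikes exist and the circular
  mean is defined.

Cycles whose spike phases cancel exactly (zero resultant) have an undefined
mean phase: they are mapped to [0, 0] in full and phase-isolated modes but
keep their rate in rate-isolated mode, because the rate is not undefined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spiketrains import SpikeTrainSet

__all__ = ["ThetaCode", "ThetaCodeMatrix", "theta_vectors", "to_cartesian",
           "isolate", "flatten", "unflatten"]

_RESULTANT_TOL = 1e-12


@dataclass
class ThetaCode:
    """Polar theta-vectors per (cell, cycle) plus definedness masks."""

    rates: np.ndarray          # (n_cells, n_cycles) Hz
    phases: np.ndarray         # (n_cells, n_cycles) rad; 0 where undefined
    has_spikes: np.ndarray     # bool
    phase_defined: np.ndarray  # bool, subset of has_spikes
    bin_width: float
    provenance: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.rates.shape[0]

    @property
    def n_bins(self) -> int:
        return self.rates.shape[1]


@dataclass
class ThetaCodeMatrix:
    """Cartesian [x, y] per (cell, cycle) with a code-mode flag."""

    values: np.ndarray        # (n_cells, n_bins, 2)
    bin_width: float
    mode: str                 # full | rate_isolated | phase_isolated
    provenance: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        n_c, n_b, _ = self.values.shape
        cell, bins = np.meshgrid(np.arange(n_c), np.arange(n_b), indexing="ij")
        return pd.DataFrame({
            "cell": cell.ravel(), "bin": bins.ravel(),
            "x": self.values[..., 0].ravel(), "y": self.values[..., 1].ravel(),
            "mode": self.mode,
        })


def theta_vectors(spikes: SpikeTrainSet, theta_freq: float) -> ThetaCode:
    """Per-(cell, cycle) firing rate and circular-mean phase."""
    n_cycles = spikes.n_cycles(theta_freq)
    if abs(n_cycles / theta_freq - spikes.duration) > 1e-9:
        raise ValueError("duration must divide into whole theta cycles")
    cycle_len = 1.0 / theta_freq
    n = spikes.n_cells
    counts = np.zeros((n, n_cycles))
    re = np.zeros((n, n_cycles))
    im = np.zeros((n, n_cycles))
    for c, t in enumerate(spikes.trains):
        if not t.size:
            continue
        cyc = np.minimum(np.floor(t * theta_freq).astype(int), n_cycles - 1)
        ph = 2.0 * np.pi * np.mod(t * theta_freq, 1.0)
        np.add.at(counts[c], cyc, 1.0)
        np.add.at(re[c], cyc, np.cos(ph))
        np.add.at(im[c], cyc, np.sin(ph))
    rates = counts / cycle_len
    resultant = np.hypot(re, im)
    has_spikes = counts > 0
    phase_defined = has_spikes & (resultant > _RESULTANT_TOL * np.maximum(counts, 1))
    phases = np.where(phase_defined, np.arctan2(im, re), 0.0) % (2.0 * np.pi)
    return ThetaCode(rates, phases, has_spikes, phase_defined, cycle_len,
                     dict(spikes.provenance))


def to_cartesian(r, theta) -> tuple[np.ndarray, np.ndarray]:
    """Polar (rate, phase) to Cartesian (x, y)."""
    r = np.asarray(r, dtype=float)
    theta = np.asarray(theta, dtype=float)
    return r * np.cos(theta), r * np.sin(theta)


def _polar_of(code: ThetaCode | ThetaCodeMatrix) -> ThetaCode:
    if isinstance(code, ThetaCode):
        return code
    v = code.values
    r = np.hypot(v[..., 0], v[..., 1])
    theta = np.arctan2(v[..., 1], v[..., 0]) % (2.0 * np.pi)
    has = r > 0
    return ThetaCode(r, np.where(has, theta, 0.0), has, has,
                     code.bin_width, dict(code.provenance))


def isolate(code: ThetaCode | ThetaCodeMatrix, mode: str) -> ThetaCodeMatrix:
    """Build the Cartesian matrix for mode 'full', 'rate' or 'phase'."""
    mode_map = {"full": "full", "rate": "rate_isolated", "phase": "phase_isolated",
                "rate_isolated": "rate_isolated", "phase_isolated": "phase_isolated"}
    if mode not in mode_map:
        raise ValueError(f"unknown mode {mode!r}")
    mode = mode_map[mode]
    c = _polar_of(code)
    if mode == "rate_isolated":
        r = np.where(c.has_spikes, c.rates, 0.0)
        theta = np.full_like(r, np.pi / 4.0)
        live = c.has_spikes
    elif mode == "phase_isolated":
        r = np.where(c.phase_defined, 1.0, 0.0)
        theta = c.phases
        live = c.phase_defined
    else:
        r = np.where(c.phase_defined, c.rates, 0.0)
        theta = c.phases
        live = c.phase_defined
    x, y = to_cartesian(r, theta)
    values = np.where(live[..., None], np.stack([x, y], axis=-1), 0.0)
    return ThetaCodeMatrix(values, c.bin_width, mode, dict(c.provenance))


def flatten(code: ThetaCodeMatrix) -> np.ndarray:
    """Fixed-order 1-D feature vector: bin-major, then cell, then coordinate."""
    return np.ascontiguousarray(code.values.transpose(1, 0, 2)).ravel()


def unflatten(vec: np.ndarray, n_cells: int, bin_width: float = 0.1,
              mode: str = "full") -> ThetaCodeMatrix:
    n_bins = vec.size // (n_cells * 2)
    values = vec.reshape(n_bins, n_cells, 2).transpose(1, 0, 2).copy()
    return ThetaCodeMatrix(values, bin_width, mode)
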