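"""Information and pattern-separation statistics.

Implements the quantities used to compare codes across pipeline stages:

* Pearson correlation between flattened Cartesian theta-codes of trajectory
  pairs, and the pattern-separation *area* between the input-output
  correlation curve and the unity line;
* Skaggs spatial information (bits/spike) from pooled spikes on the linear
  track:  I_s = sum_s p * (r_s/r) * log2(r_s/r)  with uniform occupancy p;
* Olypher positional information per position from discretized rate or
  phase values across trials:
  I_pos(x_i) = sum_k P(k|x_i) * log2(P(k|x_i)/P(k));
* population synchrony via the mean pairwise spike-count correlogram;
* the early-theta spike restriction used to probe recoding within ongoing
  activity.

Thin statistical wrappers (one-sample t, sign test, Holm-Sidak adjustment)
are provided for the seed-level comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .spiketrains import SpikeTrainSet

__all__ = [
    "pearson_pair", "SeparationCurve", "separation_area",
    "skaggs_information", "positional_information",
    "population_crosscorrelation", "early_theta_restriction",
    "one_sample_t", "sign_test", "holm_sidak",
]

MIN_SPIKES = 8   # per-cell pooled-spike inclusion threshold


# ---------------------------------------------------------------------------
# correlation / pattern separation
# ---------------------------------------------------------------------------

def pearson_pair(code_a: np.ndarray, code_b: np.ndarray) -> float:
    """Pearson R between two flattened code vectors."""
    a = np.asarray(code_a, dtype=float).ravel()
    b = np.asarray(code_b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("codes must have equal length")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("undefined correlation: zero variance input")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class SeparationCurve:
    """Input/output correlations per trajectory distance, per seed.

    ``r_in``/``r_out``: arrays of shape (n_seeds, n_distances).
    """

    distances: np.ndarray
    r_in: np.ndarray
    r_out: np.ndarray

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.r_in = np.atleast_2d(np.asarray(self.r_in, dtype=float))
        self.r_out = np.atleast_2d(np.asarray(self.r_out, dtype=float))


def separation_area(curve: SeparationCurve) -> np.ndarray:
    """Per-seed area between the correlation curve and the unity line.

    The area integrates (R_in - R_out) against the R_in axis (sorted
    ascending) per seed; positive values mean the output is decorrelated
    relative to the input.
    """
    if curve.r_in.shape[1] < 2:
        raise ValueError("need at least two trajectory distances")
    areas = np.empty(curve.r_in.shape[0])
    for i, (ri, ro) in enumerate(zip(curve.r_in, curve.r_out)):
        order = np.argsort(ri)
        areas[i] = np.trapezoid(ri[order] - ro[order], ri[order])
    return areas


# ---------------------------------------------------------------------------
# Skaggs spatial information
# ---------------------------------------------------------------------------

def skaggs_information(spike_positions: list[np.ndarray], path_length: float,
                       bin_size: float = 5.0,
                       min_spikes: int = MIN_SPIKES) -> pd.DataFrame:
    """Bits/spike per cell from pooled spike positions on the linear track.

    ``spike_positions``: per cell, positions (cm) of every pooled spike
    (across Poisson seeds).  Occupancy is uniform (constant speed), so the
    per-bin rate is proportional to the per-bin spike count.  Cells with
    fewer than ``min_spikes`` pooled spikes are flagged excluded, not
    dropped.
    """
    n_bins = int(round(path_length / bin_size))
    edges = np.linspace(0.0, path_length, n_bins + 1)
    rows = []
    for cell, pos in enumerate(spike_positions):
        pos = np.asarray(pos, dtype=float)
        n = pos.size
        if n < min_spikes:
            rows.append((cell, n, np.nan, False))
            continue
        counts, _ = np.histogram(pos, bins=edges)
        r_s = counts.astype(float)          # rate up to a common factor
        r = r_s.mean()
        nz = r_s > 0
        info = float(np.sum((1.0 / n_bins) * (r_s[nz] / r) * np.log2(r_s[nz] / r)))
        rows.append((cell, n, info, True))
    return pd.DataFrame(rows, columns=["cell", "n_spikes", "info", "included"])


def mean_skaggs(table: pd.DataFrame) -> float:
    """Population mean bits/spike over included cells."""
    inc = table.loc[table["included"], "info"]
    if inc.empty:
        raise ValueError("all cells excluded by the spike-count filter")
    return float(inc.mean())


# ---------------------------------------------------------------------------
# Olypher positional information
# ---------------------------------------------------------------------------

def _box_smooth(values: np.ndarray, width: int, circular_values: bool) -> np.ndarray:
    """Box filter across the position axis, NaN-aware; circular values are
    averaged via their resultant vector."""
    if width <= 1:
        return values
    n_pos = values.shape[0]
    out = np.full_like(values, np.nan)
    half = width // 2
    for i in range(n_pos):
        lo, hi = max(0, i - half), min(n_pos, i - half + width)
        win = values[lo:hi]
        if circular_values:
            with np.errstate(invalid="ignore"):
                s = np.nanmean(np.sin(win), axis=0)
                c = np.nanmean(np.cos(win), axis=0)
            out[i] = np.where(np.isnan(s), np.nan,
                              np.arctan2(s, c) % (2.0 * np.pi))
        else:
            with np.errstate(invalid="ignore"):
                out[i] = np.nanmean(win, axis=0)
    return out


def positional_information(values: np.ndarray, circular: bool = False,
                           n_value_bins: int = 7,
                           smoothing: int = 1,
                           mean_rate: float | None = None) -> dict:
    """Olypher positional information for one cell.

    ``values``: (n_positions, n_trials) rate or phase values; NaN marks
    trials without spikes at a position (ignored for the phase code).
    Values are box-smoothed over ``smoothing`` position bins, discretized
    into ``n_value_bins`` equal-width bins (over the observed range for
    rates, over [0, 2pi) for phases), and the per-position KL divergence of
    the conditional value distribution from the marginal is computed.

    Returns per-position information (bits), its mean over positions, and,
    if ``mean_rate`` is given, the per-spike normalization mean/mean_rate.
    """
    v = _box_smooth(np.asarray(values, dtype=float), smoothing, circular)
    finite = np.isfinite(v)
    if circular:
        edges = np.linspace(0.0, 2.0 * np.pi, n_value_bins + 1)
    else:
        lo = np.nanmin(v) if finite.any() else 0.0
        hi = np.nanmax(v) if finite.any() else 1.0
        if hi <= lo:
            hi = lo + 1.0
        edges = np.linspace(lo, hi, n_value_bins + 1)
    k = np.full(v.shape, -1, dtype=int)
    k[finite] = np.clip(np.digitize(v[finite], edges) - 1, 0, n_value_bins - 1)
    total = np.count_nonzero(finite)
    if total == 0:
        raise ValueError("no defined values")
    p_k = np.array([(k == kk).sum() for kk in range(n_value_bins)]) / total
    per_pos = np.full(v.shape[0], np.nan)
    for i in range(v.shape[0]):
        ki = k[i][k[i] >= 0]
        if ki.size == 0:
            continue       # position with no trials of data: skipped
        p_cond = np.bincount(ki, minlength=n_value_bins) / ki.size
        nz = p_cond > 0
        per_pos[i] = float(np.sum(p_cond[nz] * np.log2(p_cond[nz] / p_k[nz])))
    mean_info = float(np.nanmean(per_pos))
    out = {"per_position": per_pos, "mean": mean_info}
    if mean_rate is not None and mean_rate > 0:
        out["per_spike"] = mean_info / mean_rate
    return out


def positional_information_table(values_by_cell: list[np.ndarray],
                                 circular: bool = False,
                                 n_value_bins: int = 7,
                                 smoothing_scales=range(1, 21),
                                 mean_rates: np.ndarray | None = None) -> pd.DataFrame:
    """Population summary per smoothing scale (mean over positions, cells)."""
    rows = []
    for w in smoothing_scales:
        infos = []
        for c, vals in enumerate(values_by_cell):
            mr = None if mean_rates is None else float(mean_rates[c])
            try:
                res = positional_information(vals, circular, n_value_bins, w, mr)
            except ValueError:
                continue
            infos.append(res.get("per_spike", res["mean"]))
        rows.append((int(w), float(np.mean(infos)) if infos else np.nan,
                     len(infos)))
    return pd.DataFrame(rows, columns=["smoothing_bins", "info", "n_cells"])


# ---------------------------------------------------------------------------
# synchrony
# ---------------------------------------------------------------------------

def population_crosscorrelation(spikes: SpikeTrainSet, bin_size: float = 0.01,
                                max_lag: int = 5) -> dict:
    """Mean pairwise spike-count correlogram over active cells.

    Returns the mean Pearson correlation of binned counts at each lag (in
    bins) and the zero-lag coefficient as the synchrony index.
    """
    n_bins = int(round(spikes.duration / bin_size))
    counts = np.stack([np.histogram(t, bins=n_bins, range=(0.0, spikes.duration))[0]
                       for t in spikes.trains]).astype(float)
    active = counts.sum(axis=1) > 0
    if active.sum() < 2:
        raise ValueError("need at least two active cells")
    x = counts[active]
    x = x - x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1)
    lags = range(-max_lag, max_lag + 1)
    out = {}
    n = x.shape[0]
    for lag in lags:
        if lag >= 0:
            a, b = x[:, lag:], x[:, :x.shape[1] - lag]
        else:
            a, b = x[:, :x.shape[1] + lag], x[:, -lag:]
        cov = (a @ b.T) / x.shape[1]
        corr = cov / np.outer(sd, sd)
        mask = ~np.eye(n, dtype=bool)
        out[lag] = float(np.mean(corr[mask]))
    return {"lags": np.array(list(lags)), "correlogram": np.array([out[l] for l in lags]),
            "synchrony_index": out[0], "n_active": int(n)}


def early_theta_restriction(spikes: SpikeTrainSet, theta_freq: float,
                            half: tuple[float, float] = (0.0, np.pi)) -> SpikeTrainSet:
    """Keep only spikes whose theta phase lies in ``half`` (default [0, pi))."""
    lo, hi = half
    trains = []
    for t in spikes.trains:
        ph = 2.0 * np.pi * np.mod(t * theta_freq, 1.0)
        trains.append(t[(ph >= lo) & (ph < hi)])
    prov = dict(spikes.provenance)
    prov["theta_half"] = (float(lo), float(hi))
    return SpikeTrainSet(trains, spikes.duration, prov)


# ---------------------------------------------------------------------------
# statistics wrappers
# ---------------------------------------------------------------------------

def one_sample_t(x, popmean: float = 0.0) -> dict:
    """Two-tailed one-sample t test (seed-level comparisons)."""
    r = stats.ttest_1samp(np.asarray(x, dtype=float), popmean)
    return {"t": float(r.statistic), "p": float(r.pvalue),
            "mean": float(np.mean(x)), "sem": float(stats.sem(x))}


def sign_test(diffs) -> dict:
    """Exact two-tailed sign test on paired differences (zeros dropped)."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero")
    n_pos = int(np.sum(d > 0))
    r = stats.binomtest(n_pos, d.size, 0.5)
    return {"n_pos": n_pos, "n": d.size, "p": float(r.pvalue)}


def holm_sidak(pvalues) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = 1.0 - (1.0 - p[idx]) ** (m - rank)
        running = max(running, val)
        adj[idx] = min(running, 1.0)
    return adj
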