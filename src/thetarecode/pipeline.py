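"""Experiment orchestration: stage chaining, seed bookkeeping, summary tables.

Provides the standard protocols used throughout the analyses -- generating
EC populations and spike sets for trajectory pairs, driving the DG
surrogate under calibrated conditions, extracting theta codes, and
producing the figure-analogue result tables (separation curves, information
tables, decoder speeds, CA3 surfaces).  Every row carries its full
seed/condition provenance, and a run manifest records enough to reproduce
each number from seeds alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import gridcells as gcm
from . import dg as dgm
from .codes import flatten, isolate, theta_vectors
from .decoders import PerceptronConfig, perceptron_speed
from .info import (SeparationCurve, mean_skaggs, pearson_pair, separation_area,
                   skaggs_information)
from .spiketrains import SpikeTrainSet

__all__ = [
    "ExperimentConfig", "TRAJECTORY_DISTANCES", "ec_spike_set",
    "phase_shuffle_template", "ec_code_samples", "calibrated_dg",
    "pooled_gc_positions", "paired_info_drop", "ec_population_info",
    "rate_window_correlations", "separation_experiment", "separation_areas",
    "perceptron_ratio_at", "exclusion_rule", "run_experiment",
]

#: trajectory distances probed in the standard protocol (cm)
TRAJECTORY_DISTANCES = (0.5, 1, 1.5, 2, 2.5, 3, 4, 5, 6, 7, 8, 9, 10, 15, 45, 60)


@dataclass
class ExperimentConfig:
    grid_seeds: tuple[int, ...] = tuple(range(1, 11))
    n_poisson: int = 20
    distances: tuple[float, ...] = TRAJECTORY_DISTANCES
    conditions: tuple[str, ...] = ("full", "no_fb")
    shuffled: tuple[bool, ...] = (False, True)
    rate_controlled: bool = True
    scale_factor: float = gcm.DEFAULT_SCALE_FACTOR
    theta_freq: float = gcm.THETA_FREQ
    out_dir: str | None = None
    stages: tuple[str, ...] = ("separation", "information")


# ---------------------------------------------------------------------------
# stage helpers (the standard protocol, shared by CLI / tests / acceptance)
# ---------------------------------------------------------------------------

def _traj(distance: float) -> gcm.Trajectory:
    return gcm.Trajectory(lateral_offset=distance)


def ec_spike_set(grid_seed: int, poisson_seed: int, distance: float = 0.0,
                 scale_factor: float = gcm.DEFAULT_SCALE_FACTOR,
                 theta_freq: float = gcm.THETA_FREQ,
                 n_cells: int = 200) -> SpikeTrainSet:
    """Grid-cell spike trains for one trajectory and one Poisson draw."""
    pop = gcm.sample_grid_population(n_cells, grid_seed)
    prof = gcm.trajectory_rate_profiles(pop, _traj(distance), theta_freq,
                                        scale_factor)
    out = gcm.poisson_spikes(prof, poisson_seed)
    out.provenance.update(grid_seed=grid_seed, distance_cm=distance)
    return out


def phase_shuffle_template(grid_seed: int,
                           scale_factor: float = gcm.DEFAULT_SCALE_FACTOR,
                           theta_freq: float = gcm.THETA_FREQ,
                           n_cells: int = 200) -> gcm.PhaseTemplate:
    """Shuffle template: the emergent phase distribution of the same grid
    seed's non-shuffled EC spikes (reference trajectory, dedicated draw)."""
    ref = ec_spike_set(grid_seed, 987_000 + grid_seed, 0.0, scale_factor,
                       theta_freq, n_cells)
    return gcm.estimate_phase_template(ref, theta_freq)


def ec_code_samples(grid_seed: int, distance: float, n_poisson: int,
                    mode: str, shuffled: bool = False,
                    template: gcm.PhaseTemplate | None = None,
                    base_seed: int = 0,
                    scale_factor: float = gcm.DEFAULT_SCALE_FACTOR,
                    theta_freq: float = gcm.THETA_FREQ) -> np.ndarray:
    """(n_poisson, n_features) flattened Cartesian codes for one trajectory."""
    pop = gcm.sample_grid_population(200, grid_seed)
    prof = gcm.trajectory_rate_profiles(pop, _traj(distance), theta_freq,
                                        scale_factor)
    if shuffled and template is None:
        template = phase_shuffle_template(grid_seed, scale_factor, theta_freq)
    rows = []
    for ps in range(n_poisson):
        st = gcm.poisson_spikes(prof, base_seed + ps)
        if shuffled:
            st = gcm.shuffle_phases(st, template, theta_freq,
                                    shuffle_seed=base_seed + 70_000 + ps)
        rows.append(flatten(isolate(theta_vectors(st, theta_freq), mode)))
    return np.stack(rows)


def calibrated_dg(grid_seed: int, condition: str,
                  ec_reference: SpikeTrainSet | None = None,
                  rate_band: tuple[float, float] = dgm.RATE_BAND,
                  **config_overrides) -> dgm.DGNetwork:
    """Build + rate-calibrate the DG surrogate for one condition."""
    cfg = dgm.DGConfig(condition=condition, connectivity_seed=grid_seed,
                       **config_overrides)
    net = dgm.build_dg(cfg)
    if ec_reference is None:
        ec_reference = ec_spike_set(grid_seed, 0)
    w = dgm.calibrate_pp_weight(net, ec_reference, rate_band)
    return net.with_config(pp_weight=w)


def pooled_gc_positions(net: dgm.DGNetwork, grid_seed: int, n_poisson: int,
                        distance: float = 0.0, shuffled: bool = False,
                        template: gcm.PhaseTemplate | None = None,
                        base_seed: int = 0, speed: float = 20.0) -> list[np.ndarray]:
    """Per-GC spike positions (cm) pooled over Poisson seeds."""
    if shuffled and template is None:
        template = phase_shuffle_template(grid_seed)
    pos: list[list[np.ndarray]] = [[] for _ in range(net.config.n_gc)]
    for ps in range(n_poisson):
        ec = ec_spike_set(grid_seed, base_seed + ps, distance)
        if shuffled:
            ec = gcm.shuffle_phases(ec, template,
                                    shuffle_seed=base_seed + 70_000 + ps)
        out = dgm.run_dg(net, ec, sim_seed=base_seed + ps)
        for c, t in enumerate(out.trains):
            pos[c].append(speed * t)
    return [np.concatenate(p) if p else np.empty(0) for p in pos]


def paired_info_drop(net: dgm.DGNetwork, grid_seed: int,
                     n_poisson: int = 20, base_seed: int = 0) -> float:
    """Shuffle-induced loss of GC spatial information (bits/spike).

    Mean over the paired per-cell differences, cells passing the 8-spike
    filter in both the shuffled and the non-shuffled data.
    """
    tpl = phase_shuffle_template(grid_seed)
    t_ns = skaggs_information(
        pooled_gc_positions(net, grid_seed, n_poisson, base_seed=base_seed), 40.0)
    t_sh = skaggs_information(
        pooled_gc_positions(net, grid_seed, n_poisson, shuffled=True,
                            template=tpl, base_seed=base_seed), 40.0)
    both = (t_ns["included"] & t_sh["included"]).to_numpy()
    if not both.any():
        raise ValueError("no cells pass the spike filter in both conditions")
    return float((t_ns.loc[both, "info"] - t_sh.loc[both, "info"]).mean())


def ec_population_info(grid_seed: int, n_poisson: int = 20,
                       shuffled: bool = False, base_seed: int = 0,
                       speed: float = 20.0,
                       scale_factor: float = gcm.DEFAULT_SCALE_FACTOR) -> float:
    """Mean EC Skaggs information (bits/spike): spikes pooled over
    ``n_poisson`` Poisson seeds, 5 cm bins, 8-spike filter."""
    pop = gcm.sample_grid_population(200, grid_seed)
    prof = gcm.trajectory_rate_profiles(pop, _traj(0.0),
                                        scale_factor=scale_factor)
    tpl = (phase_shuffle_template(grid_seed, scale_factor)
           if shuffled else None)
    pos: list[list[np.ndarray]] = [[] for _ in range(200)]
    for ps in range(n_poisson):
        st = gcm.poisson_spikes(prof, base_seed + ps)
        if shuffled:
            st = gcm.shuffle_phases(st, tpl, shuffle_seed=base_seed + 70_000 + ps)
        for c, t in enumerate(st.trains):
            pos[c].append(speed * t)
    table = skaggs_information(
        [np.concatenate(p) for p in pos], speed * 2.0)
    return mean_skaggs(table)


def rate_window_correlations(grid_seed: int, n_pairs: int = 10,
                             base_seed: int = 0) -> dict:
    """Pearson R between rate codes of identical-profile spike-train pairs
    (same grid seed, different Poisson seeds), at 100 ms theta windows and
    at one 2 s window -- the time-window artifact on rate correlations."""
    pop = gcm.sample_grid_population(200, grid_seed)
    prof = gcm.trajectory_rate_profiles(pop, _traj(0.0))
    r100, r2s = [], []
    for k in range(n_pairs):
        a = gcm.poisson_spikes(prof, base_seed + 2 * k)
        b = gcm.poisson_spikes(prof, base_seed + 2 * k + 1)
        ca = np.stack([np.histogram(t, bins=20, range=(0, 2))[0]
                       for t in a.trains]).ravel()
        cb = np.stack([np.histogram(t, bins=20, range=(0, 2))[0]
                       for t in b.trains]).ravel()
        r100.append(pearson_pair(ca, cb))
        r2s.append(pearson_pair(a.counts(), b.counts()))
    return {"r_100ms": float(np.mean(r100)), "r_2s": float(np.mean(r2s)),
            "n_pairs": n_pairs}


# ---------------------------------------------------------------------------
# figure-analogue experiments
# ---------------------------------------------------------------------------

def separation_experiment(grid_seeds, distances, mode: str = "rate",
                          n_poisson: int = 5, condition: str = "full",
                          rate_band=dgm.RATE_BAND,
                          theta_freq: float = gcm.THETA_FREQ) -> pd.DataFrame:
    """Input-output correlation curve: R_in (EC) vs R_out (GC) per distance.

    Correlations are averaged over Poisson-seed pairs of the compared
    trajectories; returns one row per (grid_seed, distance).
    """
    rows = []
    for gs in grid_seeds:
        ec_ref = ec_spike_set(gs, 0)
        net = calibrated_dg(gs, condition, ec_ref, rate_band)
        for d in distances:
            r_in, r_out = [], []
            for ps in range(n_poisson):
                ec_a = ec_spike_set(gs, 1000 + ps, 0.0)
                ec_b = ec_spike_set(gs, 2000 + ps, d)
                code = lambda st: flatten(isolate(theta_vectors(st, theta_freq), mode))
                r_in.append(pearson_pair(code(ec_a), code(ec_b)))
                gc_a = dgm.run_dg(net, ec_a, sim_seed=1000 + ps)
                gc_b = dgm.run_dg(net, ec_b, sim_seed=2000 + ps)
                r_out.append(pearson_pair(code(gc_a), code(gc_b)))
            rows.append({"grid_seed": gs, "distance_cm": d, "mode": mode,
                         "condition": condition,
                         "r_in": float(np.mean(r_in)),
                         "r_out": float(np.mean(r_out))})
    return pd.DataFrame(rows)


def separation_areas(df: pd.DataFrame) -> np.ndarray:
    """Per-grid-seed pattern-separation areas from a separation table."""
    seeds = sorted(df["grid_seed"].unique())
    r_in = np.stack([df.loc[df.grid_seed == gs].sort_values("distance_cm")["r_in"]
                     .to_numpy() for gs in seeds])
    r_out = np.stack([df.loc[df.grid_seed == gs].sort_values("distance_cm")["r_out"]
                      .to_numpy() for gs in seeds])
    return separation_area(SeparationCurve(
        df["distance_cm"].unique(), r_in, r_out))


def perceptron_ratio_at(grid_seed: int, distance: float = 15.0,
                        mode: str = "phase", n_poisson: int = 20,
                        learning_rate: float = 1e-3) -> dict:
    """Non-shuffled / shuffled perceptron learning-speed ratio for EC codes."""
    tpl = phase_shuffle_template(grid_seed)
    speeds = {}
    for shuffled in (False, True):
        a = ec_code_samples(grid_seed, 0.0, n_poisson, mode, shuffled, tpl,
                            base_seed=10_000 * grid_seed)
        b = ec_code_samples(grid_seed, distance, n_poisson, mode, shuffled, tpl,
                            base_seed=10_000 * grid_seed + 500)
        res = perceptron_speed(a, b, PerceptronConfig(
            learning_rate=learning_rate, seed=grid_seed))
        speeds[shuffled] = res
    return {"grid_seed": grid_seed, "distance_cm": distance, "mode": mode,
            "speed_nonshuffled": speeds[False].speed,
            "speed_shuffled": speeds[True].speed,
            "n_e_nonshuffled": speeds[False].n_epochs,
            "n_e_shuffled": speeds[True].n_epochs,
            "ratio": speeds[False].speed / speeds[True].speed}


# ---------------------------------------------------------------------------
# bookkeeping
# ---------------------------------------------------------------------------

def exclusion_rule(rows: pd.DataFrame,
                   rate_band: tuple[float, float] = dgm.RATE_BAND,
                   rate_column: str = "gc_rate") -> pd.DataFrame:
    """Flag (never delete) rows whose GC rate leaves the permissible band."""
    out = rows.copy()
    lo, hi = rate_band
    in_band = out[rate_column].between(lo, hi)
    out["excluded"] = ~in_band
    out["exclusion_reason"] = np.where(
        in_band, "", f"gc_rate outside [{lo}, {hi}] Hz")
    return out


def run_experiment(config: ExperimentConfig) -> dict[str, pd.DataFrame]:
    """Execute the requested stages; write CSVs + manifest if out_dir set."""
    tables: dict[str, pd.DataFrame] = {}
    if "separation" in config.stages:
        frames = []
        for mode in ("rate", "phase"):
            frames.append(separation_experiment(
                config.grid_seeds, config.distances, mode,
                n_poisson=min(config.n_poisson, 5)))
        tables["separation"] = pd.concat(frames, ignore_index=True)
    if "information" in config.stages:
        rows = []
        for gs in config.grid_seeds:
            ec_ref = ec_spike_set(gs, 0)
            for cond in config.conditions:
                net = calibrated_dg(gs, cond, ec_ref)
                rate = dgm.run_dg(net, ec_ref, sim_seed=0).mean_rate()
                drop = paired_info_drop(net, gs, config.n_poisson,
                                        base_seed=1000 * gs)
                rows.append({"grid_seed": gs, "condition": cond,
                             "gc_rate": rate, "info_drop": drop})
        tables["information"] = exclusion_rule(pd.DataFrame(rows))
    if "perceptron" in config.stages:
        rows = [perceptron_ratio_at(gs, n_poisson=config.n_poisson)
                for gs in config.grid_seeds]
        tables["perceptron"] = pd.DataFrame(rows)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        manifest = {
            "grid_seeds": list(config.grid_seeds),
            "n_poisson": config.n_poisson,
            "distances": list(config.distances),
            "conditions": list(config.conditions),
            "scale_factor": config.scale_factor,
            "stages": list(config.stages),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return tables
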