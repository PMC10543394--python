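"""Phase-precessing entorhinal grid-cell simulator.

Synthetic-data stage of the pipeline.  A population of medial-entorhinal
grid cells is modelled as the sum of three sinusoidal gratings whose
wavevectors are separated by 60 deg (Solstad-style firing function).  Theta
phase precession is added by mapping the animal's linear distance to the
nearest grid vertex onto a preferred theta phase, which modulates an
inhomogeneous Poisson process through a von-Mises-shaped phase kernel::

    g_w(x, y) = 2/3 (1/3 sum_i cos(k_i . (l - l0)) + 1/2)        # grid field
    d(x, y)   = arccos(3/2 g_w/g_max - 1/2) * lambda*sqrt(6)/(4 pi)
    phi(t)    = k1 * pi * (d(t)/lambda + 0.5)                     # k1 = 1
    r_phi(t)  = exp(k2 * cos(theta(t) - phi(t)))                  # k2 = 1.5
    rate(t)   = scale * r_phi(t) * g_w(l(t))

with theta(t) = 2*pi*frac(f_theta * t), f_theta = 10 Hz, so theta cycles
are the 100 ms bins [0, 0.1), [0.1, 0.2), ...  The signed distance flips to
-d while the animal is leaving a field, which makes the preferred phase
precess monotonically from late to early theta across each field traversal.

Also provided: the per-cell, per-theta-cycle phase shuffle that destroys
spatial phase information while conserving spike counts and the population
theta-phase histogram, and counter-cyclically theta-modulated lateral-EC
(LEC) input trains.
"""

from __future__ import annotations


from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import brentq
from scipy.stats import skewnorm

from .spiketrains import SpikeTrainSet

__all__ = [
    "THETA_FREQ", "K1", "K2", "DEFAULT_SCALE_FACTOR",
    "GridCellPopulation", "Trajectory", "RateProfile", "PhaseTemplate",
    "sample_grid_population", "sample_spacings", "grid_rate",
    "linear_distance", "preferred_phase", "phase_modulation", "theta_phase",
    "trajectory_rate_profiles", "poisson_spikes", "estimate_phase_template",
    "shuffle_phases", "make_lec_inputs",
]

THETA_FREQ = 10.0     #: Hz, idealized constant theta clock
K1 = 1.0              #: phase-precession slope constant
K2 = 1.5              #: theta phase-tuning concentration
DEFAULT_SCALE_FACTOR = 20.0
"""Rate scale (Hz) multiplying the dimensionless grid x phase profile.

Calibrated so that in-field peak instantaneous rates are of order tens of
Hz (20 * e^1.5 ~ 90 Hz) and the population Skaggs information of the
non-shuffled EC code is ~0.32 bits/spike at the standard trajectory; see
docs/methods.md.
"""

SPACING_RANGE = (15.0, 120.0)   # cm
SPACING_MEDIAN = 43.0           # cm
_SPACING_LOC = 15.0             # cm, skew-normal location (support onset)
_SPACING_SCALE = 40.0           # cm, skew-normal scale


def theta_phase(t, theta_freq: float = THETA_FREQ):
    """Theta phase in [0, 2pi), phase 0 at the start of each cycle."""
    return 2.0 * np.pi * np.mod(np.asarray(t, dtype=float) * theta_freq, 1.0)


# ---------------------------------------------------------------------------
# population sampling
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def _spacing_shape() -> float:
    """Skewness of the spacing distribution, solved so the truncated
    skew-normal on [15, 120] cm has median 43 cm (only the support and the
    median are empirically constrained; the fit is done here, at runtime)."""
    lo, hi = SPACING_RANGE

    def trunc_median(a: float) -> float:
        d = skewnorm(a, loc=_SPACING_LOC, scale=_SPACING_SCALE)
        q = 0.5 * (d.cdf(lo) + d.cdf(hi))
        return float(d.ppf(q))

    # on [2, 30] the truncated median decreases monotonically through 43 cm
    return float(brentq(lambda a: trunc_median(a) - SPACING_MEDIAN, 2.0, 30.0))


def sample_spacings(n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw grid spacings (cm) from the truncated skew-normal law."""
    a = _spacing_shape()
    d = skewnorm(a, loc=_SPACING_LOC, scale=_SPACING_SCALE)
    lo, hi = d.cdf(SPACING_RANGE[0]), d.cdf(SPACING_RANGE[1])
    u = rng.uniform(lo, hi, size=n)
    return np.clip(d.ppf(u), *SPACING_RANGE)


@dataclass
class GridCellPopulation:
    """Per-cell grid parameters and derived wavevectors.

    ``wavevectors[i, j]`` is the j-th (of three) wavevector of cell i, with
    magnitude 4*pi/(sqrt(3)*lambda) and directions at the cell orientation
    plus -30, +30, +90 deg (60 deg angular separations).
    """

    spacings: np.ndarray        # cm
    orientations: np.ndarray    # deg, in [0, 60)
    offsets: np.ndarray         # (n, 2) cm, in [0, 100)^2
    grid_seed: int
    wavevectors: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ang = np.deg2rad(self.orientations[:, None] + np.array([-30.0, 30.0, 90.0]))
        mag = 4.0 * np.pi / (np.sqrt(3.0) * self.spacings)[:, None]
        self.wavevectors = np.stack(
            [mag * np.cos(ang), mag * np.sin(ang)], axis=-1
        )  # (n, 3, 2)

    @property
    def n_cells(self) -> int:
        return len(self.spacings)


def sample_grid_population(n_cells: int, grid_seed: int) -> GridCellPopulation:
    """Sample a grid-cell population from the empirical parameter laws."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(grid_seed)
    spacings = sample_spacings(n_cells, rng)
    orientations = rng.uniform(0.0, 60.0, size=n_cells)
    offsets = rng.uniform(0.0, 100.0, size=(n_cells, 2))
    return GridCellPopulation(spacings, orientations, offsets, grid_seed)


# ---------------------------------------------------------------------------
# firing-field geometry
# ---------------------------------------------------------------------------

def grid_rate(pop: GridCellPopulation, cell: int, l) -> np.ndarray | float:
    """Dimensionless grid firing weight g_w at position(s) ``l`` (cm).

    Maximum 1 at the lattice vertices, minimum 0.
    """
    l = np.asarray(l, dtype=float)
    scalar = l.ndim == 1
    pts = np.atleast_2d(l) - pop.offsets[cell]
    phases = pts @ pop.wavevectors[cell].T        # (m, 3)
    g = (2.0 / 3.0) * (np.cos(phases).mean(axis=1) + 0.5)
    return float(g[0]) if scalar else g


def linear_distance(pop: GridCellPopulation, cell: int, l,
                    g_max: float = 1.0) -> np.ndarray | float:
    """Linear distance (cm) to the nearest grid vertex, from g_w.

    Inverts the radial profile of the firing function; zero exactly at
    vertices, maximal (lambda*sqrt(6)/6) at the field troughs.
    """
    g = np.asarray(grid_rate(pop, cell, l), dtype=float)
    arg = 1.5 * g / g_max - 0.5
    if np.any(arg > 1.0 + 1e-9) or np.any(arg < -1.0 - 1e-9):
        raise FloatingPointError("arccos argument outside [-1, 1] beyond tolerance")
    d = np.arccos(np.clip(arg, -1.0, 1.0)) * pop.spacings[cell] * np.sqrt(6.0) / (4.0 * np.pi)
    return float(d) if d.ndim == 0 else d


def preferred_phase(d_signed, lam: float, k1: float = K1):
    """Preferred theta phase (rad) from signed vertex distance (cm)."""
    if lam <= 0:
        raise ValueError("spacing lambda must be positive")
    return k1 * np.pi * (np.asarray(d_signed, dtype=float) / lam + 0.5)


def phase_modulation(t, phi, theta_freq: float = THETA_FREQ, k2: float = K2):
    """Dimensionless phase-tuning weight exp(k2 * cos(theta(t) - phi))."""
    return np.exp(k2 * np.cos(theta_phase(t, theta_freq) - np.asarray(phi)))


# ---------------------------------------------------------------------------
# trajectories and rate profiles
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Straight constant-speed path; heading is +x, lateral offset is +y."""

    start: tuple[float, float] = (0.0, 50.0)   # cm
    speed: float = 20.0                        # cm/s
    duration: float = 2.0                      # s
    lateral_offset: float = 0.0                # cm

    def positions(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        x = self.start[0] + self.speed * t
        y = np.full_like(x, self.start[1] + self.lateral_offset)
        return np.stack([x, y], axis=-1)

    def path_positions_1d(self, t) -> np.ndarray:
        """Distance travelled along the path (cm)."""
        return self.speed * np.asarray(t, dtype=float)


@dataclass
class RateProfile:
    """Per-cell instantaneous firing rates (Hz) on a regular time grid."""

    rates: np.ndarray            # (n_cells, n_t)
    dt: float                    # s
    theta_freq: float
    scale_factor: float
    trajectory: Trajectory | None = None

    def __post_init__(self) -> None:
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.rates.shape[0]

    @property
    def duration(self) -> float:
        return self.rates.shape[1] * self.dt

    @property
    def t(self) -> np.ndarray:
        return (np.arange(self.rates.shape[1]) + 0.5) * self.dt

    def expected_counts(self) -> np.ndarray:
        return self.rates.sum(axis=1) * self.dt


def trajectory_rate_profiles(pop: GridCellPopulation, traj: Trajectory,
                             theta_freq: float = THETA_FREQ,
                             scale_factor: float = DEFAULT_SCALE_FACTOR,
                             dt: float = 1e-3) -> RateProfile:
    """Phase-precessing rate profiles for every cell along a trajectory.

    Leaving-field detection: the signed distance flips to -d where the
    discrete central-difference derivative of d(t) is positive; ties
    (zero derivative) count as entering.
    """
    if dt > 1e-3 + 1e-12:
        raise ValueError("dt must be <= 1 ms for phase resolution")
    n_t = int(round(traj.duration / dt))
    t = (np.arange(n_t) + 0.5) * dt
    pos = traj.positions(t)
    theta = theta_phase(t, theta_freq)
    rates = np.empty((pop.n_cells, n_t))
    for c in range(pop.n_cells):
        g = grid_rate(pop, c, pos)
        d = linear_distance(pop, c, pos)
        dd = np.gradient(d)
        d_signed = np.where(dd > 0, -d, d)
        phi = preferred_phase(d_signed, pop.spacings[c])
        rates[c] = scale_factor * np.exp(K2 * np.cos(theta - phi)) * g
    return RateProfile(rates, dt, theta_freq, scale_factor, traj)


# ---------------------------------------------------------------------------
# spiking
# ---------------------------------------------------------------------------

def poisson_spikes(profile: RateProfile, poisson_seed: int,
                   stage: str = "EC") -> SpikeTrainSet:
    """Inhomogeneous Poisson spike trains by thinning a homogeneous process."""
    rng = np.random.default_rng(poisson_seed)
    T = profile.duration
    trains = []
    for c in range(profile.n_cells):
        r = profile.rates[c]
        rmax = float(r.max())
        if rmax <= 0:
            trains.append(np.empty(0))
            continue
        n_cand = rng.poisson(rmax * T)
        t_cand = np.sort(rng.uniform(0.0, T, size=n_cand))
        idx = np.minimum((t_cand / profile.dt).astype(int), r.size - 1)
        keep = rng.uniform(0.0, rmax, size=n_cand) < r[idx]
        trains.append(np.unique(t_cand[keep]))
    prov = {"stage": stage, "poisson_seed": poisson_seed, "shuffled": False,
            "scale_factor": profile.scale_factor}
    return SpikeTrainSet(trains, T, prov)


@dataclass
class PhaseTemplate:
    """Binned probability mass over theta phase [0, 2pi)."""

    mass: np.ndarray
    bin_width: float = field(init=False)

    def __post_init__(self) -> None:
        self.mass = np.asarray(self.mass, dtype=float)
        if np.any(self.mass < 0):
            raise ValueError("template mass must be non-negative")
        tot = self.mass.sum()
        self.mass = (self.mass / tot if tot > 0
                     else np.full_like(self.mass, 1.0 / self.mass.size))
        self.bin_width = 2.0 * np.pi / self.mass.size

    def sample_phases(self, n: int, rng: np.random.Generator) -> np.ndarray:
        bins = rng.choice(self.mass.size, size=n, p=self.mass)
        return (bins + rng.uniform(0.0, 1.0, size=n)) * self.bin_width


def estimate_phase_template(spikes: SpikeTrainSet,
                            theta_freq: float = THETA_FREQ,
                            n_bins: int = 100) -> PhaseTemplate:
    """Pooled theta-phase histogram of a spike set (the emergent phase
    distribution used as the shuffle template)."""
    phases = np.concatenate(spikes.phases(theta_freq)) if spikes.n_spikes else np.empty(0)
    hist, _ = np.histogram(phases, bins=n_bins, range=(0.0, 2.0 * np.pi))
    return PhaseTemplate(hist.astype(float))


def shuffle_phases(spikes: SpikeTrainSet, template: PhaseTemplate,
                   theta_freq: float = THETA_FREQ,
                   shuffle_seed: int = 0) -> SpikeTrainSet:
    """Redraw spike times within each (cell, theta cycle) from the template.

    Conserves exactly which cells fire how many spikes in which theta
    cycles, and (in aggregate) the population theta-phase histogram, while
    destroying all spatial phase information.
    """
    rng = np.random.default_rng(shuffle_seed)
    cycle_len = 1.0 / theta_freq
    n_cycles = spikes.n_cycles(theta_freq)
    trains = []
    for t in spikes.trains:
        cyc = np.minimum(np.floor(t * theta_freq).astype(int), n_cycles - 1)
        new_t = np.empty_like(t)
        pos = 0
        for c in np.unique(cyc):
            n = int(np.sum(cyc == c))
            ph = template.sample_phases(n, rng)
            new_t[pos:pos + n] = (c + ph / (2.0 * np.pi)) * cycle_len
            pos += n
        new_t = np.unique(np.clip(new_t, 0.0, spikes.duration))
        while new_t.size < t.size:   # measure-zero collision guard
            extra = template.sample_phases(t.size - new_t.size, rng)
            cyc_fill = rng.choice(cyc, size=extra.size)
            new_t = np.unique(np.concatenate(
                [new_t, (cyc_fill + extra / (2.0 * np.pi)) * cycle_len]))
        trains.append(np.sort(new_t))
    prov = dict(spikes.provenance)
    prov.update(shuffled=True, shuffle_seed=shuffle_seed)
    return SpikeTrainSet(trains, spikes.duration, prov)


# ---------------------------------------------------------------------------
# LEC inputs
# ---------------------------------------------------------------------------

def lec_rate_envelope(t, theta_freq: float = THETA_FREQ,
                      peak_rate: float = 30.0,
                      ec_peak_phase: float = np.pi / 2) -> np.ndarray:
    """Smoothed-sawtooth rate envelope (0..peak_rate Hz), theta-modulated
    counter-cyclically to the grid-cell phase tuning (peak offset by pi
    from ``ec_peak_phase``)."""
    t = np.asarray(t, dtype=float)
    n_per_cycle = 512
    phase_grid = np.linspace(0.0, 2.0 * np.pi, n_per_cycle, endpoint=False)
    saw = np.mod(phase_grid, 2.0 * np.pi) / (2.0 * np.pi)        # rising 0..1
    smooth = gaussian_filter1d(saw, sigma=n_per_cycle / 16, mode="wrap")
    smooth = (smooth - smooth.min()) / (smooth.max() - smooth.min())
    # sawtooth peaks just before phase 0; roll so the peak sits at
    # ec_peak_phase + pi (counter-cyclical to the EC modulation)
    peak_idx = int(np.argmax(smooth))
    target_idx = int(round((ec_peak_phase + np.pi) / (2.0 * np.pi) * n_per_cycle)) % n_per_cycle
    smooth = np.roll(smooth, target_idx - peak_idx)
    idx = (np.mod(t * theta_freq, 1.0) * n_per_cycle).astype(int) % n_per_cycle
    return peak_rate * smooth[idx]


def make_lec_inputs(n_cells: int = 20, duration: float = 2.0,
                    theta_freq: float = THETA_FREQ, mode: str = "similar",
                    fanout_per_cell: int = 100, poisson_seed: int = 0,
                    context_id: int = 0, dt: float = 1e-3) -> SpikeTrainSet:
    """Counter-cyclically theta-modulated LEC spike trains.

    ``mode='identical'`` reuses one seed regardless of ``context_id`` (the
    same contextual spike patterns repeat across trajectories);
    ``mode='similar'`` redraws per context.
    """
    if mode not in ("similar", "identical"):
        raise ValueError("mode must be 'similar' or 'identical'")
    seed = poisson_seed if mode == "identical" else poisson_seed + 100003 * (context_id + 1)
    n_t = int(round(duration / dt))
    t = (np.arange(n_t) + 0.5) * dt
    env = lec_rate_envelope(t, theta_freq)
    rates = np.tile(env, (n_cells, 1))
    profile = RateProfile(rates, dt, theta_freq, scale_factor=1.0)
    out = poisson_spikes(profile, seed, stage="LEC")
    out.provenance.update(mode=mode, fanout_per_cell=fanout_per_cell,
                          context_id=context_id)
    return out
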