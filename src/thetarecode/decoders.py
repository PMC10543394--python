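"""Decodability metrics: perceptron and tempotron learning speed.

The perceptron quantifies how separable two trajectory codes are in the
flattened Cartesian theta-code space: two sigmoid output units are trained
by per-sample stochastic gradient descent on squared error to emit [1, 0]
for one trajectory and [0, 1] for the other; learning speed is 1/N_E where
N_E is the first epoch at which the root-mean-square error over all 40
training vectors drops below 0.2.

The tempotron quantifies the decodability of raw spike trains: a single
LIF readout receives all afferents through a double-exponential kernel
(tau = 10 ms, tau_s = 2 ms, unit peak) and classifies a pattern by whether
its peak potential exceeds a threshold.  The threshold is fixed per grid
seed as the mean of per-pattern potential maxima before training.  The
gradient rule adjusts afferent weights at the time of the potential
maximum for misclassified patterns.  Learning speed is 1/tau_decay of an
exponential fit to the per-epoch loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .spiketrains import SpikeTrainSet

__all__ = [
    "PerceptronConfig", "TempotronConfig", "perceptron_speed",
    "shuffle_ratio", "tempotron_kernel", "tempotron_kernel_peak_time",
    "Tempotron", "tempotron_speed", "fit_loss_decay",
]


# ---------------------------------------------------------------------------
# perceptron
# ---------------------------------------------------------------------------

@dataclass
class PerceptronConfig:
    learning_rate: float = 1e-3    # 1e-3 for 200-cell inputs, 1e-4 for 2000
    max_epochs: int = 10000
    loss_threshold: float = 0.2    # on the RMSE scale
    seed: int = 0


@dataclass
class PerceptronResult:
    speed: float
    n_epochs: int
    converged: bool
    final_loss: float


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def perceptron_speed(samples_a: np.ndarray, samples_b: np.ndarray,
                     cfg: PerceptronConfig | None = None) -> PerceptronResult:
    """Train the 2-unit sigmoid readout; return learning speed 1/N_E.

    ``samples_a``/``samples_b``: (n_samples, n_features) flattened codes for
    the two trajectories.  Weights and biases start at zero; sample order is
    reshuffled every epoch with a seeded generator.
    """
    cfg = cfg or PerceptronConfig()
    X = np.vstack([samples_a, samples_b]).astype(float)
    n_a = len(samples_a)
    T = np.zeros((len(X), 2))
    T[:n_a, 0] = 1.0
    T[n_a:, 1] = 1.0
    rng = np.random.default_rng(cfg.seed)
    W = np.zeros((2, X.shape[1]))
    b = np.zeros(2)
    n_e = cfg.max_epochs
    converged = False
    loss = np.inf
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(X))
        for i in order:
            y = _sigmoid(W @ X[i] + b)
            g = (y - T[i]) * y * (1.0 - y)      # d(squared error)/dz
            W -= cfg.learning_rate * np.outer(g, X[i])
            b -= cfg.learning_rate * g
        Y = _sigmoid(X @ W.T + b)
        loss = float(np.sqrt(np.mean((Y - T) ** 2)))
        if not np.isfinite(loss):
            raise FloatingPointError("perceptron training diverged")
        if loss < cfg.loss_threshold:
            n_e = epoch
            converged = True
            break
    return PerceptronResult(1.0 / n_e, n_e, converged, loss)


def shuffle_ratio(speeds_nonshuffled, speeds_shuffled) -> np.ndarray:
    """Per-seed ratio non-shuffled / shuffled; zero denominators excluded."""
    a = np.asarray(speeds_nonshuffled, dtype=float)
    b = np.asarray(speeds_shuffled, dtype=float)
    if a.shape != b.shape:
        raise ValueError("speed vectors must be matched per seed")
    ok = b != 0
    return a[ok] / b[ok]


# ---------------------------------------------------------------------------
# tempotron
# ---------------------------------------------------------------------------

@dataclass
class TempotronConfig:
    tau: float = 10.0         # ms, membrane kernel
    tau_s: float = 2.0        # ms, synaptic kernel
    learning_rate: float = 1e-3
    epochs: int = 200
    v_rest: float = 0.0       # mV
    dt: float = 1.0           # ms, evaluation grid
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tau > self.tau_s > 0:
            raise ValueError("require tau > tau_s > 0")


def tempotron_kernel_peak_time(tau: float = 10.0, tau_s: float = 2.0) -> float:
    """Peak time of the double-exponential kernel: tau*tau_s/(tau-tau_s)*ln(tau/tau_s)."""
    return tau * tau_s / (tau - tau_s) * np.log(tau / tau_s)


def tempotron_kernel(t, tau: float = 10.0, tau_s: float = 2.0):
    """Unit-peak kernel V0*(exp(-t/tau) - exp(-t/tau_s)) for t >= 0 (ms)."""
    t = np.asarray(t, dtype=float)
    t_star = tempotron_kernel_peak_time(tau, tau_s)
    v0 = 1.0 / (np.exp(-t_star / tau) - np.exp(-t_star / tau_s))
    out = v0 * (np.exp(-t / tau) - np.exp(-t / tau_s))
    return np.where(t >= 0, out, 0.0)


class Tempotron:
    """Single-neuron LIF readout over spike-train patterns."""

    def __init__(self, n_afferents: int, cfg: TempotronConfig | None = None):
        self.cfg = cfg or TempotronConfig()
        rng = np.random.default_rng(self.cfg.seed)
        self.weights = rng.uniform(-1e-3, 1e-3, size=n_afferents)
        self.n_afferents = n_afferents
        t_star = tempotron_kernel_peak_time(self.cfg.tau, self.cfg.tau_s)
        self._v0 = 1.0 / (np.exp(-t_star / self.cfg.tau)
                          - np.exp(-t_star / self.cfg.tau_s))

    # -- pattern preparation ------------------------------------------------
    def _prepare(self, spikes: SpikeTrainSet):
        """Afferent index / spike-time(ms) arrays and the time grid length."""
        aff = np.concatenate([np.full(t.size, i)
                              for i, t in enumerate(spikes.trains)]) \
            if spikes.n_spikes else np.empty(0, dtype=int)
        times = spikes.pooled() * 1e3     # ms
        n_t = int(round(spikes.duration * 1e3 / self.cfg.dt)) + 1
        return aff.astype(int), times, n_t

    def _voltage(self, aff, times, n_t):
        """V(t) on the grid via two exponential traces of the weighted
        impulse train (exact between-bin decay, spikes binned to dt)."""
        dt, tau, tau_s = self.cfg.dt, self.cfg.tau, self.cfg.tau_s
        imp = np.zeros(n_t)
        idx = np.minimum((times / dt).astype(int), n_t - 1)
        np.add.at(imp, idx, self.weights[aff])
        da, db = np.exp(-dt / tau), np.exp(-dt / tau_s)
        from scipy.signal import lfilter
        a_tr = lfilter([1.0], [1.0, -da], imp)
        b_tr = lfilter([1.0], [1.0, -db], imp)
        return self.cfg.v_rest + self._v0 * (a_tr - b_tr)

    def max_output(self, spikes: SpikeTrainSet) -> tuple[float, float]:
        """(max potential, time of max in ms) for one pattern."""
        aff, times, n_t = self._prepare(spikes)
        v = self._voltage(aff, times, n_t)
        i = int(np.argmax(v))
        return float(v[i]), i * self.cfg.dt

    def _gradient(self, aff, times, t_max):
        """Per-afferent kernel sums at the time of maximal potential."""
        g = np.zeros(self.n_afferents)
        mask = times <= t_max
        if np.any(mask):
            contrib = tempotron_kernel(t_max - times[mask],
                                       self.cfg.tau, self.cfg.tau_s)
            np.add.at(g, aff[mask], contrib)
        return g

    def set_threshold(self, patterns: list[SpikeTrainSet]) -> float:
        """Mean over patterns of the maximal untrained output."""
        self.threshold = float(np.mean([self.max_output(p)[0] for p in patterns]))
        return self.threshold

    def train(self, patterns_a: list[SpikeTrainSet],
              patterns_b: list[SpikeTrainSet]) -> np.ndarray:
        """Train for cfg.epochs; return the per-epoch loss curve.

        Class A patterns should exceed threshold, class B should not.
        Loss per epoch = sum of |v_max - threshold| over misclassified
        patterns, evaluated as the epoch proceeds.
        """
        prepped = ([(self._prepare(p), True) for p in patterns_a]
                   + [(self._prepare(p), False) for p in patterns_b])
        if not hasattr(self, "threshold"):
            self.set_threshold(patterns_a + patterns_b)
        rng = np.random.default_rng(self.cfg.seed + 1)
        losses = np.zeros(self.cfg.epochs)
        for epoch in range(self.cfg.epochs):
            order = rng.permutation(len(prepped))
            loss = 0.0
            for i in order:
                (aff, times, n_t), is_a = prepped[i]
                v = self._voltage(aff, times, n_t)
                j = int(np.argmax(v))
                v_max, t_max = float(v[j]), j * self.cfg.dt
                fires = v_max > self.threshold
                if fires != is_a:
                    loss += abs(v_max - self.threshold)
                    g = self._gradient(aff, times, t_max)
                    self.weights += (1 if is_a else -1) * self.cfg.learning_rate * g
            losses[epoch] = loss
        return losses


def fit_loss_decay(losses: np.ndarray) -> tuple[float, bool]:
    """Fit a*exp(-epoch/tau_decay)+c (c >= 0) to the normalized loss curve.

    Returns (1/tau_decay, fit_ok).  A non-decreasing or degenerate curve
    yields speed 0 with fit_ok False.
    """
    losses = np.asarray(losses, dtype=float)
    if losses.size < 3 or losses[0] <= 0:
        return 0.0, False
    y = losses / losses[0]
    x = np.arange(y.size, dtype=float)
    # require a systematic (not incidental) decay before fitting: noise from
    # unlearnable pattern sets must not produce spurious positive speeds.
    # Decay is accepted when the tail has collapsed relative to the head, or
    # when the loss-vs-epoch trend is significantly negative.
    from scipy.stats import spearmanr
    q = max(y.size // 4, 2)
    collapsed = y[-q:].mean() < 0.2 * y[:q].mean()
    if np.ptp(y) == 0:
        return 0.0, False
    rho, p = spearmanr(x, y)
    if not (collapsed or (rho < 0 and p < 0.05)):
        return 0.0, False
    try:
        (a, tau, c), _ = curve_fit(
            lambda x, a, tau, c: a * np.exp(-x / tau) + c, x, y,
            p0=(1.0, max(y.size / 4.0, 1.0), float(max(y.min(), 0.0))),
            bounds=([0.0, 1e-3, 0.0], [10.0, 1e6, 2.0]), maxfev=10000)
    except RuntimeError:
        return 0.0, False
    return 1.0 / tau, True


def tempotron_speed(patterns_a: list[SpikeTrainSet],
                    patterns_b: list[SpikeTrainSet],
                    cfg: TempotronConfig | None = None) -> dict:
    """End-to-end tempotron decodability of two pattern classes."""
    cfg = cfg or TempotronConfig()
    n_aff = patterns_a[0].n_cells
    tp = Tempotron(n_aff, cfg)
    tp.set_threshold(patterns_a + patterns_b)
    losses = tp.train(patterns_a, patterns_b)
    speed, ok = fit_loss_decay(losses)
    return {"speed": speed, "fit_ok": ok, "losses": losses,
            "threshold": tp.threshold}
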