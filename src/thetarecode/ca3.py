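"""CA3 LIF network with feedforward inhibition and STDP readout.

Quantifies how the synchrony of the granule-cell (GC) population code
translates into recurrent-synapse plasticity in CA3.

Minimal variant (voltage-based synapses)::

    dv/dt = (E_l - v + v_syn) / tau_m

Presynaptic spikes add instantaneous voltage steps v_syn (GC->Pyr 15 mV,
GC->IN 5 mV, IN->Pyr -0..-5 mV after a 5 ms disynaptic latency).  A single
GC spike (15 mV from rest, -67 -> -52 mV) stays below the -48 mV threshold;
two synchronous GC spikes cross it -- the synchrony-detection mechanism.
Recurrent Pyr->Pyr synapses accumulate STDP weight from zero but inject no
current, so the mean final weight is a pure readout of STDP efficacy and is
exactly proportional to the STDP amplitude.

Extended variant (current-based synapses)::

    dv/dt = (E_l - v + R_in (I_e - I_i)) / tau_m

with Tsodyks-Markram facilitation at the mossy-fiber (GC->Pyr) synapse,
recurrent current injection proportional to the learned weights, and
per-spike multiplicative synaptic scaling of each pyramidal cell's incoming
weights.

STDP kernels (trace-based, all-to-all pairing)::

    symmetric:   dw = +A * exp(-|dt|/tau)   for either spike order
    asymmetric:  dw = +A * exp(-dt/tau)  (pre before post)
                 dw = -A * exp(+dt/tau)  (post before pre)
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .spiketrains import SpikeTrainSet

__all__ = ["CA3Config", "TMParams", "CA3Network", "CA3Result", "build_ca3",
           "tm_release", "apply_stdp", "run_ca3", "normalized_potentiation",
           "sensitivity_sweep"]


@dataclass
class TMParams:
    """Tsodyks-Markram facilitating mossy-fiber synapse."""

    tau_inact: float = 30e-3        # s, EPSC decay
    delta_i_max: float = 5e-9       # A, maximal current
    release_fraction: float = 0.03
    tau_recovery: float = 130e-3    # s
    tau_facilitation: float = 530e-3  # s


def tm_release(u: np.ndarray, r: np.ndarray, p: TMParams):
    """One presynaptic spike through the facilitating TM synapse.

    Returns (EPSC amplitude in A, new utilization, new resources).  At full
    resources and zero utilization the first release has amplitude
    delta_i_max * release_fraction (150 pA at defaults).
    """
    u_new = u + p.release_fraction * (1.0 - u)
    amp = p.delta_i_max * u_new * r
    r_new = r * (1.0 - u_new)
    return amp, u_new, r_new


@dataclass
class CA3Config:
    # pyramidal cells
    n_pyr: int = 600
    pyr_tau_m: float = 45e-3        # s
    pyr_v_thr: float = -48.0        # mV
    pyr_v_reset: float = -54.0      # mV
    pyr_e_l: float = -67.0          # mV
    pyr_r_in: float = 150e6         # Ohm (extended variant)
    pyr_refractory: float = 2e-3    # s; extended variant only -- bounds burst
                                    # rates under sustained synaptic current
                                    # (voltage-step synapses cannot sustain
                                    # drive, so the minimal variant needs none)
    # feedforward interneurons
    n_in: int = 60
    in_tau_m: float = 14e-3
    in_v_thr: float = -37.0
    in_v_reset: float = -54.0
    in_e_l: float = -52.0
    in_r_in: float = 112e6
    in_refractory: float = 5e-3
    # synapses
    p_gc_pyr: float = 0.035   # in-degree ~70 GCs/Pyr, ~21 Pyr/GC (see docs)
    p_gc_in: float = 0.7
    p_in_pyr: float = 0.1
    p_pyr_pyr: float = 0.01
    v_gc_pyr: float = 15.0    # mV, minimal variant
    v_gc_in: float = 5.0      # mV
    inhibition: float = 2.0   # mV, magnitude of IN->Pyr step (0..5)
    in_latency: float = 5e-3  # s
    # extended-variant currents
    i_gc_in: float = 40e-12   # A
    i_in_pyr: float = 40e-12  # A (default; 0..80 pA)
    i_rec_unit: float = 40e-12  # A per unit recurrent weight
    tau_s: float = 15e-3      # s, current-synapse decay
    tm: TMParams = field(default_factory=TMParams)
    # plasticity
    variant: str = "minimal"          # minimal | extended
    stdp_kernel: str = "symmetric"    # symmetric | asymmetric
    tau_stdp: float = 20e-3           # s, 10..50 ms
    stdp_amplitude: float = 1.0       # arbitrary units; ratios are A-invariant
    weight_cap: float | None = 5.0    # per-synapse bound, in units of amplitude
    scaling_decrement: float = 0.05   # extended: w *= (1 - 0.05) per post spike
    # integration
    dt: float = 1e-4                  # s
    duration: float = 2.0             # s

    def __post_init__(self) -> None:
        if self.variant not in ("minimal", "extended"):
            raise ValueError("variant must be 'minimal' or 'extended'")
        if self.stdp_kernel not in ("symmetric", "asymmetric"):
            raise ValueError("stdp_kernel must be 'symmetric' or 'asymmetric'")


@dataclass
class CA3Network:
    config: CA3Config
    wiring_seed: int
    gc_pyr: np.ndarray    # (n_gc, n_pyr) bool
    gc_in: np.ndarray     # (n_gc, n_in) bool
    in_pyr: np.ndarray    # (n_in, n_pyr) bool
    rec_pre: np.ndarray   # (n_syn,) presynaptic pyramidal index
    rec_post: np.ndarray  # (n_syn,) postsynaptic pyramidal index


@dataclass
class CA3Result:
    mean_weight: float
    pyr_rate: float           # Hz
    in_rate: float            # Hz
    pyr_spikes: list[np.ndarray] = field(repr=False, default_factory=list)
    in_spikes: list[np.ndarray] = field(repr=False, default_factory=list)
    weights: np.ndarray = field(repr=False, default=None)
    config: CA3Config | None = field(repr=False, default=None)
    voltage_trace: np.ndarray | None = field(repr=False, default=None)


def build_ca3(cfg: CA3Config, wiring_seed: int, n_gc: int = 2000) -> CA3Network:
    """Random wiring at the configured connection probabilities."""
    rng = np.random.default_rng(wiring_seed)
    gc_pyr = rng.random((n_gc, cfg.n_pyr)) < cfg.p_gc_pyr
    gc_in = rng.random((n_gc, cfg.n_in)) < cfg.p_gc_in
    in_pyr = rng.random((cfg.n_in, cfg.n_pyr)) < cfg.p_in_pyr
    pre, post = np.nonzero(rng.random((cfg.n_pyr, cfg.n_pyr)) < cfg.p_pyr_pyr)
    keep = pre != post
    return CA3Network(cfg, wiring_seed, gc_pyr, gc_in, in_pyr,
                      pre[keep], post[keep])


# ---------------------------------------------------------------------------
# STDP
# ---------------------------------------------------------------------------

def apply_stdp(pre_spikes: np.ndarray, post_spikes: np.ndarray, kernel: str,
               tau_stdp: float, amplitude: float = 1.0) -> float:
    """Total weight change from all-to-all pairing of two spike trains."""
    pre = np.asarray(pre_spikes, dtype=float)
    post = np.asarray(post_spikes, dtype=float)
    if pre.size == 0 or post.size == 0:
        return 0.0
    dt = post[None, :] - pre[:, None]      # >0: pre before post
    if kernel == "symmetric":
        return float(amplitude * np.exp(-np.abs(dt) / tau_stdp).sum())
    pos = dt >= 0
    return float(amplitude * (np.exp(-dt[pos] / tau_stdp).sum()
                              - np.exp(dt[~pos] / tau_stdp).sum()))


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _binned_spikes(spikes: SpikeTrainSet, dt: float, n_steps: int):
    """Per-step lists of spiking cell indices."""
    out: dict[int, list[int]] = {}
    for cell, t in enumerate(spikes.trains):
        for s in np.minimum((t / dt).astype(int), n_steps - 1):
            out.setdefault(int(s), []).append(cell)
    return {s: np.asarray(c) for s, c in out.items()}


def run_ca3(gc_spikes: SpikeTrainSet, cfg: CA3Config,
            wiring_seed: int = 0, net: CA3Network | None = None,
            record_cell: int | None = None) -> CA3Result:
    """Simulate CA3 for the configured duration and read out plasticity.

    ``record_cell`` stores that pyramidal cell's voltage at every step
    (value after the step's update) in ``CA3Result.voltage_trace``.
    """
    if net is None:
        net = build_ca3(cfg, wiring_seed, n_gc=gc_spikes.n_cells)
    elif net.gc_pyr.shape[0] != gc_spikes.n_cells:
        raise ValueError("network wiring does not match GC count")
    cfg = net.config if net is not None else cfg
    dt = cfg.dt
    n_steps = int(round(cfg.duration / dt))
    gc_by_step = _binned_spikes(gc_spikes, dt, n_steps)
    in_delay = int(round(cfg.in_latency / dt))

    v_p = np.full(cfg.n_pyr, cfg.pyr_e_l)
    v_i = np.full(cfg.n_in, cfg.in_e_l)
    dec_p = np.exp(-dt / cfg.pyr_tau_m)
    dec_i = np.exp(-dt / cfg.in_tau_m)
    refr_until = np.full(cfg.n_in, -1)
    refr_steps = int(round(cfg.in_refractory / dt))
    p_refr_until = np.full(cfg.n_pyr, -1)
    p_refr_steps = (int(round(cfg.pyr_refractory / dt))
                    if cfg.variant == "extended" else 0)
    # IN spikes reach pyramidal cells after the disynaptic latency
    in_spike_buffer: dict[int, np.ndarray] = {}

    extended = cfg.variant == "extended"
    if extended:
        ie_p = np.zeros(cfg.n_pyr)   # A, mossy-fiber excitatory current
        ir_p = np.zeros(cfg.n_pyr)   # A, recurrent excitatory current
        ii_p = np.zeros(cfg.n_pyr)   # A, inhibitory current
        ie_i = np.zeros(cfg.n_in)
        dec_s = np.exp(-dt / cfg.tau_s)
        dec_tm = np.exp(-dt / cfg.tm.tau_inact)
        tm_r = np.ones(gc_spikes.n_cells)     # resources
        tm_u = np.zeros(gc_spikes.n_cells)    # utilization

    # plasticity state (online traces; in the minimal variant weights do not
    # feed back, so this is equivalent to post-hoc pairing)
    n_syn = net.rec_pre.size
    w = np.zeros(n_syn)
    trace = np.zeros(cfg.n_pyr)    # exp(-t/tau_stdp) spike trace per pyr
    dec_tr = np.exp(-dt / cfg.tau_stdp)
    A = cfg.stdp_amplitude
    # the bound scales with the amplitude, so final weights remain exactly
    # proportional to A and all ratio metrics are A-invariant
    cap = None if cfg.weight_cap is None else cfg.weight_cap * A
    sym = cfg.stdp_kernel == "symmetric"

    pyr_spikes: list[list[float]] = [[] for _ in range(cfg.n_pyr)]
    in_spikes: list[list[float]] = [[] for _ in range(cfg.n_in)]
    trace_v = np.empty(n_steps) if record_cell is not None else None

    for s in range(n_steps):
        gc_now = gc_by_step.get(s)
        trace *= dec_tr       # decay first so a pair spanning k steps
        # contributes exp(-k*dt/tau), matching all-to-all pairing exactly
        # --- interneurons ---
        v_i = cfg.in_e_l + (v_i - cfg.in_e_l) * dec_i
        if extended:
            ie_i *= dec_s
            if gc_now is not None:
                ie_i += net.gc_in[gc_now].sum(axis=0) * cfg.i_gc_in
            v_i += cfg.in_r_in * ie_i * (dt / cfg.in_tau_m) * 1e3  # V->mV
        elif gc_now is not None:
            v_i += net.gc_in[gc_now].sum(axis=0) * cfg.v_gc_in
        ok = refr_until < s
        fired_i = np.flatnonzero((v_i >= cfg.in_v_thr) & ok)
        v_i[~ok] = cfg.in_v_reset
        if fired_i.size:
            v_i[fired_i] = cfg.in_v_reset
            refr_until[fired_i] = s + refr_steps
            in_spike_buffer[s + in_delay] = fired_i
            t_now = (s + 0.5) * dt
            for c in fired_i:
                in_spikes[c].append(t_now)

        # --- pyramidal cells ---
        v_p = cfg.pyr_e_l + (v_p - cfg.pyr_e_l) * dec_p
        if extended:
            ie_p *= dec_tm
            ii_p *= dec_s
            if gc_now is not None:
                amp, tm_u[gc_now], tm_r[gc_now] = tm_release(
                    tm_u[gc_now], tm_r[gc_now], cfg.tm)
                ie_p += net.gc_pyr[gc_now].T @ amp
            delayed = in_spike_buffer.pop(s, None)
            if delayed is not None:
                # current amplitude scales with the inhibition setting
                # (default 2 -> 40 pA, matching the voltage-variant default)
                ii_p += net.in_pyr[delayed].sum(axis=0) * cfg.i_in_pyr \
                    * (cfg.inhibition / 2.0)
            ir_p *= dec_s
            v_p += cfg.pyr_r_in * (ie_p + ir_p - ii_p) * (dt / cfg.pyr_tau_m) * 1e3
            # TM recovery / facilitation relaxation
            tm_r += (1.0 - tm_r) * (dt / cfg.tm.tau_recovery)
            tm_u -= tm_u * (dt / cfg.tm.tau_facilitation)
        else:
            if gc_now is not None:
                v_p += net.gc_pyr[gc_now].sum(axis=0) * cfg.v_gc_pyr
            delayed = in_spike_buffer.pop(s, None)
            if delayed is not None:
                v_p -= net.in_pyr[delayed].sum(axis=0) * cfg.inhibition
        if p_refr_steps:
            ok_p = p_refr_until < s
            v_p[~ok_p] = np.minimum(v_p[~ok_p], cfg.pyr_v_reset)
            fired_p = np.flatnonzero((v_p >= cfg.pyr_v_thr) & ok_p)
        else:
            fired_p = np.flatnonzero(v_p >= cfg.pyr_v_thr)
        if fired_p.size:
            v_p[fired_p] = cfg.pyr_v_reset
            p_refr_until[fired_p] = s + p_refr_steps
            t_now = (s + 0.5) * dt
            # STDP: pair the new post/pre spikes with existing traces
            fired_mask = np.zeros(cfg.n_pyr, dtype=bool)
            fired_mask[fired_p] = True
            post_hit = fired_mask[net.rec_post]
            pre_hit = fired_mask[net.rec_pre]
            w[post_hit] += A * trace[net.rec_pre[post_hit]]
            if sym:
                w[pre_hit] += A * trace[net.rec_post[pre_hit]]
            else:
                w[pre_hit] -= A * trace[net.rec_post[pre_hit]]
            # same-step pre/post pairs (dt = 0) pair once, as potentiation
            w[pre_hit & post_hit] += A
            if cap is not None:
                np.clip(w, -cap, cap, out=w)
            if extended:
                # learned recurrent drive: each presynaptic spike injects
                # w * i_rec_unit into its postsynaptic targets
                np.add.at(ir_p, net.rec_post[pre_hit],
                          w[pre_hit] * cfg.i_rec_unit)
                if cfg.scaling_decrement > 0:
                    scale = np.ones(cfg.n_pyr)
                    scale[fired_p] = 1.0 - cfg.scaling_decrement
                    w *= scale[net.rec_post]
            for c in fired_p:
                pyr_spikes[c].append(t_now)
        if fired_p.size:
            trace[fired_p] += 1.0
        if trace_v is not None:
            trace_v[s] = v_p[record_cell]

    pyr_sts = [np.asarray(t) for t in pyr_spikes]
    in_sts = [np.asarray(t) for t in in_spikes]
    T = cfg.duration
    return CA3Result(
        mean_weight=float(w.mean()) if w.size else 0.0,
        pyr_rate=sum(len(t) for t in pyr_sts) / (cfg.n_pyr * T),
        in_rate=sum(len(t) for t in in_sts) / (cfg.n_in * T) if cfg.n_in else 0.0,
        pyr_spikes=pyr_sts, in_spikes=in_sts, weights=w, config=cfg,
        voltage_trace=trace_v)


def normalized_potentiation(result_a: CA3Result, result_b: CA3Result) -> float:
    """(weight ratio) / (pyramidal-rate ratio) between two input conditions."""
    if result_b.mean_weight == 0 or result_b.pyr_rate == 0:
        raise ZeroDivisionError("reference condition has no weights or spikes")
    return (result_a.mean_weight / result_b.mean_weight) \
        / (result_a.pyr_rate / result_b.pyr_rate)


def sensitivity_sweep(inputs_a: list[SpikeTrainSet], inputs_b: list[SpikeTrainSet],
                      inhibitions=(0.0, 1.0, 2.0, 3.0, 4.0, 5.0),
                      tau_stdps=(10e-3, 20e-3, 30e-3, 40e-3, 50e-3),
                      cfg: CA3Config | None = None,
                      wiring_seeds=(0,)) -> pd.DataFrame:
    """Mean weight / rate / ratio surfaces over the inhibition x tau grid.

    ``inputs_a``/``inputs_b`` are matched GC spike sets for the two
    conditions being compared (e.g. full vs no-feedback DG, rate-matched);
    means are taken over the input list crossed with ``wiring_seeds``.
    """
    cfg = cfg or CA3Config()
    rows = []
    for inh in inhibitions:
        for tau in tau_stdps:
            c = replace(cfg, inhibition=inh, tau_stdp=tau)
            acc = {"a": [], "b": []}
            for ws in wiring_seeds:
                for label, inputs in (("a", inputs_a), ("b", inputs_b)):
                    for spk in inputs:
                        r = run_ca3(spk, c, wiring_seed=ws)
                        acc[label].append((r.mean_weight, r.pyr_rate, r.in_rate))
            wa, ra, ia = np.mean(acc["a"], axis=0)
            wb, rb, ib = np.mean(acc["b"], axis=0)
            rows.append({
                "inhibition_mV": inh, "tau_stdp_ms": tau * 1e3,
                "mean_weight_a": wa, "mean_weight_b": wb,
                "pyr_rate_a": ra, "pyr_rate_b": rb,
                "in_rate_a": ia, "in_rate_b": ib,
                "weight_ratio": wa / wb if wb else np.inf,
                "normalized_potentiation":
                    (wa / wb) / (ra / rb) if wb and rb and ra else np.nan,
            })
    return pd.DataFrame(rows)
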