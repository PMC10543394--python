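# Methods

`thetarecode` simulates and analyses the transformation of theta-phase-coded
spatial input into sparse population rate codes across the entorhinal cortex
(EC) - dentate gyrus (DG) - CA3 axis. This note documents the models, their
assumptions, the parameters that matter, and the design choices made where
the design was genuinely open.

## 1. Grid-cell stage (`thetarecode.gridcells`)

### Firing fields

Each of the 200 medial-entorhinal grid cells is the sum of three plane-wave
gratings with wavevectors `k_i` of magnitude `4*pi/(sqrt(3)*lambda)` at the
cell's orientation plus −30°, +30°, +90° (60° angular separations):

    g_w(l) = 2/3 * (1/3 * sum_i cos(k_i . (l - l0)) + 1/2)

`g_w` is 1 exactly at lattice vertices and 0 at the field troughs. Per-cell
parameters follow the empirical distributions of rodent grid cells:

| parameter    | law                                              | units |
|--------------|--------------------------------------------------|-------|
| spacing λ    | truncated skew-normal on [15, 120], median 43    | cm    |
| orientation  | uniform on [0, 60)                               | deg   |
| offset l0    | uniform on [0, 100)²                             | cm    |

Only the support and the median of the spacing law are empirically pinned;
the skew-normal location (15 cm) and scale (40 cm) are fixed and the shape
parameter is solved at import time (Brent root-finding) so the truncated
median is exactly 43 cm. The resulting law is strongly right-skewed
(shape ≈ 7.8), consistent with the long tail of recorded grid scales.

### Phase precession

The radial distance to the nearest vertex is recovered from the field value,

    d(l) = arccos(3/2 * g_w/g_max - 1/2) * lambda*sqrt(6)/(4*pi),

negated while the animal is leaving a field (sign of the central-difference
derivative of `d(t)` along the path; ties count as entering), and mapped to
a preferred theta phase `phi = k1*pi*(d/lambda + 0.5)` with `k1 = 1`. The
instantaneous rate combines a von-Mises-like phase tuning with the spatial
envelope:

    rate(t) = scale * exp(k2 * cos(theta(t) - phi(t))) * g_w(l(t)),

with `k2 = 1.5`, theta a fixed 10 Hz clock (`theta(t) = 2*pi*frac(10 t)`,
cycles are the 100 ms bins), and the default trajectory a straight 2 s,
20 cm/s run. As the animal crosses a field, `phi` sweeps monotonically from
≈0.91π down to ≈0.09π — late-to-early precession.

`scale` (default **20 Hz**) is the only free amplitude. It was calibrated
once so that (i) peak in-field instantaneous rates are of order tens of Hz
(20·e^1.5 ≈ 90 Hz, matching MEC recordings) and (ii) the population Skaggs
information of the standard protocol sits near 0.32 bits/spike. Because
bits-per-spike is nearly scale-invariant, (ii) constrains `scale` only
weakly; the value is fixed and not tuned per analysis.

Spikes are drawn by thinning a homogeneous Poisson process at the per-cell
peak rate; every stage seeds its own `numpy` generator, and the triple
(grid seed, Poisson seed, shuffle seed) fully determines all outputs.

### Phase-shuffle null

The null model removes spatial phase information while conserving
everything else: for every (cell, theta-cycle) the spike count is kept
exactly and new within-cycle times are drawn from the population phase
template — the pooled phase histogram (100 bins) of a non-shuffled
simulation of the same grid seed. Aggregate theta modulation and all rate
information are conserved by construction.

### LEC inputs

Contextual lateral-entorhinal input is 20 Poisson cells driven by a
smoothed sawtooth envelope rescaled to 0–30 Hz, with its peak placed π
radians from the grid-cell modulation peak (counter-cyclical). `identical`
mode replays one seed across contexts; `similar` redraws per context.

## 2. Dentate surrogate (`thetarecode.dg`)

The DG stage is a deliberately reduced circuit model: its role is to carry
the one mechanism under test — net feedback inhibition arriving with a
latency and decaying slowly, so that early-theta granule-cell (GC) firing
suppresses late-theta firing — inside a network of the documented size and
connectivity (2000 GCs; every grid cell contacts 100 random GCs and one
basket cell; 24 basket, 24 HIPP and 60 mossy cells, the latter two folded
into the lumped feedback pathway, their counts kept in the config for
record).

GCs are leaky integrate-and-fire units (unitless voltage, threshold 1,
rest 0, **τ_m = 30 ms** — a granule-cell-like integrator — refractory
2 ms, Euler step 0.5 ms). Perforant-path spikes arrive as instantaneous
EPSP steps of size `pp_weight`. Inhibition is organized per basket cell:
each of the 24 basket cells owns a random block of ~83 GCs and carries two
exponentially decaying traces (decay 30 ms):

* **feedforward**: incremented by spikes of the EC cells wired to that
  basket cell, at 3 ms latency (gain 0.5);
* **feedback**: incremented by spikes of the GCs in its own block, at
  10 ms latency (gain 60).

Block-wise traces keep the competition lateral — local winners suppress
local late spikes — rather than a single global winner-take-all, which we
found numerically fragile. Output spike times carry 1 ms Gaussian
transmission jitter so downstream consumers see physiological rather than
integration-bin synchrony.

Circuit conditions ablate synapse sets exactly: `full`, `no_ff`, `no_fb`,
`disinhibited`. For every condition the PP weight is calibrated by
bisection until the mean GC rate enters the permissible 0.2–0.3 Hz band,
so comparisons across conditions are rate-controlled; seeds whose rate
leaves the band are flagged by the exclusion rule, never deleted. At the
calibrated point ~2–2.5 % of GCs are active per theta cycle.

Membrane noise is a white Gaussian current per step whose SD is specified
in pA-equivalents ({0, 50, 250, 500}); the gain maps 50 pA to ~5 % of
threshold (stationary), so the baseline is mild and 500 pA is strongly
disruptive without saturating.

**Robustness.** The feedback signatures (phase-histogram sharpening,
late-theta suppression) hold across feedback latencies of 7–15 ms. At 5 ms
the inhibition arrives inside the triggering volley itself and the
rate-calibration washes the phase structure out; we therefore document the
robustness range as 7–15 ms rather than ±50 % of the default.

**What the surrogate is not.** It has no ion channels, dendrites, or
distinct interneuron dynamics; quantitative DG-side results of
conductance-based models (e.g. exact pattern-separation areas) are outside
its scope. The per-seed strength of the feedback-dependent recoding effect
is correspondingly weaker and more heterogeneous than in a biophysical
model: a minority of grid seeds express essentially no effect (see §6).

## 3. Theta codes (`thetarecode.codes`)

Each (cell, 100 ms cycle) is summarized as a polar theta-vector — rate
(count/0.1 s) and circular-mean phase — and transformed to Cartesian
[x, y] so empty cycles are well-defined as [0, 0]. Pure codes clamp the
other coordinate: rate-isolated sets the angle to π/4 (x = y = r/√2);
phase-isolated sets the magnitude to 1 Hz. Cycles whose phases cancel
exactly (zero resultant) have undefined mean phase: they map to the origin
in full/phase modes but keep their rate in rate mode. Flattening is
bin-major, then cell, then coordinate (20 × n_cells × 2 features).

## 4. Information and decodability metrics (`thetarecode.info`, `.decoders`)

* **Pattern separation**: Pearson R between flattened codes of trajectory
  pairs at the input (EC) and output (GC); the area between the R_out
  curve and the unity line, integrated against R_in, per grid seed.
* **Skaggs information** (bits/spike): 5 cm bins, uniform occupancy,
  spikes pooled over 20 Poisson seeds, cells with fewer than 8 pooled
  spikes excluded (flagged, not dropped).
* **Olypher positional information**: per-position KL divergence of the
  trial-conditional discretized value distribution from its marginal;
  7 equal-width value bins (per-cell observed range for rates, [0, 2π)
  for phases), NaN trials ignored for phases, box smoothing over 1–20
  position bins reported per scale, per-spike normalization by the cell
  mean rate. Equals the position-value mutual information under uniform
  occupancy (tested against a joint-histogram oracle).
* **Perceptron decodability**: two sigmoid units on the flattened code,
  per-sample SGD (seeded order), zero init, RMSE threshold 0.2; speed
  1/N_E with floor 1/10000. Learning rate 1e-3 for 200-cell input, 1e-4
  for 2000-cell input; only shuffle *ratios* are interpreted, which are
  insensitive to this choice.
* **Tempotron decodability**: single LIF readout, unit-peak
  double-exponential kernel (τ = 10 ms, τ_s = 2 ms, peak at
  2.5·ln 5 ≈ 4.02 ms), threshold fixed per grid seed as the mean of
  untrained per-pattern maxima, gradient updates at the time of the
  potential maximum, 200 epochs. Speed is 1/τ_decay of an exponential fit
  to the per-epoch loss; the fit is gated on a systematic decay (tail
  collapse or significantly negative Spearman trend) so unlearnable
  pattern sets report speed 0 instead of noise.

## 5. CA3 stage (`thetarecode.ca3`)

600 pyramidal cells and 60 feedforward interneurons, parameters from the
experimental literature (pyramids: τ_m 45 ms, threshold −48 mV, reset
−54 mV, rest −67 mV; interneurons: τ_m 14 ms, threshold −37 mV, rest
−52 mV, 5 ms refractory). Wiring: GC→Pyr p = 0.035 (≈70 GCs per pyramid,
≈21 pyramids per GC — the in-degree statement; a printed p = 0.35 would
contradict it), GC→IN p = 0.7, IN→Pyr p = 0.1 with 5 ms disynaptic
latency, Pyr→Pyr p = 0.01.

**Minimal variant** (voltage synapses, Euler–exponential integration at
0.1 ms): a single GC spike depolarizes 15 mV from rest — subthreshold;
two synchronous spikes cross threshold. Recurrent synapses accumulate
STDP weight from zero but inject no current, so the mean final weight is
a pure plasticity readout, exactly proportional to the STDP amplitude A.

**STDP**: trace-based all-to-all pairing; symmetric kernel
`A·exp(−|Δt|/τ)` (CA3-like, potentiates either order) or asymmetric
(Hebbian signs). τ ∈ [10, 50] ms, default 20 ms. Weights are bounded per
synapse at **5·A** (online clip), the standard bounded-STDP form of the
mechanism this model adapts. The bound matters scientifically: without
it, theta-synchronous input retains a pairing advantage even with CA3
inhibition removed, whereas with the bound the full/no-feedback weight
ratio collapses to ≈1 at zero inhibition and sits in the 2–5 range at
2–3 mV inhibition — the saturation is what makes the effect
inhibition-dependent. Because the cap scales with A, final weights remain
exactly ∝ A and all ratio metrics are A-invariant.

**Extended variant**: current-based synapses (Eq-9-style,
`dv/dt = (E_l − v + R_in(I_e − I_i))/τ_m`), Tsodyks–Markram facilitation
at the mossy fiber (τ_inact 30 ms, ΔI_max 5 nA, release fraction 0.03,
τ_rec 130 ms, τ_facil 530 ms; first release 150 pA), recurrent current
injection proportional to learned weights, and multiplicative synaptic
scaling (w ← 0.95 w per postsynaptic spike). Sustained currents can hold
the membrane above threshold, so the extended variant adds a 2 ms
pyramidal refractory; rates still run high (hundreds of Hz during
volleys) and the variant is used for qualitative robustness only.

## 6. Study protocols, problem sizes, and what passing shows

The standard protocol is 2 s trajectories, 200 grid cells, 20 Poisson
seeds pooled, 10 grid seeds for population estimates. The test suite runs
the same protocols at reduced seed counts (stated per test: 5–10 grid
seeds for information and separation analyses, 3 Poisson pairs per
distance for separation curves, one wiring seed for CA3 grids), chosen so
the whole suite completes on a single CPU in minutes.

The shuffle-induced GC information loss is measured as the mean paired
per-cell difference (cells passing the spike filter in both conditions),
which removes inclusion-composition variance. Characterizing the
feedback-vs-no-feedback difference of this loss over independent Poisson
pools shows that roughly three quarters of grid seeds carry a clear
positive effect (+0.04 to +0.11 bits/spike) while the remainder are null
(|difference| < 0.01, unchanged under tight rate matching) — a genuine
heterogeneity of the reduced surrogate. Seed-level inference therefore
uses a one-sided Wilcoxon signed-rank over per-seed pool-averaged
differences, which weights the strong majority by magnitude instead of
treating null seeds as informative coin flips the way a raw sign test
would.

Because all inputs are synthetic, passing tests demonstrate internal
consistency of the mechanism — phase information in, rate information
out, mediated by feedback inhibition — not quantitative agreement with
biological dentate recordings. Real EC input has velocity modulation,
theta-frequency drift, conjunctive cells and non-grid input, none of
which are modelled; trajectories are straight lines, so 2-D field
geometry enters only through where the path cuts each lattice.

## 7. Numerical choices

* arccos argument clipped to [−1, 1] within 1e-9; larger violations raise.
* LIF leak uses the exact exponential between events; synaptic currents
  are explicit-Euler within a step (O(dt); verified to converge to the
  closed-form double-exponential response).
* Degenerate inputs: zero-spike histograms raise on circular means;
  undefined-phase cycles map to the origin; zero-variance correlation
  inputs raise rather than return NaN.
* The exclusion rule flags rows (`excluded`, `exclusion_reason`) and
  never deletes them.
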