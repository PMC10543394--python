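# thetarecode

Phase-to-rate recoding in the entorhinal cortex → dentate gyrus → CA3
system: a simulation and analysis pipeline for computational
neuroscientists studying how inhibitory circuits transform neural codes.

Entorhinal grid cells carry spatial information in two channels at once: a
*rate code* (how much each cell fires) and a *phase code* (theta-phase
precession — when in the ~10 Hz theta cycle each spike lands encodes where
the animal is inside a firing field). The dentate gyrus reads this input
through one of the brain's strongest feedback-inhibitory microcircuits.
This package implements the full chain needed to ask what that circuit does
to each coding channel:

1. **`gridcells`** — phase-precessing grid-cell spike trains. Fields are
   sums of three 60°-separated gratings; the preferred phase follows the
   vertex distance, `phi = pi*(d/lambda + 0.5)`, modulated as
   `exp(1.5*cos(theta - phi))`; spiking is inhomogeneous-Poisson. Includes
   the per-cell, per-theta-cycle phase shuffle that destroys spatial phase
   information while conserving counts and the population phase histogram,
   and counter-cyclically modulated LEC context inputs.
2. **`dg`** — a reduced spiking dentate surrogate (2000 LIF granule cells,
   per-basket-cell feedforward and feedback inhibition, switchable circuit
   ablations, rate-calibrated perforant-path weights).
3. **`codes`** — theta-vector codes: per-cycle (rate, mean-phase) pairs in
   Cartesian coordinates, with pure rate- or phase-isolated variants.
4. **`info`** — pattern-separation curves and areas, Skaggs spatial
   information (bits/spike), Olypher positional information, population
   synchrony.
5. **`decoders`** — perceptron learning speed on theta codes, tempotron
   learning speed on raw spike trains.
6. **`ca3`** — a 600-pyramid CA3 network with feedforward inhibition and a
   symmetric (or asymmetric) STDP readout of recurrent plasticity, plus a
   Tsodyks–Markram/current-based extended variant.
7. **`pipeline`** — seed bookkeeping, calibrated standard protocols,
   figure-analogue experiment tables, and the `theta-recode` CLI.

The headline phenomenon the pipeline reproduces: feedback inhibition
converts upstream *phase* information into downstream *rate* information
("phase-to-rate recoding") — shuffling EC spike phases costs the granule
cells spatial rate information, much more so when feedback inhibition is
intact — and the resulting within-cycle synchrony makes recurrent CA3
STDP several-fold more effective at matched firing rates.

## Worked example

```python
import numpy as np
from thetarecode import gridcells as gcm, dg as dgm
from thetarecode.codes import theta_vectors, isolate, flatten
from thetarecode.pipeline import calibrated_dg, perceptron_ratio_at

# 200 grid cells, 2 s straight run at 20 cm/s, 10 Hz theta
pop = gcm.sample_grid_population(200, grid_seed=1)
prof = gcm.trajectory_rate_profiles(pop, gcm.Trajectory())
ec = gcm.poisson_spikes(prof, poisson_seed=0)
print(f"EC: {ec.n_spikes} spikes, {ec.mean_rate():.1f} Hz mean rate")

# rate-calibrated dentate surrogate, full inhibitory circuit
net = calibrated_dg(1, "full", ec)
gc = dgm.run_dg(net, ec, sim_seed=0)
rep = dgm.phase_histogram_report(gc)
print(f"GC: rate {gc.mean_rate():.3f} Hz, "
      f"circular variance {rep['circular_variance']:.3f} "
      f"(EC: {dgm.phase_histogram_report(ec)['circular_variance']:.3f})")

# perceptron decodability of the EC phase code, 15 cm trajectory distance
row = perceptron_ratio_at(1, distance=15.0, mode="phase", n_poisson=20)
print(f"speed ratio non-shuffled/shuffled: {row['ratio']:.2f}")
```

Output:

```
EC: 4396 spikes, 11.0 Hz mean rate
GC: rate 0.232 Hz, circular variance 0.165 (EC: 0.577)
speed ratio non-shuffled/shuffled: 2.00
```

Reading: the dentate stage is ~50× sparser than its input (0.2–0.3 Hz,
about 2 % of granule cells per theta cycle) and its spikes are compressed
into the early theta cycle (circular variance 0.17 vs 0.58 in EC — the
feedback circuit suppresses late-theta spikes). A perceptron learns to
tell two trajectories apart from the EC phase code about twice as fast as
from phase-shuffled input with identical rates and sparsity, i.e. half of
its learnable structure is genuine spatial phase information.

The same protocols are available from the shell:

```bash
theta-recode simulate-ec --grid-seed 1 --poisson-seed 0 --out out/
theta-recode run-dg --condition full --calibrate --in out/ec_spikes.csv --out out/gc.csv
theta-recode run-ca3 --variant minimal --inhibition 2 --in out/gc.csv --out out/ca3.csv
```

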