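"""Grid-cell generator: firing-field geometry, phase precession, spiking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import i0
from scipy.stats import chisquare

import thetarecode.gridcells as gcm


class TestPopulationSampling:
    def test_spacing_law_median_and_support(self):
        rng = np.random.default_rng(0)
        sp = gcm.sample_spacings(10_000, rng)
        assert np.all((sp >= 15.0) & (sp <= 120.0))
        assert np.median(sp) == pytest.approx(43.0, abs=1.0)
        # right-skew: mean exceeds median
        assert sp.mean() > np.median(sp)

    def test_seeded_determinism(self):
        a = gcm.sample_grid_population(50, 7)
        b = gcm.sample_grid_population(50, 7)
        assert np.array_equal(a.spacings, b.spacings)
        assert np.array_equal(a.orientations, b.orientations)
        assert np.array_equal(a.offsets, b.offsets)
        assert np.array_equal(a.wavevectors, b.wavevectors)

    def test_orientation_uniform_on_0_60(self):
        pop = gcm.sample_grid_population(10_000, 3)
        assert np.all((pop.orientations >= 0) & (pop.orientations < 60))
        counts, _ = np.histogram(pop.orientations, bins=12, range=(0, 60))
        assert chisquare(counts).pvalue > 0.01

    def test_offsets_within_arena(self):
        pop = gcm.sample_grid_population(1000, 4)
        assert np.all((pop.offsets >= 0) & (pop.offsets < 100))

    def test_invalid_n_cells(self):
        with pytest.raises(ValueError):
            gcm.sample_grid_population(0, 1)


class TestFieldGeometry:
    def test_rate_is_one_at_offset_and_lattice_translates(self, population):
        for c in range(5):
            l0 = population.offsets[c]
            assert gcm.grid_rate(population, c, l0) == pytest.approx(1.0)
            # lattice vector: solve k1.u = k2.u = 2*pi
            k = population.wavevectors[c]
            u = np.linalg.solve(k[:2], [2 * np.pi, 2 * np.pi])
            assert gcm.grid_rate(population, c, l0 + u) == pytest.approx(1.0, abs=1e-9)

    def test_rate_range_and_minimum(self, population):
        lam = population.spacings[0]
        xs = np.linspace(0, 2 * lam, 400)
        X, Y = np.meshgrid(xs, xs)
        pts = np.stack([X.ravel(), Y.ravel()], -1) + population.offsets[0]
        g = gcm.grid_rate(population, 0, pts)
        assert g.min() >= -1e-9 and g.max() <= 1 + 1e-9
        assert g.min() == pytest.approx(0.0, abs=1e-6)

    def test_distance_zero_at_vertex_and_trough_value(self, population):
        assert gcm.linear_distance(population, 0, population.offsets[0]) \
            == pytest.approx(0.0)
        # g_w = 0 at spacing 43 -> d = 43*sqrt(6)/6
        pop43 = gcm.GridCellPopulation(
            np.array([43.0]), np.array([0.0]), np.zeros((1, 2)), 0)
        lam = 43.0
        xs = np.linspace(0, 2 * lam, 600)
        X, Y = np.meshgrid(xs, xs)
        pts = np.stack([X.ravel(), Y.ravel()], -1)
        d = gcm.linear_distance(pop43, 0, pts)
        assert d.max() == pytest.approx(43 * np.sqrt(6) / 6, abs=0.01)

    def test_distance_monotone_in_rate_and_inverts(self, population):
        lam = population.spacings[0]
        g = np.linspace(0, 1, 200)
        d = np.arccos(np.clip(1.5 * g - 0.5, -1, 1)) * lam * np.sqrt(6) / (4 * np.pi)
        assert np.all(np.diff(d) < 0)           # monotone decreasing in g
        g_back = (np.cos(4 * np.pi * d / (lam * np.sqrt(6))) + 0.5) / 1.5
        assert np.allclose(g_back, g, atol=1e-6)

    def test_arccos_domain_guard(self, population):
        with pytest.raises(FloatingPointError):
            gcm.linear_distance(population, 0, population.offsets[0], g_max=0.5)


class TestPhasePrecession:
    def test_preferred_phase_values(self):
        lam = 40.0
        d_half = lam * np.sqrt(6) / 6
        assert gcm.preferred_phase(0.0, lam) == pytest.approx(np.pi / 2)
        assert gcm.preferred_phase(d_half, lam) == pytest.approx(
            np.pi * (np.sqrt(6) / 6 + 0.5))   # ~2.853 entering edge
        assert gcm.preferred_phase(-d_half, lam) == pytest.approx(
            np.pi * (0.5 - np.sqrt(6) / 6))   # ~0.289 leaving edge
        with pytest.raises(ValueError):
            gcm.preferred_phase(0.0, -1.0)

    def test_phase_modulation_bounds_and_cycle_mean(self):
        assert gcm.phase_modulation(0.0, 0.0) == pytest.approx(np.exp(1.5))
        t_antiphase = 0.05    # half a 10 Hz cycle
        assert gcm.phase_modulation(t_antiphase, 0.0) == pytest.approx(np.exp(-1.5))
        t = np.linspace(0, 0.1, 20_000, endpoint=False)
        for phi in (0.0, 1.0, 2.5):
            assert gcm.phase_modulation(t, phi).mean() == pytest.approx(
                i0(1.5), rel=1e-4)

    def test_precession_is_late_to_early(self, rate_profile):
        """Per-theta-cycle mean spike phase drifts from late to early as
        the animal moves through a field (pooled over Poisson draws)."""
        # strong field with its peak near the middle of the trajectory
        t_of_peak = rate_profile.t[np.argmax(rate_profile.rates, axis=1)]
        score = rate_profile.rates.sum(axis=1) * np.exp(-(t_of_peak - 1.0) ** 2)
        c = int(np.argmax(score))
        prof = gcm.RateProfile(rate_profile.rates[[c]], rate_profile.dt,
                               rate_profile.theta_freq, rate_profile.scale_factor)
        by_cycle = [[] for _ in range(20)]
        for seed in range(200):
            st = gcm.poisson_spikes(prof, seed)
            cyc = np.minimum(np.floor(st.trains[0] * 10).astype(int), 19)
            ph = 2 * np.pi * np.mod(st.trains[0] * 10.0, 1.0)
            for cc, pp in zip(cyc, ph):
                by_cycle[cc].append(pp)
        means = [np.angle(np.exp(1j * np.array(p)).mean())
                 for p in by_cycle if len(p) > 30]
        assert len(means) >= 8
        # net circular drift across the traversal is a substantial decrease
        steps = [np.angle(np.exp(1j * (b - a)))
                 for a, b in zip(means, means[1:])]
        assert sum(steps) < -0.5
        # and the drift is consistent, not one jump
        assert np.mean(np.array(steps) <= 0.05) > 0.7


class TestSpiking:
    def test_zero_profile_zero_spikes(self):
        prof = gcm.RateProfile(np.zeros((3, 2000)), 1e-3, 10.0, 0.0)
        assert gcm.poisson_spikes(prof, 0).n_spikes == 0

    def test_poisson_mean_count(self):
        prof = gcm.RateProfile(np.full((400, 2000), 10.0), 1e-3, 10.0, 1.0)
        st = gcm.poisson_spikes(prof, 5)
        counts = st.counts()
        # 400 cells x Poisson(20): mean 20, sem = sqrt(20/400) ~ 0.22
        assert counts.mean() == pytest.approx(20.0, abs=1.0)

    def test_seeded_determinism(self, rate_profile):
        a = gcm.poisson_spikes(rate_profile, 9)
        b = gcm.poisson_spikes(rate_profile, 9)
        assert all(np.array_equal(x, y) for x, y in zip(a.trains, b.trains))

    def test_expected_counts_match_integral(self, rate_profile):
        sims = [gcm.poisson_spikes(rate_profile, s).n_spikes for s in range(20)]
        expected = rate_profile.expected_counts().sum()
        assert np.mean(sims) == pytest.approx(expected, rel=0.03)


class TestShuffle:
    def test_counts_preserved_per_cell_cycle(self, ec_spikes, phase_template):
        sh = gcm.shuffle_phases(ec_spikes, phase_template, shuffle_seed=3)
        for a, b in zip(ec_spikes.trains, sh.trains):
            ca = np.bincount(np.floor(a * 10).astype(int), minlength=20)
            cb = np.bincount(np.floor(b * 10).astype(int), minlength=20)
            assert np.array_equal(ca, cb)

    def test_empty_input(self, phase_template):
        from thetarecode.spiketrains import SpikeTrainSet
        empty = SpikeTrainSet([np.empty(0)] * 4, 2.0)
        out = gcm.shuffle_phases(empty, phase_template, shuffle_seed=0)
        assert out.n_spikes == 0

    def test_pooled_phases_converge_to_template(self):
        # high-rate trains so >= 1e5 spikes are redrawn
        prof = gcm.RateProfile(np.full((100, 2000), 500.0), 1e-3, 10.0, 1.0)
        spikes = gcm.poisson_spikes(prof, 1)
        assert spikes.n_spikes > 1e5
        mass = np.exp(np.cos(np.linspace(0, 2 * np.pi, 100, endpoint=False)))
        tpl = gcm.PhaseTemplate(mass)
        sh = gcm.shuffle_phases(spikes, tpl, shuffle_seed=2)
        phases = np.concatenate(sh.phases(10.0))
        # KS distance against the template CDF
        cdf = np.concatenate([[0.0], np.cumsum(tpl.mass)])
        grid = np.linspace(0, 2 * np.pi, 101)
        emp = np.searchsorted(np.sort(phases), grid) / phases.size
        assert np.abs(emp - cdf).max() < 0.01

    def test_shuffle_determinism(self, ec_spikes, phase_template):
        a = gcm.shuffle_phases(ec_spikes, phase_template, shuffle_seed=11)
        b = gcm.shuffle_phases(ec_spikes, phase_template, shuffle_seed=11)
        assert all(np.array_equal(x, y) for x, y in zip(a.trains, b.trains))


class TestLEC:
    def test_envelope_range(self):
        t = np.linspace(0, 0.1, 2000, endpoint=False)
        env = gcm.lec_rate_envelope(t)
        assert env.min() == pytest.approx(0.0, abs=1e-9)
        assert env.max() == pytest.approx(30.0, abs=1e-9)

    def test_counter_cyclical_peak(self):
        t = np.linspace(0, 0.1, 2000, endpoint=False)
        env = gcm.lec_rate_envelope(t, ec_peak_phase=np.pi / 2)
        peak_phase = 2 * np.pi * np.mod(t[np.argmax(env)] * 10.0, 1.0)
        target = np.pi / 2 + np.pi
        assert abs(np.angle(np.exp(1j * (peak_phase - target)))) < 0.3

    def test_identical_mode_determinism(self):
        a = gcm.make_lec_inputs(mode="identical", poisson_seed=5, context_id=0)
        b = gcm.make_lec_inputs(mode="identical", poisson_seed=5, context_id=1)
        assert all(np.array_equal(x, y) for x, y in zip(a.trains, b.trains))
        c = gcm.make_lec_inputs(mode="similar", poisson_seed=5, context_id=0)
        d = gcm.make_lec_inputs(mode="similar", poisson_seed=5, context_id=1)
        assert not all(np.array_equal(x, y) for x, y in zip(c.trains, d.trains))


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), cell=st.integers(0, 19))
def test_rate_in_unit_interval_property(seed, cell):
    pop = gcm.sample_grid_population(20, seed)
    rng = np.random.default_rng(seed)
    pts = rng.uniform(-50, 150, size=(200, 2))
    g = gcm.grid_rate(pop, cell, pts)
    assert np.all(g >= -1e-9) and np.all(g <= 1 + 1e-9)
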