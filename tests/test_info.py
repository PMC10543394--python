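"""Information metrics: Skaggs, Olypher, pattern-separation area, synchrony.

The Skaggs and positional measures are checked against independent
brute-force histogram oracles on small synthetic tables.
"""

import numpy as np
import pytest

from thetarecode.info import (SeparationCurve, early_theta_restriction,
                              holm_sidak, mean_skaggs, one_sample_t,
                              pearson_pair, population_crosscorrelation,
                              positional_information, separation_area,
                              sign_test, skaggs_information)
from thetarecode.spiketrains import SpikeTrainSet


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def skaggs_oracle(counts: np.ndarray) -> float:
    """Bits/spike via the spike-conditional position distribution:
    I = sum_s P(s|spike) log2(P(s|spike)/p_s), uniform occupancy p_s."""
    counts = np.asarray(counts, dtype=float)
    p_s = 1.0 / counts.size
    p_spike = counts / counts.sum()
    nz = p_spike > 0
    return float(np.sum(p_spike[nz] * np.log2(p_spike[nz] / p_s)))


def mutual_information_oracle(k: np.ndarray) -> float:
    """MI(position; value bin) from the joint histogram; k[i, j] is the
    discretized value of trial j at position i (-1 = missing)."""
    pairs = [(i, v) for i in range(k.shape[0]) for v in k[i] if v >= 0]
    pos = np.array([p for p, _ in pairs])
    val = np.array([v for _, v in pairs])
    joint = np.zeros((k.shape[0], val.max() + 1))
    for p, v in zip(pos, val):
        joint[p, v] += 1
    joint /= joint.sum()
    px = joint.sum(1, keepdims=True)
    pv = joint.sum(0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / (px @ pv)[nz])))


# ---------------------------------------------------------------------------
# Pearson / separation area
# ---------------------------------------------------------------------------

class TestPearson:
    def test_identity_and_negation(self, rng):
        x = rng.normal(size=500)
        assert pearson_pair(x, x) == pytest.approx(1.0)
        assert pearson_pair(x, -x) == pytest.approx(-1.0)

    def test_independent_vectors_near_zero(self, rng):
        a, b = rng.normal(size=(2, 8000))
        assert abs(pearson_pair(a, b)) < 0.05

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            pearson_pair(np.ones(10), np.arange(10.0))


class TestSeparationArea:
    def test_identity_curve_zero_area(self):
        r = np.linspace(0.1, 0.5, 6)
        areas = separation_area(SeparationCurve(np.arange(6), r, r))
        assert areas[0] == pytest.approx(0.0)

    def test_triangle_closed_form(self):
        r_in = np.linspace(0.0, 0.4, 9)
        r_out = np.zeros(9)
        areas = separation_area(SeparationCurve(np.arange(9), r_in, r_out))
        assert areas[0] == pytest.approx(0.08)   # integral of r dr on [0, 0.4]

    def test_pointwise_dominance_positive(self, rng):
        r_in = np.sort(rng.uniform(0, 0.8, 8))
        r_out = r_in - rng.uniform(0.01, 0.1, 8)
        areas = separation_area(SeparationCurve(np.arange(8), r_in, r_out))
        assert areas[0] > 0

    def test_needs_two_distances(self):
        with pytest.raises(ValueError):
            separation_area(SeparationCurve([1], [[0.5]], [[0.2]]))


# ---------------------------------------------------------------------------
# Skaggs information
# ---------------------------------------------------------------------------

class TestSkaggs:
    def test_uniform_rate_zero_bits(self, rng):
        pos = [np.repeat(np.arange(8) * 5.0 + 2.5, 50)]
        table = skaggs_information(pos, 40.0)
        assert table["info"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_single_bin_three_bits(self):
        pos = [np.full(64, 12.5)]      # all spikes in 1 of 8 bins
        table = skaggs_information(pos, 40.0)
        assert table["info"].iloc[0] == pytest.approx(3.0)

    def test_minimum_spike_filter(self):
        table = skaggs_information([np.linspace(1, 39, 7)], 40.0)
        assert not table["included"].iloc[0]
        assert np.isnan(table["info"].iloc[0])
        with pytest.raises(ValueError):
            mean_skaggs(table)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            counts = rng.poisson(3.0, size=8)
            if counts.sum() < 8:
                continue
            pos = np.repeat(np.arange(8) * 5.0 + 2.5, counts)
            table = skaggs_information([pos], 40.0)
            assert table["info"].iloc[0] == pytest.approx(
                skaggs_oracle(counts), abs=1e-9)

    def test_non_negative(self, rng):
        pos = [rng.uniform(0, 40, rng.integers(8, 200)) for _ in range(30)]
        table = skaggs_information(pos, 40.0)
        assert (table.loc[table.included, "info"] >= -1e-12).all()


# ---------------------------------------------------------------------------
# positional information
# ---------------------------------------------------------------------------

class TestPositionalInformation:
    def test_position_independent_values_zero(self, rng):
        v = np.tile(rng.normal(size=20), (10, 1))   # same per trial everywhere
        res = positional_information(v, n_value_bins=7)
        assert res["mean"] == pytest.approx(0.0, abs=1e-9)

    def test_deterministic_unique_bins(self):
        # 7 positions, each deterministically in its own value bin
        v = np.tile(np.arange(7.0)[:, None], (1, 12))
        res = positional_information(v, n_value_bins=7)
        assert res["mean"] == pytest.approx(np.log2(7))

    def test_matches_mutual_information_oracle(self, rng):
        v = rng.normal(size=(10, 15))
        res = positional_information(v, n_value_bins=5)
        # rebuild the discretization used by the implementation
        edges = np.linspace(v.min(), v.max(), 6)
        k = np.clip(np.digitize(v, edges) - 1, 0, 4)
        assert res["mean"] == pytest.approx(mutual_information_oracle(k),
                                            abs=1e-9)

    def test_nan_trials_ignored_for_phase(self, rng):
        v = rng.uniform(0, 2 * np.pi, size=(8, 10))
        v[2, :5] = np.nan
        res = positional_information(v, circular=True)
        assert np.isfinite(res["mean"])

    def test_per_spike_normalization(self, rng):
        v = rng.normal(size=(10, 10))
        r1 = positional_information(v, mean_rate=2.0)
        assert r1["per_spike"] == pytest.approx(r1["mean"] / 2.0)


# ---------------------------------------------------------------------------
# synchrony and restriction
# ---------------------------------------------------------------------------

class TestCrossCorrelation:
    def test_duplicated_train_unit_zero_lag(self, rng):
        t = np.sort(rng.uniform(0, 2, 80))
        spikes = SpikeTrainSet([t, t.copy()], 2.0)
        res = population_crosscorrelation(spikes)
        assert res["synchrony_index"] == pytest.approx(1.0)

    def test_independent_near_zero_and_shared_parent_increasing(self, rng):
        def thin(parent, p, r):
            return parent[r.uniform(size=parent.size) < p]
        parent = np.sort(rng.uniform(0, 2, 2000))
        vals = []
        for share in (0.0, 0.5, 1.0):
            r = np.random.default_rng(5)
            trains = []
            for _ in range(2):
                own = np.sort(r.uniform(0, 2, 1000))
                mixed = np.unique(np.concatenate(
                    [thin(parent, share, r), thin(own, 1 - share, r)]))
                trains.append(mixed)
            res = population_crosscorrelation(SpikeTrainSet(trains, 2.0))
            vals.append(res["synchrony_index"])
        assert abs(vals[0]) < 0.1
        assert vals[0] < vals[1] < vals[2]

    def test_single_active_cell_raises(self):
        spikes = SpikeTrainSet([np.array([0.5]), np.empty(0)], 2.0)
        with pytest.raises(ValueError):
            population_crosscorrelation(spikes)


class TestEarlyTheta:
    def test_half_cycle_restriction(self, ec_spikes):
        early = early_theta_restriction(ec_spikes, 10.0)
        ph = np.concatenate(early.phases(10.0))
        assert np.all(ph < np.pi)
        again = early_theta_restriction(early, 10.0)
        assert again.n_spikes == early.n_spikes   # idempotent

    def test_uniform_phases_keep_half(self, rng):
        t = np.sort(rng.uniform(0, 2, 4000))
        spikes = SpikeTrainSet([t], 2.0)
        early = early_theta_restriction(spikes, 10.0)
        assert early.n_spikes / spikes.n_spikes == pytest.approx(0.5, abs=0.05)

    def test_all_late_empty(self):
        t = np.array([0.06, 0.17, 0.28])   # phases 2*pi*0.6 etc, all >= pi
        spikes = SpikeTrainSet([t], 0.3)
        assert early_theta_restriction(spikes, 10.0).n_spikes == 0


class TestStatsWrappers:
    def test_one_sample_t(self, rng):
        x = rng.normal(0.5, 0.1, 20)
        res = one_sample_t(x, 0.0)
        assert res["p"] < 1e-6 and res["mean"] > 0.4

    def test_sign_test(self):
        res = sign_test([1, 2, 3, 4, 5, 0.5, 1.5, 2.5])
        assert res["n_pos"] == 8 and res["p"] == pytest.approx(2 / 256)

    def test_holm_sidak_monotone_and_bounded(self, rng):
        p = np.array([0.001, 0.02, 0.4, 0.8])
        adj = holm_sidak(p)
        assert np.all(adj >= p) and np.all(adj <= 1)
        assert np.all(np.diff(adj[np.argsort(p)]) >= -1e-12)
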