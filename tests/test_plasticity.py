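"""Hebbian weight rule and structural creation/removal on the synapse lattice."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from assemblysim import ModelParams, SynapseTable
from assemblysim.params import DAY
from assemblysim.protocol import AssemblySpec, init_assemblies
from assemblysim.synapses import (
    deletion_rate,
    equilibrium_occupancy,
    hebbian_step,
    run_structural_event_based,
    structural_step,
)


def single_synapse_table(params, w):
    table = SynapseTable.empty(params.n_cells, params.s_max)
    table.occ[0, 1, 0] = True
    table.w[0, 1, 0] = w
    table.t_create[0, 1, 0] = 0.0
    return table


class TestDeletionRate:
    def test_sigmoid_midpoint(self, params):
        assert deletion_rate(params.w_off, params) == pytest.approx(
            (24.0 + 0.03) / 2, abs=1e-9
        )

    def test_extremes(self, params):
        # d(0) = 0.03 + 23.97/(1+exp(-4.9)); d(w_max) = 0.03 + 23.97/(1+exp(9.1))
        assert deletion_rate(0.0, params) == pytest.approx(23.8228, abs=1e-3)
        assert deletion_rate(params.w_max, params) == pytest.approx(0.03268, abs=1e-4)

    def test_strictly_decreasing(self, params):
        w = np.linspace(0, params.w_max, 200)
        d = deletion_rate(w, params)
        assert np.all(np.diff(d) < 0)

    def test_out_of_range_rejected(self, params):
        with pytest.raises(ValueError):
            deletion_rate(-0.01, params)
        with pytest.raises(ValueError):
            deletion_rate(params.w_max + 0.01, params)


class TestHebbianStep:
    def test_soft_bound_at_ceiling(self, small_params):
        table = single_synapse_table(small_params, small_params.w_max)
        v = np.full(12, 0.9)
        hebbian_step(table, v, small_params)
        assert table.w[0, 1, 0] == small_params.w_max

    def test_low_activity_decay_closed_form(self, small_params):
        # both rates low for 2 days -> w * exp(-1) (Euler error ~ dt*rate, tiny)
        table = single_synapse_table(small_params, 0.35)
        v = np.full(12, 0.1)
        factor = (1 - small_params.dt * small_params.delta_decay) ** int(
            2 * DAY / small_params.dt
        )
        # closed form vs the Euler product: indistinguishable at this rate
        assert factor == pytest.approx(np.exp(-1), rel=1e-6)
        for _ in range(1000):
            hebbian_step(table, v, small_params)
        assert table.w[0, 1, 0] == pytest.approx(
            0.35 * (1 - small_params.dt * small_params.delta_decay) ** 1000, rel=1e-12
        )

    def test_ltd_one_step_arithmetic(self, small_params):
        # pre active, post quiet: dw = -0.01 * 0.7 * dt = -7e-4 * dt... per step
        table = single_synapse_table(small_params, 0.7)
        v = np.full(12, 0.1)
        v[1] = 0.9  # presynaptic active
        hebbian_step(table, v, small_params)
        assert table.w[0, 1, 0] == pytest.approx(0.7 - 0.01 * 0.7 * 0.1, abs=1e-15)

    def test_tie_falls_in_ltd_branch(self, small_params):
        table = single_synapse_table(small_params, 0.5)
        v = np.full(12, 0.5)
        hebbian_step(table, v, small_params)
        assert table.w[0, 1, 0] == pytest.approx(0.5 * (1 - 0.01 * 0.1), abs=1e-15)

    @settings(derandomize=True, max_examples=30)
    @given(
        st.floats(0.0, 0.7),
        st.floats(0.001, 0.999),
        st.floats(0.001, 0.999),
    )
    def test_weights_stay_bounded(self, w, v_pre, v_post):
        p = ModelParams(n_cells=12)
        table = single_synapse_table(p, w)
        v = np.full(12, 0.2)
        v[1], v[0] = v_pre, v_post
        for _ in range(20):
            hebbian_step(table, v, p)
        assert 0.0 <= table.w[0, 1, 0] <= p.w_max

    def test_exactly_one_regime_applies(self, small_params):
        # the three regimes partition rate space: step effect matches the
        # analytic one-regime update everywhere on a grid incl. boundaries
        p = small_params
        for v_pre in (0.2, 0.5, 0.8):
            for v_post in (0.2, 0.5, 0.8):
                table = single_synapse_table(p, 0.3)
                v = np.full(12, 0.0)
                v[1], v[0] = v_pre, v_post
                hebbian_step(table, v, p)
                if v_pre > 0.5 and v_post > 0.5:
                    expected = 0.3 + p.dt * p.delta_ltp * (p.w_max - 0.3)
                elif v_pre < 0.5 and v_post < 0.5:
                    expected = 0.3 * (1 - p.dt * p.delta_decay)
                else:
                    expected = 0.3 * (1 - p.dt * p.delta_ltd)
                assert table.w[0, 1, 0] == pytest.approx(expected, abs=1e-15)


class TestStructuralStep:
    def test_zero_dt_is_identity(self, small_params, rng):
        spec = AssemblySpec(groups=[[0, 1, 2]], s_init=4)
        table = init_assemblies(spec, small_params)
        before = table.occ.copy()
        structural_step(table, small_params, 0.0, rng)
        assert np.array_equal(table.occ, before)

    def test_creation_probability_magnitude(self, small_params, rng):
        # per-slot creation probability over one 0.1 s step ~ 1.157e-6
        p_expected = -np.expm1(-small_params.b_per_s * 0.1)
        assert p_expected == pytest.approx(1.1574e-6, rel=1e-3)
        table = SynapseTable.empty(12, 16)
        n_slots = 12 * 11 * 16
        draws = 40000
        created = 0
        for _ in range(draws):
            structural_step(table, small_params, 0.1, rng)
            created += table.n_occupied()
            table = SynapseTable.empty(12, 16)
        mean = created / draws
        expect = n_slots * p_expected
        # 5 sigma Poisson band
        assert abs(mean - expect) < 5 * np.sqrt(expect / draws)

    def test_conservation_when_full(self, small_params, rng):
        spec = AssemblySpec(groups=[list(range(12))], s_init=16)
        table = init_assemblies(spec, small_params)
        structural_step(table, small_params, 100.0, rng)
        assert np.all(table.pair_counts() <= 16)

    def test_diagonal_never_occupied(self, small_params, rng):
        table = SynapseTable.empty(12, 16)
        for _ in range(50):
            structural_step(table, small_params, 1000.0, rng)
        idx = np.arange(12)
        assert not table.occ[idx, idx, :].any()


class TestEquilibriumOccupancy:
    def test_default_value(self, params):
        assert equilibrium_occupancy(params) == pytest.approx(0.64)

    def test_limits(self, params):
        assert equilibrium_occupancy(params.replace(b=1e-12)) == pytest.approx(0.0, abs=1e-9)
        assert equilibrium_occupancy(params.replace(d0=1e-9, d1=1e-10)) == pytest.approx(
            16.0, abs=1e-6
        )

    def test_detailed_balance_of_frozen_simulation(self, rng):
        # freeze weights at w0, run structural dynamics 10 days, compare the
        # final occupancy with s_max * b / (b + d(w0)) within a binomial CI
        p = ModelParams(n_cells=12)
        table = SynapseTable.empty(12, 16)
        # 60 s steps: discrete-chain bias ~0.8%, far inside the CI
        for _ in range(3 * 1440):
            structural_step(table, p, 60.0, rng)
        d_w0 = deletion_rate(p.w0, p)
        p_slot = p.b / (p.b + d_w0)
        n_slots = 12 * 11 * 16
        occ = table.n_occupied()
        sd = np.sqrt(n_slots * p_slot * (1 - p_slot))
        assert abs(occ - n_slots * p_slot) < 4 * sd

    def test_event_based_matches_bernoulli_distribution(self, rng):
        # 4-neuron frozen-weight network: occupancy after 12 h must be
        # distributed identically under both structural schemes
        p = ModelParams(n_cells=4)
        duration = 12 * 3600.0
        n_runs = 500
        counts_b, counts_e = [], []
        for k in range(n_runs):
            tb = SynapseTable.empty(4, 16)
            for _ in range(720):
                structural_step(tb, p, 60.0, rng)
            counts_b.append(tb.n_occupied())
            te = SynapseTable.empty(4, 16)
            run_structural_event_based(te, duration, p, rng)
            counts_e.append(te.n_occupied())
        res = stats.mannwhitneyu(counts_b, counts_e)
        assert res.pvalue > 1e-3
        # and both near the expected equilibrium
        expect = 4 * 3 * 16 * p.b / (p.b + deletion_rate(p.w0, p))
        assert np.mean(counts_b) == pytest.approx(expect, rel=0.15)
        assert np.mean(counts_e) == pytest.approx(expect, rel=0.15)
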