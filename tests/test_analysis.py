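"""Connectivity classes, turnover/persistence, reactivations, completion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from assemblysim import ModelParams, SynapseTable
from assemblysim import analysis
from assemblysim.protocol import AssemblySpec, init_assemblies


@pytest.fixture
def params60():
    return ModelParams(n_cells=60)


class TestClassConnectivity:
    def test_prewired_assembly_stats(self, params60):
        spec = AssemblySpec(groups=[list(range(30))], s_init=8)
        table = init_assemblies(spec, params60)
        cs = analysis.class_connectivity(table, spec.groups)
        assert cs.stats["intra"]["mean_synapses"] == pytest.approx(8.0)
        assert cs.stats["intra"]["mean_weight"] == pytest.approx(0.7)
        assert cs.stats["inter"]["mean_synapses"] == 0.0
        assert cs.stats["control"]["mean_synapses"] == 0.0

    def test_relabeling_invariance(self, params60, rng):
        spec = AssemblySpec(groups=[list(range(10, 40))], s_init=5)
        table = init_assemblies(spec, params60)
        perm = rng.permutation(60)
        table2 = SynapseTable(
            occ=table.occ[np.ix_(perm, perm)],
            w=table.w[np.ix_(perm, perm)],
            t_create=table.t_create[np.ix_(perm, perm)],
        )
        inv = np.argsort(perm)
        groups2 = [[int(inv[i]) for i in spec.groups[0]]]
        a = analysis.class_connectivity(table, spec.groups).stats
        b = analysis.class_connectivity(table2, groups2).stats
        for cls in a:
            if a[cls] is None:
                assert b[cls] is None
                continue
            for key in a[cls]:
                assert b[cls][key] == pytest.approx(a[cls][key], nan_ok=True)

    def test_empty_class_reported_absent(self, params):
        # all neurons grouped: no control pairs exist
        groups = [list(range(params.n_cells))]
        table = SynapseTable.empty(params.n_cells, params.s_max)
        cs = analysis.class_connectivity(table, groups)
        assert cs.stats["control"] is None
        assert cs.stats["inter"] is None

    def test_partition_covers_all_pairs(self, params60):
        masks = analysis.class_masks(60, [list(range(20)), list(range(15, 35))])
        total = sum(m.sum() for m in masks.values())
        assert total == 60 * 59
        overlap_pair = masks["intra"][16, 33]  # both only via different groups?
        # 16 and 33 share group 2 -> intra
        assert overlap_pair


class TestTurnover:
    def make_snaps(self, sets, shape=(2, 2, 4)):
        out = []
        for s in sets:
            occ = np.zeros(shape, dtype=bool)
            for tpl in s:
                occ[tpl] = True
            out.append(occ)
        return out

    def test_counting_example(self):
        # day1 {A,B,C}, day2 {B,C,D}: created 1/3, removed 1/3
        a, b, c, d = (0, 1, 0), (0, 1, 1), (1, 0, 2), (1, 0, 3)
        snaps = self.make_snaps([{a, b, c}, {b, c, d}])
        rep = analysis.turnover_stats(snaps, [0.0, 86400.0])
        assert rep.created_fraction[0] == pytest.approx(1 / 3)
        assert rep.removed_fraction[0] == pytest.approx(1 / 3)

    def test_identical_snapshots_zero_turnover(self):
        a, b = (0, 1, 0), (1, 0, 1)
        snaps = self.make_snaps([{a, b}, {a, b}])
        rep = analysis.turnover_stats(snaps, [0.0, 86400.0])
        assert rep.created_fraction[0] == 0.0
        assert rep.removed_fraction[0] == 0.0

    def test_single_snapshot_rejected(self):
        with pytest.raises(ValueError):
            analysis.turnover_stats([np.zeros((2, 2, 4), bool)], [0.0])

    def test_persistence_non_increasing_and_slot_identity(self):
        # slot removed at t=1.5d and re-created at t=1.6d is NOT persistent
        ref = np.zeros((2, 2, 4), bool)
        ref[0, 1, 0] = ref[0, 1, 1] = ref[1, 0, 0] = True
        events = pd.DataFrame(
            {
                "t": [1.5 * 86400, 1.6 * 86400, 2.5 * 86400],
                "post": [0, 0, 1],
                "pre": [1, 1, 0],
                "slot": [0, 0, 0],
                "kind": [-1, 1, -1],
            }
        )
        times = np.array([0.0, 1.0, 2.0, 3.0]) * 86400
        t, frac = analysis.persistence_curve(ref, 0.0, times, events)
        assert np.all(np.diff(frac) <= 0)
        np.testing.assert_allclose(frac, [1.0, 1.0, 2 / 3, 1 / 3])


class TestDetectReactivations:
    def test_flat_trace_no_events(self):
        t = np.arange(100.0)
        assert analysis.detect_reactivations(t, np.zeros(100)) == []

    def test_square_pulse_single_event(self):
        t = np.arange(100.0)
        trace = ((t >= 20) & (t < 24)).astype(float)
        ev = analysis.detect_reactivations(t, trace, 0.5, 2.0)
        assert len(ev) == 1
        assert ev[0] == (20.0, 24.0)

    def test_three_crossings_counted(self):
        t = np.arange(0, 60, 1.0)
        trace = np.zeros(60)
        for start in (5, 20, 40):
            trace[start : start + 2] = 0.9
        ev = analysis.detect_reactivations(t, trace, 0.5, 1.0)
        assert len(ev) == 3

    def test_min_duration_filters(self):
        t = np.arange(0, 30, 1.0)
        trace = np.zeros(30)
        trace[10] = 0.9  # 1-sample blip = 1 s at this cadence
        assert analysis.detect_reactivations(t, trace, 0.5, 2.0) == []


class TestCorruptPattern:
    def test_zero_fraction_identity(self, rng):
        pat = set(range(30))
        assert analysis.corrupt_pattern(pat, 0.0, range(120), rng) == pat

    @settings(derandomize=True, max_examples=40)
    @given(st.floats(0, 1), st.integers(0, 10_000))
    def test_size_preserved(self, fraction, seed):
        rng = np.random.default_rng(seed)
        pat = set(range(30))
        out = analysis.corrupt_pattern(pat, fraction, range(120), rng)
        assert len(out) == 30

    def test_swap_counts(self, rng):
        pat = set(range(30))
        out = analysis.corrupt_pattern(pat, 0.2, range(120), rng)
        assert len(pat - out) == 6
        assert len(out - pat) == 6

    def test_bad_fraction_rejected(self, rng):
        with pytest.raises(ValueError):
            analysis.corrupt_pattern({0, 1}, 1.5, range(10), rng)


class TestEvaluateCompletion:
    def test_strong_assembly_perfect_at_zero_corruption(self, rng):
        p = ModelParams(n_cells=60)
        spec = AssemblySpec(groups=[list(range(30))], s_init=12)
        table = init_assemblies(spec, p)
        res = analysis.evaluate_completion(
            table, spec.groups, [0.0], p, rng, n_trials=5
        )
        # intra input 29*12*0.7 = 243.6 over inhibition 2.45*30 = 73.5
        assert res.fraction_correct[0] == 1.0
        cur = res.currents[0.0]["pattern"]
        np.testing.assert_allclose(cur, 29 * 12 * 0.7 - 73.5)

    def test_empty_table_all_silent(self, rng):
        p = ModelParams(n_cells=60)
        table = SynapseTable.empty(60, 16)
        pattern = list(range(30))
        res = analysis.evaluate_completion(table, [pattern], [0.0], p, rng, n_trials=3)
        # every neuron classified inactive: errors = |pattern| / n_cells
        assert res.false_negative[0] == pytest.approx(30 / 60)
        assert res.false_positive[0] == 0.0
        assert res.fraction_correct[0] == pytest.approx(0.5)

    def test_quality_non_increasing_in_corruption(self, rng):
        p = ModelParams(n_cells=90)
        spec = AssemblySpec(groups=[list(range(30)), list(range(30, 60))], s_init=10)
        table = init_assemblies(spec, p)
        levels = [0.0, 0.1, 0.2, 0.3, 0.4, 0.5]
        res = analysis.evaluate_completion(
            table, spec.groups, levels, p, rng, n_trials=100
        )
        # monotone trend: allow tiny sampling jitter per adjacent pair
        assert np.all(np.diff(res.fraction_correct) <= 0.01)
        assert res.fraction_correct[0] >= res.fraction_correct[-1]
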