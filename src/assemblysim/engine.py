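"""Time-stepping engine: wires neuron dynamics, plasticity and protocol.

The engine advances the model phase by phase with the compiled kernel
(:mod:`assemblysim._kernel`), records group-mean activity traces,
pair-level connectivity snapshots, slot-level occupancy snapshots and a
synapse creation/removal event log, and guarantees bit-reproducible runs
for a fixed seed.

Randomness is split into named substreams derived from one master seed:
the kernel stream (membrane noise + structural events) and the sensory
pattern stream are independent, so changing how patterns are drawn leaves
the noise sequence untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernel
from .params import ModelParams
from .protocol import (
    AssemblySpec,
    Phase,
    PhaseSchedule,
    init_assemblies,
    sample_sensory_events,
)
from .state import NetworkState
from .synapses import SynapseTable

__all__ = ["RunConfig", "Recorder", "run", "run_retention_experiment"]

_MAX_CHUNK_S = 3600.0  # upper bound on kernel block length, seconds


@dataclass
class RunConfig:
    """Run-level knobs: cadences, seed, output location."""

    seed: int = 0
    record_every: float = 1.0          # activity trace cadence, s
    snapshot_every: float = 3600.0     # pair-level connectivity cadence, s
    occ_snapshot_every: float = 86400.0  # slot-occupancy cadence, s
    structural_on: bool = True
    out_dir: str | None = None

    def validate(self, params: ModelParams) -> None:
        for name in ("record_every", "snapshot_every", "occ_snapshot_every"):
            val = getattr(self, name)
            if val < params.dt:
                raise ValueError(f"{name} must be >= dt")
            if abs(round(val / params.dt) * params.dt - val) > 1e-9:
                raise ValueError(f"{name} must be a multiple of dt")


@dataclass
class Recorder:
    """Everything a run measured, ready for the analysis module."""

    group_names: list
    times: np.ndarray = field(default_factory=lambda: np.empty(0))
    group_rates: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    snap_times: list = field(default_factory=list)
    snap_counts: list = field(default_factory=list)   # (n, n) int synapse counts
    snap_wsum: list = field(default_factory=list)     # (n, n) summed weights
    occ_snap_times: list = field(default_factory=list)
    occ_snaps: list = field(default_factory=list)     # (n, n, s_max) bool
    events: pd.DataFrame = field(default_factory=pd.DataFrame)
    phase_log: list = field(default_factory=list)     # (kind, t_start, t_end)

    def activity_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.group_rates, columns=self.group_names)
        frame.insert(0, "t", self.times)
        return frame

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.activity_frame().to_csv(out / "activity.csv", index=False)
        self.events.to_csv(out / "synapse_events.csv", index=False)
        pd.DataFrame(self.phase_log, columns=["kind", "t_start", "t_end"]).to_csv(
            out / "phases.csv", index=False
        )
        np.savez_compressed(
            out / "connectivity.npz",
            snap_times=np.asarray(self.snap_times),
            snap_counts=np.asarray(self.snap_counts),
            snap_wsum=np.asarray(self.snap_wsum),
            occ_snap_times=np.asarray(self.occ_snap_times),
            occ_snaps=np.asarray(self.occ_snaps, dtype=bool),
        )


def _kernel_seed(seed: int) -> int:
    return int(np.random.SeedSequence([seed, 0x6B65726E]).generate_state(1)[0] % (2**31))


def _pattern_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, 0x70617474]))


def _events_to_arrays(events, dt, n_stim_max):
    starts = np.array([int(round(ev.t_start / dt)) for ev in events], dtype=np.int64)
    ends = np.array([int(round(ev.t_end / dt)) for ev in events], dtype=np.int64)
    amps = np.array([ev.amplitude for ev in events], dtype=float)
    neurons = np.full((len(events), n_stim_max), -1, dtype=np.int32)
    for row, ev in enumerate(events):
        ids = np.asarray(ev.neuron_ids, dtype=np.int32)
        neurons[row, : ids.size] = ids
    return starts, ends, neurons, amps


def _clip_events(starts, ends, neurons, amps, c0, c1):
    """Select events intersecting block [c0, c1) and shift to block-local steps."""
    mask = (starts < c1) & (ends > c0)
    s = np.clip(starts[mask] - c0, 0, None)
    e = np.minimum(ends[mask], c1) - c0
    return s, e, neurons[mask], amps[mask]


class _SynArrays:
    """Lattice arrays shared with the kernel.

    Weights are stored as per-slot base values plus per-pair affine
    transforms (M, C); the true weight of an occupied slot is
    ``M[i, j] * base[i, j, k] + C[i, j]`` (see :mod:`assemblysim._kernel`).
    """

    def __init__(self, table: SynapseTable):
        n, s_max = table.n_cells, table.s_max
        self.occ = table.occ.copy()
        self.base = table.w.copy()
        tc = table.t_create.copy()
        tc[~np.isfinite(tc)] = 0.0
        self.t_create = tc
        self.M = np.ones((n, n))
        self.C = np.zeros((n, n))
        self.s_count = table.occ.sum(axis=2).astype(np.int32)
        self.wbase_sum = (self.base * self.occ).sum(axis=2)
        cap = n * (n - 1) * s_max
        self.post = np.zeros(cap, dtype=np.int32)
        self.pre = np.zeros(cap, dtype=np.int32)
        self.slot = np.zeros(cap, dtype=np.int32)
        post, pre, slot = np.nonzero(table.occ)
        m = post.size
        self.post[:m] = post
        self.pre[:m] = pre
        self.slot[:m] = slot
        self.n = np.array([m], dtype=np.int64)

    def weights(self) -> np.ndarray:
        out = np.empty_like(self.base)
        _kernel.materialize_weights(self.occ, self.base, self.M, self.C, out)
        return out

    def to_table(self) -> SynapseTable:
        table = SynapseTable(
            occ=self.occ.copy(),
            w=self.weights(),
            t_create=np.where(self.occ, self.t_create, np.nan),
        )
        return table


class _EventLog:
    def __init__(self, cap: int = 1 << 18):
        self.t = np.zeros(cap)
        self.post = np.zeros(cap, dtype=np.int32)
        self.pre = np.zeros(cap, dtype=np.int32)
        self.slot = np.zeros(cap, dtype=np.int32)
        self.kind = np.zeros(cap, dtype=np.int8)
        self.n = np.array([0], dtype=np.int64)

    def ensure_headroom(self, needed: int) -> None:
        cap = self.t.shape[0]
        used = int(self.n[0])
        if cap - used >= needed:
            return
        new_cap = max(2 * cap, used + 2 * needed)
        for name in ("t", "post", "pre", "slot", "kind"):
            arr = getattr(self, name)
            grown = np.zeros(new_cap, dtype=arr.dtype)
            grown[:used] = arr[:used]
            setattr(self, name, grown)

    def frame(self) -> pd.DataFrame:
        m = int(self.n[0])
        return pd.DataFrame(
            {
                "t": self.t[:m],
                "post": self.post[:m],
                "pre": self.pre[:m],
                "slot": self.slot[:m],
                "kind": self.kind[:m],
            }
        )


def run(
    schedule: PhaseSchedule,
    params: ModelParams,
    cfg: RunConfig,
    state: NetworkState | None = None,
    table: SynapseTable | None = None,
    groups: list | None = None,
):
    """Advance the full model through ``schedule``.

    Per step: recurrent current (with utilization) from step-start rates
    and weights -> membrane -> global inhibition -> depression or
    adaptation -> new rates -> Hebbian weights -> structural removals and
    creations.  Deterministic given ``cfg.seed``.

    ``groups`` lists the learned/initialized neuron groups: they define the
    recorded group-mean traces (neurons outside any group form the
    ``control`` trace) and are excluded from sensory-phase stimulation.
    Warm-up phases stimulate all neurons.  Phases of kind ``sensory`` or
    ``warmup`` with an empty event list get their random 1 s patterns
    drawn at run time from the pattern substream.

    Returns ``(recorder, final_state, final_table)``.
    """
    cfg.validate(params)
    n = params.n_cells
    state = NetworkState.initial(params) if state is None else state.copy()
    state.validate(params)
    table = SynapseTable.empty(n, params.s_max) if table is None else table.copy()
    table.validate(params)
    groups = [] if groups is None else [list(g) for g in groups]
    schedule.validate(n)

    # group index: listed groups, then one control group for the rest.
    # Overlap neurons are attributed to the first group containing them
    # (trace bookkeeping only).
    group_index = np.full(n, -1, dtype=np.int32)
    for gi, g in enumerate(groups):
        for i in g:
            if group_index[i] < 0:
                group_index[i] = gi
    control = np.flatnonzero(group_index < 0)
    group_names = [f"group{gi}" for gi in range(len(groups))]
    if control.size:
        group_index[control] = len(groups)
        group_names.append("control")
    group_sizes = np.bincount(group_index, minlength=len(group_names)).astype(float)

    dt = params.dt
    total_steps = sum(int(round(p.duration / dt)) for p in schedule.phases)
    rec_stride = int(round(cfg.record_every / dt))
    snap_stride = int(round(cfg.snapshot_every / dt))
    occ_stride = int(round(cfg.occ_snapshot_every / dt))

    rec = np.zeros((total_steps // rec_stride + 1, len(group_names)))
    rec_n = np.array([1], dtype=np.int64)
    for g in range(len(group_names)):
        rec[0, g] = state.v[group_index == g].mean()

    syn = _SynArrays(table)
    log = _EventLog()

    recorder = Recorder(group_names=group_names)
    t0 = state.t

    def snapshot(step: int) -> None:
        recorder.snap_times.append(t0 + step * dt)
        recorder.snap_counts.append(syn.s_count.copy())
        recorder.snap_wsum.append((syn.weights() * syn.occ).sum(axis=2))

    def occ_snapshot(step: int) -> None:
        recorder.occ_snap_times.append(t0 + step * dt)
        recorder.occ_snaps.append(syn.occ.copy())

    snapshot(0)
    occ_snapshot(0)

    _kernel.seed_kernel(_kernel_seed(cfg.seed))
    pat_rng = _pattern_rng(cfg.seed)
    i_inh_arr = np.array([state.i_inh])
    mode = (
        _kernel.SFA_MODE
        if params.adaptation_mode == "spike_frequency_adaptation"
        else _kernel.STD_MODE
    )
    slot_total = n * (n - 1) * params.s_max
    # expected creations per second; removals balance creations near
    # equilibrium, so 2.2x covers both with margin (log grows on overflow)
    events_per_s = slot_total * 2.2 * params.b_per_s

    assembly_ids = sorted({i for g in groups for i in g})
    global_step = 0
    for phase in schedule.phases:
        n_steps_phase = int(round(phase.duration / dt))
        if n_steps_phase == 0:
            continue
        events = phase.events
        if phase.kind in ("sensory", "warmup") and not events:
            eligible = (
                range(n)
                if phase.kind == "warmup"
                else [i for i in range(n) if i not in assembly_ids]
            )
            events = sample_sensory_events(eligible, n_steps_phase * dt, pat_rng)
        n_stim_max = max((len(ev.neuron_ids) for ev in events), default=1)
        ph_starts, ph_ends, ph_neurons, ph_amps = _events_to_arrays(
            events, dt, n_stim_max
        )
        recorder.phase_log.append(
            (phase.kind, t0 + global_step * dt, t0 + (global_step + n_steps_phase) * dt)
        )

        done_phase = 0
        while done_phase < n_steps_phase:
            chunk = min(
                n_steps_phase - done_phase,
                int(round(_MAX_CHUNK_S / dt)),
                snap_stride - (global_step % snap_stride) or snap_stride,
                occ_stride - (global_step % occ_stride) or occ_stride,
            )
            log.ensure_headroom(int(events_per_s * chunk * dt * 3) + 4096)
            s, e, neu, amp = _clip_events(
                ph_starts, ph_ends, ph_neurons, ph_amps, done_phase, done_phase + chunk
            )
            to_do = chunk
            while to_do > 0:
                status, steps = _kernel.run_block(
                    to_do, global_step,
                    state.u, state.v, state.f, state.i_ad, i_inh_arr,
                    syn.occ, syn.base, syn.t_create, syn.M, syn.C,
                    syn.wbase_sum, syn.s_count, syn.n,
                    syn.post, syn.pre, syn.slot,
                    log.t, log.post, log.pre, log.slot, log.kind, log.n,
                    s, e, neu, amp,
                    rec, rec_n, rec_stride, group_index, group_sizes,
                    dt, params.tau, params.w_inh, params.noise_sd,
                    params.tau_relax, params.f_dep,
                    params.alpha_adapt, params.tau_adapt,
                    params.w_max, params.delta_decay, params.delta_ltp,
                    params.delta_ltd,
                    params.b_per_s, params.d0_per_s, params.d1_per_s,
                    params.w_off, params.beta, params.w0,
                    mode, cfg.structural_on,
                )
                global_step += steps
                done_phase += steps
                to_do -= steps
                if status == _kernel.NAN_ABORT:
                    raise RuntimeError(
                        f"non-finite membrane potential at t={t0 + global_step * dt:.1f} s "
                        f"(phase {phase.kind}); aborting instead of clipping"
                    )
                if status == _kernel.EVENT_LOG_FULL:
                    log.ensure_headroom(1 << 16)
                    s, e, neu, amp = _clip_events(
                        ph_starts, ph_ends, ph_neurons, ph_amps,
                        done_phase, done_phase + to_do,
                    )
            if global_step % snap_stride == 0:
                snapshot(global_step)
            if global_step % occ_stride == 0:
                occ_snapshot(global_step)

    if recorder.snap_times[-1] != t0 + global_step * dt:
        snapshot(global_step)
    if recorder.occ_snap_times[-1] != t0 + global_step * dt:
        occ_snapshot(global_step)

    state.i_inh = float(i_inh_arr[0])
    state.t = t0 + global_step * dt
    m = int(rec_n[0])
    recorder.times = t0 + np.arange(m) * cfg.record_every
    recorder.group_rates = rec[:m]
    recorder.events = log.frame()

    final_table = syn.to_table()
    if cfg.out_dir is not None:
        recorder.save(cfg.out_dir)
    return recorder, state, final_table


def run_retention_experiment(
    spec: AssemblySpec,
    cycles,
    params: ModelParams,
    cfg: RunConfig,
):
    """Pre-wired retention driver: init assemblies, cycle sensory/rest.

    ``cycles`` is a list of ``(t_sens, t_rest)`` pairs in seconds.  With an
    empty list only the initialization snapshot is produced.  Returns
    ``(recorder, final_state, final_table)``.
    """
    table = init_assemblies(spec, params)
    phases = []
    for t_sens, t_rest in cycles:
        if t_sens > 0:
            phases.append(Phase("sensory", float(t_sens), []))
        if t_rest > 0:
            phases.append(Phase("rest", float(t_rest), []))
    schedule = PhaseSchedule(phases)
    return run(schedule, params, cfg, table=table, groups=spec.groups)
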