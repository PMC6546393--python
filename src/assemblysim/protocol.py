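"""Stimulation schedules and initial conditions for the three experiment
families: learning from scratch, sensory/rest retention cycling, and
pre-wired assembly experiments.

The simulated day is divided into phases:

* ``warmup`` — a sensory phase run before learning so that structural
  turnover reaches its creation/removal equilibrium.
* ``learning`` — groups of neurons receive strong rectangular stimulation
  (amplitude 200 for 18 s) in round-robin order with 36 s gaps.
* ``sensory`` — background input: every second a fresh random set of 15
  non-assembly neurons is stimulated at amplitude 50.
* ``rest`` — no external input; assemblies reactivate spontaneously.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ModelParams
from .synapses import SynapseTable

LEARNING_AMPLITUDE = 200.0
LEARNING_STIM_S = 18.0
LEARNING_GAP_S = 36.0
SENSORY_AMPLITUDE = 50.0
SENSORY_PATTERN_S = 1.0
SENSORY_PATTERN_SIZE = 15
WARMUP_S = 6 * 3600.0

__all__ = [
    "StimEvent",
    "Phase",
    "PhaseSchedule",
    "AssemblySpec",
    "build_learning_schedule",
    "sample_sensory_events",
    "sample_phase_durations",
    "init_assemblies",
    "build_warmup",
]


@dataclass(frozen=True)
class StimEvent:
    """Rectangular current pulse to a set of neurons, times in seconds."""

    t_start: float
    t_end: float
    neuron_ids: tuple
    amplitude: float

    def __post_init__(self):
        if not self.t_end > self.t_start:
            raise ValueError("StimEvent requires t_end > t_start")


@dataclass
class Phase:
    kind: str  # warmup | learning | sensory | rest
    duration: float
    events: list = field(default_factory=list)

    def __post_init__(self):
        if self.kind not in ("warmup", "learning", "sensory", "rest"):
            raise ValueError(f"unknown phase kind {self.kind!r}")
        if self.duration < 0:
            raise ValueError("phase duration must be non-negative")
        if self.kind == "rest" and self.events:
            raise ValueError("rest phases deliver no stimulation")


@dataclass
class PhaseSchedule:
    """Contiguous sequence of phases; event times are phase-local."""

    phases: list

    @property
    def total_time(self) -> float:
        return float(sum(p.duration for p in self.phases))

    def validate(self, n_cells: int) -> None:
        for phase in self.phases:
            for ev in phase.events:
                if ev.t_start < 0 or ev.t_end > phase.duration + 1e-9:
                    raise ValueError("event outside its phase")
                if any(i < 0 or i >= n_cells for i in ev.neuron_ids):
                    raise ValueError("event targets neuron outside the network")

    def to_frame(self):
        """Tidy event table (global times) for audit/export as CSV."""
        import pandas as pd

        rows = []
        t0 = 0.0
        for pi, phase in enumerate(self.phases):
            rows.append(
                {
                    "phase": pi,
                    "kind": phase.kind,
                    "t_start": t0,
                    "t_end": t0 + phase.duration,
                    "amplitude": 0.0,
                    "neuron_ids": "",
                }
            )
            for ev in phase.events:
                rows.append(
                    {
                        "phase": pi,
                        "kind": f"{phase.kind}:stim",
                        "t_start": t0 + ev.t_start,
                        "t_end": t0 + ev.t_end,
                        "amplitude": ev.amplitude,
                        "neuron_ids": ";".join(str(i) for i in ev.neuron_ids),
                    }
                )
            t0 += phase.duration
        return pd.DataFrame(rows)


@dataclass
class AssemblySpec:
    """Pre-wired assembly layout for retention experiments.

    ``groups`` are lists of neuron-id lists; consecutive groups may share
    ``overlap`` neurons.  Every ordered intra-group pair starts with
    ``s_init`` synapses at weight ``w_init`` (maximal weight by default).
    """

    groups: list
    s_init: int
    w_init: float | None = None  # default: params.w_max

    def __post_init__(self):
        if any(len(g) < 1 for g in self.groups):
            raise ValueError("every group needs at least one neuron")
        if self.s_init < 0:
            raise ValueError("s_init must be non-negative")

    @classmethod
    def overlapping(
        cls, n_groups: int, group_size: int, overlap: int, s_init: int,
        w_init: float | None = None, start: int = 0,
    ) -> "AssemblySpec":
        """Consecutive groups of ``group_size`` sharing ``overlap`` neurons."""
        if overlap >= group_size:
            raise ValueError("overlap must be smaller than the group size")
        groups = []
        base = start
        for _ in range(n_groups):
            groups.append(list(range(base, base + group_size)))
            base += group_size - overlap
        return cls(groups=groups, s_init=s_init, w_init=w_init)


def build_learning_schedule(
    groups, duration: float, params: ModelParams
) -> PhaseSchedule:
    """Round-robin learning phase.

    Each group in turn is stimulated at amplitude 200 for 18 s, followed
    by 36 s without stimulation, then the next group; repeated until
    ``duration`` is exhausted.  Groups must be disjoint.
    """
    flat: list = []
    for g in groups:
        flat.extend(g)
    if len(set(flat)) != len(flat):
        raise ValueError("learning groups must be disjoint")
    events = []
    t = 0.0
    gi = 0
    cycle = LEARNING_STIM_S + LEARNING_GAP_S
    while t + LEARNING_STIM_S <= duration + 1e-9:
        events.append(
            StimEvent(
                t_start=t,
                t_end=t + LEARNING_STIM_S,
                neuron_ids=tuple(sorted(groups[gi])),
                amplitude=LEARNING_AMPLITUDE,
            )
        )
        gi = (gi + 1) % len(groups)
        t += cycle
    return PhaseSchedule([Phase("learning", duration, events)])


def sample_sensory_events(
    eligible, duration: float, rng: np.random.Generator
) -> list:
    """Back-to-back 1 s patterns of 15 eligible neurons at amplitude 50.

    ``eligible`` must exclude all learned/initialized assembly neurons, so
    random background input cannot accidentally cue a stored pattern.
    """
    eligible = np.asarray(sorted(eligible), dtype=int)
    if eligible.size < SENSORY_PATTERN_SIZE:
        raise ValueError(
            f"need at least {SENSORY_PATTERN_SIZE} eligible neurons, "
            f"got {eligible.size}"
        )
    events = []
    n_events = int(np.floor(duration / SENSORY_PATTERN_S + 1e-9))
    for k in range(n_events):
        chosen = rng.choice(eligible, size=SENSORY_PATTERN_SIZE, replace=False)
        events.append(
            StimEvent(
                t_start=k * SENSORY_PATTERN_S,
                t_end=(k + 1) * SENSORY_PATTERN_S,
                neuron_ids=tuple(sorted(int(i) for i in chosen)),
                amplitude=SENSORY_AMPLITUDE,
            )
        )
    return events


def sample_phase_durations(
    mode: str,
    mean_sens: float,
    mean_rest: float,
    n_cycles: int,
    rng: np.random.Generator,
) -> list:
    """Alternating (sensory, rest) duration list for ``n_cycles`` cycles.

    ``exponential``: i.i.d. exponential with the stated means (post-learning
    retention).  ``truncated_normal``: normal with sd = 0.25 * mean,
    truncated at zero (pre-wired assembly experiments).
    """
    if mean_sens <= 0 or mean_rest <= 0:
        raise ValueError("phase duration means must be positive")
    if mode not in ("exponential", "truncated_normal"):
        raise ValueError(f"unknown duration mode {mode!r}")
    out = []
    for _ in range(n_cycles):
        for mean in (mean_sens, mean_rest):
            if mode == "exponential":
                d = rng.exponential(mean)
            else:
                d = -1.0
                while d <= 0:
                    d = rng.normal(mean, 0.25 * mean)
            out.append(float(d))
    return out


def init_assemblies(
    spec: AssemblySpec, params: ModelParams, rng: np.random.Generator | None = None
) -> SynapseTable:
    """Pre-wire strongly connected assemblies.

    Every ordered intra-group pair (i != j) receives ``s_init`` occupied
    slots (slots 0..s_init-1) at weight ``w_init``.  Pairs inside an
    overlap region belong to several groups but still receive at most
    ``s_init`` synapses (idempotent initialization).
    """
    if spec.s_init > params.s_max:
        raise ValueError("s_init exceeds s_max")
    w_init = params.w_max if spec.w_init is None else spec.w_init
    if not 0 <= w_init <= params.w_max:
        raise ValueError("w_init outside [0, w_max]")
    table = SynapseTable.empty(params.n_cells, params.s_max)
    for group in spec.groups:
        ids = np.asarray(group, dtype=int)
        if ids.min() < 0 or ids.max() >= params.n_cells:
            raise ValueError("group contains neuron id outside the network")
        for i in ids:
            for j in ids:
                if i == j:
                    continue
                table.occ[i, j, : spec.s_init] = True
                table.w[i, j, : spec.s_init] = w_init
                table.t_create[i, j, : spec.s_init] = 0.0
    return table


def build_warmup(duration: float = WARMUP_S) -> PhaseSchedule:
    """Single sensory phase run before learning (default 6 h).

    Brings the empty lattice to the creation/removal equilibrium of about
    ``s_max * b / (b + d0)`` synapses per pair.  Events are sampled at run
    time by the engine (all neurons eligible, no groups learned yet).
    """
    return PhaseSchedule([Phase("warmup", float(duration), [])])
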