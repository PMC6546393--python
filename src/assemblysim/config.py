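"""Experiment configuration and deterministic test fixtures.

A config file (YAML or JSON) has up to three top-level sections --
``params``, ``experiment``, ``run`` -- each a flat mapping.  Unknown keys
anywhere are rejected with a list of every offending key.  An empty file
resolves to all defaults (a plain warm-up run).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .engine import RunConfig
from .params import ModelParams, ParamError
from .protocol import (
    AssemblySpec,
    Phase,
    PhaseSchedule,
    build_learning_schedule,
    init_assemblies,
    sample_phase_durations,
    WARMUP_S,
)
from .state import NetworkState
from .synapses import SynapseTable

__all__ = ["ExperimentConfig", "load_config", "make_fixture"]

_EXPERIMENT_KEYS = {
    "kind",            # "learning" | "retention"
    "groups",          # explicit neuron-id lists (optional)
    "fixture",         # {kind, scale, s_init, n_controls} (optional)
    "warmup",          # seconds
    "learning_duration",  # seconds
    "phase_mode",      # exponential | truncated_normal
    "mean_sens",       # seconds
    "mean_rest",       # seconds
    "n_cycles",
    "cycles",          # explicit [[t_sens, t_rest], ...] seconds
}
_RUN_KEYS = {f.name for f in dataclasses.fields(RunConfig)}


@dataclass
class ExperimentConfig:
    """Fully resolved experiment: parameters, layout, phase plan, run knobs."""

    params: ModelParams = field(default_factory=ModelParams)
    kind: str = "learning"
    groups: list = field(default_factory=list)
    fixture: dict | None = None
    warmup: float = WARMUP_S
    learning_duration: float = 9 * 3600.0
    phase_mode: str = "exponential"
    mean_sens: float = 4 * 3600.0
    mean_rest: float = 2 * 3600.0
    n_cycles: int = 0
    cycles: list | None = None
    run: RunConfig = field(default_factory=RunConfig)

    def manifest(self) -> dict:
        out = {
            "params": self.params.to_dict(),
            "experiment": {
                "kind": self.kind,
                "groups": [list(map(int, g)) for g in self.groups],
                "fixture": self.fixture,
                "warmup": self.warmup,
                "learning_duration": self.learning_duration,
                "phase_mode": self.phase_mode,
                "mean_sens": self.mean_sens,
                "mean_rest": self.mean_rest,
                "n_cycles": self.n_cycles,
                "cycles": self.cycles,
            },
            "run": dataclasses.asdict(self.run),
        }
        return out

    # -- materialization -------------------------------------------------
    def resolve_layout(self):
        """Return (groups, initial_table_or_None) after applying a fixture."""
        if self.fixture is not None:
            fx = dict(self.fixture)
            kind = fx.pop("kind")
            _, _, table, groups = make_fixture(
                kind, params=self.params, seed=self.run.seed, **fx
            )
            if self.kind == "learning":
                table = None  # learned from scratch; fixture fixes the layout
            return groups, table
        groups = [list(map(int, g)) for g in self.groups]
        if self.kind == "retention" and groups:
            spec = AssemblySpec(groups=groups, s_init=8)
            return groups, init_assemblies(spec, self.params)
        return groups, None

    def build_schedule(self) -> PhaseSchedule:
        phases = []
        if self.kind == "learning":
            if self.warmup > 0:
                phases.append(Phase("warmup", float(self.warmup), []))
            if self.learning_duration > 0:
                learn = build_learning_schedule(
                    self.groups_resolved(), self.learning_duration, self.params
                )
                phases.extend(learn.phases)
        cycles = self.cycles
        if cycles is None and self.n_cycles > 0:
            rng = np.random.default_rng(
                np.random.SeedSequence([int(self.run.seed), 0x70686173])
            )
            durations = sample_phase_durations(
                self.phase_mode, self.mean_sens, self.mean_rest, self.n_cycles, rng
            )
            cycles = list(zip(durations[0::2], durations[1::2]))
        for t_sens, t_rest in cycles or []:
            if t_sens > 0:
                phases.append(Phase("sensory", float(t_sens), []))
            if t_rest > 0:
                phases.append(Phase("rest", float(t_rest), []))
        return PhaseSchedule(phases)

    def groups_resolved(self) -> list:
        groups, _ = self.resolve_layout()
        return groups


def _reject_unknown(section: str, data: dict, allowed: set) -> list:
    return [f"{section}.{key}" for key in data if key not in allowed]


def load_config(path: str | Path) -> ExperimentConfig:
    """Parse and validate a config file; all defaults materialized."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ParamError(f"{path}: top level must be a mapping")
    bad = _reject_unknown("", raw, {"params", "experiment", "run"})
    params_d = raw.get("params") or {}
    exp_d = raw.get("experiment") or {}
    run_d = raw.get("run") or {}
    bad += _reject_unknown("experiment", exp_d, _EXPERIMENT_KEYS)
    bad += _reject_unknown("run", run_d, _RUN_KEYS)
    try:
        params = ModelParams.from_dict(params_d)
    except ParamError as exc:
        raise ParamError(f"{path}: {exc}") from exc
    if bad:
        raise ParamError(f"{path}: unknown keys: " + ", ".join(sorted(bad)))
    cfg = ExperimentConfig(params=params, run=RunConfig(**run_d))
    for key, val in exp_d.items():
        setattr(cfg, key, val)
    if cfg.kind not in ("learning", "retention"):
        raise ParamError(f"{path}: experiment.kind must be learning or retention")
    return cfg


def save_config(cfg: ExperimentConfig, path: str | Path) -> None:
    path = Path(path)
    manifest = cfg.manifest()
    if path.suffix == ".json":
        path.write_text(json.dumps(manifest, indent=2))
    else:
        path.write_text(yaml.safe_dump(manifest, sort_keys=False))


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def make_fixture(
    kind: str,
    scale: int = 30,
    seed: int = 0,
    s_init: int | None = None,
    n_controls: int | None = None,
    overlap: int | None = None,
    params: ModelParams | None = None,
):
    """Deterministic miniature networks for tests and retention experiments.

    Kinds (``scale`` is the neurons-per-group count):

    * ``background_equilibrium`` — ``scale`` unconnected neurons, empty
      lattice, no groups.
    * ``single_assembly`` — one group pre-wired at ``s_init`` (default 8)
      synapses per connection at maximal weight, plus ``scale`` controls.
    * ``two_overlapping`` — two groups sharing ``overlap`` neurons
      (default 5), pre-wired at ``s_init`` (default 12), plus controls.
    * ``three_learned`` — three disjoint groups plus ``5 * scale``
      controls (240 neurons at the reference scale 30); pre-wired at
      ``s_init`` (default 8) as a post-learning analogue.

    Returns ``(params, state, table, groups)``.
    """
    if scale < 1:
        raise ValueError("scale must be at least 1 neuron per group")
    base = ModelParams() if params is None else params

    if kind == "background_equilibrium":
        n = scale
        groups: list = []
        spec = None
    elif kind == "single_assembly":
        nc = scale if n_controls is None else n_controls
        n = scale + nc
        groups = [list(range(scale))]
        spec = AssemblySpec(groups=groups, s_init=8 if s_init is None else s_init)
    elif kind == "two_overlapping":
        ov = 5 if overlap is None else overlap
        if ov >= scale:
            raise ValueError("overlap must be smaller than the group size")
        nc = max(15, scale // 2) if n_controls is None else n_controls
        g1 = list(range(scale))
        g2 = list(range(scale - ov, 2 * scale - ov))
        n = 2 * scale - ov + nc
        groups = [g1, g2]
        spec = AssemblySpec(groups=groups, s_init=12 if s_init is None else s_init)
    elif kind == "three_learned":
        nc = 5 * scale if n_controls is None else n_controls
        n = 3 * scale + nc
        groups = [list(range(g * scale, (g + 1) * scale)) for g in range(3)]
        spec = AssemblySpec(groups=groups, s_init=8 if s_init is None else s_init)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")

    fixture_params = base.replace(n_cells=n)
    state = NetworkState.initial(fixture_params)
    if spec is None:
        table = SynapseTable.empty(n, fixture_params.s_max)
    else:
        table = init_assemblies(spec, fixture_params)
    return fixture_params, state, table, groups
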