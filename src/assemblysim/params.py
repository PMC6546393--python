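"""Model parameters for the assembly-maintenance network.

All quantities are kept in SI-ish units: time in seconds, rates in 1/s,
currents and weights in the dimensionless units of the rate model.  The
structural-plasticity rates ``b``, ``d0`` and ``d1`` are conventionally
quoted per day; here they are stored per day as well (the integrator
converts to per-second internally) so that configuration files read like
the literature.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

DAY = 86400.0  # seconds

#: Fields that are derived from ``w_max`` unless explicitly overridden.
_DERIVED = {"w_inh": 3.5, "w_off": 0.35}


class ParamError(ValueError):
    """Raised when a parameter set violates a model invariant."""


@dataclass(frozen=True)
class ModelParams:
    """Complete parameter set of the neuron, plasticity and adaptation model.

    Parameters
    ----------
    tau:
        Membrane time constant of the rate units, seconds.
    n_cells:
        Number of neurons in the network.
    s_max:
        Number of potential synaptic locations per ordered neuron pair.
    w_max:
        Weight scale; maximal (soft-bound) synaptic weight.
    w_inh:
        Inhibitory coupling weight of the global inhibitory current,
        ``3.5 * w_max`` by default.
    noise_sd:
        Standard deviation of the per-neuron Gaussian noise current drawn
        once per Euler step.
    b:
        Synapse creation rate at a vacant potential location, per day.
    d0, d1:
        Deletion rates at zero and at maximal weight, per day.
    w_off, beta:
        Offset and steepness of the weight-dependent deletion sigmoid;
        ``w_off = 0.35 * w_max`` by default.
    w0:
        Weight at which a newly created synapse starts.
    delta_decay:
        Weight decay rate when both neurons are inactive, per second
        (default ``1 / (2 days)``).
    delta_ltp, delta_ltd:
        Potentiation / depression rates of the Hebbian rule, per second.
    tau_relax, f_dep:
        Recovery time constant (s) and utilization rate (1/s) of
        short-term depression.
    alpha_adapt, tau_adapt:
        Strength and time constant (s) of spike-frequency adaptation.
    dt:
        Forward-Euler integration step, seconds.
    adaptation_mode:
        ``"short_term_depression"`` (default) or
        ``"spike_frequency_adaptation"``.  With spike-frequency adaptation
        the utilization variable is pinned at 1.
    """

    tau: float = 0.155
    n_cells: int = 240
    s_max: int = 16
    w_max: float = 0.7
    w_inh: float | None = None
    noise_sd: float = 1.5
    b: float = 1.0
    d0: float = 24.0
    d1: float = 0.03
    w_off: float | None = None
    beta: float = 20.0
    w0: float = 0.001
    delta_decay: float = 1.0 / (2.0 * DAY)
    delta_ltp: float = 0.1
    delta_ltd: float = 0.01
    tau_relax: float = 5.0
    f_dep: float = 1.0
    alpha_adapt: float = 33.0
    tau_adapt: float = 5.0
    dt: float = 0.1
    adaptation_mode: str = "short_term_depression"

    def __post_init__(self) -> None:
        # materialize derived couplings unless explicitly overridden
        if self.w_inh is None:
            object.__setattr__(self, "w_inh", _DERIVED["w_inh"] * self.w_max)
        if self.w_off is None:
            object.__setattr__(self, "w_off", _DERIVED["w_off"] * self.w_max)
        self._validate()

    def _validate(self) -> None:
        positive = (
            "tau", "w_max", "w_inh", "noise_sd", "b", "d0", "d1", "beta",
            "w0", "delta_decay", "delta_ltp", "delta_ltd", "tau_relax",
            "f_dep", "tau_adapt", "dt",
        )
        errors = []
        for name in positive:
            if not getattr(self, name) > 0:
                errors.append(f"{name} must be strictly positive")
        if self.n_cells < 1:
            errors.append("n_cells must be >= 1")
        if self.s_max < 1:
            errors.append("s_max must be >= 1")
        if not self.dt < self.tau:
            errors.append("dt must be smaller than the membrane time constant tau")
        if not (0 < self.w0 < self.w_off < self.w_max):
            errors.append("need 0 < w0 < w_off < w_max")
        if not self.d1 < self.d0:
            errors.append("deletion rate at maximal weight (d1) must be below d0")
        if self.adaptation_mode not in (
            "short_term_depression",
            "spike_frequency_adaptation",
        ):
            errors.append(f"unknown adaptation_mode {self.adaptation_mode!r}")
        if self.alpha_adapt < 0:
            errors.append("alpha_adapt must be non-negative")
        if errors:
            raise ParamError("; ".join(errors))

    # -- derived helpers -------------------------------------------------
    @property
    def b_per_s(self) -> float:
        return self.b / DAY

    @property
    def d0_per_s(self) -> float:
        return self.d0 / DAY

    @property
    def d1_per_s(self) -> float:
        return self.d1 / DAY

    def replace(self, **overrides: Any) -> "ModelParams":
        """Return a copy with ``overrides`` applied.

        If ``w_max`` is overridden while ``w_inh`` / ``w_off`` are not,
        the latter are re-derived from the new ``w_max``.
        """
        current = dataclasses.asdict(self)
        if "w_max" in overrides:
            for name in _DERIVED:
                if name not in overrides:
                    current[name] = None  # re-derive in __post_init__
        current.update(overrides)
        return ModelParams(**current)

    # -- (de)serialisation ----------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParamError(
                "unknown parameter keys: " + ", ".join(sorted(unknown))
            )
        base: dict[str, Any] = dict(data)
        if "w_max" in base:
            for name in _DERIVED:
                base.setdefault(name, None)
        return cls(**base)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "ModelParams":
        path = Path(path)
        data = yaml.safe_load(path.read_text()) or {}
        if not isinstance(data, dict):
            raise ParamError(f"{path} does not contain a parameter mapping")
        return cls.from_dict(data)
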