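"""Dynamical state of the rate network at a single instant."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParams


@dataclass
class NetworkState:
    """Membrane potentials, rates and adaptation variables of all neurons.

    Attributes
    ----------
    u:
        Membrane potential per neuron (dimensionless current units).
    v:
        Firing rate per neuron, in the open interval (0, 1); always the
        logistic image of ``u`` (plus the adaptation current when
        spike-frequency adaptation is active).
    i_inh:
        Global inhibitory current, one value shared by all neurons.
    f:
        Short-term-depression utilization factor per *presynaptic* neuron,
        in (0, 1].  Pinned at 1 under spike-frequency adaptation.
    i_ad:
        Spike-frequency-adaptation current per neuron (non-positive).
    t:
        Simulation time in seconds.
    """

    u: np.ndarray
    v: np.ndarray
    i_inh: float
    f: np.ndarray
    i_ad: np.ndarray
    t: float = 0.0

    @classmethod
    def initial(cls, params: ModelParams) -> "NetworkState":
        """Quiescent initial condition: u=0 (hence v=0.5), i_inh=0, f=1, i_ad=0."""
        n = params.n_cells
        return cls(
            u=np.zeros(n),
            v=np.full(n, 0.5),
            i_inh=0.0,
            f=np.ones(n),
            i_ad=np.zeros(n),
            t=0.0,
        )

    def copy(self) -> "NetworkState":
        return NetworkState(
            u=self.u.copy(),
            v=self.v.copy(),
            i_inh=float(self.i_inh),
            f=self.f.copy(),
            i_ad=self.i_ad.copy(),
            t=float(self.t),
        )

    def validate(self, params: ModelParams) -> None:
        n = params.n_cells
        for name in ("u", "v", "f", "i_ad"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ValueError(f"state.{name} has shape {arr.shape}, expected ({n},)")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("non-finite membrane potential")
        if np.any(self.f <= 0) or np.any(self.f > 1):
            raise ValueError("utilization factor f must lie in (0, 1]")
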