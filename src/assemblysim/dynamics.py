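"""Single-step updates of the neuron-level dynamics.

These are the reference (plain NumPy) semantics of one forward-Euler step
of the rate model:

.. math::

    \\tau \\dot u_i = -u_i + \\sum_j \\sum_k f_j w_{ijk} v_j
                     + I_{inh} + I_{stim,i} + I_{noise,i} (+ I_{ad,i})

with logistic gain ``v = 1 / (1 + exp(-u))``, a single global inhibitory
current driven by the summed rates, short-term depression of presynaptic
utilization, and (optionally) a spike-frequency-adaptation current.

The long-run engine (:mod:`assemblysim.engine`) executes the same update
order in a compiled kernel; these functions define the behaviour it must
reproduce and are used directly for small networks and in tests.
"""

from __future__ import annotations

import numpy as np

from .params import ModelParams
from .state import NetworkState

__all__ = [
    "firing_rate",
    "update_membrane",
    "update_inhibition",
    "update_short_term_depression",
    "update_adaptation",
    "step",
]


def firing_rate(u):
    """Logistic gain function mapping potential to rate in (0, 1).

    Accepts scalars or arrays; raises on non-finite input.
    """
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("non-finite membrane potential passed to firing_rate")
    out = 1.0 / (1.0 + np.exp(-u))
    return out if out.ndim else float(out)


def _check_shape(state: NetworkState, arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if arr.shape != state.u.shape:
        raise ValueError(
            f"{name} has shape {arr.shape}, expected {state.u.shape}"
        )
    return arr


def update_membrane(
    state: NetworkState,
    params: ModelParams,
    recurrent_current: np.ndarray,
    i_stim: np.ndarray,
    noise: np.ndarray,
) -> NetworkState:
    """Euler step of the membrane equation (in place on ``state.u``).

    ``recurrent_current`` must already include utilization factors and all
    synaptic weights, i.e. equal ``sum_j f_j (sum_k w_ijk) v_j``.  The
    noise is drawn externally so that seeding is the caller's concern.
    Under spike-frequency adaptation the adaptation current ``i_ad`` is
    added to the summed input.
    """
    rec = _check_shape(state, recurrent_current, "recurrent_current")
    stim = _check_shape(state, i_stim, "i_stim")
    noi = _check_shape(state, noise, "noise")
    total = rec + state.i_inh + stim + noi
    if params.adaptation_mode == "spike_frequency_adaptation":
        total = total + state.i_ad
    state.u += (params.dt / params.tau) * (-state.u + total)
    return state


def update_inhibition(state: NetworkState, params: ModelParams) -> NetworkState:
    """Euler step of the global inhibitory current.

    ``tau dI_inh/dt = -I_inh - w_inh * sum_i v_i``; the sum runs over all
    neurons (including the postsynaptic one) and the same current is
    delivered to every neuron.
    """
    drive = -state.i_inh - params.w_inh * float(np.sum(state.v))
    state.i_inh = state.i_inh + (params.dt / params.tau) * drive
    return state


def update_short_term_depression(
    state: NetworkState, params: ModelParams
) -> NetworkState:
    """Euler step of the presynaptic utilization factor.

    ``df_i/dt = (1 - f_i)/tau_relax - F f_i v_i``.  One factor per
    presynaptic neuron; it multiplies all its outgoing synapses in the
    recurrent-current computation.  No-op (f pinned at 1) when the model
    runs with spike-frequency adaptation.
    """
    if params.adaptation_mode == "spike_frequency_adaptation":
        return state
    if np.any(state.f <= 0) or np.any(state.f > 1):
        raise ValueError("utilization factor outside (0, 1]")
    df = (1.0 - state.f) / params.tau_relax - params.f_dep * state.f * state.v
    state.f += params.dt * df
    return state


def update_adaptation(state: NetworkState, params: ModelParams) -> NetworkState:
    """Euler step of the adaptation current.

    ``tau_adapt dI_ad/dt = -I_ad - alpha * v_i``; the current enters the
    membrane equation as an additional input, shifting the gain function.
    """
    if params.adaptation_mode != "spike_frequency_adaptation":
        return state
    di = -state.i_ad - params.alpha_adapt * state.v
    state.i_ad += (params.dt / params.tau_adapt) * di
    return state


def step(
    state: NetworkState,
    params: ModelParams,
    weight_sum: np.ndarray,
    i_stim: np.ndarray,
    noise: np.ndarray,
) -> NetworkState:
    """One full neural step with pinned update order.

    Order: recurrent current from step-start rates -> membrane ->
    depression or adaptation (step-start rates) -> recompute rates ->
    global inhibition from the *fresh* rates.  The sequential
    (Gauss-Seidel) placement of the inhibition update matters beyond
    O(dt): with dt/tau ~ 0.65, integrating the inhibitory feedback from
    step-start rates makes the quiescent network an unstable discrete map
    (collective relaxation oscillations); feeding it the freshly computed
    rates is stable at the model's step size.  ``weight_sum[i, j]`` is the
    summed weight of all synapses from j onto i.
    """
    sfa = params.adaptation_mode == "spike_frequency_adaptation"
    recurrent = weight_sum @ (state.f * state.v)
    update_membrane(state, params, recurrent, i_stim, noise)
    # state.v still holds the step-start rates here: depression and
    # adaptation integrate the step-start activity
    update_adaptation(state, params)
    update_short_term_depression(state, params)
    state.v = firing_rate(state.u + state.i_ad) if sfa else firing_rate(state.u)
    update_inhibition(state, params)
    state.t += params.dt
    return state
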