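"""Mean-field theory of intra-assembly connectivity.

During a sensory phase an assembly's neurons are quiet, so every
intra-assembly weight decays exponentially from the ceiling,
``w(t) = w_max exp(-delta_decay t)``.  Feeding this trajectory through the
weight-dependent removal hazard ``d(w)`` yields the survival probability
of a pre-existing synapse,

    s(t) = exp(-Integral_0^t d(w(tau)) dtau),

which has no closed form (the hazard is sigmoidal in w) and is evaluated
by adaptive quadrature.  Around the decaying skeleton, small new synapses
are created at vacant locations and removed at ~d0; their number is
approximated by the creation/removal equilibrium

    S_small(t) = b/(d0+b) * (s_max - S0 s(t)).

A rest phase re-potentiates every surviving synapse to w_max (assemblies
reactivate) and stabilizes synapses created during the rest phase itself.
One full sensory+rest cycle then changes the expected synapse number per
connection by

    Delta S = s_max (1 - gamma) - S0 (1 - gamma s(t_sens)),
    gamma(t_rest) = d0/(d0+b) * exp(-b t_rest),

with stationary point  S* = s_max (1 - gamma) / (1 - gamma s(t_sens)).

Reactivation itself requires that recurrent excitation between two
assembly neurons, S0 s(t) w(t), still exceeds the inhibitory coupling
w_inh; the latest time this holds, t_max, solves
``exp(-delta_decay t) s(t) = w_inh / (w_max S0)``.

All functions are deterministic pure functions; time arguments are in
seconds unless noted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq

from .params import DAY, ModelParams
from .synapses import deletion_rate

__all__ = [
    "weight_decay",
    "survival_probability",
    "small_synapse_count",
    "total_synapse_count",
    "t_max",
    "gamma_rest",
    "delta_S_cycle",
    "stationary_S",
    "phase_diagram",
    "sustainable",
]

_QUAD_RTOL = 1e-9
_ROOT_XTOL = 1e-3  # seconds


def weight_decay(t, params: ModelParams):
    """Intra-assembly weight during a sensory phase: w_max * exp(-delta_decay t)."""
    return params.w_max * np.exp(-params.delta_decay * np.asarray(t, dtype=float))


def _hazard_per_s(t: float, params: ModelParams) -> float:
    return deletion_rate(weight_decay(t, params), params) / DAY


def survival_probability(t, params: ModelParams):
    """Probability that a synapse at the ceiling at t=0 survives until t.

    ``s(t) = exp(-int_0^t d(w(tau)) dtau)`` by adaptive quadrature
    (relative tolerance 1e-9); vectorizes over t.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("survival_probability needs t >= 0")
    out = np.empty_like(t_arr)
    for i, ti in enumerate(t_arr):
        if ti == 0:
            out[i] = 1.0
            continue
        integral, err = quad(
            _hazard_per_s, 0.0, ti, args=(params,),
            epsrel=_QUAD_RTOL, epsabs=0.0, limit=200,
        )
        if not np.isfinite(integral) or (integral > 0 and err / integral > 1e-6):
            raise RuntimeError(
                f"hazard quadrature failed at t={ti}: integral={integral}, err={err}"
            )
        out[i] = np.exp(-integral)
    return out if np.ndim(t) else float(out[0])


def small_synapse_count(t, S0: float, params: ModelParams):
    """Equilibrium count of small background synapses during decay.

    ``S_small(t) = b/(d0+b) * (s_max - S0 s(t))`` — creations at vacant
    locations balanced against removal at ~d0.
    """
    s = survival_probability(t, params)
    return params.b / (params.d0 + params.b) * (params.s_max - S0 * np.asarray(s))


def total_synapse_count(t, S0: float, params: ModelParams):
    """Predicted synapses per connection during a pure sensory phase:
    surviving originals plus equilibrated small synapses."""
    s = np.asarray(survival_probability(t, params))
    return S0 * s + params.b / (params.d0 + params.b) * (params.s_max - S0 * s)


def t_max(S0: float, params: ModelParams, t_upper: float = 100 * DAY):
    """Latest reactivation time: largest t with S0 s(t) w(t) >= w_inh.

    Returns ``None`` when the condition already fails at t=0
    (``S0 w_max <= w_inh``).  The left side is strictly decreasing, so the
    crossing is bracketed and found by Brent's method to 1e-3 s.
    """
    if S0 <= 0:
        raise ValueError("S0 must be positive")
    target = params.w_inh / (params.w_max * S0)

    def excess(t: float) -> float:
        return float(
            np.exp(-params.delta_decay * t) * survival_probability(t, params) - target
        )

    if excess(0.0) <= 0:
        return None
    if excess(t_upper) > 0:
        raise RuntimeError("t_max bracket too small; raise t_upper")
    return float(brentq(excess, 0.0, t_upper, xtol=_ROOT_XTOL))


def gamma_rest(t_rest, params: ModelParams):
    """gamma(t_rest) = d0/(d0+b) * exp(-b t_rest): fraction of locations
    still vacant at the end of a rest phase, out of those not carrying a
    stabilized synapse."""
    t_rest = np.asarray(t_rest, dtype=float)
    out = params.d0 / (params.d0 + params.b) * np.exp(-params.b_per_s * t_rest)
    return out if out.ndim else float(out)


def delta_S_cycle(S0, t_rest, t_sens, params: ModelParams):
    """Expected change in synapses per connection over one sensory+rest cycle."""
    gamma = gamma_rest(t_rest, params)
    s = survival_probability(t_sens, params)
    return params.s_max * (1.0 - gamma) - np.asarray(S0) * (1.0 - gamma * s)


def stationary_S(t_rest, t_sens, params: ModelParams):
    """Stationary synapse number per connection: Delta S(S*) = 0."""
    gamma = gamma_rest(t_rest, params)
    s = survival_probability(t_sens, params)
    return params.s_max * (1.0 - gamma) / (1.0 - gamma * s)


def sustainable(t_rest, t_sens, params: ModelParams) -> bool:
    """Whether the stationary assembly still reactivates at the end of a
    sensory phase: S* s(t_sens) w(t_sens) >= w_inh."""
    s_star = stationary_S(t_rest, t_sens, params)
    s = survival_probability(t_sens, params)
    return bool(s_star * s * weight_decay(t_sens, params) >= params.w_inh)


def phase_diagram(
    t_sens_grid,
    t_rest_grid,
    S0: float,
    n_cycles_total_time: float,
    params: ModelParams,
) -> pd.DataFrame:
    """Predicted connectivity change over a fixed total simulated time.

    For each (t_sens, t_rest) the number of cycles is the total time
    divided by the cycle length; the cumulative change iterates
    ``S <- clip(S + Delta S(S), 0, s_max)`` per cycle.  Columns:
    t_sens, t_rest (s), n_cycles, delta_S (after all cycles), S_star,
    sustainable.
    """
    rows = []
    for t_rest in np.asarray(t_rest_grid, dtype=float):
        gamma = gamma_rest(t_rest, params)
        for t_sens in np.asarray(t_sens_grid, dtype=float):
            s = survival_probability(t_sens, params)
            n_cycles = int(n_cycles_total_time / (t_sens + t_rest))
            S = float(S0)
            for _ in range(n_cycles):
                S += params.s_max * (1 - gamma) - S * (1 - gamma * s)
                S = min(max(S, 0.0), float(params.s_max))
            s_star = params.s_max * (1 - gamma) / (1 - gamma * s)
            rows.append(
                {
                    "t_sens": t_sens,
                    "t_rest": t_rest,
                    "n_cycles": n_cycles,
                    "delta_S": S - S0,
                    "S_star": s_star,
                    "sustainable": bool(
                        s_star * s * weight_decay(t_sens, params) >= params.w_inh
                    ),
                }
            )
    return pd.DataFrame(rows)


def sustainability_boundary(
    t_rest: float,
    params: ModelParams,
    t_sens_hi: float = 60 * 3600.0,
) -> float:
    """Largest t_sens (seconds) for which the stationary assembly still
    meets the end-of-sensory-phase reactivation condition, by bisection on
    the sign change of ``S* s w - w_inh``."""

    def margin(t_sens: float) -> float:
        s = survival_probability(t_sens, params)
        s_star = stationary_S(t_rest, t_sens, params)
        return float(s_star * s * weight_decay(t_sens, params) - params.w_inh)

    lo, hi = 1.0, t_sens_hi
    if margin(lo) <= 0:
        return 0.0
    if margin(hi) > 0:
        raise RuntimeError("sustainability boundary beyond bracket; raise t_sens_hi")
    return float(brentq(margin, lo, hi, xtol=_ROOT_XTOL))


def decay_boundary(
    S0: float,
    t_rest: float,
    params: ModelParams,
    t_sens_hi: float = 100 * 3600.0,
) -> float:
    """Sensory-phase duration (seconds) at which the per-cycle change
    Delta S(S0, t_rest, t_sens) crosses from positive to negative."""

    def f(t_sens: float) -> float:
        return float(delta_S_cycle(S0, t_rest, t_sens, params))

    lo, hi = 1.0, t_sens_hi
    if f(lo) <= 0:
        return 0.0
    if f(hi) > 0:
        raise RuntimeError("decay boundary beyond bracket; raise t_sens_hi")
    return float(brentq(f, lo, hi, xtol=_ROOT_XTOL))
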