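"""Potential-synapse lattice: Hebbian weight dynamics and structural turnover.

Every ordered neuron pair (i, j), i != j, owns ``s_max`` potential synaptic
locations.  A vacant location turns into a functional synapse with constant
rate ``b`` (weight ``w0``); an occupied location is removed with a
weight-dependent hazard

    d(w) = d1 + (d0 - d1) / (1 + exp(-beta * (w_off - w)))

that interpolates between ``d0`` (small synapses, fast removal) and ``d1``
(strong synapses, nearly stable).  Weights of existing synapses follow a
three-regime threshold Hebbian rule driven by the pre- and postsynaptic
rates:

    dw/dt = -delta_decay * w              if v_pre < 0.5 and v_post < 0.5
          = +delta_ltp * (w_max - w)      if v_pre > 0.5 and v_post > 0.5
          = -delta_ltd * w                otherwise (ties included)

The per-step Bernoulli update (:func:`structural_step`) is the reference
semantics; :func:`run_structural_event_based` is an exact event-driven
equivalent for frozen weights, used as an independent oracle and as a fast
path for purely structural simulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import DAY, ModelParams

__all__ = [
    "SynapseTable",
    "deletion_rate",
    "hebbian_step",
    "structural_step",
    "run_structural_event_based",
    "equilibrium_occupancy",
]


@dataclass
class SynapseTable:
    """Occupancy, weight and creation time of every potential synapse.

    Arrays are indexed ``[post, pre, slot]``.  The diagonal (post == pre)
    is structurally forbidden: no self-connections.
    """

    occ: np.ndarray       # bool  (n, n, s_max)
    w: np.ndarray         # float (n, n, s_max); 0 where vacant
    t_create: np.ndarray  # float (n, n, s_max); NaN where vacant

    @classmethod
    def empty(cls, n_cells: int, s_max: int) -> "SynapseTable":
        shape = (n_cells, n_cells, s_max)
        return cls(
            occ=np.zeros(shape, dtype=bool),
            w=np.zeros(shape),
            t_create=np.full(shape, np.nan),
        )

    # -- basic queries ---------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.occ.shape[0]

    @property
    def s_max(self) -> int:
        return self.occ.shape[2]

    def n_occupied(self) -> int:
        return int(self.occ.sum())

    def pair_counts(self) -> np.ndarray:
        """Number of synapses S_ij per ordered pair, shape (n, n)."""
        return self.occ.sum(axis=2).astype(np.int64)

    def pair_weight_sum(self) -> np.ndarray:
        """Summed weight per ordered pair, shape (n, n)."""
        return (self.w * self.occ).sum(axis=2)

    def copy(self) -> "SynapseTable":
        return SynapseTable(self.occ.copy(), self.w.copy(), self.t_create.copy())

    def validate(self, params: ModelParams | None = None) -> None:
        n = self.n_cells
        idx = np.arange(n)
        if self.occ[idx, idx, :].any():
            raise ValueError("self-connections are forbidden (occupied diagonal slot)")
        if np.any(self.w[~self.occ] != 0):
            raise ValueError("vacant slots must carry zero weight")
        if params is not None:
            wocc = self.w[self.occ]
            if wocc.size and (wocc.min() < 0 or wocc.max() > params.w_max + 1e-12):
                raise ValueError("occupied weight outside [0, w_max]")

    # -- I/O ---------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Sparse triplet view: one row per occupied location."""
        post, pre, slot = np.nonzero(self.occ)
        return pd.DataFrame(
            {
                "post": post,
                "pre": pre,
                "slot": slot,
                "weight": self.w[post, pre, slot],
                "t_create": self.t_create[post, pre, slot],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, n_cells: int, s_max: int) -> "SynapseTable":
        table = cls.empty(n_cells, s_max)
        post = frame["post"].to_numpy(dtype=int)
        pre = frame["pre"].to_numpy(dtype=int)
        slot = frame["slot"].to_numpy(dtype=int)
        if np.any(post == pre):
            raise ValueError("triplet table contains self-connections")
        table.occ[post, pre, slot] = True
        table.w[post, pre, slot] = frame["weight"].to_numpy(dtype=float)
        tc = (
            frame["t_create"].to_numpy(dtype=float)
            if "t_create" in frame
            else np.zeros(len(frame))
        )
        table.t_create[post, pre, slot] = tc
        return table


def deletion_rate(w, params: ModelParams):
    """Weight-dependent removal hazard in 1/day; strictly decreasing in w.

    Scales from ``d0`` at w -> 0 down to ``d1`` at w -> w_max.
    """
    w = np.asarray(w, dtype=float)
    if np.any(w < 0) or np.any(w > params.w_max + 1e-12):
        raise ValueError("weight outside [0, w_max]")
    out = params.d1 + (params.d0 - params.d1) / (
        1.0 + np.exp(-params.beta * (params.w_off - w))
    )
    return out if out.ndim else float(out)


def hebbian_step(
    table: SynapseTable, v: np.ndarray, params: ModelParams, dt: float | None = None
) -> SynapseTable:
    """One Euler step of the three-regime Hebbian rule (in place).

    Rates at exactly 0.5 fall in the heterosynaptic-depression branch
    ("otherwise"), pinning the measure-zero boundary case.
    """
    if dt is None:
        dt = params.dt
    v = np.asarray(v, dtype=float)
    wocc = table.w[table.occ]
    if wocc.size and (wocc.min() < -1e-15 or wocc.max() > params.w_max + 1e-12):
        raise ValueError("weight outside [0, w_max] before Hebbian step")
    active = v > 0.5
    inactive = v < 0.5
    both_low = inactive[:, None] & inactive[None, :]    # [post, pre]
    both_high = active[:, None] & active[None, :]
    dw = np.where(
        both_low[:, :, None],
        -params.delta_decay * table.w,
        np.where(
            both_high[:, :, None],
            params.delta_ltp * (params.w_max - table.w),
            -params.delta_ltd * table.w,
        ),
    )
    table.w += dt * dw * table.occ
    np.clip(table.w, 0.0, params.w_max, out=table.w)
    table.w[~table.occ] = 0.0
    return table


def structural_step(
    table: SynapseTable,
    params: ModelParams,
    dt: float,
    rng: np.random.Generator,
    t: float = 0.0,
) -> SynapseTable:
    """Per-slot Bernoulli creation/removal over an interval dt (in place).

    Each vacant slot becomes occupied with probability ``1 - exp(-b dt)``
    (exact for the constant creation hazard); each occupied slot is removed
    with probability ``1 - exp(-d(w) dt)``.  Both decisions are taken from
    the step-start configuration, so a synapse removed in this step cannot
    be recreated within the same step and vice versa.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    if dt == 0:
        return table
    n = table.n_cells
    offdiag = ~np.eye(n, dtype=bool)[:, :, None]
    occ0 = table.occ.copy()
    vacant0 = (~occ0) & offdiag

    p_create = -np.expm1(-params.b_per_s * dt)
    d_per_s = np.zeros_like(table.w)
    d_per_s[occ0] = deletion_rate(table.w[occ0], params) / DAY
    p_delete = -np.expm1(-d_per_s * dt)

    u = rng.random(size=table.occ.shape)
    created = vacant0 & (u < p_create)
    deleted = occ0 & (u < p_delete)

    table.occ[deleted] = False
    table.w[deleted] = 0.0
    table.t_create[deleted] = np.nan
    table.occ[created] = True
    table.w[created] = params.w0
    table.t_create[created] = t
    return table


def equilibrium_occupancy(params: ModelParams) -> float:
    """Expected synapses per pair when all weights sit near zero.

    Detailed balance of creation (rate b per vacant slot) against removal
    (rate ~ d0 per occupied slot) gives ``s_max * b / (b + d0)``.
    """
    return params.s_max * params.b / (params.b + params.d0)


def run_structural_event_based(
    table: SynapseTable,
    duration: float,
    params: ModelParams,
    rng: np.random.Generator,
    t0: float = 0.0,
) -> SynapseTable:
    """Advance structural turnover by ``duration`` seconds, weights frozen.

    Event-driven (Gillespie) simulation with thinning: candidate events are
    drawn from the bound process with creation rate ``b`` per vacant slot
    and removal rate ``d0`` per occupied slot; removal candidates are
    accepted with probability ``d(w)/d0``.  Exact when weights do not
    change during the interval, which makes it the independent oracle for
    :func:`structural_step` and a fast path for purely structural runs.
    """
    n, s_max = table.n_cells, table.s_max
    offdiag = ~np.eye(n, dtype=bool)[:, :, None] & np.ones((n, n, s_max), dtype=bool)
    valid_flat = np.flatnonzero(offdiag.ravel())
    occ_flat = table.occ.ravel()
    w_flat = table.w.ravel()
    tc_flat = table.t_create.ravel()

    b = params.b_per_s
    d0 = params.d0_per_s
    t = 0.0
    n_occ = int(occ_flat[valid_flat].sum())
    n_vac = valid_flat.size - n_occ
    while True:
        rate = n_vac * b + n_occ * d0
        if rate <= 0:
            break
        t += rng.exponential(1.0 / rate)
        if t >= duration:
            break
        if rng.random() < n_vac * b / rate:
            vac_idx = valid_flat[~occ_flat[valid_flat]]
            k = vac_idx[rng.integers(vac_idx.size)]
            occ_flat[k] = True
            w_flat[k] = params.w0
            tc_flat[k] = t0 + t
            n_occ += 1
            n_vac -= 1
        else:
            occ_idx = valid_flat[occ_flat[valid_flat]]
            k = occ_idx[rng.integers(occ_idx.size)]
            # thinning: accept removal with d(w)/d0
            if rng.random() < deletion_rate(w_flat[k], params) / params.d0:
                occ_flat[k] = False
                w_flat[k] = 0.0
                tc_flat[k] = np.nan
                n_occ -= 1
                n_vac += 1
    return table
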