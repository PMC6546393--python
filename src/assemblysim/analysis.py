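"""Measurement tooling: class-resolved connectivity, synapse turnover and
persistence, reactivation detection, and associative pattern completion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ModelParams
from .synapses import SynapseTable

__all__ = [
    "ConnectivityClassStats",
    "TurnoverReport",
    "CompletionResult",
    "class_masks",
    "class_connectivity",
    "turnover_stats",
    "persistence_curve",
    "detect_reactivations",
    "corrupt_pattern",
    "evaluate_completion",
]


# ---------------------------------------------------------------------------
# connectivity by class
# ---------------------------------------------------------------------------

def class_masks(n_cells: int, groups) -> dict:
    """Partition ordered pairs (i != j) into connection classes.

    ``intra``: both neurons share a group (overlap pairs count as intra);
    ``inter``: at least one neuron belongs to a group but the pair shares
    none (assembly-assembly or assembly-control); ``control``: neither
    neuron belongs to any group.
    """
    in_group = np.zeros(n_cells, dtype=bool)
    intra = np.zeros((n_cells, n_cells), dtype=bool)
    for g in groups:
        ids = np.asarray(list(g), dtype=int)
        in_group[ids] = True
        block = np.zeros(n_cells, dtype=bool)
        block[ids] = True
        intra |= block[:, None] & block[None, :]
    offdiag = ~np.eye(n_cells, dtype=bool)
    intra &= offdiag
    either = in_group[:, None] | in_group[None, :]
    inter = either & ~intra & offdiag
    control = ~either & offdiag
    return {"intra": intra, "inter": inter, "control": control}


@dataclass
class ConnectivityClassStats:
    """Per-class summary plus dense pair matrices for plotting."""

    stats: dict                 # class -> dict of means/sds (None if class empty)
    counts: np.ndarray          # S_ij per ordered pair
    weight_sums: np.ndarray     # sum_k w_ijk per ordered pair
    timestamp: float = 0.0


def class_connectivity(
    table: SynapseTable, groups, timestamp: float = 0.0
) -> ConnectivityClassStats:
    """Mean/s.d. of weight-per-synapse and synapses-per-connection by class."""
    masks = class_masks(table.n_cells, groups)
    counts = table.pair_counts()
    wsums = table.pair_weight_sum()
    stats = {}
    for name, mask in masks.items():
        if not mask.any():
            stats[name] = None
            continue
        pair_counts = counts[mask]
        occ = table.occ & mask[:, :, None]
        weights = table.w[occ]
        stats[name] = {
            "mean_synapses": float(pair_counts.mean()),
            "sd_synapses": float(pair_counts.std()),
            "mean_weight": float(weights.mean()) if weights.size else float("nan"),
            "sd_weight": float(weights.std()) if weights.size else float("nan"),
            "n_pairs": int(mask.sum()),
            "n_synapses": int(weights.size),
        }
    return ConnectivityClassStats(
        stats=stats, counts=counts, weight_sums=wsums, timestamp=timestamp
    )


# ---------------------------------------------------------------------------
# turnover and persistence
# ---------------------------------------------------------------------------

@dataclass
class TurnoverReport:
    times: np.ndarray            # snapshot times (s), from the second one
    created_fraction: np.ndarray  # |occ_d \ occ_{d-1}| / |occ_{d-1}|
    removed_fraction: np.ndarray
    persistence_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    persistence: np.ndarray = field(default_factory=lambda: np.empty(0))


def turnover_stats(
    occ_snaps,
    snap_times,
    slot_mask: np.ndarray | None = None,
    events: pd.DataFrame | None = None,
) -> TurnoverReport:
    """Day-to-day creation/removal fractions at fixed potential locations.

    ``occ_snaps`` is a sequence of boolean slot-occupancy snapshots (e.g.
    daily); fractions are relative to the previous snapshot's occupied
    population, optionally restricted to ``slot_mask`` (e.g. intra-assembly
    slots).  If a creation/removal ``events`` log is given, the persistence
    curve (continuously occupied since the first snapshot, same slot) is
    attached.
    """
    occ_snaps = [np.asarray(o) for o in occ_snaps]
    if len(occ_snaps) < 2:
        raise ValueError("need at least two occupancy snapshots")
    snap_times = np.asarray(snap_times, dtype=float)
    if slot_mask is None:
        slot_mask = np.ones_like(occ_snaps[0], dtype=bool)
    created, removed = [], []
    for prev, cur in zip(occ_snaps[:-1], occ_snaps[1:]):
        prev_m = prev & slot_mask
        cur_m = cur & slot_mask
        n_prev = prev_m.sum()
        if n_prev == 0:
            created.append(np.nan)
            removed.append(np.nan)
            continue
        created.append((cur_m & ~prev_m).sum() / n_prev)
        removed.append((prev_m & ~cur_m).sum() / n_prev)
    report = TurnoverReport(
        times=snap_times[1:],
        created_fraction=np.asarray(created),
        removed_fraction=np.asarray(removed),
    )
    if events is not None:
        pt, pc = persistence_curve(
            occ_snaps[0] & slot_mask, snap_times[0], snap_times, events
        )
        report.persistence_times = pt
        report.persistence = pc
    return report


def persistence_curve(
    reference_occ: np.ndarray,
    t_ref: float,
    eval_times,
    events: pd.DataFrame,
):
    """Fraction of reference synapses continuously occupied until each time.

    Slot-identity based: a synapse that is removed and later re-created at
    the same location does not count as persistent.  ``events`` must hold
    columns (t, post, pre, slot, kind) with kind=-1 for removals.
    """
    eval_times = np.asarray(eval_times, dtype=float)
    post, pre, slot = np.nonzero(reference_occ)
    n_ref = post.size
    if n_ref == 0:
        return eval_times, np.full(eval_times.shape, np.nan)
    s_max = reference_occ.shape[2]
    n = reference_occ.shape[0]
    ref_key = (post.astype(np.int64) * n + pre) * s_max + slot

    dels = events[(events["kind"] == -1) & (events["t"] > t_ref)]
    del_key = (
        (dels["post"].to_numpy(np.int64) * n + dels["pre"].to_numpy(np.int64)) * s_max
        + dels["slot"].to_numpy(np.int64)
    )
    del_t = dels["t"].to_numpy(float)
    # first removal time per reference slot (inf if never removed)
    order = np.lexsort((del_t, del_key))
    del_key, del_t = del_key[order], del_t[order]
    first = np.full(n_ref, np.inf)
    idx = np.searchsorted(del_key, ref_key)
    hit = (idx < del_key.size) & (del_key[np.minimum(idx, del_key.size - 1)] == ref_key)
    first[hit] = del_t[idx[hit]]
    frac = [(first > t).mean() for t in eval_times]
    return eval_times, np.asarray(frac)


# ---------------------------------------------------------------------------
# reactivation detection
# ---------------------------------------------------------------------------

def detect_reactivations(
    times: np.ndarray,
    trace: np.ndarray,
    threshold: float = 0.5,
    min_duration: float = 1.0,
):
    """Maximal intervals with mean rate above threshold, lasting at least
    ``min_duration`` seconds.  Returns a list of (t_start, t_end).

    The default threshold 0.5 is the midpoint of the logistic gain and the
    Hebbian plasticity threshold; an assembly above it is in an Up state.
    """
    times = np.asarray(times, dtype=float)
    trace = np.asarray(trace, dtype=float)
    above = trace > threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(times.size)
    dt_samp = times[1] - times[0] if times.size > 1 else min_duration
    out = []
    for s, e in zip(starts, ends):
        t_start, t_end = times[s], times[e - 1] + dt_samp
        if t_end - t_start >= min_duration - 1e-9:
            out.append((float(t_start), float(t_end)))
    return out


# ---------------------------------------------------------------------------
# pattern completion
# ---------------------------------------------------------------------------

def corrupt_pattern(
    pattern, fraction: float, universe, rng: np.random.Generator
):
    """Swap a fraction of the active set against inactive neurons.

    ``round(fraction * |pattern|)`` (banker's rounding) active neurons are
    switched off and the same number of inactive ones switched on, so the
    corrupted cue has exactly the original size.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("corruption fraction must lie in [0, 1]")
    pattern = sorted(pattern)
    universe = sorted(universe)
    inactive = sorted(set(universe) - set(pattern))
    k = int(round(fraction * len(pattern)))
    if k > len(inactive):
        raise ValueError("not enough inactive neurons to switch on")
    if k == 0:
        return set(pattern)
    off = rng.choice(np.asarray(pattern), size=k, replace=False)
    on = rng.choice(np.asarray(inactive), size=k, replace=False)
    return (set(pattern) - set(int(i) for i in off)) | {int(i) for i in on}


@dataclass
class CompletionResult:
    levels: np.ndarray            # corruption fractions
    fraction_correct: np.ndarray  # averaged over patterns and trials
    false_negative: np.ndarray    # wrongly inactive / n_cells
    false_positive: np.ndarray    # wrongly active / n_cells
    currents: dict                # level -> class -> pooled input currents


def evaluate_completion(
    table: SynapseTable,
    patterns,
    corruption_levels,
    params: ModelParams,
    rng: np.random.Generator,
    n_trials: int = 100,
) -> CompletionResult:
    """Binary-unit pattern completion with a zero input threshold.

    For each corrupted cue the cue neurons are clamped to rate 1 and all
    others to 0, with utilization at rest (f = 1).  Each neuron's input is

        I_i = sum_j sum_k w_ijk v_j + I_inh*,   I_inh* = -w_inh sum_j v_j,

    the inhibitory fixed point under the clamped rates (deterministic, no
    noise).  A neuron is classified active iff I_i > 0 and compared
    against the uncorrupted pattern; fractions are averaged over
    ``n_trials`` corrupted cues per pattern per level.

    Current histograms are pooled per class: neurons of the tested
    pattern, neurons of other patterns, and the remaining neurons.
    """
    n = table.n_cells
    W = table.pair_weight_sum()
    universe = list(range(n))
    patterns = [set(p) for p in patterns]
    levels = np.asarray(corruption_levels, dtype=float)

    frac_correct = np.zeros(levels.size)
    false_neg = np.zeros(levels.size)
    false_pos = np.zeros(levels.size)
    currents: dict = {}
    for li, level in enumerate(levels):
        pooled = {"pattern": [], "other": [], "control": []}
        acc = np.zeros(3)
        for pat in patterns:
            target = np.zeros(n, dtype=bool)
            target[list(pat)] = True
            other = np.zeros(n, dtype=bool)
            for q in patterns:
                if q is not pat:
                    other[list(q)] = True
            other &= ~target
            ctrl = ~target & ~other
            for _ in range(n_trials):
                cue = corrupt_pattern(pat, level, universe, rng)
                v = np.zeros(n)
                v[list(cue)] = 1.0
                current = W @ v - params.w_inh * v.sum()
                active = current > 0
                acc[0] += (active == target).mean()
                acc[1] += (target & ~active).mean()
                acc[2] += (~target & active).mean()
                pooled["pattern"].append(current[target])
                pooled["other"].append(current[other])
                pooled["control"].append(current[ctrl])
        denom = len(patterns) * n_trials
        frac_correct[li], false_neg[li], false_pos[li] = acc / denom
        currents[float(level)] = {
            k: np.concatenate(vs) if vs else np.empty(0) for k, vs in pooled.items()
        }
    return CompletionResult(
        levels=levels,
        fraction_correct=frac_correct,
        false_negative=false_neg,
        false_positive=false_pos,
        currents=currents,
    )
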