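"""Compiled forward-Euler stepping kernel.

The kernel advances the full model (membrane, global inhibition,
short-term depression or spike-frequency adaptation, three-regime Hebbian
weights, structural creation/removal) for a block of steps.  It
reproduces the reference semantics of :mod:`assemblysim.dynamics` and
:mod:`assemblysim.synapses` exactly for the deterministic parts and is
distributionally equivalent for the stochastic structural updates.

Weight updates use an exact algebraic shortcut: within one ordered pair
all synapses see the same pre/post rates, so a Euler step multiplies
every weight of the pair by the same factor and adds the same offset
(LTP: ``w <- (1-a) w + a w_max``; LTD/decay: ``w <- (1-a) w``).  The
kernel therefore keeps per-pair affine transforms ``(M, C)`` over base
weights and composes them per step in O(n_cells^2), materializing
individual weights only when a removal candidate is tested, a synapse is
created (the pair is then rebased), or a snapshot is taken.  This is
bit-for-bit the per-synapse Euler recursion, evaluated lazily; when M
underflows, all weights of the pair have converged to the common
trajectory C and the flush to zero is exact at float precision.

Structural turnover per step: creations are Binomial(n_vacant,
1-exp(-b dt)) placed uniformly on distinct vacant slots; removal
candidates are Binomial(n_occupied, 1-exp(-d0 dt)) thinned by
(1-exp(-d(w) dt))/(1-exp(-d0 dt)) -- per-slot Bernoulli removal with
hazard d(w) without touching every slot each step.

All randomness is drawn from Numba's internal Mersenne-Twister stream,
seeded once per run through :func:`seed_kernel`; runs are
bit-reproducible for a fixed seed and step sequence.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by run_block
OK = 0
EVENT_LOG_FULL = 1
NAN_ABORT = 2

STD_MODE = 0
SFA_MODE = 1

_M_FLUSH = 1e-250  # below this the affine scale is exactly 0 at float precision


@njit(cache=False)
def seed_kernel(seed):
    np.random.seed(seed)


@njit(cache=False)
def _binom_inv(n, p):
    """Binomial sample by CDF inversion; exact, O(result) for small n*p."""
    if n <= 0 or p <= 0.0:
        return 0
    if p >= 1.0:
        return n
    u = np.random.random()
    pk = np.exp(n * np.log1p(-p))  # (1-p)^n without cancellation
    cdf = pk
    k = 0
    ratio = p / (1.0 - p)
    while u > cdf and k < n:
        pk *= (n - k) / (k + 1.0) * ratio
        k += 1
        cdf += pk
    return k


@njit(cache=False)
def _deletion_rate_per_s(w, d0_s, d1_s, w_off, beta):
    return d1_s + (d0_s - d1_s) / (1.0 + np.exp(-beta * (w_off - w)))


@njit(cache=False)
def _rebase_pair(i, j, s_max, occ, base, M, C):
    """Materialize pair (i, j): base <- M*base + C, transform <- identity."""
    m = M[i, j]
    c = C[i, j]
    for k in range(s_max):
        if occ[i, j, k]:
            base[i, j, k] = m * base[i, j, k] + c
    M[i, j] = 1.0
    C[i, j] = 0.0


@njit(cache=False)
def materialize_weights(occ, base, M, C, out):
    """Dense weight array from base weights and pair transforms."""
    n = occ.shape[0]
    s_max = occ.shape[2]
    for i in range(n):
        for j in range(n):
            m = M[i, j]
            c = C[i, j]
            for k in range(s_max):
                out[i, j, k] = m * base[i, j, k] + c if occ[i, j, k] else 0.0


@njit(cache=False)
def run_block(
    n_steps,
    step0,
    # neural state
    u, v, f, i_ad, i_inh,
    # synapse lattice: occupancy, base weights, pair transforms, counts
    occ, base, t_create, M, C, wbase_sum, s_count, n_syn,
    # compact occupied-slot index (for uniform removal sampling)
    syn_post, syn_pre, syn_slot,
    # structural event log
    ev_t, ev_post, ev_pre, ev_slot, ev_kind, ev_n,
    # stimulation events (block-local step indices, non-overlapping, sorted)
    stim_start, stim_end, stim_neurons, stim_amp,
    # recording
    rec, rec_n, rec_stride, group_index, group_sizes,
    # parameters
    dt, tau, w_inh, noise_sd, tau_relax, f_dep, alpha_adapt, tau_adapt,
    w_max, delta_decay, delta_ltp, delta_ltd,
    b_s, d0_s, d1_s, w_off, beta, w0,
    mode, structural_on,
):
    """Advance ``n_steps`` steps; returns (status, steps_done).

    On EVENT_LOG_FULL the caller may grow the log and resume for the
    remaining steps (state arrays are always consistent at return).
    """
    n = u.shape[0]
    s_max = occ.shape[2]
    total_slots = n * (n - 1) * s_max
    n_groups = group_sizes.shape[0]

    p_create = -np.expm1(-b_s * dt)
    p_del_bound = -np.expm1(-d0_s * dt)

    # per-regime affine coefficients of one Euler step
    m_ltp = 1.0 - dt * delta_ltp
    c_ltp = dt * delta_ltp * w_max
    m_dec = 1.0 - dt * delta_decay
    m_ltd = 1.0 - dt * delta_ltd

    i_stim = np.zeros(n)
    cur_event = -1
    next_event = 0
    n_events = stim_start.shape[0]

    act_hi = np.zeros(n, dtype=np.bool_)
    act_lo = np.zeros(n, dtype=np.bool_)
    fv = np.zeros(n)
    group_acc = np.zeros(n_groups)
    del_idx = np.zeros(256, dtype=np.int64)

    for local in range(n_steps):
        # ---- stimulation bookkeeping (events sorted, non-overlapping)
        if cur_event >= 0 and local >= stim_end[cur_event]:
            for kk in range(stim_neurons.shape[1]):
                nid = stim_neurons[cur_event, kk]
                if nid >= 0:
                    i_stim[nid] = 0.0
            cur_event = -1
        if cur_event < 0 and next_event < n_events and local >= stim_start[next_event]:
            cur_event = next_event
            next_event += 1
            for kk in range(stim_neurons.shape[1]):
                nid = stim_neurons[cur_event, kk]
                if nid >= 0:
                    i_stim[nid] = stim_amp[cur_event]

        # ---- step-start rates, Hebbian regime masks
        sum_v = 0.0
        for i in range(n):
            vi = v[i]
            sum_v += vi
            act_hi[i] = vi > 0.5
            act_lo[i] = vi < 0.5
            fv[i] = f[i] * vi

        # ---- recurrent current from step-start weights, then compose this
        #      step's Hebbian transform onto each pair (one O(n^2) pass)
        a = dt / tau
        for i in range(n):
            hi_i = act_hi[i]
            lo_i = act_lo[i]
            rec_cur = 0.0
            for j in range(n):
                s_ij = s_count[i, j]
                if s_ij > 0:
                    m = M[i, j]
                    c = C[i, j]
                    rec_cur += (m * wbase_sum[i, j] + s_ij * c) * fv[j]
                    # Hebbian regime of this step (ties -> LTD branch)
                    if hi_i and act_hi[j]:
                        M[i, j] = m * m_ltp
                        C[i, j] = c * m_ltp + c_ltp
                    elif lo_i and act_lo[j]:
                        M[i, j] = m * m_dec
                        C[i, j] = c * m_dec
                    else:
                        M[i, j] = m * m_ltd
                        C[i, j] = c * m_ltd
                    if M[i, j] < _M_FLUSH:
                        M[i, j] = 0.0
            total = rec_cur + i_inh[0] + i_stim[i] + np.random.normal(0.0, noise_sd)
            if mode == SFA_MODE:
                total += i_ad[i]
            u[i] += a * (-u[i] + total)

        if mode == SFA_MODE:
            for i in range(n):
                i_ad[i] += (dt / tau_adapt) * (-i_ad[i] - alpha_adapt * v[i])
        else:
            for i in range(n):
                f[i] += dt * ((1.0 - f[i]) / tau_relax - f_dep * f[i] * v[i])

        # ---- new rates; NaN guard
        bad = False
        new_sum_v = 0.0
        for i in range(n):
            x = u[i]
            if mode == SFA_MODE:
                x += i_ad[i]
            if not np.isfinite(x):
                bad = True
                break
            v[i] = 1.0 / (1.0 + np.exp(-x))
            new_sum_v += v[i]
        if bad:
            return NAN_ABORT, local
        # inhibition integrates the freshly computed rates (sequential
        # Gauss-Seidel ordering): at the model's dt/tau ~ 0.65, lagging
        # the inhibitory feedback by a full step makes the quiescent state
        # an unstable discrete map and the network oscillates collectively;
        # the sequential order is stable (see docs/methods.md).
        i_inh[0] += a * (-i_inh[0] - w_inh * new_sum_v)

        t_now = (step0 + local + 1) * dt

        if structural_on:
            # ---- removals: bound-rate candidates, thinned by d(w)/d0
            ns = n_syn[0]
            k_cand = _binom_inv(ns, p_del_bound)
            if k_cand > 0:
                if k_cand > del_idx.shape[0]:
                    k_cand = del_idx.shape[0]  # unreachable at physical rates
                m_got = 0
                while m_got < k_cand:
                    cand = np.random.randint(0, ns)
                    dup = False
                    for q in range(m_got):
                        if del_idx[q] == cand:
                            dup = True
                            break
                    if not dup:
                        del_idx[m_got] = cand
                        m_got += 1
                # sort descending so swap-remove keeps pending indices valid
                for a_i in range(k_cand):
                    for b_i in range(a_i + 1, k_cand):
                        if del_idx[b_i] > del_idx[a_i]:
                            tmp = del_idx[a_i]
                            del_idx[a_i] = del_idx[b_i]
                            del_idx[b_i] = tmp
                for q in range(k_cand):
                    s = del_idx[q]
                    ip = syn_post[s]
                    jp = syn_pre[s]
                    kp = syn_slot[s]
                    w = M[ip, jp] * base[ip, jp, kp] + C[ip, jp]
                    d_w = _deletion_rate_per_s(w, d0_s, d1_s, w_off, beta)
                    accept_p = -np.expm1(-d_w * dt) / p_del_bound
                    if np.random.random() < accept_p:
                        if ev_n[0] >= ev_t.shape[0]:
                            return EVENT_LOG_FULL, local + 1
                        ev_t[ev_n[0]] = t_now
                        ev_post[ev_n[0]] = ip
                        ev_pre[ev_n[0]] = jp
                        ev_slot[ev_n[0]] = kp
                        ev_kind[ev_n[0]] = -1
                        ev_n[0] += 1
                        occ[ip, jp, kp] = False
                        wbase_sum[ip, jp] -= base[ip, jp, kp]
                        s_count[ip, jp] -= 1
                        if s_count[ip, jp] == 0:
                            wbase_sum[ip, jp] = 0.0
                        last = n_syn[0] - 1
                        syn_post[s] = syn_post[last]
                        syn_pre[s] = syn_pre[last]
                        syn_slot[s] = syn_slot[last]
                        n_syn[0] = last

            # ---- creations on vacant slots (pre-removal vacancy count)
            n_vac = total_slots - ns
            k_new = _binom_inv(n_vac, p_create)
            for _ in range(k_new):
                # uniform vacant slot by rejection on the full lattice
                while True:
                    ip = np.random.randint(0, n)
                    jp = np.random.randint(0, n)
                    kp = np.random.randint(0, s_max)
                    if ip != jp and not occ[ip, jp, kp]:
                        break
                if ev_n[0] >= ev_t.shape[0]:
                    return EVENT_LOG_FULL, local + 1
                ev_t[ev_n[0]] = t_now
                ev_post[ev_n[0]] = ip
                ev_pre[ev_n[0]] = jp
                ev_slot[ev_n[0]] = kp
                ev_kind[ev_n[0]] = 1
                ev_n[0] += 1
                # rebase the pair so the new base weight is w0 exactly
                _rebase_pair(ip, jp, s_max, occ, base, M, C)
                occ[ip, jp, kp] = True
                base[ip, jp, kp] = w0
                t_create[ip, jp, kp] = t_now
                s_count[ip, jp] += 1
                ws = 0.0
                for kk in range(s_max):
                    if occ[ip, jp, kk]:
                        ws += base[ip, jp, kk]
                wbase_sum[ip, jp] = ws
                s = n_syn[0]
                syn_post[s] = ip
                syn_pre[s] = jp
                syn_slot[s] = kp
                n_syn[0] = s + 1

        # ---- recording (end-of-step rates, per-group means)
        if (step0 + local + 1) % rec_stride == 0:
            for g in range(n_groups):
                group_acc[g] = 0.0
            for i in range(n):
                group_acc[group_index[i]] += v[i]
            r = rec_n[0]
            if r < rec.shape[0]:
                for g in range(n_groups):
                    rec[r, g] = group_acc[g] / group_sizes[g]
                rec_n[0] = r + 1

    return OK, n_steps
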