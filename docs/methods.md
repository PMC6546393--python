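# Methods

## Model

`assemblysim` simulates a recurrent network of `n_cells` rate neurons in
which long-term memories are stored as Hebbian cell assemblies and
maintained, despite continuous synapse turnover, by self-organized
reactivation during rest.

**Neuron and network.** Each neuron's membrane potential follows

    tau du_i/dt = -u_i + sum_j sum_k f_j w_ijk v_j + I_inh + I_stim,i + I_noise,i

with logistic gain `v_i = 1/(1+exp(-u_i))` and `tau = 155 ms`. A single
global inhibitory current, shared by all neurons, integrates the summed
rates: `tau dI_inh/dt = -I_inh - w_inh * sum_i v_i` with
`w_inh = 3.5 w_max`. The noise current is one Gaussian draw (sd 1.5) per
neuron per Euler step, held constant over the step; results are therefore
tied to the reference step `dt = 0.1 s`, which is a configuration knob but
is pinned for all shipped experiments.

**Synapses.** Every ordered pair of distinct neurons owns
`s_max = 16` potential synaptic locations. A vacant location becomes a
functional synapse with rate `b = 1/day` (initial weight `w0 = 0.001`);
an occupied one is removed with the weight-dependent hazard

    d(w) = d1 + (d0 - d1) / (1 + exp(-beta (w_off - w))),

which falls from `d0 = 24/day` for small synapses to `d1 = 0.03/day` at
the ceiling (`w_off = 0.35 w_max`, `beta = 20`): strong synapses are
nearly stable, weak ones churn. Weights of existing synapses follow the
three-regime threshold Hebbian rule (LTP `+0.1 (w_max - w)` per second
when both rates exceed 0.5, slow decay `-(2 days)^-1 w` when both are
below, LTD `-0.01 w` otherwise; ties at exactly 0.5 fall in the LTD
branch). Short-term depression multiplies each presynaptic neuron's
outgoing efficacy by a utilization factor `f` recovering over
`tau_relax = 5 s`; it terminates assembly Up states. Spike-frequency
adaptation (`alpha = 33`, `tau_adapt = 5 s`) is the alternative
termination mechanism; with it `f` is pinned at 1.

**Protocol.** Simulations pass through a warm-up (6 h of background
patterns that brings the empty lattice to structural equilibrium), a
learning phase (groups of 30 neurons stimulated at amplitude 200 for
18 s, round-robin with 36 s gaps, typically 9 h), and then alternating
sensory phases (a fresh random pattern of 15 non-assembly neurons at
amplitude 50 every second) and rest phases (no input) with durations
drawn per phase (exponential after learning; truncated normal, sd = 0.25
mean, for pre-wired retention experiments).

## Numerical choices

**Update order.** One step computes: recurrent current from step-start
rates and weights -> membrane update -> depression/adaptation update
(step-start rates) -> new rates -> inhibition update from the *new*
rates -> Hebbian weight step (step-start rates) -> structural removals,
then creations. The placement of the inhibition update is load-bearing,
not an O(dt) detail: at `dt/tau ≈ 0.65` the variant in which inhibition
integrates step-start rates linearizes to a discrete map with spectral
radius ≈ 1.3 around the quiescent state, and the network settles into a
network-wide ~1 Hz relaxation oscillation regardless of noise amplitude.
That artifact destroys winner-take-all reactivation and potentiates
unrelated connections. The sequential order used here has spectral
radius ≤ 0.74 and leaves the quiescent state quiet, which is the regime
the model is meant to operate in. Non-finite state aborts the run with a
diagnostic rather than being clipped.

**Lazy pair-affine weight updates.** All synapses of an ordered pair see
the same pre/post rates, so one Euler step maps every weight of the pair
through the same affine function (`w <- (1-a) w + a w_max` for LTP,
`w <- (1-a) w` otherwise). The engine composes these per-pair transforms
(M, C) step by step in O(n_cells^2) and applies them to per-slot base
weights only when a weight is actually needed (removal test, creation,
snapshot). This is the exact per-synapse Euler recursion evaluated
lazily — verified against the straightforward NumPy loop to ~1e-10 over
hundreds of steps — and makes runtime independent of the number of
functional synapses. When M underflows, all weights of the pair have
converged to the common trajectory C and the flush to zero is exact at
float precision.

**Structural sampling.** The reference semantics is a per-slot Bernoulli
decision per step with `p = 1 - exp(-rate dt)` (exact for a constant
hazard). The engine draws the *number* of creations as
Binomial(n_vacant, p_create) placed uniformly on distinct vacant slots,
and removal candidates as Binomial(n_occupied, p_d0) thinned by
`(1-exp(-d(w)dt))/(1-exp(-d0 dt))` — the identical per-slot law at
O(events) instead of O(slots) cost. An independent event-driven
implementation (exponential waiting times with thinning, exact for
frozen weights) serves as a distributional oracle in the tests.

**Theory evaluation.** The survival probability
`s(t) = exp(-int_0^t d(w_max e^{-delta_decay tau}) dtau)` is computed by
adaptive quadrature (relative tolerance 1e-9; cross-checked against a
10^6-point trapezoid). Boundary times (latest reactivation `t_max`, the
sustainability boundary, the sign change of the per-cycle change
`Delta S`) are found by bracketed Brent root finding at 1e-3 s
resolution; all theory functions are pure and deterministic.

**Randomness.** A master seed is split into named substreams (kernel
noise + structural events, sensory patterns, phase durations), so
changing one stochastic component leaves the others' draws unchanged.
The compiled kernel uses Numba's Mersenne-Twister stream seeded once per
run; runs are bit-reproducible for a fixed seed and configuration.

## What the generator emulates, and scale caveats

Fixtures pre-wire assemblies exactly as the retention experiments
specify: every ordered intra-group pair gets `s_init` synapses at
`w_max`; overlapping groups share neurons without exceeding `s_max` per
pair. The shipped experiment scales are: full 240-neuron network for
learning and rest-dynamics runs; one 30-neuron assembly plus 30 controls
for the three-day turnover runs; fifteen 8-neuron assemblies for the
decay-curve comparison; two 15-neuron groups sharing 5 neurons (plus 45
controls) for the adaptation-mechanism comparison.

The adaptation-mechanism comparison (overlap preservation under
short-term depression versus separation under spike-frequency
adaptation) is evaluated after two simulated days: at 15 neurons per
group the adaptation variant's assemblies are too small to self-maintain
for much longer, and by day two the separation is already complete while
both variants still carry live assemblies. At larger group sizes the
pre-wired assemblies saturate the potential lattice before competition
can separate them, so the contrast is a genuinely scale-sensitive
observable.

Two further artifacts of scaling down deserve note. First, the background
pattern size is fixed at 15 neurons, so in small control pools the
patterns cover a much denser fraction than at full scale; below roughly
90 eligible neurons the repeated co-activation stabilizes control-control
synapses into a spurious attractor. The turnover fixture (30 controls)
accepts this — the measured intra-assembly quantities still track the
mean-field prediction — while fixtures whose conclusions depend on clean
competition (overlap separation) use control pools above that density
threshold. Second, the warm-up equilibrium occupancy exceeds the
frozen-weight value `s_max b/(b+d0) = 0.64` slightly (≈0.75 per pair at
240 neurons) because background weights equilibrate near 0.14 where the
removal hazard is below `d0`; the 0.64 figure is exact only for weights
pinned near zero, and the tests distinguish the two settings.

Passing tests show that the implemented dynamics reproduce the model's
reported phenomenology under these synthetic protocols; they do not
speak to biological realism beyond the model's assumptions (rate
neurons, global inhibition, all-to-all potential connectivity, fixed
pattern statistics).

## Known limitations

- Results are `dt`-dependent by construction (fixed-step noise and the
  reported step size); `dt` is exposed but the shipped defaults pin it.
- The mean-field cycle theory assumes every rest phase fully
  re-potentiates surviving synapses; very short rest phases violate this
  and the theory is not corrected for that regime.
- No mean-field treatment of overlapping assemblies or of the
  spike-frequency-adaptation variant is provided.
- Daily turnover measured a few days after pre-wiring reflects the
  growth transient (creation elevated over removal); stationary turnover
  is lower for a single assembly than for several assemblies sharing
  rest-phase reactivation time.
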