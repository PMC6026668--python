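# Methods

## The model

`capsim` simulates *phase-ternary* computation with action potentials on
neurite networks. Each travelling pulse is read as a ternary digit along
the membrane: resting potential is 0, the all-or-none threshold front is
+1, and the analog refractory tail trailing the front is −1. The front
moves at a constant conduction velocity `v` set by the local membrane
dynamics; the tail occupies the preceding refractory duration `τ`.
Computation arises entirely from timing (phase) interactions:

* **Head-on annihilation.** Two fronts approaching on one segment meet
  where their linear trajectories intersect and both die — each +1 runs
  into the other's −1. Meeting time and position are solved in closed
  form and are symmetric in the order of the two pulses.
* **Occlusion (annulment) at junctions.** A node keeps a memory of recent
  threshold passages. A front arriving a delay Δ after a passage *from a
  different segment* is annulled when `tol < Δ < τ`: the refractory tail
  left at the node blocks the second threshold.
* **In-phase merging.** When `Δ ≤ tol`, the two arrivals are
  indistinguishable at the membrane's temporal grain and map together:
  one pulse continues, the other is absorbed.
* **Energy failure.** The mechanical soliton that carries the front has a
  scalar energy budget `E` that dissipates linearly with distance,
  `E_d = E − rate·d` (floored at zero). A pulse whose residual energy
  falls below a segment's activation threshold cannot trigger the next
  ion channels and fails; a budget exhausted mid-segment kills the pulse
  where it runs out.

The merge tolerance `tol` defaults to the membrane's *temporal accuracy*
`channel spacing / velocity` — about 1 µs at the default 1.5 µm spacing
(the measured minimum inter-channel distance; the measured range is
1.5–5 µm) and 1 m/s (the unmyelinated conduction maximum). It is the
finest phase difference channel-to-channel propagation can resolve.

### The cross-pathway rule

Occlusion and the refractory blocking of daughter branches apply only
*across* pathways. Two pulses travelling the same path at the same speed
keep a constant gap: the follower never enters the leader's tail, so a
spike train on a single chain propagates unimpeded regardless of its
inter-spike interval, and the node memory records which segment each
passage arrived by so that same-segment followers pass freely. This is
what makes redaction a property of *parallel* structure: a lone chain
removes nothing, while any re-convergence of parallel paths compares
phases and redacts mismatches.

### Propagation at junctions

Stimuli are injected at ENTRY nodes and launch one pulse along every
incident segment, travelling away from the node (so a segment can be
traversed against its nominal direction — the head-on collision motif
stimulates both ends of one edge). At interior nodes a passing front
continues along every *forward* (directed-out) segment except the one it
arrived by; a daughter whose entry is inside the refractory window left by
a cross-pathway entry is skipped (the "diffraction" of pulses away from
blocked branches, implemented as routing with no added delay); a daughter
whose activation threshold exceeds the residual energy is skipped. A node
with no forward continuation is an exit and records the arrival in the
output phase pattern. A pulse blocked on every daughter is annulled (if
refractory blocked) or fails (if energy blocked).

Each continuation keeps the parent's full residual energy — energy is a
viability token for channel triggering, not a conserved fluid divided
among branches.

### Bookkeeping

The `spawned` counter counts every pulse record created (stimulus
injections plus branch copies). Every record ends in exactly one of
exited / annihilated / annulled / merged / failed / still-active, so

    spawned = exited + annihilated + annulled + merged + failed + active

holds exactly on every run; the suite asserts it on randomized networks.
Node memory retains passages up to the longest refractory duration in the
graph, so high-rate inputs are handled correctly as long as interactions
matter only within one refractory window.

## The two engines

The production engine is event-driven: a priority queue ordered by
(time, monotone event id) processes stimulus injections, analytically
computed node arrivals, head-on meetings and energy deaths. Stale entries
(a pulse killed or moved before its scheduled event) are dropped by
liveness and entry-time checks. Identical inputs give byte-identical
canonical logs.

The verification oracle advances every front by `v·dt` per step and
detects the same events by interval crossing, interpolating the crossing
instant linearly inside the step; it shares the rule core (node logic,
collision algebra, energy rule) but none of the scheduling. The suite
requires the two engines to produce identical event-kind sequences and
times within `dt` on randomized graphs of ≤ 10 nodes. A `dt` coarser than
a tenth of the smallest segment transit time triggers a warning.

Time is kept in seconds internally; logs also report microseconds for
readability. Because event times are linear in `1/v`, doubling every
segment velocity halves every event time exactly (bit-exactly for
stimuli at t = 0), which the suite asserts without tolerance.

## Noise redaction experiments

`run_redaction_experiment` builds a parallel ladder (one entry fanning
into `n_parallel` equal paths that re-converge at each of `n_layers`
nodes), drives it with a periodic SIGNAL train (default period 5 ms,
longer than τ = 2 ms so the signal never self-occludes) plus
NOISE-labelled spontaneous spikes, and tallies provenance-labelled
terminal exits:

    redaction_fraction = 1 − noise exits / out-of-phase noise injected.

Noise within the merge tolerance of a signal firing is *in phase*: the
node rule merges it with the signal, which is duplicate suppression, not
redaction, so in-phase noise is reported separately and excluded from the
denominator (the mechanism cannot remove what it cannot distinguish).
Noise offsets inside `(tol, τ)` of a signal passage are annulled at the
first convergence — the suite verifies this by an exhaustive offset sweep
— so for out-of-phase-only noise the fraction is exactly 1.0 at any depth
≥ 1 with ≥ 2 parallel paths. Noise falling outside every refractory
window survives.

With equal-length paths and entry-injected noise, the noise–signal phase
offset is the same at every convergence layer, so redaction is decided at
the first layer and the depth curve is flat; the depth sweep
(`redaction_vs_depth`, paired noise draws per depth) therefore shows a
non-decreasing-with-equality trend under Poisson noise and 1.0 at every
depth for out-of-phase-only noise. Per-segment length jitter
(`jitter_sd_um`) makes phase relationships vary by layer when
layer-dependent redaction is of interest. A dispersion-of-exit-latencies
metric is emitted as a synchronization measure; no quantitative target
exists for it.

The Poisson noise generator is a homogeneous process per entry node,
deterministic under a fixed seed; its empirical mean count is checked
against `rate · horizon · n_entries` over 200 seeds.

## Feasibility calculators

* **Charge-diffusion speed limit.** `t = x² / 2D` (1-D mean-squared
  displacement — the fastest, hence most conservative, spreading
  estimate) gives the time for Na⁺ charge to diffuse the inter-channel
  distance `x`; the effective charge speed is `x/t = 2D/x`. With
  `D = 1.33×10⁻⁹ m²/s` (handbook value for Na⁺ in water at 25 °C,
  configurable) and the upper end of the measured spacing range
  (`x = 5 µm`), the speed ratio against the required 1 m/s is
  5.32×10⁻⁴ — below 1/1000, and below 1 across the whole 1.5–5 µm range,
  so diffusing charge alone cannot carry propagation.
* **Temporal accuracy and precision gain.** `x/v`, and the ratio of a
  coarse to a fine accuracy; millisecond voltage-trajectory accuracy vs
  microsecond phase accuracy gives the 1000× figure.
* **Moens–Korteweg pulse-wave velocity** for the myelinated case, in its
  textbook form `PWV = √(E·h/(ρ·d))`, since only the square-root
  proportionality in the elastic modulus is specified by the physiology.

## Numerical and design choices

* Refractory windows are half-open `[0, τ)`: an arrival exactly τ after a
  passage passes. The merge window is closed at the tolerance: `Δ = tol`
  merges. Energy exactly at threshold activates. Stated conventions,
  asserted at the boundaries in the suite.
* Roles (ENTRY/BRANCH/CONVERGE/TERMINAL/PASS) are annotations; the
  validator reports topology–role mismatches as warnings, and structural
  violations (dangling segment endpoints, disconnection, isolated
  entries/terminals) as errors.
* SWC import takes the standard 7 columns, lengths from 3-D Euclidean
  distances, default dynamics everywhere; radius is ignored (no
  radius–velocity law is assumed).
* The native JSON graph format is written canonically (sorted keys,
  shortest round-trip float repr), so write∘read∘write is byte-identical.
* Default dynamics: v = 1 m/s, τ = 2 ms (a typical absolute refractory
  period; only an absolute window is modelled — no relative refractory
  period or synaptic prolongation), spacing 1.5 µm, dissipation 0 and
  threshold 0 (energy modelling is opt-in).
* Simulations in the tests and the acceptance script use desk-scale
  networks (≤ 10 nodes, horizons of a few tens of milliseconds, oracle
  steps of 2 µs), chosen because every modelled effect — annihilation,
  occlusion, merging, redaction, failure — is exact at that scale rather
  than asymptotic.

## What the synthetic networks do and do not show

The generators produce idealized motifs: equal-length (optionally
jittered) parallel ladders, uniform fan-out trees, single collision
edges. They capture the timing logic of convergent/divergent neurites but
none of real morphology's heterogeneity: no distribution of segment
calibres or velocities, no synapses, no relative refractory period, no
stochastic channel gating, no graded potentials. Passing tests therefore
demonstrate the internal consistency of the phase-ternary rules and the
claims that follow from them (complete out-of-phase noise redaction,
collision algebra, energy-failure behaviour), not that biological
networks realize them.
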