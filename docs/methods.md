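# Methods

`gammarkov` implements three nested Markov models of the same small
excitatory–inhibitory spiking network, together with the statistics and
state-space geometry tools used to compare them. This note records the
models, the numerical choices, and the limits of what the test suite shows.

## The full model (MIF)

The network has `N_E = 75` excitatory and `N_I = 25` inhibitory neurons.
Each neuron carries an integer membrane potential on the lattice
`Γ = {V_I, …, V_th} ∪ {R}` with `V_I = −66` (inhibitory reversal),
`V_r = 0` (rest), `V_th = 100` (threshold) and a refractory token `R` —
168 states per neuron. The integer unit is the size of one external kick.

* **External drive.** Each neuron receives an independent Poisson stream at
  `λ_E = λ_I = 7000` Hz; each arrival raises `v` by 1.
* **Recurrent kicks.** A spike of a type-`Q` neuron is received by each
  type-`Q′` neuron independently with probability `P_{Q′Q}`
  (`P_EE = 0.15`, `P_IE = P_EI = 0.5`, `P_II = 0.4`; autapses permitted).
  Received kicks join per-neuron *pending pools* `H_i^E`, `H_i^I` and act
  after independent exponential delays: mean `τ_EE` on E targets, `τ_IE`
  on I targets for E-kicks, `τ_I = 4.5` ms for I-kicks. The ensemble mean
  of a pool equals the exponential Green's-function convolution of the
  conductance it replaces — a property the suite verifies directly.
* **Kick effects.** An E-kick raises `v` by `S_{QE}` (`S_EE = 20`,
  `S_IE = 8`); an I-kick lowers it by `(v − V_I)/(V_th − V_I) · S_{QI}`
  (`S_EI = S_II = 20`), reflecting the proximity of the inhibitory
  reversal potential. The fractional decrement is realized by stochastic
  rounding (floor plus a Bernoulli on the remainder), which preserves the
  expected decrement exactly and never undershoots `V_I`. Overshoot above
  threshold is discarded: the neuron fires and enters `R`.
* **Firing and refractoriness.** At `V_th` the neuron spikes, delivers
  kicks, and dwells in `R` for an exponential time (`τ_R^E = τ_R^I = 2.5`
  ms by default; both configurable) before resetting to `V_r`. Kicks
  arriving during `R` are consumed with no effect.

Simulation is exact: all event categories (external arrivals, pool
consumptions, refractory exits) race with exponential waiting times; the
first event is selected with probability proportional to its rate. The
event loop is JIT-compiled (numba) and advances ~0.7–0.9 M events per
simulated second at the baseline parameters.

Three regimes differ only in the excitatory synaptic time scales:
homogeneous (`Hom`, `τ_EE = 4`), regular (`Reg`, `τ_EE = 1.7`) and
synchronized (`Syn`, `τ_EE = 1.4`), all with `τ_IE = 1.2` ms. Smaller
`τ_EE/τ_I` makes recurrent excitation act faster than inhibition and
pushes the network from near-Poisson firing to strong gamma-band
synchrony.

## The two-state reduced network (RN)

The RN collapses each membrane potential to *base* (`v < V_c`, including
`R`) or *gate* (`v ≥ V_c`): gate neurons are a couple of E-kicks from
firing. The cutoff is `V_c = 60` by default (two `S_EE` kicks below
threshold; the `≥` convention is used and the cutoff is configurable).

The RN keeps the pool and drive machinery but replaces the deterministic
voltage updates with learned flip probabilities: for each kick class
(external, E, I), target population and pre-state, the flip probability is
tabulated against the pre-event base count (base targets) or gate count
(gate targets) of the target's population. This is the
conditional-expectation closure of the reduction: each entry is the
empirical flip frequency among matching kick-effect events in a long MIF
simulation. Estimation details:

* conditioning is on the exact integer count (counts ≤ 75 make binning
  unnecessary); entries with fewer than 30 samples are smoothed by a
  ±2-count sample-weighted moving average;
* unvisited counts are filled by linear interpolation between visited
  neighbours, with constant extrapolation at the edges, and flagged as
  imputed;
* I-kicks never flip base neurons (a decrement cannot cross the cutoff
  upward), so those keys are identically zero;
* refractory dynamics are folded into the base state: kicks wasted on
  refractory neurons are logged as base events with no flip, so they
  dilute the learned base-flip probabilities by exactly their frequency in
  the training run.

Structurally, a gate neuron flipped down by an upward (external or E) kick
*fires* — it delivers recurrent kicks exactly as in the MIF — while
I-kicks flip gate→base silently. A table trained in one regime is reusable
in the others because the regimes differ only in waiting times, not in the
per-kick geometry of the voltage distribution.

**Known limitation.** The closure carries no information about *where* in
the base (or gate) interval a neuron sits, nor about refractory timing.
In the homogeneous regime the RN tracks the full model closely; as
synchrony grows the bias grows, because a firing volley depletes the
near-threshold end of the gate interval faster than the count-conditioned
average can express. At the synchronized baseline the RN overestimates
firing rates by roughly 30–60% while preserving the gamma-band spectral
peak, the I-before-E rate ordering, and the ordering of synchrony across
regimes. The test suite asserts exactly those preserved properties (rates
within a factor of two, peak in the gamma band, SSI ordering), not a
tighter rate match.

## The coarse-grained chain (CG)

Merging all pending pools network-wide and forgetting neuron identities
leaves a four-variable Markov chain `(N_GE, N_GI, H_E, H_I)`: gate counts
per population and the two network pools. Because `τ_EE ≠ τ_IE`, the E
pool is split by fixed allocation fractions
`a_EE = P_EE N_E / (P_EE N_E + P_IE N_I)` (and `a_IE = 1 − a_EE`) rather
than tracked separately — the one approximation this level adds. The
inhibitory-side fractions `a_EI`, `a_II` are defined analogously. A
firing event adds the mean recipient count `M_E = P_EE N_E + P_IE N_I =
23.75` (or `M_I = 47.5`) to the matching pool.

From any interior state at most 12 distinct non-self transitions exist:
4 external (two base→gate flips, two gate fires), 5 pending-E (two flips,
two fires, one consumption without flip), 3 pending-I (two gate drops, one
consumption). Per-category rates close exactly: external events total
`(N_E λ_E + N_I λ_I)/1000` per ms, pending-E events total
`(a_EE/τ_EE + a_IE/τ_IE) H_E`, pending-I events total `H_I/τ_I`.

Numerical choices:

* The event-driven simulator drops no-op external events from the race
  (they change nothing, so the law is unchanged) and by default rounds the
  fractional pool increments stochastically (expectation-preserving). The
  generator uses fixed round-half-up integers (`24`, `48`) so each row has
  a fixed sparsity pattern of ≤ 13 nonzeros.
* The generator is assembled over a truncated box
  `[0..N_E]×[0..N_I]×[0..cap_E]×[0..cap_I]`; transitions that would
  exceed a pool cap get rate zero (truncation, not clipping). Caps are
  chosen from observed simulation maxima with headroom (≈1.2×) and are
  recorded in output metadata. A configurable state-count limit guards
  against accidental huge enumerations.
* The stationary law is the leading left eigenvector of the uniformized
  matrix `P = I + Q/Λ` (ARPACK), polished by power iteration until
  `‖πQ‖∞` is at machine level relative to `Λ`; tiny chains use a dense
  null-space solve. Reducible chains are restricted to the recurrent class
  reachable from the start state, with a warning. The computed law is the
  continuous-time stationary distribution (holding-time weighted), which
  is also what the time-sampled occupancy of a long simulation estimates —
  the suite checks the two agree in total variation on a reduced chain.
* The shrunk (SCG) lumping merges every `K` pending-kick counts into one.
  A lumped state lifts to the mid-cell raw pools `(H − 0.5)·K` (with 0
  lifting to 0 and `K = 1` an exact identity), transitions are sampled at
  the lifted state, and pool changes project back as
  `floor(x/K) + Bernoulli(frac(x/K))`, preserving expected drift exactly.

## Statistics

All statistics consume time-stamped, neuron-labelled spike trains and are
invariant under a global time shift.

* **Firing rates**: spikes per neuron per second per population; the first
  second is discarded by default to wash out the rest-state initial
  condition.
* **SSI** (spike synchrony index): for each spike, the fraction of the
  whole network with at least one spike within a ±2.5 ms window (the
  reference neuron counts), averaged over spikes; 1 for full synchrony.
* **PSD**: squared modulus of the DFT of the per-1-ms-bin, per-neuron
  spike density on the frequency grid `k/T`; the spectrogram applies the
  same on 256-ms windows with 10-ms stride (no taper). Peak searches
  start at 15 Hz to skip the DC/slow trend.
* **Correlograms**: per reference spike, target-population spikes within
  ±15 ms binned at 1 ms as within-window fractions, averaged over
  reference spikes.
* **MFE (spiking-volley) detection**: population counts in 1-ms bins; a
  bin is elevated if its count exceeds `(1+δ)` times the mean bin count
  (δ = 0.33); a volley is a maximal run of elevated bins tolerating 1-bin
  gaps with at least ε = 8 spikes. δ, ε, the bin width and the gap
  tolerance are parameters; this run-of-elevated-bins formalization is
  this package's concretization of the published threshold idea.

## Trajectory geometry

* **Local dimensionality**: participation ratio `(Σλ)²/Σλ²` of the
  correlation-matrix spectrum of a point and its K = 100 nearest
  neighbours (ties broken by index), on per-dimension standardized
  coordinates. Evaluation points are subsampled (default 2000) with
  probability proportional to squared distance from the density mode (the
  fullest cell of a 25-per-dim histogram), evening out trajectory
  coverage. Validated against a noisy planar cloud (median ≈ 2.1) and an
  isotropic 4-D Gaussian (median ≈ 3.9). On the synchronized-regime
  trajectory itself the median reads ≈ 3.7 rather than ≈ 2: the integer
  gate counts carry shot noise comparable to the K = 100 neighbourhood
  extent, which lifts the local rank above the dimension of the
  underlying sheet. Treat absolute trajectory values as
  resolution-dependent; the planar/Gaussian calibrations and the relative
  ordering across regimes are the meaningful outputs.
* **Entropy**: occupancy entropy `−Σ P log₂ P` over an `n⁴` grid on the
  trajectory bounding box (`n = N_I = 25` by default; degenerate
  dimensions collapse to one cell).
* **LLE**: k-nearest-neighbour graph (k = 20 default), reconstruction
  weights from regularized local Gram solves (rows sum to 1), embedding
  from the bottom non-constant eigenvectors of `(I−W)ᵀ(I−W)` scaled to
  zero mean and identity covariance; eigen-signs fixed by making each
  component's largest-magnitude entry positive. Per-component eigenvalues
  are returned so a planar cloud is recognizable by its two near-zero
  reconstruction costs. A disconnected neighbour graph is an error.

## Synthetic fixtures and what passing tests show

The fixture module generates the deterministic inputs the statistics are
calibrated on: fully synchronized trains (SSI = 1, comb spectrum), Poisson
trains (rate and window-occupancy oracles), burst trains (volley-detector
recovery), planar/Gaussian clouds (dimensionality and LLE oracles), and
explicit toy CTMCs (closed-form stationary laws). These fixtures have
none of the temporal structure of network data — no refractoriness, no
E–I interaction, no rate fluctuations — so passing them shows the
*estimators* are correct, not that the network statistics are
biologically calibrated. Network-level claims are tested on the
simulators themselves at reduced problem sizes: 3–10 s runs of the
100-neuron network, five-point parameter sweeps at 5 s per point, and a
~15k-state truncated chain for the ergodic stationary-law check; these
sizes keep the default suite within a typical CI budget while leaving
every statistical assertion several standard errors of headroom.

## Randomness and reproducibility

Every simulator takes an explicit integer seed and is bit-reproducible
for fixed `(parameters, duration, seed)`; the CLI derives per-stage and
per-sweep-point seeds deterministically from one run seed and records
them in the manifest. Statistical invariance across seeds (batch means
within batch standard errors) is part of the test suite.
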