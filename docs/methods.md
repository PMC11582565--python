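# Methods

## Kinetic scheme

The enzyme is a 10-state continuous-time Markov chain over conformational /
ligation states (row order M0, M1, M1\*, M, M\*, M2\*, M2\*\*, M\*\*, M1\*\*,
M3\*\*; asterisks count bound ligands).  Observable current levels depend only
on the LID/NMP arrangement, partitioning states into five emission groups
(M0, M, M1, M2, M3); the LID-closed group is {M2\*, M2\*\*, M3\*\*} and the
NMP-closed group {M1, M1\*, M1\*\*, M3\*\*}.  Bimolecular association enters
the generator as k₁·|ligand₁| (M → M\*, M1 → M1\*) and k₂·|ligand₂|
(M2\* → M2\*\*); for the ATP/AMP model ligand₁ = ATP and ligand₂ = AMP, for
the ADP model both are ADP.  The rate vector also carries r±₂, which the
kinetic scheme never uses; they are stored but never placed in the generator
nor fitted, and we deliberately do not guess their intent.

Variant topologies: V3 (full endosteric model) omits M\* ↔ M\*\* and keeps
r₁/r₋₁ distinct from r₃/r₋₃; V1 ties r₃ ≔ r₁, r₋₃ ≔ r₋₁; V2 restores
M\* ↔ M\*\* re-using k₂/k₋₂.  Each reduced variant removes exactly one
endosteric effect and keeps the other; the reductions are nested (V1) or
parameter-shared (V2) so all three expose the same parameter names.

## Units and discretization

Rates are stored in s⁻¹ (bimolecular: s⁻¹·mM⁻¹), concentrations in mM,
currents in pA, time in ms.  The ms/s conversion happens in exactly one
place — discretization, Γ = exp(Δt·Q/1000) via scipy's scaling-and-squaring
matrix exponential (verified against a truncated power series to 1e-10 on the
10×10 generators).  Δt defaults to 0.2 ms, the recording sampling interval.
Dose-response interfaces take µM because dissociation constants are reported
in µM; converters bridge the two.

## Likelihood

Scaled forward recursion with the transition matrix applied before *every*
emission including the first (L = δ′(∏ B_t)1, B_t = Γ·diag φ): the stationary
prior is propagated one step before the first sample is scored.  This differs
from the common textbook ordering by one transition and is deliberate.  The
stationary distribution δ′ is computed from Γ at each trace's own
concentrations.  Emission log-densities are computed per group and broadcast
to states; each forward step is rescaled by its maximal log-density and the
forward vector normalized to unit sum, so samples 25σ into the tails (e.g.
open-pore excursions) cannot underflow.  Uniqueness of δ′ requires exactly
one closed communicating class — at zero second-ligand concentration the
two-ligand states are unreachable but δ′ remains unique; an error is raised
only when several closed classes exist.  The recursion is an njit-compiled
kernel; exhaustive hidden-path enumeration and an independent HMM library
reproduce its values to 1e-10.

## Estimation

Bounded multistart maximum likelihood in log₁₀-parameter space: global bounds
[0.1, 10⁶] s⁻¹ map to [−1, 6], L-BFGS-B with finite-difference gradients
(step 10⁻⁴ in log₁₀ units), at most 200 iterations, six starts log-uniform
within the bounds, best kept.  The configured step tolerance (default 10⁻³)
is applied through the optimizer's relative-improvement threshold
(ftol = step_tol·10⁻⁶), which in practice terminates runs at comparable
parameter resolution.  Emission parameters can be co-estimated as one mean
offset per group (±3 pA around the canonical level — the interval width is a
package choice, as only "a short interval" is documented) and one σ per group
bounded to [7, 10] pA.

A 22-dimensional likelihood with six random starts frequently strands in
poor local optima.  Two documented-protocol devices address this:

1. **Data-derived bounds** (`derive_bound_overrides`): several elementary
   rates are pinned to within 1–2 orders of magnitude by event-level dwell
   statistics before any likelihood evaluation — LID opening from mean
   LID-closed dwells, k₁ from the closing frequency per unit concentration,
   b₂ from M2→M3 transition frequencies, b₋₂ from M3 dwells, M0 exchange
   from M0 dwells and visit counts.  Rates without an event-level signature
   (ligand unbinding, hidden second-ligand exchange) keep global bounds.
   Elementary closing rates get a wide downward band because a slow parallel
   closing channel can sit far below the pooled aggregate; M ↔ M1 event
   statistics get wide downward bands because noise chatter biases those
   frequencies upward.
2. **Cross-seeded comparison**: when ranking variants, each variant is
   polished once from the other variants' solutions (they share parameter
   names; V1 is nested in V3).  This prevents a lucky basin found under one
   topology from distorting the likelihood comparison.

Model comparison reports raw maximal log-likelihood differences, matching
how the original analysis compared models directly by likelihood; AIC/BIC are intentionally not
the primary output.

## Aggregate rates

For a rate vector and condition, one 20,000 ms sample path is simulated
(exact Gillespie; exponential sojourns, jumps proportional to off-diagonal
rates) and dwells are pooled by LID group; the LID closing (opening) rate is
the inverse mean *completed* dwell in the open (closed) group — the trailing
truncated dwell is discarded.  A group with no completed dwell reports the
rate as undefined rather than a number.  The NMP closing frequency is
computed the same way over the NMP grouping.  On a two-state chain this
estimator returns the elementary rates within sampling error, and at 200 s it
converges to the stationary-weighted group exit rates within 5%.

## Synthetic data

The generator emulates the recording campaign, not the amplifier: hidden
paths are sampled exactly, discretized at 0.2 ms (sojourns that straddle no
sampling instant leave no sample — deliberate aliasing, as in any sampled
recording), and emitted with white Gaussian noise per group.  Defaults are
the recording conditions: emission means from the reported residual-current levels
times the −433.3 pA open-pore current (M −199.3, M1 −211.0, M2 −221.0,
M3 −233.1, M0 −180 pA), σ = 8 pA (within the documented 7–10 pA), the
ATP/AMP design (0.01/0, 0.1/0, 1/0, 1/0.01, 1/0.1, 1/1 mM) and ADP design
(0.01–1 mM, 7 points), 3 replicates (within the documented 2–4) of 2000 ms
(within the 500–10,000 ms range).  Initial states draw from the condition's
stationary distribution.  Artifact injection overwrites stretches with
open-pore (≈ −433 pA) or shallow (≥ −160 pA) current to exercise the segment
filters.

White noise is an idealization: the real chain (10 kHz Bessel + 2 kHz
Gaussian filter) produces colored noise and rounded transitions, and real
molecules show per-molecule baseline offsets.  Passing tests therefore
demonstrate correctness of the inference machinery under the model's own
assumptions, not robustness to filtering artifacts; per-segment mean offsets
are the hook for molecule-to-molecule variability, with the offset magnitude
distribution unknown.

### Reference rate vector

The originally fitted elementary rates are reported only graphically, so the
canonical simulation rates are anchored to the reported kinetic constants:
k₁ = 2200 mM⁻¹s⁻¹ (association 2.2 µM⁻¹s⁻¹), r₋₁ = 693.4 s⁻¹ (binary LID
opening), b₁/b₋₁ = 4.66/55.2 s⁻¹ (apo NMP exchange), b₂ = 200 s⁻¹ (NMP
closing), b₋₂ = 3400 s⁻¹ (M3 exit).  The remaining rates were chosen once so
the simulated aggregates reproduce the reported aggregate kinetics —
r₁ = 1300 s⁻¹ gives aggregate LID closing ≈ 1000 s⁻¹ at 1 mM ATP (open-group
dwells restart at M\* after reopening, so r₁ must exceed the aggregate), and
k₂ = 3000, k₋₂ = 300, r₋₃ = 50, r₋₄ = 25 s⁻¹ give ternary aggregate opening
≈ 120 s⁻¹.  These three reported anchors (association slope, binary opening,
~1000 s⁻¹ closing) cannot be satisfied simultaneously by a sequential
bind-then-close scheme together with the reported 75.9% closed fraction; the
aggregate-rate anchors take priority, and the 75.9% figure is instead
reproduced by the separate two-state consistency check.

## Event analysis

Segment screening uses a centered 50 ms sliding mean (the window length is a
package choice) with cutoffs −350 pA (open pore; "around −400" is
approximate) and −160 pA (shallow).  Idealization assigns (optionally
boxcar-smoothed) samples to the nearest configured level — equivalent to
half-amplitude thresholds — compresses runs, and merges events shorter than
the minimum dwell into their flanking events, shortest first; the vendor
search algorithm is undocumented, and this is the standard single-channel
equivalent with fixed thresholds.  Defaults: 0.1 ms minimum dwell for level
events, 1 ms for blockade classification.  With σ = 8 pA and levels ≈ 12 pA
apart, 1 ms smoothing plus 1 ms minimum dwell recovers ≥ 95% of events with
dwells ≥ 2 ms.  Dwell fits offer a binned least-squares single exponential
(bin width near the expected dwell) and the direct exponential ML estimator
(the sample mean).  All-point histograms use 0.1 pA bins anchored at 0 pA so
edges reproduce across runs; level occurrence uses Gaussian peak *heights*,
not areas.

## Problem sizes and numerical choices

Tests and the acceptance script run reduced designs chosen as the package's
working scale: refits use 6 conditions × 1000 ms (one replicate), model
selection 6 conditions × 800 ms with 2 multistarts plus cross-seeding, and
dose-response recovery 7 concentrations × 3 replicates.  At these sizes the
V3-over-V2 likelihood margin is a few log-units (their discrimination relies
on the concentration scaling of the spurious exchange flux, since the
exchange links states with identical emissions); the tied-rate variant V1 is
rejected by >100 log-units.  Degenerate inputs are handled explicitly:
constant-current histograms return flagged moment estimates; generators with
absorbing, unreachable states fall back to a uniform initial state for path
simulation and report undefined aggregate rates for never-exited groups.
Bootstrap confidence intervals are case-resampling percentile intervals and
are labelled plumbing — the original interval method is not documented.

## Known limitations

* The ADP-model topology is built by analogy (single species binding both
  sites); its authoritative diagram is not in the available text.
* The exact per-group emission means used in the original fits are only
  approximately recoverable from reported residual currents.
* No Baum–Welch/EM, no Viterbi decoding, no Hessian or profile-likelihood
  uncertainties; no modelling of capture/escape events, voltage protocols,
  alternative blockade types, or the Ap5A-bound fully-closed level.
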