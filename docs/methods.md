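# Methods

This note documents the models implemented in `extsig`, the numerical
choices behind them, what the simulators do and do not emulate, and the
known limitations.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Time trees

All trees are rooted, strictly binary, and time-calibrated with ages
measured back from the present (present = 0).  A node is a lineage
segment from its `birth` age (the parent's splitting age) down to its
`end` age; tips with `end > 0` are extinct.  The root is the crown node
(zero-length root edge); the stem lineage is not modeled, matching the
convention that a clade's history starts at the first split among its
sampled descendants.  Trees round-trip through Newick via dendropy; on
reading, the deepest tip defines the present and shallower tips are
interpreted as extinct.  Time comparisons use an absolute tolerance of
1e−9.

## Conditioned birth–death simulation

### Generalized sampling approach (GSA)

For regimes without a fixed recent history (constant-rate BD and HE, and
the crown-anchored decaying-rate grid), the forward Gillespie process is
run from a crown pair until extinction or a lineage cap (10·N for
supercritical regimes; eventually-subcritical schedules run to
extinction).  The "present" is then drawn uniformly, duration-weighted,
among the periods during which exactly N lineages were alive, and the
tree is truncated there.  This is the standard conditioning on N
survivors under an improper uniform prior on the observation age.

Sampling across runs proportional to each run's total N-period duration
W requires an upper bound on W, which near-critical regimes do not have.
We therefore use clipped rejection: a pilot of 300 usable runs sets
C = 1.5·max(W); subsequent candidate runs are accepted with probability
min(1, W/C).  Runs with W above the clip (rare by construction) are
slightly under-weighted; the test suite checks the sampler against a
naive rejection oracle (uniform random checkpoint on unconditioned
forward runs) and against an independent implementation of the same
conditioned process in `ape::rphylo`.

### Episodic regimes (fixed recent history)

The mass-extinction (ME) and rate-shift (SRD) scenarios fix a recent
epoch program measured back from the present: e.g. for ME, rates
(λ=2, μ=0.3) until an event at age 1 in which each lineage survives
independently with probability ρ = 0.1, then (λ=2, μ=1) until the
present.  Joint conditioning on N extant tips *and* the event age uses
the same improper-uniform-age logic: the crown-to-event duration τ is
drawn uniformly over a span covering all viable durations (calibrated by
pilot runs), the forward process is run through the epoch program, and
the draw is accepted iff exactly N lineages reach the present.  Accepted
draws are therefore exact samples from the joint conditional, up to two
documented truncations: lineage counts above a threshold at which the
probability of returning to N is < 1e−12 are aborted, and the uniform
span is finite (1.2× the largest pilot run).  Retries are bounded
(400 000) with a diagnostic error.

### The decaying-rate (DDC) grid

The diversity-dependent scenario holds μ = 0.01 and decays speciation on
a discrete grid, λ = λ₀·e^(−K·t_cell) with λ₀ = 6, K = 5 and cells of
0.2 time units, taking the printed sequence 6, 2.21, 0.81, 0.29, 0.11,
0.04.  The grid can be anchored two ways and the source material is
ambiguous about which:

* **present-anchored** (default): the oldest phase runs at λ₀ and the
  rate steps down cell by cell toward the present (the convention of
  shift-time simulators that measure time back from the present, and the
  natural reading of the ascending printed sequence);
* **crown-anchored**: the grid is measured forward from the crown.

We verified by large-replicate simulation that only the present-anchored
version reproduces the published tree-shape signature of this scenario
(strongly negative γ near −5 with ~0.2 extinct tips per tree; the
crown-anchored variant yields γ near the −7.3 saturation limit and ~7
extinct tips because the conditioned present falls long after the rate
collapse).  Both anchors remain available via `ddc_regime(anchor=...)`.

### What the simulators emulate — and what they do not

The generators reproduce the study conditions exactly as printed: N = 20
extant tips, 10 replicates for table-shaped output, the rate sets listed
in the README.  They do not emulate phylogenetically clustered
(overdispersed) taxon sampling, fossilized lineages, protracted
speciation, or diversity-dependence implemented as a feedback on the
standing lineage count (the DDC grid is a deterministic time proxy).
Passing tests therefore demonstrate correctness of the algorithms under
these idealized processes, not robustness to the sampling biases of real
phylogenies.

A calibration note: several published 10-replicate table cells
(constant-rate extinct-tip mean, sampled-γ medians, ME γ median) sit
1–2 standard errors from the large-replicate expectations of the process
they describe; our acceptance tests therefore check each such cell
against the Monte-Carlo sampling interval of a 10-replicate summary
statistic estimated from a 300–500 replicate pool, rather than against a
tight band around the printed number.  Two independent implementations
(`ape::rphylo` for the conditioned simulation itself, and a naive
rejection sampler) agree with our large-replicate values.

## Gamma statistic

With g_k the duration during which the reconstructed tree has exactly k
lineages and T_k = Σ_{j=2..k} j·g_j,

    γ = [ (1/(n−2))·Σ_{i=2..n−1} T_i − T_n/2 ] / ( T_n·√(1/(12(n−2))) ).

γ is undefined for n < 3, invariant under rescaling time, and
asymptotically standard normal under the pure-birth model — properties
the suite asserts (including a KS test on 1000 conditioned pure-birth
trees and a cross-check against `ape::gammaStat`).  Replicate summaries
report medians with 2.5–97.5 percentile intervals: with 10 replicates a
percentile range is the only computable reading of a "95% interval".
Average LTT curves align replicates at the present on a 200-point grid
from the oldest root; at ages older than a replicate's own root that
replicate contributes nothing (not zero), because complete trees have
varying ages and initial counts.

## Episodic birth–death likelihood

The likelihood of a reconstructed ultrametric tree uses two scalar
functions of age: x(t), the probability that a lineage at age t has at
least one sampled descendant, and q(t), the density of surviving to the
present as a single observed lineage.  Within an interval of constant
(λ, μ), x obeys the logistic equation dx/dt = rx − λx² (r = λ − μ) and
q satisfies dq/dt = (r − 2λx)q, both with closed forms; crossing a
sampling event of survival ρ multiplies both by ρ, and the present-day
sampling fraction ρ₀ enters as x(0) = q(0) = ρ₀.  With branching ages
x₁ ≥ … ≥ x_{n−1},

    log L = Σ_{i≥2} [log λ(x_i) + log q(x_i)] + 2·log q(x₁) − 2·log x(x₁),

conditioned on the crown age and on both crown lineages being
represented — the same convention as `ape::birthdeath`, with which the
ML estimates agree to ~1e−3 on a 200-tip tree in the test suite.  The
closed forms are validated against numerical ODE integration
(`solve_ivp`) to 1e−7, and the μ = 0, ρ = 1 limit against the forward
pure-birth density.  r → 0 is handled through `expm1`-based expressions.

### Estimating the event age

`fit_me_time` profiles the likelihood over a grid of candidate event
ages (default: crown age / 100 steps) with λ and μ shared across the
event and ρ free — fixing the rate shift to zero is the standard
identifiability workaround, since the shift and the event intensity
cannot be estimated jointly.  Each grid point maximizes over
(λ, μ, ρ) by Nelder–Mead from both a warm start (previous grid point)
and a cold start; the best grid point is refined by bounded scalar
optimization, and ties break toward the more recent age.  A profile
whose total range is below 2 log-units is flagged flat (no signal)
rather than raised as an error.  On 20-tip trees the estimator scatters
widely around the true age (and TreePar-style grid searches snap to grid
points); consistency is demonstrated on 100–200-tip trees, where the
median estimate lands within a few percent of the truth.  The published
accuracy/precision rows labelled "MAPE" and "PREC" are not reproduced —
their definitions are never given — and the incomplete-sampling
experiment reports mean absolute error and percentile-interval width as
clearly named substitutes.

## DEC model

States are the bitmask ranges {∅, A, B, AB}; the generator has
dispersal entries A→AB (D_AB), B→AB (D_BA), extirpation entries A→∅
(E_A), B→∅ (E_B), AB→B (E_A), AB→A (E_B), zero direct A↔B entries
(two instantaneous events would be required) and zero AB→∅.  Transition
probabilities are exp(Qt) (scipy `expm`; likelihood evaluation uses a
verified eigendecomposition fast path).  At cladogenesis a single-area
range is inherited identically; AB splits by vicariance (A | B) or
peripheral-isolate speciation (AB | A, AB | B), the three outcomes
equiprobable — the reference DEC convention.  The root prior is flat
over the observable ranges {A, B, AB}; no prior is stated in the source
material and a flat prior matches reporting a single root-range call.
`dec_fit` maximizes over one dispersal and one extirpation rate (the
standard 2-parameter model) on log scale by Nelder–Mead from two starts;
the root call is the argmax marginal with exact ties reported as ties
(and counted as wrong calls in the experiment, conservatively).
The pruning likelihood is verified against exhaustive enumeration over
all internal-node states and cladogenetic outcomes on trees of up to 5
tips.

## Range-dependent diversification and the asymmetric-extinction experiment

The forward simulator is GeoSSE-style: a lineage in A speciates at s_A
(daughters A, A), dies at x_A, expands at d_AB; an AB lineage speciates
within A at s_A (daughters A | AB), within B at s_B (B | AB), between
areas at s_AB (A | B), and contracts by extirpation (AB→B at x_A,
AB→A at x_B); full lineage extinction strikes only single-area ranges.
Which daughter continues the parent's bookkeeping lineage is randomized
so asymmetric outcomes remain exchangeable.  Conditioning on N extant
tips reuses the GSA machinery.

The experiment simulates trees rooted in AB under three extinction
scenarios — equal rates (E_A = E_B = 0.9), moderate asymmetry
(E_A = 0.9, E_B = 1.9) and strong asymmetry (E_A = 0.4, E_B = 1.9) —
prunes extinct lineages, fits DEC to the extant tip ranges, and scores
the fraction of root calls ≠ AB plus the fitted rates.  The source
material never prints the speciation and dispersal values it used, so
the package fixes s_A = s_B = 1.0, s_AB = 0, d_AB = d_BA = 0.5, N = 20
as defaults (configurable); accordingly the acceptance surface for this
experiment is the qualitative pattern — the wrong-root fraction grows
with E_B − E_A and the fitted extirpation rate undershoots the
simulating extinction rates by orders of magnitude — not the plotted
percentages.

The model-correctness of the DEC fitter itself is established separately
by anagenetic simulation under the DEC chain along fixed trees
(`simulate_dec_states`), with pooled-likelihood recovery of (d, e)
within two observed-information standard errors.  Realizations in which
a tip reaches the unobservable null range are redrawn; the simulation
scale is chosen so this conditioning is a negligible perturbation.

## Event costs

The parsimony event-cost calculator scores a reconstruction as the dot
product of its event counts (vicariance V, duplication U, extirpation E,
dispersal D) with the default unit costs V = U = 0.01, E = 1, D = 2,
reproducing the three worked scenarios (2·U + 2·E + 1·V = 2.03,
2·U + 1·D = 2.02, 3·D = 6.0).  Full lineage extinction is not a scorable
event: it leaves no observable descendant.

## Problem sizes and determinism

Stochastic acceptance summaries use 300–500 replicates per scenario and
10 replicate fits for the event-age median; the test suite uses pools of
120–1000 trees chosen so the whole run completes comfortably on one CPU.
Every public sampler takes an explicit `numpy.random.Generator`; a seed
plus a configuration determines outputs bit-for-bit, which the suite
asserts at the level of serialized Newick and TSV bytes.

## Known limitations

* Exact GSA weighting is approximated by clipped rejection (above);
  episodic conditioning truncates the uniform age span at 1.2× the
  largest pilot run.
* Only one mass extinction per regime; no greedy multi-shift search, no
  Bayesian event detection, no diversity-dependent likelihoods.
* DEC is limited to two areas, without founder-event (jump) speciation;
  GeoSSE-style *inference* is out of scope (only forward simulation).
* The event-age estimator's small-sample scatter on 20-tip trees is
  intrinsic to the likelihood surface, not tightened here.
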