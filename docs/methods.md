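# Methods

## Model and likelihood

All computations assume the Jukes–Cantor (JC69) substitution model:
equal equilibrium base frequencies (¼ each, not configurable) and a single
exchange rate, so the transition probability over a branch of length *d*
(expected substitutions per site — the unit of every branch length in the
package) is ¼ + ¾·e^(−4d/3) for identity and ¼ − ¼·e^(−4d/3) otherwise.

A quartet tree is either the star (four terminal branches b₁..b₄, internal
branch structurally zero) or one of the three resolved pairings 12|34,
13|24, 14|23 with a fifth, internal branch b₅ ≥ 0. The star is exactly the
b₅ = 0 boundary of every resolved topology, which is what makes the
star-vs-resolved comparison a nested, one-degree-of-freedom test.

Column probabilities come from the pruning algorithm, evaluated once per
JC69 pattern class (15 classes) rather than per column; class counts then
weight the per-class log-probabilities. The 256 → 15 collapse is exact
under JC69 and is the package's key efficiency contract. An invariant used
throughout the tests: multiplicity-weighted class probabilities sum to 1
for any tree and any rate multiplier.

If a class with a positive count has probability exactly zero (e.g. an
all-distinct column on a tree with all branch lengths zero), lnL is −∞;
this is the mathematically correct value, returned as `-inf` rather than
raised as an error so that optimizer restarts passing through such corners
stay usable.

## Continuous-gamma rate heterogeneity

Site rates follow a mean-1 gamma with shape α (shape = rate = α; variance
1/α). The marginal class probability is ∫ g(r; α) · L(class | r·b) dr,
integrated by adaptive vector quadrature (`scipy.integrate.quad_vec`,
relative tolerance 1e−9, all 15 classes in one adaptive pass, so a full
lnL costs one quadrature call).

The integral is computed in quantile space: substituting r = F⁻¹(q) for
the gamma CDF F gives ∫₀¹ L(class | F⁻¹(q)·b) dq, whose integrand is
bounded and smooth for *every* α. This matters at both extremes: for
α < 1 the gamma density is unbounded at r → 0 (an integrable singularity
that overflows naive weighted quadrature), and for very large α it is a
needle at r = 1 whose tails adaptive rules silently miss. The quantile
substitution absorbs the density into the measure, handles all tail mass
exactly, and needs no truncation. Fixed breakpoints at
{0.005, 0.05, 0.25, 0.5, 0.75, 0.95, 0.995, 1−1e−4} seed the adaptive
subdivision where the rate quantile changes fastest. A quadrature error
estimate above 1e−6 raises an integration-accuracy error.

As α → ∞ the gamma model collapses onto the constant-rate model; the test
suite asserts agreement within 1e−3 lnL units at α = 10⁶ on the largest
datasets used.

## Bounded maximum-likelihood fitting

Branch lengths are optimised inside a box [b_min, b_max] (defaults 0 and
10 — branch lengths above 10 are biologically implausible and the
likelihood is nearly flat there, but the cap is configurable, e.g. 50) and
the gamma shape on a log scale inside [1e−3, 10000] (upper cap
configurable, e.g. 5000). An estimate at a bound is reported in
`bound_hits`, never hidden: α̂ at the cap reads "no detectable rate
heterogeneity", terminal branches at the cap read "saturation".

The optimiser is L-BFGS-B on the *per-site mean* negative log-likelihood.
The per-site scaling keeps gradients of order 1; on the raw scale the
first (unit-Hessian) step of L-BFGS-B overshoots onto the b_max corner,
where the projected gradient vanishes and the search terminates at a
spurious point. Gamma objectives use a finite-difference step of 1e−6,
well above the quadrature noise floor of the lnL (the scipy default step,
~1.5e−8, sits below it and yields unusable gradients).

Three deterministic restarts are used: all branches at d̂/2 (d̂ = JC69
distance from the mean pairwise difference proportion implied by the
counts), at 0.1·b_max, and at 0.9·b_max, with α always started at 1; the
best restart wins and two runs with identical inputs give bit-identical
results.

Resolved-topology fits (including fixed-b₅ profile fits with b₅ > 0)
precede the gradient stage with two rounds of sequential one-dimensional
(Brent) optimisation of each parameter in turn. The reason is symmetry:
exactly equidistant data make the likelihood surface invariant under OTU
permutations, and gradient iterations started from permutation-symmetric
points stay on the symmetric manifold — which for the resolved surface of
G4-excess data is a *saddle*, not the maximum. Sequential single-edge
updates (the strategy tree programs use when optimising edge by edge)
break the symmetry deterministically and reach the asymmetric ridge optima
that characterise these surfaces. On such ridges several parameter vectors
attain the same maximum; the maximised lnL, not the individual branch
values, is the quantity of record.

Star fits deliberately use the plain gradient stage from the symmetric
start grid. The star tree of an equidistant dataset is exchangeable in its
four branches, and the symmetric stationary point is the answer every
standard implementation reports. A caveat discovered while validating the
optimiser, worth recording: for adversarial pattern combinations with a
large G4 excess, the star surface itself can possess *asymmetric boundary
maxima* that beat the symmetric solution (for the combination
(24, 24, 12, 96, 32), branches (1.694, 1.694, 1.694, 0) exceed the
symmetric optimum by 0.36 lnL units — verified against brute-force state
enumeration). The default star fit intentionally reports the symmetric
solution; a profile fit with b₅ fixed exactly at 0 follows the same path,
preserving the star ≡ resolved-at-b₅=0 identity. Users probing such
pathological surfaces can fit the three resolved topologies, whose
symmetry-breaking path explores the wider surface.

A fit result records the fitted tree, α̂ (gamma fits), maximised lnL,
bound hits, a convergence flag (an L-BFGS-B line-search warning at an
essentially converged point is recorded, not raised) and the number of
restarts used.

## Star-vs-resolved test and goodness of fit

The likelihood-ratio statistic is 2(lnL_resolved − lnL_star) with the best
resolved topology (ties within 1e−6 resolve to the fixed order 12|34,
13|24, 14|23), referred to χ²₁ by default. Because b₅ sits on its boundary
under the null, the textbook reference is the 50:50 mixture of χ²₀ and
χ²₁; the mixture is available via `boundary_mix` but the plain χ²₁ test is
the default, matching common practice (and halving the p-value when
chosen). Tiny negative statistics from optimizer tolerance are clamped to
zero; a resolved fit materially below the star fit raises, since the star
is nested.

The goodness-of-fit check asks whether *any* single tree+model explains
the observed class counts: G = 2 Σ O_c ln(O_c/E_c) over classes with
O_c > 0, with expected counts from the fitted tree and model. Its null
distribution is built by parametric bootstrap — multinomial draws from the
fitted class probabilities, each replicate refit (default two restarts)
and its G recomputed — rather than an asymptotic χ² with a contested
degree-of-freedom count. The p-value is the fraction of bootstrap G values
at or above the observed one (default 200 replicates, explicit seed). If
an observed class has zero expectation G is infinite and the p-value is
reported as the upper bound 1/n_boot.

## Simulation

Sequence evolution is simulated exactly, not by event-level simulation:
per site, a uniform root state, an optional gamma rate multiplier, and
direct transition-probability sampling along each branch (a site changes
with probability ¾(1 − e^(−4d/3)) and lands uniformly on the other three
nucleotides — exact under JC69). On a resolved tree the root is placed at
the internal node next to the first cherry; JC69 is reversible, so root
placement is immaterial. Replicate *i* of a run seeded with *s* uses its
own generator seeded *s + i*, making individual replicates reproducible.

The simulator emulates: equidistant-in-expectation star data at any
divergence, rate heterogeneity via gamma multipliers, and the symmetrised
datasets used for star-recovery checks. It does not emulate: indels,
non-uniform base composition, transition/transversion asymmetry (invisible
to JC69 likelihoods), or among-lineage rate variation. Consequently,
passing tests demonstrate correctness of the JC69 machinery and the
claimed star/resolved phenomena under the model's own assumptions — not
robustness on real data, which violate all of the above.

`symmetrize` on pattern counts equalises the classes within G2, G3 and G4
(making the data support no resolved topology preferentially) and errors
if a group total is not divisible by the group size, so constructed
datasets are always exact. Simulated counts almost never divide evenly, so
the simulation pipeline's symmetrise flag first truncates each group total
down to the nearest multiple of the group size — dropping at most
5 + 3 + 2 sites — and then redistributes equally.

One property deserves emphasis because it is easy to over-claim:
symmetrised star-simulated data are *not* guaranteed a literal zero
likelihood-ratio statistic. Sampling fluctuation can hand a replicate a
mildly G4-rich combination whose resolved optimum sits at a genuinely
positive (if tiny) b₅ — observed gains of ~0.002 lnL units, identical
across all three topologies. The correct statement, and the one the tests
assert over seeded replicates, is that the star is never *rejected*: the
statistic stays far below any significance threshold and the fitted b₅ is
negligible.

The n₄-sweep utility shifts n₄ while holding n₃ fixed and preserving the
total alignment length by proportionally rebalancing n₁, n₂ and n₅
(weights equal to their current site contributions, n₂ counting six sites
per unit, rounded exactly; infeasible non-negative adjustments raise).
The rebalancing rule is exposed as a replaceable function, since any
length-preserving adjustment is admissible; proportional rebalancing is
the shipped default.

## Problem sizes in tests

The test suite uses desk-scale problem sizes chosen once: 20 symmetrised
star replicates (2528 sites each) for the star-retention check, 40
replicates × 49 bootstrap draws for the goodness-of-fit calibration check,
40 replicates for simulator-vs-expectation agreement, and 10⁴–2×10⁴ sites
for closed-form divergence checks. These keep each property comfortably
identifiable while the whole suite runs in minutes.

## Known limitations

- JC69 only. Under any model with unequal rates or frequencies (F84,
  HKY85, TN93, GTR) the 15-class collapse is invalid, so the machinery
  does not extend by swapping the transition matrix alone.
- Four OTUs only; no topology search beyond the three quartet pairings.
- No standard errors or confidence intervals on estimates.
- The discrete-gamma (category) approximation is deliberately absent: the
  package's purpose includes the exactly-integrated continuous gamma.
- On pathological equidistant data the likelihood surfaces have multiple
  optima and flat saturated plateaus; branch-length estimates on such data
  are reportable only up to the ridge, and only lnL values are stable.
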