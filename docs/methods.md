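# Methods

## Substitution model and ancestral inference

The phylogeny is fixed and rooted; every branch ("lineage", named after its
child node) carries an independent table of conditional substitution
probabilities P(child = y | parent = x, 5′ flank = a, 3′ flank = b): 16
flanking contexts, each a row-stochastic 4×4 conditional. There are no
branch lengths, no global rate matrix and no reversibility assumption — the
conditionals themselves are the parameters, which accommodates lineages
whose composition drifts. The flanking context is read from the **parent**
(ancestral) sequence, since rates condition the mutation process that acted
on the ancestor; whether ancestral or extant flanks should condition the
rates is genuinely open, and this choice is recorded here as the package's
convention. The root sequence follows a 2nd-order Markov model (transition
table plus a joint distribution for the first two positions).

Ancestral inference runs loopy belief propagation on a factor graph with one
variable per (node, site): per branch and site a factor over (parent j−1,
parent j, parent j+1, child j); per root site a triplet chain factor; leaf
evidence as unary one-hot factors. At the ends of a block the missing flank
is treated as a latent uniformly distributed nucleotide. Messages are
flooding-scheduled (variables, then factors), damped by 0.25, and iterated
to a maximum message change below 1e-6 (cap 200 iterations; non-convergence
raises an error carrying the delta trace). With context-free rates the
factors decouple per site and BP is exact — the test suite checks equality
with brute-force enumeration (equivalently Felsenstein pruning) to 1e-8 on
all small instances, including the Bethe free energy, which then equals the
exact log-likelihood.

Long alignments are processed in 10 kb sub-blocks overlapping by two sites,
so every kept column retains its full flanking context; the root chain is
restarted at each sub-block boundary, a deliberate approximation that
touches only the two boundary columns of each block. Columns containing any
non-ACGT symbol in any leaf are masked and carry no likelihood.

Parameter estimation is a generalized EM. The E-step accumulates expected
(5′, 3′, parent, child) counts per lineage from the branch-factor beliefs
and triplet counts for the root model; the M-step row-normalizes both. The
Bethe free energy is tracked as the approximate log-likelihood; iteration
stops when the largest rate change falls below `tol` (default 1e-4) or at
`max_iter`. Contexts with fewer than `min_columns` (default 200) expected
opportunities for a lineage are flagged and held at their initial values.
The standard initialisation is context-uniform with equal off-diagonals
(Jukes-Cantor-like); exactly uniform rows are a degenerate EM fixed point
and are not used.

Two identifiability limits are worth knowing. First, the two branches
meeting at the root are only jointly identifiable (the root can slide along
that path without changing the likelihood), so recovery is only guaranteed
for lineages strictly below the root; the recovery tests assert on those.
Second, at realistic data sizes the per-entry relative error of *any*
consistent estimator is bounded below by counting noise — at 200 kb
(≈ 12.5 kb per context) entries of rate r carry a binomial floor of roughly
(2 · 12500 · r)^(−1/2) after reverse-complement averaging. The recovery
criterion therefore checks the context-averaged substitution-type rates
entry-wise at 10 % and the full context-resolved table at the median; the
default generator keeps all off-diagonal conditionals ≥ 0.03 so that every
pooled quantity is estimable at that scale.

Parsimony validation uses exhaustive small parsimony per column (memoised
over the ≤ 4^leaves distinct patterns): a column is counted only when the
minimum-substitution labelling of the internal nodes is unique; ties —
including the intrinsic ambiguity of placing a change on either side of a
degree-two root — are excluded and tallied. Rates are substitutions over
parent-state opportunity counts on the unambiguous columns.

## Spatial coupling of A/T gains and losses

From the focal branch's (parent, child) pair posteriors, position j gets
expected gain mass g(j) (sum of posterior over parent ∈ {C,G}, child ∈
{A,T}) and loss mass l(j) (the reciprocal block); conserved and
within-class pairs contribute nothing. Windowed sums over the *preceding*
horizon h (default 5 bp, never including j) give the net A/T divergence
D(j); D > 0.9 labels a gaining context, D < −0.9 a losing context, and the
background label requires a conserved window (total windowed event mass
below 1 − 0.9) rather than merely |D| ≤ 0.9. Because each position's own
mass conditions only on its predecessors, every unit of event mass enters
exactly one conditional-rate numerator (verified by a total-mass accounting
test). Opportunity counts are posterior-weighted by the inferred ancestral
nucleotide class.

The significance test preserves the total number of gains and losses and
the opportunity-site composition of the two context classes while breaking
the association between event direction and context: total gains are drawn
without replacement from the pooled C/G sites of the gaining and losing
contexts (a hypergeometric draw), losses likewise from pooled A/T sites,
and the null statistic is the resampled count of compensatory events
(gains in losing contexts plus losses in gaining contexts). Expected
fractional counts are rounded to integers for resampling; p = (1 + #{null ≥
observed}) / (B + 1) with B = 100,000 by default, so p is never below
1/(B+1). On instances small enough to enumerate, the Monte-Carlo p matches
the exact convolution of the two hypergeometrics, and under a simulated
null the p-values are uniform.

The planted-coupling positive control uses context-free rates. That is a
design point, not a shortcut: with context-dependent rates, a horizon-1
divergence context is *also* a flanking-nucleotide context, so context
modulation of rates masquerades as (or cancels) spatial coupling; the
clustering null shares this confound. Under context-free rates the only
spatial structure is the planted one, and the test isolates it.

## Synthetic worlds

The generator realises the inference model exactly: a root sequence from
the 2nd-order Markov model, then one draw per branch and site from
P(child | parent, parent flanks) in preorder. This one-draw semantics is
what makes "true rates" well-defined for recovery tests. A gradual
multi-sub-step mode (off-diagonal mass split so each step is ≤ 0.01, flanks
re-read from the evolving sequence) is available for realism experiments,
but it composes to a different effective conditional and is not the
default.

Default conditions emulate yeast intergenic DNA: stationary G+C 35 %
(A/T-ward mutational bias via a reversible base conditional), per-branch
divergence ≈ 0.12 with transition:transversion 2:1, and log-normal
context modulation spanning roughly four-fold — the spread seen in real
context-resolved C→T rates. Occupancy tracks are coupling · z(windowed
G+C) + N(0, noise_sd): a deliberately minimal stand-in that reproduces the
sign and strength of the occupancy/A+T anti-correlation and supports exact
quantile partitions, but none of the dinucleotide periodicity, ~147 bp
footprint structure, or measurement idiosyncrasies of MNase data — so
passing tests say nothing about occupancy *prediction*, only about the
downstream statistics. Compensatory pairs are planted on terminal branches
only (descendants would otherwise inherit inconsistent histories), at about
`excess` pairs per kb, each within the stated horizon. SNP panels draw
minor-allele counts from the folded diffusion spectrum with density ∝
(1 − e^(−2γ(1−x))) / ((1 − e^(−2γ)) · x(1−x)), γ = N·s of the minor
variant (neutral limit ∝ 1/x folded); allele identities then realise the
class label, so classes are exact by construction.

Everything is deterministic given the spec's seed; independent substreams
(`default_rng([seed, k])`) keep the occupancy noise and auxiliary draws
decoupled from the alignment simulation.

## Wright-Fisher model and analytic approximation

The forward simulation follows the initialize / sample / update-reference
procedure: fitness-proportional multinomial resampling of N binary genomes
(G = strong allele), per-site mutation at μ₁ (G→A) and μ₂ (A→G), burn-in of
4 coalescent times (4N generations), and a reference genome R updated
whenever a site's major allele exceeds frequency 0.95 and differs from R,
incrementing the corresponding fixation counter. Exposure (N_A, N_G) is
tallied from R once per generation, in site-generations, so the neutral
estimator N_{G→A}/N_G equals μ₁ exactly in expectation — the per-sampled-
individual tally would divide this by N. Landscapes: goal f(n) =
exp(−η(n−n_opt)²) — a log-quadratic chosen over a truncated parabola
because fitness must stay positive — and threshold f(n) = min(1,
exp(−η(n−n_opt))). Both reduce to neutrality at η = 0.

The analytic approximation treats the population as a single resident
genome whose G/C count n performs a birth-death walk: λ⁺(n) =
Nμ₂(L−n)·u(s⁺), λ⁻(n) = Nμ₁n·u(s⁻), with s the marginal fitness change and
u(s) the haploid diffusion fixation probability (u(0) = 1/N, computed in
log space with saturation guards for 2N|s| ≫ 1). The stationary law follows
from detailed balance (verified to 1e-10); per-site substitution rates are
exposure-weighted expected fixations per site-generation, matching the
simulator's estimators; at η = 0 the chain is Binomial(L, μ₂/(μ₁+μ₂)) and
the rates equal the mutation rates exactly. An independent brute-force
check builds the complete population-composition Markov chain at N = 10,
L = 2 and agrees with the birth-death mean G+C within 5 % at θ ≤ 0.01.

Defaults are N = 10,000, L = 20, μ₁ = 7·10⁻⁷, μ₂ = 3·10⁻⁷ (θ = 0.014,
within the θ < 0.04 drift-dominance bound). Simulation-based tests rescale
to N of a few hundred with μ scaled up (preserving Nμ and Nη where the
comparison requires it) so that tens of fixations accumulate in seconds;
the analytic chain always runs at the full printed parameters.

## SNP stage

Informative sites are intergenic, biallelic, called in more than 20
strains. The major allele is the more abundant one; exact 50/50 ties have
no defined major allele and are excluded and tallied. Minor-allele
frequencies use the per-site number of called strains as denominator (call
counts vary across sites; a fixed denominator would bias sites with missing
data). Rare means frequency strictly below 0.20 (0.14 and 0.30 available as
robustness settings). Class comparisons use the 2×2 Pearson chi-squared
without continuity correction, appropriate at the class sizes the analyses
produce; a warning is attached when an expected cell drops below 1.

## Problem sizes used by the test suite

Chosen as the smallest scales at which each property is statistically
decidable: EM recovery at 200 kb on a three-leaf tree; planted coupling and
horizon robustness at 100 kb on the five-taxon tree with 300 planted pairs;
ancestral-G+C stationarity at 40 kb with 10 occupancy bins; simulator
versus analytic agreement at N = 300 over 2·10⁵ generations per intensity;
coupling-test calibration with 200 replicates of 2,000 resamples; SNP tests
at 10,000–20,000 sites. Monte-Carlo tolerances are 3 standard errors
computed from the realised event counts.

## Known limitations

* Loopy BP is exact only without context coupling; with it, posteriors and
  the Bethe log-likelihood are approximations (empirically, expected event
  counts match realised counts to within sampling error in the regimes
  tested, and EM recovery matches a perfect-ancestor counting oracle).
* Root-adjacent branch rates are only jointly identifiable; reported
  per-branch values for the root's two children depend on the root prior.
* The occupancy generator is an affine G+C surrogate; no claim of fidelity
  to MNase data is made or needed by the statistics built on it.
* The coupling test conditions on one focal lineage at a time;
  cross-lineage compensation is out of scope.
* Indels are not generated; the alignment path assumes gapless blocks and
  masks non-ACGT columns.
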