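# Methods

`phaseuncouple` asks a single scientific question of a clade with a complex
life cycle: do the larval and adult phases evolve as one coupled phenotype,
or as two largely independent ones?  It answers it with a chain of analyses
on a time-calibrated phylogeny — categorical-morphology distances reduced by
ordination, diversification-model selection, disparity through time,
Bayesian branch-rate inference, multi-optimum Ornstein–Uhlenbeck (OU)
regime-shift detection, randomization tests for cross-phase shift
concordance, likelihood-ratio tests of pairwise character coevolution, and a
phase-bias classification of expression data.  A seeded synthetic-data
module generates every input with the statistical structure the analyses
assume, so the whole chain is testable without external data.

Conventions used throughout: trees are rooted and ultrametric with node ages
in Myr measured backwards from the present (tips at age 0, root at age `T`);
a branch is identified by its child node; traits are indexed in `tree.tips`
order.

## Tree and character data model (`phylo_io`)

Trees are stored as flat parent/length/label arrays.  Newick and NEXUS
parsing is delegated to dendropy; after reading, tip depths are renormalized
so tips sit exactly at age 0 (empirical trees carry rounding), with
ultrametricity enforced to a relative tolerance of `1e-6 · T`.  Character
matrices hold small-integer states with `-1` as the missing marker;
polymorphic (bracketed) NEXUS entries are read as missing, and per-character
ordered flags are supplied by the caller because published matrices rarely
carry machine-readable TYPESETs.  Pruning to a common taxon set re-roots at
the MRCA of the retained tips and merges degree-2 nodes; patristic distances
among retained tips are preserved exactly.

## Character distances and ordination (`chardist`, `ordination`)

The pairwise distance between two species is the number of character-state
transformations summed over characters scored in both (`|i−j|` for ordered,
0/1 for unordered characters); missing data are handled by pairwise
deletion, with an optional per-pair normalization by the number of
comparable characters.  Recodings (all-unordered, binary 0-vs-positive) and
a drop-k character jackknife helper support robustness checks.

Non-metric MDS minimizes Kruskal stress-1 by SMACOF majorization alternated
with isotonic regression of the configuration distances on the
dissimilarities.  Ties are handled by the secondary (tie-averaging)
approach: tied dissimilarities share one disparity, so for example three
mutually equidistant points cannot be embedded on a line with zero stress.
Defaults: 20 seeded random restarts, convergence when stress changes by
< 1e-6 or at 500 iterations; the lowest-stress solution is returned with its
stress path (non-increasing by construction of the majorizer).  Because
stress is scale-free, the returned configuration is normalized to unit RMS
pairwise distance and centered; axes can be reordered by variance with a
deterministic sign convention (largest-magnitude loading positive).
Determinism is by seed; two NMDS implementations will in general agree in
stress but not in coordinates.

## Diversification models (`diversification`)

Six nested birth–death models of the reconstructed process are fitted by
maximum likelihood: constant or exponential speciation `λ(t)=λ0·e^{a·t}`
crossed with zero, constant, or exponential extinction `μ(t)=μ0·e^{b·t}`,
with time measured from the present into the past, so `a>0` means faster
speciation deeper in the past (an early burst reads `a>0` backwards in
time).  The likelihood is conditioned on the crown age and on survival of
both crown lineages; the survival integral
`G(t)=log(1+∫₀ᵗ λ(s)e^{ρ(s)}ds)` (with `ρ` the cumulative net
diversification) is integrated as the ODE `dG/dt = λ(t)·e^{ρ(t)−G}`, which
is stable in log space where the raw integral overflows; constant-rate
models use the closed form.  The pure-birth case reduces to the familiar
`(n−2)·log λ − λ·Σ(branch lengths)`, which serves as an exact oracle in the
tests.  Fitting uses bounded L-BFGS-B from Latin-hypercube starts
(λ0 ∈ (1e-6, 10), μ0 ∈ [0, 10), a, b ∈ (−2, 2)); models are ranked by AICc
with `n` = number of tips.  No incomplete-sampling correction is applied.

## Disparity through time (`disparity`)

Disparity is the mean squared pairwise Euclidean distance.  The DTT curve
evaluates, at each internal-node age from the root toward the present, the
mean relative disparity (subclade / whole tree) of the lineages alive just
*before* that node splits — under this convention the root point is the
whole clade and equals 1 identically.  The MDI is the trapezoid-rule signed
area, over relative time, between the observed curve and the median of
`nsim` (default 1000) Brownian-motion simulations whose rate is the ML
estimate from the data; the simulation engine is vectorized across
replicates (per-node running sums), so a 1000-simulation MDI on a 64-tip
tree costs milliseconds.  MDI is invariant to affine trait rescaling and is
centered on 0 under BM (mean −0.0002 over 50 replicates in the test suite);
negative values mean subclades partitioned morphospace early.

## Branch-rate heterogeneity (`rate_mcmc`)

Brownian-motion rate variation across branches is modelled by a set of
*shift branches*: each branch inherits the rate class of its nearest
ancestral shift (background class at the root).  The reversible-jump sampler
draws the number and placement of shifts, per-class rates, and the root
state, with moves {rate update 0.4, root update 0.1, split 0.25, merge
0.25}.  Priors: Poisson(1) on the shift count, uniform placement over branch
subsets, root state Normal(trait mean, (10·trait SD)²), and per-class rates
lognormal centred on the single-rate ML estimate with SD 6 in log space.
The rate prior doubles as the split proposal, so its density cancels in the
acceptance ratio and the dimension-change terms reduce to the Poisson ratio
times the move-probability ratio (the uniform-placement prior exactly
cancels the branch-choice Hastings factor); the split/merge pair is
algebraically reciprocal, which the tests check directly.  The prior is
deliberately diffuse: the Occam factor it induces is what lets the sampler
prefer zero shifts on homogeneous data while a planted 10× clade rate is
still detected essentially always.  Likelihoods use scalar Felsenstein
pruning (O(n) per evaluation).  Defaults mirror the production analysis
(two chains of 1e6 generations, first half discarded); tests run scaled
chains of 2e4 generations.  Branch rates are summarized as geometric means
over post-burn-in samples (arithmetic means and per-branch shift posterior
probabilities are also reported), cross-phase comparisons use Kruskal–Wallis
on the rate samples and Pearson correlation on per-branch z-scored rates,
and rates can be binned into 4-Myr intervals anchored at the present with
branch-length-weighted averaging.

## OU regime shifts (`ou_regimes`)

The multi-optimum OU (Hansen) model paints every branch with a selective
regime; per trait axis there is one attraction `α` (1/Myr), one diffusion
`σ²`, and an optimum `θ` per regime, all axes sharing the painting.  The
root state equals the root-regime optimum, tip means are the usual
exponentially-weighted averages of the optima along each root-to-tip path,
and the covariance is `(σ²/2α)·e^{−α·d_ij}(1−e^{−2α·s_ij})`.  Fitting
profiles `θ` by GLS and `σ²` analytically, leaving a 1-D search over
`log α` (grid `α·T ∈ [0.01, 500]` plus a bounded polish); as `α→0` the model
reproduces the BM likelihood, an identity the tests verify.

The shift search has two stages.  *Exploration* greedily adds the shift that
most decreases the plain summed-across-axes AICc, screening candidates at
the incumbent α and refitting the winner, until no addition helps.
*Selection* then prunes shifts by backward elimination, followed by a local
relocation polish, under a placement-corrected criterion that charges each
shift an extra `2·ln(#branches)`: a shift is the best of ~2n candidate
placements, so the best of ~2n χ²(1) noise improvements (~2·ln 2n) must not
clear the bar — without this term the stepwise search accepts spurious
shifts on homogeneous data almost surely, and with it applied during
exploration the search cannot take the first step toward genuinely paired
shifts whose joint support is decisive but whose single-shift margins are
not.  Model dimension is `K = axes·(optima+2) + shifts` on `n = tips·axes`
observations.  The backward *convergence* phase merges regime pairs toward
shared optima while AICc improves; the number of collapses is the
convergence statistic.  Its significance is a parametric bootstrap under
non-convergent nulls: datasets simulated with the fitted painting, α and σ²
but each regime's optimum redrawn from a normal with the mean and SD of the
fitted optima (simulating at the fitted optima themselves would reproduce
any observed convergence and destroy the test's power), rerun through the
full forward+backward procedure, with `p = (1+#{collapses ≥ observed})/(nrep+1)`
(default nrep 100).  Convergence detection draws its power from multi-axis
data — a chance near-coincidence of optima in all four axes at once is rare —
so the convergence tests run on 4-axis scenarios.  Phylogenetic half-lives
are `ln 2 / α`.

## Shift concordance (`shift_concordance`)

Two randomization tests compare phases.  The *node* test uses the shared
shift-node ratio `|A∩B| / max(|A|,|B|)` against a null that re-places both
phases' shift counts uniformly without replacement over all non-root nodes
(configurably internal-only).  The *direction* test, restricted to shared
shift nodes, asks how often the same child lineage carries the new optimum
in both phases, against independent uniform child choices.  P-values are
`(1 + rank)/(nreps+1)` with seeded uniform tie-breaking: the statistics are
coarsely discrete (a ratio with ≤ 9 attainable values), and counting ties as
"greater or equal" would leave the nominal 5% test rejecting at ~1%; with
randomized ranks the type-I error is 0.065 and the null p-values pass a KS
uniformity check at 200 replicates.  Shift counts can be binned into 4-Myr
intervals anchored at the present, and two phases' interval series compared
by Pearson correlation with pairwise NaN deletion.

## Pairwise character coevolution (`discrete_correlation`)

For every adult × larval character pair (binarized 0 vs >0; tips missing
either character pruned per pair), the dependent model (8 transition rates —
each character's gain/loss rate conditioned on the other's state) is
compared with the independent model (4 rates) by a likelihood-ratio test
with 4 degrees of freedom at α = 0.05.  Likelihoods use pruning over the
joint 4-state chain, with all branch transition matrices obtained from one
eigendecomposition of the rate matrix (scipy `expm` fallback if
ill-conditioned) and the root weighted by the stationary distribution of the
fitted matrix (uniform in the degenerate all-zero-rates case).  ML fits use
L-BFGS-B on log rates from Latin-hypercube starts, and the dependent fit is
additionally seeded with the duplicated independent optimum so the nesting
inequality holds numerically.  The summary reports the count and percentage
(one decimal) of significant pairs plus Benjamini–Hochberg q-values, since
the appropriate multiplicity handling is a judgment left to the analyst.

## Expression phase bias (`expression_phase`)

Genes are classified by the adult/tadpole FPKM ratio: > 1.6 adult-biased,
< 0.4 tadpole-biased, otherwise even; genes under an expression floor
(default FPKM 1.0) in both phases are unclassifiable, and under the floor in
exactly one phase a gene is biased toward the expressed phase (this floor
rule avoids ratios of near-zero values).  Morphology association is a
case-insensitive keyword match of annotation text against a term list, and
the proportion of morphology-associated genes in each biased class is
compared with the evenly-expressed class by a two-sided pooled two-proportion
Z-test (degenerate pooled proportions return z=0, p=1).

## Synthetic data (`synthetic_data`)

All generators take a seed (or Generator) and are exactly reproducible.

*Trees* come from a forward birth–death simulation started at the crown and
conditioned on the tip count by stopping at the first event after the
process reaches `n` lineages (so the holding time at `n` is included, which
makes the expected Yule root age `Σ_{k=2..n} 1/(λk)` — verified at 10%
tolerance over 500 replicates); extinct lineages are pruned and runs that
die out or stall are retried.  An exponentially decaying speciation rate
(thinning algorithm) produces early-burst trees for the model-selection
power tests.

*Two-phase traits* are BM with planted clade rate multipliers (default 10×)
or OU with planted regime shifts; in coupled mode both phases share the
shift branches, in uncoupled mode they are placed independently.  Planted OU
regimes are designed to be identifiable — this is what "planted strong
shift" means here, and each constraint removes a genuine degeneracy found
during design: disjoint subclades (a shift nested inside an equal-optimum
regime is invisible), clade sizes between `min_clade` and half the tree (a
near-whole-tree regime is confounded with the background), not on the root's
children (confounded with the root state), onsets at least two phylogenetic
half-lives before the present (so clades actually reach their optima), and
alternating-sign optimum offsets of `theta_offset_sd` (default 4) stationary
SDs so all optima are mutually distinct; a `convergent_regimes` flag instead
gives every planted regime one shared optimum for convergence testing.
Default `α = 1.5`/Myr puts the ratio of tree depth to half-life near 8 on
the default trees, in the range implied by the empirical adult-phase
half-lives.  Defaults: 64 tips, 20 characters per phase, 2000 genes — sizes
chosen so the full test battery runs in minutes.

*Discrete characters* evolve under Mk chains (nearest-neighbour steps for
ordered characters), with optional missing cells and optional dependent
binary pairs whose second character switches toward matching the first at
`d·rate` and away at `rate/d`.

*Expression tables* are lognormal FPKM (baseline `lognormal(1.5, 1)`,
per-phase noise SD 0.15 in log space — small enough that unbiased genes
produce < 5% false classifications at the 1.6/0.4 thresholds) with planted
biased fractions receiving a 4× phase effect, and morphology flags drawn at
0.35 for biased classes vs 0.15 for even genes (qualitatively mirroring the
enrichment ordering the real data show); annotations are assembled from
morphology and housekeeping term pools so keyword flagging can be tested
against an independent regex scan.

## What the synthetic tests do and do not show

The generators reproduce the *statistical* structure the methods assume —
ultrametric trees, Markovian character change, Gaussian trait processes with
piecewise-constant parameters, lognormal expression with multiplicative
phase effects.  They do not emulate correlated characters within a phase,
ordination distortion of real categorical data, phylogenetic error,
among-lineage sampling biases, or library-size artefacts in expression data.
Passing tests therefore demonstrate correctness and calibration of the
implementations under their own model assumptions, not robustness of the
biological conclusions to violations of those assumptions.

## Numerical choices and limitations

Ultrametricity tolerance `1e-6·T` with exact tip renormalization; quadrature
via LSODA at rtol 1e-8/atol 1e-10; Cholesky jitter `1e-12` on OU
covariances; AICc ties broken by original order; forward-search ties by
preorder branch index; randomization p-values never 0 by the `(k+1)/(n+1)`
rule.  Known limitations: the OU search is greedy and can misplace shifts by
one branch on weak signals (tests count immediate neighbours as recovered);
the rjMCMC uses full-likelihood recomputation per move (adequate at n ≤ a
few hundred tips); the diversification models assume complete sampling; and
the discrete-character test binarizes multistate characters, discarding
within-character ordering information.
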