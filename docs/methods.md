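# Methods

`shiftorder` asks an ordering question on a dated phylogeny: when a lineage
both colonized a novel environment (here: mountains) and shifted to a new
functional pollinator group, which came first?  The package implements the
full inference chain — discrete-character likelihoods and ancestral
reconstruction, shift-path extraction and 1:1-line classification,
correlated-evolution testing, climate-niche summarization, and
phylogenetically corrected regressions — together with a synthetic-data
generator whose ground truth makes every stage testable.

## Characters and their models

Two discrete characters live on the tips of a dated, (near-)ultrametric
tree with branch lengths in Myr:

* **Pollination syndrome**, 4 states: `bee` (ancestral, buzz pollination),
  `generalist`, `nectar_vertebrate`, `foodbody_vertebrate`.  For the
  ordering analysis the three non-bee states are merged into "shifted".
* **Elevation category**, 4 left-closed bins of the per-species median
  elevation: E1 < 500 m, E2 [500, 1000), E3 [1000, 1500), E4 ≥ 1500 m.
  Binarization to lowland/montane is done at a cutoff c ∈ {500, 1000,
  1500} m; "montane" aggregates every bin whose lower boundary is ≥ c.
  The left-closed convention is used everywhere (bins, montane flags), so a
  species with median elevation exactly 1000 m is montane under the 1000 m
  cutoff and sits in bin E3.

Character evolution is modeled as a continuous-time Markov (Mk) process
with rate matrix Q (per Myr).  Three parameterizations are supported: SYM
(one rate per unordered state pair, k(k−1)/2 free rates), ARD (every
ordered pair free, k(k−1)), and CONSTRAINED (ARD with a user-supplied zero
mask; masks are data, shipped as a CSV of forbidden transitions, because
biologically motivated constraints belong to the analysis, not the code).

The likelihood is computed by Felsenstein pruning with per-branch
transition matrices P(t) = exp(Qt).  Exponentials come from one
eigendecomposition of Q per likelihood evaluation, vectorized over
branches, with a scaling-and-squaring `expm` fallback whenever the
eigenbasis is ill-conditioned (condition number > 1e8) or row sums drift
beyond 1e-8; state spaces are at most 16.  Partial likelihoods are
renormalized per node, accumulating log scale factors, so underflow cannot
occur on large trees.  Missing tip states enter as uniform partial
likelihoods.  Root priors: uniform, stationary, or FitzJohn weighting
(default) in which each root state is weighted by its relative contribution
to the likelihood.

Marginal ancestral probabilities use the standard inside–outside pass
(equivalent to rerooting at every node): the "outside" vector of a child
combines the parent's outside vector with the siblings' branch messages,
and the node posterior is the normalized product of inside and outside
vectors.  Exactness is enforced in the tests against brute-force summation
over all internal-state assignments on trees of up to 6 tips and 3 states.

**Fitting.**  Rates are optimized on the log scale with L-BFGS-B inside
bounds [1e-9, 100] per Myr, with multi-start (default 5 restarts spread
±2 log-units around 1/tree-height; deterministic under the seed).  Model
selection among schemes is by AIC with ties going to fewer parameters;
schemes are fitted in order of increasing parameter count and each solution
seeds the next richer scheme, which keeps nested log-likelihoods monotone.

**State-dependent diversification (MuSSE-style).**  The SSE engine
integrates the standard clade/extinction ODE system per branch
(`solve_ivp`, adaptive Runge-Kutta, rtol 1e-8 / atol 1e-10, checkpointed at
nodes), with tip conditions E_i(0) = 1−ρ, D_i(0) = ρ·1[state], λ-weighted
products at nodes, and optional survival conditioning.  When all λ are
zero the parameterization contains no speciation events; the node factor is
then omitted and the likelihood reduces exactly to the Mk likelihood —
this limit and the k = 1 constant-rate birth–death closed form are both
regression-tested.  The scenario pipeline uses the Mk engine by default:
only node state probabilities feed downstream, the Mk path is orders of
magnitude faster, and its agreement with enumeration is provable; the SSE
engine is available behind `engine="sse"` for users who want
diversification rates co-estimated.

## Shift paths and the scenario verdict

A **shifted clade** is a maximal monophyletic set of tips that all carry a
non-bee syndrome (singletons allowed).  For each shifted clade and cutoff,
the **shift path** walks rootward collecting per node x = P(pollinator
shifted) = 1 − P(bee), y = P(montane), and node age.  The walk starts at
the clade MRCA when its x ≥ τ (the "last shared node" rule) and otherwise
at the representative tip; it stops at (and includes) the first node with
P(bee) ≥ τ, flagging paths that hit the root first.  τ defaults to 0.95:
ML marginal probabilities essentially never reach literal 100%, so
"fully shifted / fully bee" is read as a high-probability plateau; the
report always includes a sensitivity sweep over τ ∈ {0.90, 0.95, 0.99}.

Each path is classified twice, with margin δ = 0.10 (both τ and δ are
configuration values; the defaults are declared choices, since "on the
axis" and "close to zero" are inherently visual categories):

* **axis category** of the ancestral-most node (x_a, y_a): ON_Y_AXIS
  (x_a ≤ δ ≤ y_a: environment had shifted while pollination was still
  ancestral), NEAR_ORIGIN (both ≤ δ), ON_X_AXIS (x_a > δ > y_a), else
  INTERIOR;
* **line position**: mean of (y − x) over the deduplicated path nodes,
  ABOVE_1_1 / NEAR_1_1 / BELOW_1_1 with the same margin.

The per-cutoff **verdict** is a strict majority vote.  The line position
carries the ordering signal (above the 1:1 line ⇔ environment-shift
probability led along the history); the axis category must not contradict
it.  A lineage votes environment-first when it is ABOVE_1_1 with an
ancestor on the y axis *or at the origin* — the walk frequently ends at a
node older than the environment shift itself, where both probabilities are
legitimately small — and votes pollinator-first in the mirrored way
(BELOW_1_1 with an x-axis or origin ancestor).  No majority ⇒
SIMULTANEOUS; no shifted lineages ⇒ UNDEFINED.  Note the path
construction itself forces x_a ≤ 1 − τ on every non-flagged path, so an
ON_X_AXIS ancestor can only arise on root-capped paths; treating
origin-ancestored BELOW_1_1 trajectories as pollinator-first evidence is
what makes the two verdicts symmetric in practice.

**Correlated evolution.**  The dependent/independent comparison fits each
character separately (log-likelihoods and parameter counts add) against an
ARD Mk model on the product state space with simultaneous double
transitions structurally forbidden; the lower AIC wins.  Product spaces
beyond 16 states are refused with advice to binarize.  The pipeline runs
this test on the binarized characters (2×2, 8 dependent rates): the full
4×4 product space is legal but its 96-rate dependent model is far beyond
what 150–333 tips can inform.

## Phylogenetic regression battery

All tests share the Brownian covariance C (C_ij = depth of the tips' MRCA,
scaled to unit height).

* **Binary phylogenetic GLMM** (`phylo_logistic_fit`): logit P(y=1) =
  Xβ + b, b ~ N(0, s²C), estimated by penalized quasi-likelihood in the
  Ives–Garland formulation — iterate the working linear mixed model,
  profiling s² by a bounded REML-type 1-D optimization inside each update;
  convergence when the relative change in (β, s²) drops below 1e-6 (max
  200 iterations).  Predictors are z-scored internally and coefficients
  back-transformed; p-values use the normal reference, matching the source
  method's reporting style.  Perfect separation is detected on the initial
  non-phylogenetic fit and reported with the offending predictor.
* **Phylogenetic linear model** (`phylo_lm_fit`): GLS with covariance σ²C
  (statsmodels GLS under the hood); log transforms of responses (petal
  length, pore area) are the caller's responsibility.
* **Two-sample test**: the group-indicator coefficient of the linear model.
* **Phylogenetic ANOVA**: observed one-way F referred to F statistics from
  `nsim` Brownian simulations on the tree, with the BM rate estimated by
  ML from the data; p = (1 + #{F_sim ≥ F_obs})/(nsim + 1).
* **Backward stepwise selection** drops the highest-p term above α = 0.05
  (ties to the larger column index, for determinism), never orphaning an
  interaction's main effects.
* **Single-occurrence resampling** redraws one record per species
  (seeded), refits the binary GLMM, and reports the percentage of
  iterations with p < 0.05; failed fits are tallied, never silently
  dropped.
* A collinearity guard refuses designs containing predictor pairs with
  |r| > 0.8 (elevation and temperature, in practice), so only one enters a
  model at a time.

On a star phylogeny every routine reduces to its classical counterpart
(ordinary logistic/OLS/t-test/ANOVA); these reductions are tested at tight
tolerances, and exactly (1e-6) when s² is pinned to zero.

## Niche summarization

Occurrence records (species, lon, lat, elevation, bio1 = mean annual
temperature, bio12 = annual precipitation — climate pre-extracted per
record) are deduplicated on exact coordinates and then thinned to one
record per species per 1/120° grid cell (≈1 km at the equator, matching a
30 arc-second raster; no projection is applied).  The retained record is
the first under a deterministic (lon, lat, elevation) sort, so the result
is independent of input order.  Species are summarized by medians (even
counts average the middle pair); latitude is summarized as median |lat|
because the latitudinal effects of interest are symmetric about the
equator (a signed option exists).  Whittaker biomes are assigned by
point-in-polygon in the temperature × precipitation plane against a
packaged polygon file; the file is a hand-digitized straight-sided
approximation of the classic diagram (marked *synthetic* in its name —
no published polygon dataset is redistributed), and points outside every
polygon take the nearest polygon's biome with an `extrapolated` flag.
Group × biome contingency tables are tested by Pearson chi-squared with
standardized residuals (O−E)/√(E(1−row/n)(1−col/n)); |r| > 2 flags a
strongly contributing cell.  Pore area is A = π·(height/2)·(width/2) mm².

## The synthetic generator

`synth` emulates the study system, not any particular dataset:

* **Trees**: constant-rate birth–death conditioned on n extant tips
  (dendropy's simulator), with every pendant edge extended by one
  exponential waiting time so the process is stopped between events rather
  than exactly at the n-th speciation; this removes zero-length terminals
  and matches the Yule height expectation Σ_{k=2..n} 1/(λk).  Default
  λ = 0.25/Myr, μ = 0 for the replicated studies: a 150-tip tree is then
  ≈ 20–25 Myr tall and carries on the order of ten shifted lineages,
  the calibration target for the scenario rates below.
* **Coupled characters**: exact Gillespie simulation of a two-character
  jump process along branches, root fixed at (lowland, bee).  ENV_FIRST:
  environment flips at 0.05 (up) / 0.02 (down) per Myr and the pollinator
  shifts at 0.001 + 0.05·1[montane] (a 50-fold montane boost);
  POLL_FIRST mirrors the roles; SIMULTANEOUS uses a single coupled jump
  channel (0.05 / 0.02); INDEPENDENT removes the coupling and gives the
  pollination character its own reversible rates (0.05 / 0.02) so the
  correlated-evolution test faces two genuinely variable characters.
  True event times are recorded, so orderings can be scored exactly.
* **Four-state refinement**: lowland ↦ E1/E2, montane ↦ E3/E4
  (equiprobable; binarizing at 1000 m inverts the mapping exactly);
  shifted tips draw a syndrome with weights (0.6, 0.3, 0.1) for
  generalist / nectar-vertebrate / food-body-vertebrate, reflecting their
  relative frequencies in real occurrence data.
* **Occurrences**: Normal clouds around per-species optima (σ defaults:
  200 m elevation, 0.5 °C temperature, 300 mm precipitation, ~40 records
  per species); temperature is generated from the *drawn* elevation via a
  −5.5 °C/km lapse rate off a 27 °C sea-level baseline plus noise, which
  reproduces the strong (|r| > 0.8) elevation–temperature correlation of
  raster extractions and exercises the collinearity guard.

What the generator does **not** emulate: spatial range structure and
sampling bias (coordinates are uniform jitter around a species center),
taxonomic error, elevation-dependent diversification, and measurement
error in the syndrome assignments.  Passing the recovery studies therefore
shows the inference chain is correct and well-calibrated under the model's
own assumptions — it does not certify robustness to those real-data
pathologies.

## Replicated validation studies and problem sizes

* **Scenario recovery**: 50 replicates each of ENV_FIRST and POLL_FIRST at
  150 tips.  Both binary characters are fitted with the SYM scheme for
  this study: on a single binary character the one-rate model is markedly
  more stable than ARD, whose maximum-likelihood solution occasionally
  pins the reverse rate at zero and collapses ancestral montane
  probabilities (scheme comparison itself is a pipeline stage, not part of
  the recovery study).  Classification with the *true* simulated node
  states recovers the generating scenario in ≈ 82–90% of replicates —
  the remainder are histories whose environment reverted after the shift
  or whose shifts fell on the same branch — and the ML pipeline tracks
  that ceiling within a few percent.
* **Correlation specificity**: 50 INDEPENDENT replicates at 100 tips;
  the independent model should win the AIC comparison in ≥ 70%.
* **Classical reductions and calibration**: star-tree equivalences;
  phylogenetic-ANOVA type-I error over 200 null Brownian replicates at 50
  tips (nsim = 200 each) should sit in [0.02, 0.08] at α = 0.05.
* **Resampling**: 80 species × 8 records; a strong standardized elevation
  effect (β = 3) must be significant in 100/100 iterations, a null effect
  in ≤ 15.

These sizes keep the full validation suite at a few minutes on one core
while leaving each study enough replicates for its pass bands.

## Numerical choices and degenerate inputs

Zero-length terminal branches are replaced by 1e-8 × tree height (with a
warning) before likelihood work; ultrametricity is checked at relative
tolerance 1e-4 and only warned about, since posterior summary trees are
near- but not exactly ultrametric.  Pruning preserves the original root,
so root-to-tip depths and patristic distances survive taxon filtering
exactly.  Monomorphic characters fit with rates at the lower bound and a
warning.  Negative elevations (coastal raster artifacts) bin to E1 with a
warning; negative precipitation is an error.  Consecutive duplicate path
points are dropped before the trajectory mean so path cleaning is
idempotent.

## Known limitations

* PQL estimation of the binary GLMM attenuates large coefficients (a
  known property of the method family); recovery tests assert the median
  estimate within a generous band rather than unbiasedness.
* When the binary response is perfectly clade-structured and the predictor
  is equally heritable, the phylogenetic random effect can absorb most of
  the signal — the demo dataset's single-record resampling is honest
  about this (low percentages at 150 tips), and real-data analyses should
  read the resampling percentage together with the median-based fit.
* The verdict is a majority over lineages and becomes noisy below ~5
  shifted lineages; the report carries per-lineage rows so users can see
  the split rather than trusting the headline label.
* Hidden-state models, stochastic character mapping, branch-heterogeneous
  rates and OU optimum-shift detection are out of scope.
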