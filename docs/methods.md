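# Methods

## Model

A rooted binary time tree T over N taxa has node heights t_i (tips of an
ultrametric tree at 0, root maximal); every non-root node i carries a branch
of duration τ_i = t_parent(i) − t_i and a substitution rate r_i, so the
expected number of substitutions on the branch is the *genetic distance*
μ_C · r_i · τ_i. Branch rates are i.i.d. log-normal with log-mean −σ²/2, so
the prior mean rate is exactly 1 and the overall clock rate μ_C stays
identifiable. The tree likelihood is Felsenstein pruning over compressed site
patterns under per-partition HKY models (closed-form transition matrices,
vectorised over branches; gaps and ambiguity codes enter as partial
likelihood 1 in every state). Hyperpriors: σ ~ Gamma(0.5396, 0.3819)
(shape, scale), κ and λ ~ Log-normal(1, 1.25), base frequencies ~
Dirichlet(10,10,10,10), μ_C ~ Log-normal(−0.18, 0.6) with the site-weighted
mean across partitions pinned at 1 by a delta-exchange move (a single
partition fixes μ_C = 1).

**Yule prior.** We use the labelled-history form
log p(T|λ) = (N−1) log λ − λ·l, with l the tree length. Derivation: every
lineage splits independently at rate λ; a branch ending in a split
contributes λe^{−λτ}, a branch surviving to the present e^{−λτ}, and the root
split contributes λ. Two properties matter downstream: (i) forward simulation
— pure birth from two root lineages, present placed Exp(Nλ) after the Nth
lineage appears — has exactly this density, so the simulator and the prior
are one object; (ii) ∫ p(T|λ) dT is λ-free, so in a data-free chain λ's
marginal is exactly its hyperprior, which the prior-sampling tests rely on.

## Rate parameterisations

*real* stores the rates themselves (log-normal prior density). *cat* stores
an integer bin per branch, default n = 2N−2 bins; a bin's rate is the
log-normal quantile at its midpoint, and the prior is flat 1/n. Bin-median
discretisation biases the implied mean rate slightly low (≈1–3% at moderate
σ), a known property of the parameterisation, verified in the tests. *quant*
stores the rate's quantile in (0,1) with flat prior; rates come from a
100-piece approximation of the inverse CDF: pieces on equal quantile spacing,
the first and last evaluating the exact inverse CDF, interior pieces linear
in rate space between exact knots. The forward (CDF) direction inverts the
same piecewise map exactly, so quantile→rate→quantile round-trips are
lossless apart from float rounding; the approximation error is largest beside
the exact tail pieces and scales ≈ 3%·σ (measured; it shrinks quadratically
in the piece count). Proposals pushing a quantile beyond 10⁻⁹ of either
boundary are rejected — past that the map cannot round-trip at double
precision.

## Operators and their Green ratios

Every operator returns the proposed state, a log Hastings ratio, and the log
absolute Jacobian determinant of its deterministic reparameterisation;
domain exits (a non-positive rate or σ, a quantile at the boundary, a height
ordering violation) return a reject sentinel. The constant-distance family
moves a node height and rescales the incident rates so each genetic distance
is unchanged; its Jacobian is the product of the per-rate scale factors, and
in *quant* mode each rewritten rate multiplies in the ratio of
inverse-CDF-map derivatives at the old and new quantiles. All analytic
Jacobians are validated against central finite differences in the tests.

The NER (narrow-exchange-rate) family augments the minimal
branch-rearrangement move with rate updates conserving a subset of the six
pairwise genetic distances among the affected quartet {A, B, C, E}. Each
subset defines a linear system in the four proposed rates, solved once
symbolically and cached; unconstrained rates keep their current values, which
makes the empty subset exactly classic narrow exchange. Of the 64 subsets, 54
are solvable and 6 of those have identically zero Jacobian determinant
(irreversible maps), leaving 48 usable operators. The 5×5 Jacobian of
(r′_A..r′_D, t′_D) w.r.t. (r_A..r_D, t_D) has last row (0,0,0,0,1) — the
height walk is additive — so its determinant is the 4×4 rate block. The
Hastings ratio carries the ratio of eligible-grandparent counts before and
after the move (the move can change which nodes have an internal child).
Equal-height children tie-break by rejection (measure zero). The default
variant conserves {D_AE, D_BE, D_CE} with no height walk; screening shows the
height-walk (NERw) versions are dominated.

Plumbing operators the named configurations need but that target no clock
parameter: a uniform node-height redraw, a root scaler, the **UpDown** move
(all internal heights ×f, all rates ÷f — the likelihood-invariant move along
the rate–time ridge, Hastings (1−N)·log f; a heights-only TreeScale replaces
it under *cat*), a frequency delta-exchange, and a **λ conditional draw**
(independence proposal λ′ ~ Gamma(N, 1/l), whose density cancels the Yule
term exactly so the move accepts on the hyperprior ratio alone).

## Kernels and tuning

Step sizes are s·Σ with Σ from a uniform(−1,1) or Bactrian(m = 0.95) kernel —
the two-humped unit-variance normal mixture ½N(−m, 1−m²) + ½N(m, 1−m²) that
avoids wastefully small steps. Scales tune toward acceptance 0.234 (uniform)
or 0.3 (Bactrian) via log s += (α_obs − α_target)/√(batch) in batches of 50 —
diminishing adaptation, so the asymptotic kernel is fixed.

## Adaptive operator weighting

The AdaptiveOperatorSampler owns a roster and a parameter-of-interest (POI):
either a set of numerical parameters or the tree, never both. Phases over the
chain: burn-in (first 10%, uniform sampling, nothing recorded), learn-in
(next 10%, uniform sampling, statistics accumulate), then sampling, where
sub-operator ω is drawn with probability Ω/K + (1−Ω)·score(ω)/Σscore,
score(ω) = Σ_accepted D(x, x′) / T(ω). D is the squared Robinson–Foulds
distance for a tree POI and the squared norm of the change scaled by the
parameter's streaming sample standard deviation and dimension for numerical
POIs; T(ω) is wall time from proposal through the accept/reject decision, so
induced likelihood recomputation is charged to the operator that caused it.
Sub-operator step-size tuning freezes when sampling begins so the learned
weights stay meaningful. Because T(ω) is measured time, adaptive runs are
reproducible in distribution but not bit-identical; fixed-weight
configurations are bit-reproducible under a seed. The LeafAVMVN roster entry
proposes all N transformed leaf rates (log r, or logit q under *quant*)
jointly from a multivariate normal centred at the current point with
covariance (2.38²/N)·[(1−β)Σ̂_N + βI], β = 0.05, Σ̂_N a streaming covariance
of the post-burn-in trajectory; it is unavailable (never selected) until 200
observations have accumulated. The scale 2.38²/N is the standard adaptive-MVN
choice.

## Chain driver and diagnostics

Single chain, operators sampled by weight; the likelihood is recomputed only
when a proposal touches it (the constant-distance family, UpDown and pure
prior moves skip it). Traces log posterior/likelihood/prior, tree length,
mean rate, σ, κ, λ, μ_C and base frequencies at a fixed interval; trees go to
a NEXUS-style log. ESS uses the initial-positive-sequence rule on paired
autocorrelations (Geyer), cross-checked against arviz in the tests; a
constant series is degenerate and reported as n.

## Synthetic data and study protocols

The generator draws a Yule tree (forward simulation above), i.i.d. log-normal
rates (σ = 0 is the strict-clock limit), and evolves sequences down the tree
under HKY (κ = 1 gives Jukes–Cantor). Default study conditions: screening
uses σ ∈ {0.1, 0.3, 0.5, 0.8} crossed with L ∈ {0.1, 0.3, 1, 3} kb; the
scaled screening contrast in the tests uses N = 10 with (σ = 0.8, L = 2 kb)
against (σ = 0.1, L = 0.2 kb), chains of a few thousand states, and untuned
kernels so acceptance rates are comparable across variants. One-sided pooled
two-proportion z-tests at p = 0.001 compare each variant's acceptance against
the null operator in both directions.

The well-calibrated coverage study draws all truths from the priors,
simulates an alignment (N = 8, L = 500, 50 replicates in the tests), runs the
chain, and checks 95% credible-interval coverage of σ, tree length and κ
against the exact binomial band. Chains start at the generating truth: the
truth is by construction a draw from the joint distribution of parameters and
data, so the chain starts in equilibrium and coverage is not distorted by
burn-in transients — at these chain lengths (20 000 states) a prior-random
start leaves the σ descent of the σ–rates funnel visibly unfinished.

Prior-sampling (likelihood-off) runs are the operator-correctness surface:
every Hastings or Jacobian error biases some marginal. KS tests run on
ESS-thinned samples (KS assumes independence). Each named configuration is
exercised under a parameterisation in which a 10⁵-state data-free chain
actually converges: the plain one-dimensional scheme has no joint σ–rates
move, so under *real* rates its σ marginal cannot traverse the funnel at that
length (a mixing failure, not a bias — the same roster passes with longer
chains at smaller N); it is tested under *cat*, where the flat rate prior
decouples σ, while the constant-distance-bearing schemes are tested under
*real* and *quant*.

## What the synthetic data do and do not show

The generator matches the inference model exactly (no model misspecification,
no alignment error, no rate autocorrelation, equal base composition unless
asked otherwise, contemporaneous tips). Passing coverage and prior-sampling
tests therefore demonstrates internal correctness of priors, likelihood and
proposals — not robustness to real-data violations of the relaxed clock.
ESS-per-state comparisons between configurations transfer qualitatively to
real alignments; absolute ESS-per-hour figures are hardware-bound and are
deliberately not asserted anywhere.

## Numerical choices and limitations

Pruning runs unscaled and retries with per-node rescaling on underflow.
Closed-form HKY matrices are clipped at [0,1] to absorb ulp-level rounding.
The symbolic census takes ~30 s at first use per process (cached thereafter).
Problem sizes in tests (N ≤ 10, L ≤ 2 kb, chains ≤ 10⁵) were chosen so every
stochastic check converges reliably; all are configurable. Known limitations:
single-chain only (no heated chains), no checkpointing, Yule is the only tree
prior, log-normal the only clock prior family, and the *cat* parameterisation
has no constant-distance or NER rate solutions (as designed — those require
continuous rates).
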