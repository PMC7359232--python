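# Methods

## The model

`dtmbvs` regresses tree-structured compositional count data — typically
microbial taxon abundances from 16S rRNA or shotgun profiling — on a set
of subject-level covariates, and selects which covariates matter on
which parts of the tree.

A rooted phylogeny with B parent→child edges (*branches*) factorizes
each subject's leaf-count vector: every internal node v allocates its
total among its C_v children through an independent Dirichlet-
multinomial (DM) kernel. Writing y_{iv} for subject i's child-count
vector at node v and γ_{iv} for the corresponding concentration vector,

    p(y_{iv} | γ_{iv}) = Γ(Σγ)/Γ(Σγ + Σy) · Π_c Γ(γ_c + y_c)/Γ(γ_c)

(the multinomial coefficient is constant in all parameters and omitted
from the sampler's objective; it is available for pmf validation). The
full Dirichlet-tree multinomial (DTM) log-likelihood is the sum of
these kernels over internal nodes and subjects. On a star tree — one
internal node with every taxon as a direct child — the DTM collapses
exactly to a DM regression on the raw count matrix; this is the
recommended fallback for large taxon sets where the tree adds little
(`star_tree`, or `--dm` on the command line).

The concentration of branch b for subject i follows a log-linear link
gated by binary inclusion indicators:

    γ_{ib} = exp( α_b + Σ_p ζ_{bp} β_{bp} x_{ip} ),

a spike-and-slab formulation: ζ_{bp} = 0 pins β_{bp} to a point mass at
zero and the covariate leaves the likelihood entirely; ζ_{bp} = 1 frees
β_{bp} under a diffuse normal slab. Concentrations are parameterized one
per branch with no reference category; DM concentrations are
identifiable without a baseline constraint. The exact link and move
schedule of the original implementation this package is patterned after
live in material we did not have; the per-branch log-linear link above
is the standard construction for DM-family regression and is the one
this package both fits and simulates from.

## Priors

* **Intercepts** α_b ~ N(0, σ²_α), default σ²_α = 10.
* **Slab** β_{bp} | ζ_{bp}=1 ~ N(0, σ²_β), default σ²_β = 10.
* **Inclusion indicators**, two options:
  * *Beta-Binomial* (default): a common Bernoulli inclusion probability
    integrated against Beta(a, b), giving
    p(ζ) = B(a+k, b+M−k)/B(a, b) with k = Σζ active out of M = B·P.
    Defaults a = b = 1 (uniform over the inclusion probability); the
    prior marginal inclusion probability is then 1/2 and the add-one
    prior ratio is (a+k)/(b+M−k−1).
  * *Markov random field*: unnormalized log-prior d·Σζ + f·Σ_b ζ_b' G ζ_b
    over each branch's covariate-indicator row, sharing a user-supplied
    symmetric 0/1 covariate adjacency G across branches. The quadratic
    form uses both triangles of G (an active linked pair contributes
    2f). Defaults d = −2.2 (≈ logit 0.1, sparse) and f = 0.5; both are
    fixed constants, not hyperpriors, because MRF priors of this type
    have a known phase transition in f beyond which the prior swamps the
    data. Applying the MRF within each branch (rather than across
    branches or to pooled indicators) is this package's design choice:
    G encodes relations between covariates, and branch rows are the
    natural exchangeable unit. A helper thresholds an empirical
    correlation matrix (|r| ≥ cutoff) into G when no curated graph
    exists.

Only prior *ratios* enter the sampler, so the MRF's intractable
normalizing constant is never required.

## Sampler

A Metropolis-Hastings-within-Gibbs scheme. Each iteration runs
`moves_per_iter` between-model proposals followed by a within-model
sweep.

**Between-model.** With probability 1−`swap_prob` a uniformly chosen
(b, p) entry is toggled: an *add* proposes β′ ~ N(0, rw_sd_beta²)
(the proposal density, not the slab, enters the acceptance ratio — this
keeps acceptance stable when the slab is diffuse); a *delete* sends β
to zero. With probability `swap_prob` a branch is chosen uniformly and
one active and one inactive entry of its row exchange states with a
fresh coefficient; a row with no active (or no inactive) entry
degenerates the swap to an add (or delete) on that row. Because a
single-entry toggle can then arise from two distinct mechanisms, the
acceptance ratio uses the total proposal probability of the transition
summed over mechanisms in both directions; this restores exact
reversibility in the degenerate cases, which a per-mechanism ratio
would violate whenever P > 1.

**Within-model.** Symmetric random-walk updates of every intercept
(sd `rw_sd_alpha`) and every active coefficient (sd `rw_sd_beta`), so
the acceptance ratio is the posterior ratio.

**Initialization.** Empty model (ζ = 0, β = 0), matching the sparsity
assumption; α_b starts at log(mean observed child proportion + 0.01),
the offset guarding branches with no reads.

**Defaults and tuning.** `moves_per_iter` defaults to
max(1, ⌈B·P/10⌉) so between-model mixing scales with model size;
`swap_prob` = 0.5; `rw_sd_alpha` = `rw_sd_beta` = 0.5; kernels are
fixed throughout (no adaptation), which preserves the target exactly
and makes runs bit-reproducible from the seed. When the likelihood is
weak or disabled (prior-recovery studies), set `rw_sd_beta` near the
slab sd √σ²_β: a small add-proposal relative to the slab makes deletes
of wandered-off coefficients astronomically rare and the model-size
chain correspondingly sticky. The 150,000-iteration / 75,000-burn-in
defaults mirror the settings used for genus-level analyses of ~100
subjects; all desk-scale studies in this repository use 8k–50k
iterations, sizes chosen so each run completes in seconds to tens of
seconds.

Likelihood bookkeeping is incremental: a proposal on branch b touches
only the DM kernel of b's parent node, so a move costs one small
subjects × children evaluation regardless of tree size. All
gamma-function ratios are computed via `gammaln`; a link overflow to a
nonfinite concentration rejects the proposal (and raises at
initialization, where it indicates unstandardized covariates).

## Posterior summaries and selection

The marginal posterior probability of inclusion (MPPI) of a pair is the
post-burn-in mean of its ζ samples. Selection is either

* **MPPI rule**: include pairs with MPPI ≥ 0.50 (median model), or
* **Bayesian FDR**: sort pairs by descending MPPI; the expected FDR of
  the top k is the mean of (1−MPPI) over those k; the cutoff is the
  smallest MPPI among the largest k whose expected FDR ≤ α. Ties at the
  cutoff are included (≥, matching the MPPI rule); if no nonempty
  selection qualifies the rule returns a select-none sentinel. The
  α → cutoff mapping is data-dependent and not portable across
  datasets. Lowering α can only shrink the selection.

Selected pairs are reported as a taxon/node ↔ covariate edge list;
internal branches keep stable synthesized `node_<k>` labels rather than
being dropped, because associations are genuinely branch-level. A
root→leaf path filter reproduces the per-genus summary view.

Convergence is assessed on the traces the model's users actually
inspect — model size n_active and log posterior — plus a Geweke z-score
on the post-burn-in log posterior (segment means compared with
batch-means spectral variances; undefined on a constant chain and
reported as not-applicable). `mcse_mean` exposes the batch-means Monte
Carlo standard error used throughout the tests. Richer diagnostics are
delegated to external MCMC tooling via the flat CSV export.

## Simulator

The simulator generates data through the *exact* forward model of the
likelihood, so the generator and the likelihood test each other:

* random rooted bifurcating trees by sequential uniform edge splitting
  (B = 2J−2);
* covariates from a mean-zero MVN with exchangeable correlation ρ,
  then z-scored;
* a sparse truth: `n_active` uniformly chosen (b, p) pairs (internal
  branches eligible) at β = ±effect with random signs, intercepts
  uniform on (−0.5, 0.5);
* counts drawn top-down: at each internal node, child proportions
  ~ Dirichlet(γ) then a multinomial split of the node total.

Defaults — n = 200 subjects, J = 4 leaves, P = 10 covariates, ρ = 0,
3 active pairs at |β| = 1, 10,000 reads/subject — describe a modest,
well-powered 16S study. What the simulator does *not* emulate: zero
inflation beyond what the DM induces, batch or sequencing-run effects,
taxon-specific amplification bias, compositional artifacts of variable
library size beyond the depth parameter, or misspecified trees. Passing
recovery tests therefore demonstrate correctness of the inference
machinery under the model's own assumptions, not robustness of the
model on real data.

## Numerical and design notes

* Branch indexing is depth-first from the root with children in Newick
  source order — reproducible across runs; branch lengths are accepted
  and discarded (the model is topology-only); unary nodes are collapsed
  at load (a one-child node is a degenerate multinomial contributing
  non-identifiable parameters).
* Taxa present in the tree but not the counts (or vice versa) are a
  hard error listing the symmetric difference — silent pruning hides
  data bugs. Zero counts need no pseudocount; the DM kernel handles
  them.
* Continuous covariates are z-scored with sample sd (ddof = 1);
  indicator columns are exempted by name; a constant continuous column
  is an error naming the column.
* Standardization is recommended not just cosmetically: the exp link
  overflows for large covariate × coefficient products, and the error
  message says so.
* Determinism: all randomness flows through `numpy.random.Generator`
  seeded from the configuration; the simulator spawns independent child
  streams for tree/covariates/truth/counts so components are separately
  reproducible.
* The tiny-model verification oracle integrates each model's marginal
  likelihood on a dense grid centered at the posterior mode and aligned
  with Hessian eigen-axes. A prior-scaled grid is hopeless here — the
  integrand is many orders of magnitude narrower than the prior — and
  the mode-centered grid is converged to ~1e-8 in the model
  probabilities at 31 points per axis spanning ±6 posterior sds.

## Known limitations

* Exchangeable Beta-Binomial and within-branch MRF are the only
  inclusion priors; no interaction/group structure, no hyperprior on
  the MRF constants.
* Single-chain sampler; no parallel tempering or variational mode.
  Mixing degrades with strongly correlated covariates and large B·P —
  the model space has 2^{B·P} members, and runs at the
  150k-iteration scale are expected for real data of ~100 taxa ×
  ~100 covariates.
* Zero-inflated and negative-binomial variants are out of scope.
* The tree is taken as known; no uncertainty in the phylogeny is
  propagated.
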