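# Methods

This note records the models, parameter choices, numerical conventions and
known limitations of the package, in the order the pipeline runs.

## Quality control and normalization

Cells are kept when (strictly) min_genes < genes detected < max_genes and
total UMIs < max_counts. The defaults (200, 4,000, 10,000) are the windows
used for derived-species sea urchin data; the ancestral-species window uses
an upper gene bound of 7,000. The inequalities are strict on purpose:
boundary cells (exactly 200 genes, exactly 10,000 UMIs) are removed, so
survivor counts are reproducible to the cell.

Normalization is x = log(1 + c·S/d) with c a gene's UMI count in a cell,
d the cell's total, and S the median total over cells. This is a plain
depth normalization: cells with the same gene proportions map to identical
columns regardless of library size. It deliberately replaces
regression-based normalization (Pearson residuals with ribosomal/cell-cycle
covariates); the downstream contracts do not depend on those specifics, and
the co-expression stage never sees normalized values at all — co-expression
is defined on raw UMIs and stays there.

Variable-gene selection ranks genes by variance of normalized expression
(ties broken lexicographically by gene id, so results are deterministic).
PCA uses the exact SVD of the centered matrix with a sign convention
(largest-magnitude loading positive per component). Clustering is Leiden
modularity (RBConfiguration) on an unweighted k-nearest-neighbor graph with
a fixed seed. Defaults: 2,000 variable genes, 30 PCs, k = 15, resolution
1.0. Note that modularity at resolution 1.0 intentionally over-partitions
large homogeneous populations; downstream lineage trees absorb this because
cluster nodes are majority-mapped to lineages, and tests that need exact
blob recovery use a denser graph (k = 30).

## Unbalanced entropic optimal transport

The coupling between consecutive time points minimizes

    F(γ) = ⟨C, γ⟩ − ε H(γ) + λ₁ KL(γ𝟙 ‖ a) + λ₂ KL(γᵀ𝟙 ‖ b),

H(γ) = −Σ γ_ij (log γ_ij − 1), KL(x‖y) = Σ x log(x/y) − x + y. The solver is
the generalized Sinkhorn scaling u ← (a ⊘ Kv)^{λ₁/(λ₁+ε)},
v ← (b ⊘ Kᵀu)^{λ₂/(λ₂+ε)} with K = exp(−C/ε) and γ = diag(u) K diag(v).

Parameters and conventions:

- ε = 0.05 (entropic blur), λ₁ = 1 (weak source constraint: cells may
  create/destroy mass, i.e. divide or die), λ₂ = 50 (strong target
  constraint: observed cells at t+1 must be explained). These are the
  published settings of the transport-based trajectory method this package
  operates.
- Ground cost: squared Euclidean distance in the PCA embedding, divided by
  its median nonzero entry. The normalization makes ε scale-free across
  data sets; without it exp(−C/ε) under- or overflows unpredictably.
- Convergence: change in the row marginal below tol = 1e-8 (max-norm), cap
  5,000 iterations. Non-convergence warns and flags the map rather than
  raising — a near-converged coupling is still informative.
- Underflowed kernels (a row or column of K identically zero) raise with
  advice to rescale the cost; this happens when ε is far too small for the
  cost scale.

## Growth-rate learning

Growth enters through the source marginal: a cell with growth rate g
(expected descendants per hour) carries source weight g^Δt, Δt the real gap
in hours between time points (the sampling grid is uneven: 12→16 hpf is 4
h). Iteration 0 assumes divisions are uniform, g_i = (N_{t+1}/N_t)^{1/Δt},
with N_t the externally expected total cell numbers. Each of 20 iterations
re-solves all maps with a_i ∝ g_i^{Δt} (total mass N_{t+1}/N_t, target
uniform at the same mass) and re-reads growth from the realized row
marginals: g_i^{Δt} = n_t · p_i · (N_{t+1}/N_t), p the normalized row-mass
distribution. The update is exact in the two book-keeping limits (a single
source cell inherits the full mass ratio; an exchange-symmetric cloud with
constant totals learns g ≡ 1) and redistributes growth toward cells that
transport more mass than average.

A caveat worth knowing: with the weak λ₁ = 1 source constraint the fixed
point of this iteration carries geometry-driven structure — cells at the
periphery of a cloud transport slightly less mass and end below g = 1 even
when no growth differences exist (about ±10% on an isotropic Gaussian
cloud). Relative comparisons between lineages are robust (a lineage
simulated at twice the growth rate is ranked above its sibling in 20/20
seeded replicates); absolute per-cell growth values should be read with
that baseline wobble in mind.

## Fates, triangles, trees

Couplings are row-normalized into Markov transition matrices and
chain-multiplied; rows that lose all mass along the chain are flagged and
excluded downstream, never renormalized (renormalizing would invent
probabilities for cells the model says have no descendants). Fate
probabilities pull back indicator sets of annotated cell types at the
reference time point (each species' final common time point). When the fate
sets partition the reference cells, rows sum to 1 to 1e-8, and composition
is consistent: t→T equals t→t′→T to 1e-10.

Triangle plots embed (p_A, p_B, p_other) barycentrically into an
equilateral triangle (focal fate A at the top vertex, B at the right, the
pooled remainder at the origin); commitment threshold 0.7.

Lineage trees: edge weight from cluster i at t to cluster j at t+1 is the
mass-weighted descendant fraction Σ_{x∈i,y∈j} γ_xy / Σ_{x∈i} γ_x·, computed
on the growth-adjusted couplings as solved (not Markov-renormalized),
because "fraction of descendants" is a statement about mass. Clusters with
fewer than 10 cells are removed before the sums (their cells drop out);
edges below 0.15 are pruned after. Outgoing fractions from any retained
parent sum to 1 before pruning. Whether the published trees weighted edges
by mass or by cell count is not stated; mass-weighting is this package's
choice and is flagged here.

## Cross-species alignment

Both species are restricted to 1:1 orthologs (the ortholog table is an
input; in the simulator it is the identity map, deliberately isolating
alignment logic from orthology errors). The shared space comes from a
truncated SVD of K = X_Aᵀ X_B, the cross-covariance of gene-standardized
matrices through shared genes: each triplet (u_j, s_j, v_j) defines a
shared gene direction w_j ∝ X_A u_j + X_B v_j (unit-normalized, sign fixed
by the largest loading), and both species' cells are projected onto the
w's. This is a diagonal-covariance simplification of CCA: it provides the
one thing the alignment needs — a common metric space — without any
anchor-pair heuristics. Identical inputs map to identical coordinates, and
the construction is invariant to permuting genes consistently in both
species.

Earth mover distance between two weighted cell clouds is computed exactly
as the transportation linear program (HiGHS, sparse constraints, Euclidean
ground metric, weights normalized to 1). Clouds above a size cap (default
2,000; the pipeline uses 150 for speed at simulation scale) are reduced by
seeded weighted resampling. For each lineage, cells at every (species, time
point) are weighted by their fate probability toward that lineage
(referenced to each species' own final time point), the EMD matrix over all
time-point pairs is filled, and each species-A time point is matched to the
species-B time point of minimal EMD (ties to the earliest). Rows or columns
whose total fate weight falls below 1e-6 are flagged missing and excluded.
The per-lineage "median offset" (median of matched B-time minus A-time) and
the count of matches above the slope-1 line summarize which species runs
late. Whether the original analysis measured EMD on expression vectors or
an embedding is unstated; the joint embedding is this package's choice.

## Co-expression and interaction evolution

A cell co-expresses a gene pair when both genes have ≥ 1 UMI in it; both
≥ 2 UMIs is "moderate-to-high", otherwise "low". Counting always uses raw
UMIs. Per time point the profile records total cells, co-expressing cells,
the low/high split, and the proportion (linear scale).

The evolutionary call cascade, with defaults:

1. *Support*: each gene needs ≥ 20 cells with ≥ 1 UMI somewhere in its
   species, else `indeterminate` — absence of co-expression is only
   meaningful when both genes are detectable at all.
2. *Lost*: species B has zero moderate-to-high cells and ≤ 2 stray low
   cells overall while species A has a supported signal (some time point
   with proportion ≥ 0.005 and ≥ 5 high cells). A stray low cell or two is
   tolerated because isolated single-UMI coincidences are expected from
   transcriptional noise.
3. *Novel*: the mirror image.
4. *Temporal shift*: onsets in both species, differing by ≥ 4 h. Onset is
   the half-maximum crossing (t50): the earliest time point whose
   proportion reaches 50% of the pair's peak (floored by 0.005), sustained
   for 2 consecutive time points. The relative threshold matters: an
   absolute one fires on the leading tail of a strong signal and
   systematically reads onsets one sampling interval early; requiring
   sustained signal resists single-time-point dropout artifacts.
5. *Spatial shift*: the plurality co-expressing cluster in B is not
   homologous to A's (skipped, with a note, when no homology map is
   supplied).
6. Otherwise `conserved`.

All thresholds live in `CoexpressionParams` and are configuration, not
canon: the cascade reconstructs verbal criteria, and real analyses should
expect to tune it. Swapping which species is called "A" relabels lost ↔
novel and leaves everything else fixed.

## The synthetic embryo generator

What it emulates: two species sampled at discrete hpf time points (defaults
mirror the real designs — hourly 2–24 hpf for the ancestral-like species A,
6/9/12/16/20/24/30 hpf for the derived-like species B); a branching lineage
tree with equal splits at branch points and per-lineage exponential growth;
logistic onset gates for lineage marker programs (steepness 1 h) plus
staggered "maturation" genes giving a continuous developmental axis;
species-B specification delays per lineage; regulator–target pairs sharing
a gate in one lineage, with the four B-side statuses (conserved, shifted
+Δh, lost — target's gated term removed, regulator kept — and novel);
negative-binomial (gamma–Poisson) counts with dispersion θ = 2 around
depth-scaled means, lognormal per-cell depth (mean 2,500 UMIs, σ = 0.35),
and independent dropout at rate 0.1. Regulated genes are silent outside
their gated domains, and every interaction's target (and regulator, when a
spare lineage exists) gets a second expression domain in another lineage —
so a lost interaction leaves both genes individually expressed, which is
exactly the evidence pattern that distinguishes loss from non-detection.
For the delay scenario, species B is sampled one interval beyond species
A's window, as the real design did for the slower species; otherwise the
final time points truncate the recoverable offset toward zero.

What it does not emulate: ambient RNA and doublets, batch/replicate
structure, cell-cycle and ribosomal covariation, unequal ortholog
divergence (the ortholog map is the identity), annotation errors in the
cell-type table, and continuous (rather than gated) expression dynamics.
Passing tests therefore demonstrate that the pipeline's inferences are
correct when its modelling assumptions hold and detection noise is
UMI-like; they do not certify robustness to the artefacts listed above.

Determinism: every draw flows from `numpy.random.default_rng` seeded from
the config; a fixed seed reproduces byte-identical matrices.

## Problem sizes and runtime

The shipped study designs are sized for a single CPU: the tree design uses
3 terminal lineages × 5 time points × 300 cells; the delay design 4
lineages × 6–7 time points × 250 cells with EMD clouds capped at 150
points; the interaction design 12 pairs × 7 time points × 500 cells. The
full test suite runs in well under a minute, and `scripts/acceptance.py`
(which re-simulates and re-analyzes all three designs) in ~10 s.

## Known limitations

- Growth absolute values inherit geometric bias under weak λ₁ (above).
- The EMD down-sampling cap trades exactness for speed on large clouds;
  below the cap the value is the exact LP optimum.
- The spatial-shift call depends on a user-supplied cluster homology map;
  without one the cascade can only distinguish temporal classes.
- Early time points carry little lineage-specific signal, so alignment
  offsets at the first sampled stages bias toward zero; the per-lineage
  median is the robust summary.
- `indeterminate` is a catch-all for insufficient expression support; it
  makes no claim about the interaction's existence.
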