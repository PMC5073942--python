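# Methods

## Model and procedure

`netmark` treats subnetwork-marker discovery as clustering on a directed,
sparse gene–gene similarity defined only for *candidate pairs* — genes whose
proteins interact (default) or lie within network distance 2.

**Class model and LLR.** Each gene's expression is modelled per phenotype as
a Gaussian with sample mean and sd (denominator n−1). The log-likelihood
ratio λ(x) = log f¹(x) − log f²(x) maps an expression value to signed
evidence for phenotype 1. Class sd's are floored at
max(10⁻³ · pooled sd, 10⁻⁶) so degenerate (constant) genes cannot produce
infinite LLRs; a gene whose two class models coincide has λ ≡ 0.

**Discriminative-power similarity.** With t-scores of the LLR profiles
(t_i, t_k) and of their per-sample sum (t_ik),

    s_DP(i,k) = t_k + min(t_ik − t_i, t_ik − t_k) − α·|t_i − t_k|.

The three terms encode: the candidate exemplar k should itself discriminate;
pooling the genes should not lose discrimination; and partners should have
comparable power (α, default 0.5, weights the mismatch penalty). The t's
enter as absolute values by default (`use_abs_t`) — discriminative power is a
magnitude, and mixing signed t's would make the min and the penalty
incoherent for anti-correlated genes; a signed mode is retained for
sensitivity analysis and the choice is recorded in the output provenance.
t statistics use the Welch form by default (`t_variant = pooled` available),
are computed with the same variance floor, and are capped at |t| = 10³ so
degenerate fixtures stay finite.

**Topological similarity.** Neighborhood-overlap indices on the induced
network: Jaccard, Kulczyński, or Tversky with weights (a, b) = (1, 0), which
equals |N_i ∩ N_k| / |N_i| and deliberately rewards a candidate member whose
partners are contained in the exemplar's — exemplars end up better connected
than members. Tversky at (1,1) is Jaccard and at (0.5, 0.5) is Dice; Dice
and Ochiai are implemented only as rank-comparison references. Each protein
is included in its own neighborhood by default (`include_self`): without
self-inclusion, two directly interacting proteins with no shared third
partner would score 0, which contradicts the premise that interacting
proteins are clusterable. All indices return 0 when a denominator vanishes.
Indices of common *non*-neighbors are intentionally out of scope.

**Integration.** Product mode multiplies the two scores (a negative s_DP is
damped toward 0 by weak topology; `clamp_negative_dp` clips it at 0 first if
desired). Linear mode min–max rescales s_DP to [0,1] over the full
candidate-pair set — the same set the clustering sees — and forms
β·s_T + (1−β)·ŝ_DP with β ∈ {0.25, 0.5, 0.75} as the standard grid.

**Preference.** All self-similarities are set to a common preference c, the
lower 1 % linear-interpolation percentile of the directed pair similarities
(computed over candidate pairs, the only pairs with defined similarity), so
no gene starts privileged as an exemplar. Raising the quantile yields more,
smaller clusters.

**Affinity propagation.** Standard responsibility/availability message
passing restricted to the sparse candidate-pair support; absent pairs behave
as similarity −∞. Messages are damped (λ_d = 0.7 default), a seeded jitter
of scale 10⁻¹² breaks exact ties deterministically, and convergence means an
exemplar set unchanged for 200 consecutive iterations (max 2000; memory is
O(|candidate pairs|)). Finalization follows the reference practice: each
gene takes its best a+r choice, genes pointing at a non-exemplar fall back
to their best exemplar neighbor by similarity (or become singletons), and
within each cluster the exemplar is re-elected as the member maximizing the
incoming within-cluster similarity sum when that member is reachable from
all others on the sparse support. Without the re-election step the correct
partition is regularly found with a marginally suboptimal exemplar identity
(94/100 vs 100/100 agreement with exhaustive search on small block
instances). Non-convergence returns the best-effort partition with
`converged=False` and a warning; on dense planted-module instances the
exemplar set can cycle indefinitely at any damping in [0.7, 0.95] — we
verified against an independent dense implementation that this is a genuine
AP limit cycle on such similarity structures, not an implementation
artifact. Results with identical inputs, configuration and seed are
bit-reproducible either way.

**Ranking and selection.** Cluster activity is the per-sample sum of member
LLRs (additive over any partition of the members). Clusters are ranked by
descending |t| of activity between phenotypes — markers may be protective or
risk-directional, so magnitude is what matters — with ties broken by the
smaller exemplar identifier. The top K = 50 form the marker panel.

## Evaluation protocols

Marker statistics report the mean member count and the unique-gene union;
cross-dataset overlap is the Jaccard of two panels' gene unions (a
containment variant — intersection over the smaller union — is available,
and reports label which was used). Discriminative-power curves average the
top-K |t| for K ∈ {10, 20, 30, 40, 50}; transferring a panel to another
dataset keeps the discovery ranking, drops unmeasured genes per marker
(logged), and recomputes activities there.

Classification uses LDA under stratified 5-fold cross-validation repeated
over (default) 100 random partitions; each repeat's AUC pools the
out-of-fold decision scores, and the mean over repeats is reported with the
per-repeat vector for dispersion. LDA runs with the lsqr solver and
Ledoit–Wolf shrinkage unconditionally — deterministic, and well-defined when
the within-class covariance is singular — instead of a
singularity-triggered fallback. When markers are evaluated on any dataset,
LLR class parameters are re-fit on that dataset's *training folds only*, so
held-out samples never inform the class models; whether the original method
re-fit or froze cross-dataset parameters is unstated in the literature this
follows, and re-fitting is the safer default (recorded in metadata).

## Synthetic benchmark

The generator plants a partition: modules of 10 genes (30 modules over 300
genes by default) with within-module edge probability 0.6 and background
edge probability 0.01; 3 modules are flagged as disease modules, whose genes
get a class-1 mean shift of Δ (default 1.5) within-class sd's; everything
else is N(0, σ²) noise in both classes, 50 samples per class. All
randomness flows from one master seed through named substreams (network,
expression, folds), so each component can be varied independently. An
optional second expression draw over the same network and truth provides a
genuinely held-out evaluation dataset for the benchmark's AUC.

What the generator does *not* emulate: probe effects, batch structure,
correlated noise within modules, heavy-tailed expression, degree-matched
topology (a planted-partition graph was chosen over degree-matched rewiring
for analytic transparency). Passing the benchmark therefore shows that the
pipeline recovers dense, differentially active modules under idealized
noise — not that it handles real microarray artifacts.

**Recovery scoring.** The benchmark's recovery is the Jaccard between the
union of the top *m* markers' genes (m = number of planted disease modules)
and the union of planted disease genes. Selecting m markers rather than the
full top-50 panel keeps the score informative: with 50 markers from ~55
clusters the union covers most of the genome and the Jaccard would measure
panel size, not recovery.

**Known limitation — recovery is not monotone in Δ.** Measured means over
seeds 1–10 are 0.627, 0.645, 0.611, 0.607 for Δ = 0.5, 1.0, 1.5, 2.0. Two
effects cap and then erode recovery: ranking saturates (even at Δ = 0.5 a
10-gene module's aggregate activity t ≈ Δ·√(n/2)·√10 ≈ 8 towers over the
background, so the disease clusters are always found), and cluster impurity
grows with Δ — for a background gene i adjacent to a disease exemplar k,
s_DP(i,k) ≈ (1−α)·t_k + α·t_i increases with t_k, so strong modules absorb
more of their network neighbors. The corresponding test documents this
behavior and fails by design; the recovery and AUC bounds themselves hold
with margin.

## Numerical and design choices

- Duplicate gene rows collapse by arithmetic mean (deterministic,
  label-independent). Rows with ≤ 10 % missing values are row-mean imputed,
  heavier rows dropped; both logged.
- Many-to-many gene↔protein maps resolve at overlay: a protein keeps its
  highest-variance measured gene (lexicographic tie-break), a gene maps onto
  every protein node it matches, so each node carries exactly one profile.
  Isolated post-overlay nodes stay in the dataset but cannot enter any
  candidate pair and are excluded from clustering (logged).
- Min–max rescaling of a constant s_DP collection returns 0.5 everywhere;
  empty collections are errors, not conventions.
- The candidate-pair radius (adjacent vs within2) defaults to adjacent:
  the overlap indices already reward shared neighbors, and distance 1 keeps
  the similarity graph sparse. With within2, clusters may be disconnected in
  the raw interaction graph; they are kept intact and a connectivity report
  is logged.
- Every output artifact embeds the full run configuration, package version
  and a SHA-256 content hash of the inputs; equal hashes imply byte-identical
  outputs.

## Problem sizes used by the test suite and acceptance script

Index oracles run on 200 random graphs (n ≤ 50) and 500 random set pairs;
AP is checked against exhaustive exemplar search on 100 block instances with
n ≤ 8 (the largest size where enumeration over all 2⁸−1 exemplar subsets is
instant); null calibration uses 1000 genes and 100 label permutations at
n = 200; the end-to-end benchmark uses the default 300-gene conditions with
10 seeds per effect size and 20 cross-validation repeats for the held-out
AUC. These sizes make the whole suite run in well under a minute while
keeping every Monte-Carlo bound comfortably inside its tolerance.
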