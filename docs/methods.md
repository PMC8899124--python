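# Methods

`dims` implements a driver-induced modular screening analysis for
drug-combination expression studies: given a five-group design (Sham,
Vehicle, two monotherapies A and B, and their combination), it asks which
co-expression modules respond specifically to the combination and which
genes structurally control those modules.

## Pipeline model

1. **Differential screen.** Per gene, a one-way fixed-effects ANOVA across
   the study groups gives *p*; the fold change between a drug group and
   Vehicle is computed on the linear intensity scale after exponentiating
   the log2 values and is direction-symmetric, FC = max(m_d/m_r, m_r/m_d).
   A gene is differentially expressed (DEG) for a drug group when the
   Bonferroni-adjusted *p* < α and FC > the threshold (defaults α = 0.05,
   FC > 1.5). Correction is applied across all tested genes before
   thresholding, so test multiplicity does not depend on the FC filter.
2. **Condition networks and modules.** For each drug group, an unsigned
   weighted co-expression network is built on that group's DEGs from its own
   samples: adjacency a_ij = |cor(x_i, x_j)|^β, topological overlap
   TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij). Modules are
   clusters of the average-linkage tree of 1 − TOM. The tree is cut at a
   grid of candidate heights (all midpoints between the top 30 merge heights
   plus 10 lower quantiles); clusters smaller than the minimum module size
   are merged into their nearest proper cluster by mean TOM, or left
   unassigned when no proper cluster exists. Among the candidate partitions
   the one maximizing Newman modularity
   Q = 1/(2n) Σ_ij [a_ij − k_i k_j/(2n)] σ(c_i, c_j)
   is kept, with n the total edge weight, σ = 1 only for pairs sharing a
   proper module (unassigned genes contribute nothing), ties broken by fewer
   unassigned genes and then lower cut height.
3. **On-, conserved and Add-modules.** Two partitions are compared by the
   Jaccard matrix B_ij between module gene sets; each module's response
   score is s_i = max_j B_ij — how well *any* counterpart matches it.
   Against the Vehicle background partition (built on the same genes from
   Vehicle samples), a module with s < min(s) + θ₁ is an On-module
   (drug-responsive), s > max(s) − θ₂ a conserved module (θ₁ = θ₂ = 0.1,
   strict inequalities). A module eligible for both labels — possible when
   the score spread is narrower than θ₁ + θ₂ — is labeled ambiguous and
   excluded from further screening. Combination On-modules that remain
   On-modules against both monotherapy partitions are additive
   (Add-) modules.
4. **Driver genes.** Per Add-module, a differential network keeps the edge
   (i, j) when |cor in the combination − cor in the monotherapy| ≥ 0.5, and
   orients every edge from its higher-degree endpoint to the lower
   (lexicographic ties, smaller id as tail; a bidirectional option exists).
   By the minimum-input theorem, a directed network is structurally
   controllable from the nodes unmatched in a maximum matching of its
   bipartite out-copy/in-copy representation, and the minimum driver count
   is N_D = max(N − |M*|, 1). Because maximum matchings are not unique, the
   pipeline reports **possible drivers** by default: all nodes belonging to
   at least one minimum driver set, computed exactly by alternating-path
   reachability from the unmatched in-copies (deterministic; a single
   canonical matching is available as `driver_mode="canonical"`). Drivers
   found against both monotherapies (union over Add-modules, then
   intersection across the two comparisons) are the synergistic drivers.
5. **Validation.** Five centralities — degree, eigenvector (power iteration,
   tol 1e−8), betweenness (pair-normalized), PageRank (damping 0.85) and
   closeness (reachable-set scaling) — are computed on each Add-module's
   combination-condition co-expression graph (|cor| ≥ 0.5). We use the
   module's own co-expression network here rather than the differential
   network: with nine samples per group the differential edge indicator is
   dominated by correlation sampling noise (null sd of a pairwise
   correlation ≈ 0.35), while the within-condition correlation ranks hubs
   reliably. Drivers are compared with non-drivers per metric by a one-sided
   Mann–Whitney test (exact when the pooled sample is ≤ 20 without ties,
   normal approximation with tie correction otherwise), and every node gets
   a per-metric decile (10 = top).
6. **Preservation (optional).** A permutation Z_summary checks whether a
   combination module survives in the Vehicle network: observed intramodular
   density and the reference/test correlation of intramodular connectivity
   are compared with ≥ 100 random equal-size gene sets;
   Z_summary = mean(Z_density, Z_connectivity), with ≥ 2 read as preserved.

## Synthetic data generator

The generator emulates the structure of a five-group, nine-profiles-per-group
two-channel microarray study with thousands of genes. Log2 intensities are
baseline + differential shift + noise:

* **Modules** follow a per-group single-latent-factor model: in each group a
  module is active in, member i is l_i·f_g + √(1−l_i²)·ε, so member pairs
  have expected correlation l_i·l_j there and ≈ 0 elsewhere. The realized
  factors of co-active modules are centered and orthogonalized in-sample
  (possible while the number of active modules ≤ n−1). This matters at
  n = 9: independently drawn factor vectors correlate by chance with
  sd ≈ 1/√8 ≈ 0.35, which plants strong spurious between-module correlation
  blocks and makes the ground-truth partition unrecoverable in principle;
  orthogonalization pins the planted between-module structure at exactly
  zero so recovery failures are attributable to the method, not to an
  ambiguous truth.
* **Driver hubs** are module members whose loading is raised to 0.99
  (capped), giving them top intramodular connectivity.
* **Differential expression**: module members active in a drug group are
  shifted there by ±log2(fold change) so they pass the DEG screen that
  gates network construction; an additional `deg_fraction` of background
  genes get a shift in one random drug group. Background genes are
  otherwise independent noise, keeping the ground truth unambiguous.
* **Defaults** (the study conditions): 2000 genes, 9 samples/group, fold
  change 2, residual sd 0.35 log2 units (at which a 2-fold single-group
  shift reaches ≈ 0.9 power under Bonferroni over 2000 genes — the screen is
  informative but not saturated), seven planted modules: two conserved
  (all groups, loading 0.8), one per monotherapy and one shared drug-response
  module (loading 0.8), and two combination-only modules of 35 genes at
  loading 0.70 with one hub each. The combination-module loading is the one
  deliberately lower value: at 0.8 the member–member correlation (0.64)
  passes the |Δcor| ≥ 0.5 differential-edge threshold so often that the
  network saturates and hub degree no longer stands out; at 0.70 the member
  baseline (0.49) sits just below the threshold while hub–member
  correlations (≈ 0.69) sit above it, which is the regime the driver stage
  is designed for.

What the generator does **not** emulate: probe-level artifacts, dye bias,
batch effects, heavy-tailed intensity distributions, correlated background
genes, or modules with internal sub-structure. Passing recovery tests
therefore show that the pipeline's stages compose correctly and are
well-calibrated under a faithful factor-model idealization — not that real
microarray data will yield comparable sensitivity.

## Numerical and design choices

* **Soft power.** `pick_soft_threshold` implements the scale-free criterion
  (smallest power with signed fit ≥ 0.8, else the best-fitting power), but
  the pipeline defaults to the conventional unsigned-network power β = 6:
  DEG-restricted networks are block-structured rather than scale-free, the
  fit criterion never reaches its threshold there, and its argmax fallback
  chases noise (powers up to 20 in pilots). `soft_power="auto"` restores the
  automatic choice.
* **Q normalization.** The modularity denominator is the total network edge
  weight (the standard Newman form); per-module contributions are reported.
* **Degenerate inputs.** Constant genes get correlation 0 by convention;
  all-zero networks give Q = 0 with a warning; ANOVA on genes with zero
  within- and between-group variance gives p = 1; both-empty sets have
  Jaccard 0; an all-equal similarity spread makes every module ambiguous
  (with a warning) rather than silently On and conserved at once.
* **Determinism.** All stochastic stages take explicit seeds; pipeline stage
  seeds derive from the master seed by fixed offsets (simulation +0,
  preservation +1000+module id) recorded in the report; arc lists and driver
  sets are canonically sorted, so byte-identical reports follow from equal
  config and seed.
* **Problem sizes.** Benchmarks run the full pipeline on ten seeded studies
  of 2000 genes (condition networks of ~200–260 DEGs), 100 random digraphs
  of ≤ 7 nodes for the matching oracle, 10 random networks of ≤ 20 nodes
  for the TOM/modularity oracles, and 150–200 permutations for preservation
  Z — sizes at which the exhaustive oracles are exact and the whole
  benchmark completes in well under a minute.

## Known limitations

* The multi-height static cut with nearest-cluster merging approximates the
  dynamic hybrid tree cut; PAM-like reassignment stages are not implemented.
* s_i = max_j B_ij is one reading of the module response score; aggregating
  over all counterparts (e.g., a weighted mean) is a defensible alternative
  that this implementation does not explore.
* The On/conserved thresholds are relative to the realized score spread
  (min(s), max(s)); with very few modules the spread itself is noisy and
  the ambiguous label becomes common.
* Possible-driver sets in dense differential networks routinely cover most
  of a module; the synergistic intersection, not the per-network driver
  set, is the discriminating quantity.
* Enrichment is plain over-representation against user-supplied GMT
  collections; no ranked/permutation GSEA, no database retrieval.
* Networks beyond ~5000 genes are out of scope (dense matrices throughout).
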