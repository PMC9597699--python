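# Methods

`endosig` isolates the chronic-inflammation (CI) component of a complex
disease on a gene interaction network and prioritizes drugs against it.
This note documents the model and procedure, the parameters that matter,
what the synthetic-data generator does and does not emulate, and the
numerical choices made where the design was genuinely open.

## The procedure

The unit of analysis is an *owner*: a disease or trait represented by a set
of seed genes on an undirected interactome. The pipeline runs five stages
per owner.

**1. Negative selection.** Negative training genes are the union of all
annotation sets restricted to network nodes, minus the owner's seeds, minus
every gene of any annotation set that significantly overlaps the seeds
(one-sided Fisher's exact test, p < 0.05, universe = network nodes). The
rationale: genes annotated to unrelated diseases are confident
non-members of this owner's gene set, while sets that overlap the seeds may
describe the same biology and would poison the labels.

**2. Qualification and expansion (guilt by association).** A gene's feature
vector is its adjacency row; an L2-regularized logistic regression is
trained on seeds (positives) vs the negatives. Performance is estimated by
stratified 3-fold cross-validation, scoring each fold as
log2(auPRC/prior) where auPRC is step-wise average precision over the
held-out genes and prior is the held-out positive fraction — 0 means
chance-level retrieval, 1 means twice chance. An owner qualifies when it
has ≥ 15 seed genes on the network and a median fold score ≥ 1; owners
failing the gate are excluded (diffuse gene sets cannot support a
network-based analysis). For qualified owners, every network gene with
predicted probability ≥ 0.80 joins the seeds. Seeds are always retained,
whatever their own scores: the annotation is treated as ground truth and
the model only adds, never removes.

**3. Clustering.** The owner-specific subnetwork is the induced subgraph on
the expanded gene set. It is partitioned with the Leiden algorithm
optimizing plain modularity (`ModularityVertexPartition`, 100 iterations,
explicit seed); clusters with < 5 genes are discarded. Edge weights, when
the input network has them, enter only the modularity objective — degrees
and shortest paths are always unweighted.

**4. CI enrichment with a degree-matched permutation null.** For each
cluster CG and CI gene set CI on a network of `background` genes,

    E = log2( (|CG ∩ CI| / |CG|) / (|CI| / background) ),

with E = −∞ when the overlap is zero. The null: each gene of the owner's
final gene list is replaced by a random gene of equal degree (widening to
neighbouring degrees when fewer than 10 candidates share the exact degree);
the random list is induced, Leiden-partitioned and size-filtered exactly
like the real one; the E of every surviving random cluster, pooled over all
random lists (default 5,000; zero-overlap clusters included at −∞), forms
the null. The permutation p-value is

    p = #(null scores ≥ E_observed) / (n + 1),

implemented verbatim with no pseudo-count in the numerator, so p can be
exactly 0; `pseudo_count=True` switches to the conventional
(1 + #exceedances)/(n + 1). p-values are BH-corrected within the owner and
clusters with FDR < 0.05 *and* E > 0 are called CI-enriched. The E > 0
condition prevents calling clusters that are CI-depleted yet extreme
against a degenerate null. Owners whose random lists never produce a
≥ 5-gene cluster are excluded with an explicit reason rather than given a
vacuous p-value.

The CI gene list itself is first expanded with the same machinery (stage 2
applied to the CI seeds, negatives drawn from annotation sets that do not
overlap them), mirroring how a curated inflammation list under-covers the
true pathway.

**5. Signatures and drugs.** CI-enriched clusters are compared across
diseases by network proximity: d(A,B) = mean over a∈A of the shortest-path
distance to the closest b∈B, similarity s = 1/(1+d). Both directions are
scored, each gets an empirical p against degree-matched random set pairs
preserving both sizes and degree multisets, the two one-sided p-values are
Stouffer-combined and the similarities averaged. Pairs significant after BH
across pairs (α = 0.05) define a weighted cluster-level graph whose Leiden
partition is the set of signature groups; groups are characterized by
hypergeometric over-representation of their group-unique genes. Drugs are
scored against CI-enriched clusters with the same proximity (symmetrized
mean of the two directions by default; a drug→disease-only direction is
available), an empirical p against 200 size/degree-matched random pairs
(+1-corrected — with so small a null a zero p would break the −log10
ranking), min–max similarity normalization and BH within disease, each
drug keeping its lowest-FDR cluster; FDR < 0.01 marks a predicted
treatment.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `reg` | 1.0 | ridge strength; maps to scikit-learn `C = 1/reg`. Feature columns are standardized over training genes so the penalty is scale-free. |
| `expansion_threshold` | 0.80 | probability cut for adding predicted genes |
| `min_qualifying_genes` / `min_median_score` | 15 / 1.0 | the inclusion gate |
| `min_cluster_size` | 5 | smallest cluster analysed anywhere |
| `leiden_iterations` | 100 | Leiden iterations, with a mandatory seed |
| `n_null_lists` | 5000 | random lists per owner for the enrichment null |
| `min_degree_candidates` | 10 | degree-bucket size below which the matched sampler widens to neighbouring degrees |
| `ci_fdr_alpha` / drug FDR | 0.05 / 0.01 | call thresholds |
| drug `n_null` | 200 | random pairs per drug–cluster score |
| cluster-pair `n_null` | 1000 | random pairs per cluster–cluster score (not stated alongside the drug value in the source method; config-exposed) |

## The synthetic scenario

Real inputs (curated disease annotations, GWAS gene scores, literature CI
lists, drug–target databases) are deliberately out of scope; a generator
produces scenarios with the statistical structure the analysis assumes:

- **Interactome**: a planted-partition graph — 2,000 genes in 20 equal
  blocks, within-block edge probability 0.15, between-block 0.004 (mean
  degree ≈ 22). Two blocks are designated CI blocks.
- **CI genes**: 80, split evenly between the CI blocks (a curated list that
  under-covers its modules, leaving room for expansion).
- **Diseases**: 10 sets of 60 seeds, 60% drawn from CI blocks, 40%
  scattered — modular, autoimmune-like.
- **Traits**: 10 sets of 60 seeds drawn uniformly and degree-preservingly
  shuffled — realistic hubness, no block coherence.
- **Annotation universe**: the disease seed sets plus 15
  "non-inflammatory disease-like" sets (60 genes, 60% concentrated in one
  random non-CI block). Disease annotation collections are modular, so the
  negative pool is built from sets with their own (non-CI) modules rather
  than uniform draws, which would scatter spurious negatives into the CI
  blocks at the background rate.
- **Drugs**: 10 with 5 targets inside CI blocks, 20 with degree-matched
  random targets; the indications table marks each CI-module drug as a
  trial positive for every CI-planted disease.

One RNG stream per scenario, consumed in a fixed order (interactome, CI
genes, diseases, traits, annotations, drugs), makes scenarios byte-identical
across regenerations.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: heavy-tailed interactome degree distributions and
hub biases; overlapping pathway membership (blocks are disjoint);
annotation noise (false seed genes); disease sets of widely varying size;
traits with weak-but-real network coherence (our traits are exactly
degree-matched random, so they fail the qualification gate outright, whereas
real non-disease traits may pass it and be cleared only by the permutation
null); drug polypharmacology beyond flat target lists.

## Numerical choices and degenerate inputs

- **Ties in rankings** are broken deterministically: drugs by
  (−log10 FDR, normalized similarity, id); held-out CV genes by
  (probability, id); cluster ids by (size, smallest member).
- **Average precision** is the step-wise estimator. It is positively biased
  under random rankings at small list length (the exact permutation
  expectation for 10 items with 3 positives is 0.45 against a prior of
  0.30), so chance-level log2(auPRC/prior) approaches 0 only as the ranked
  list grows; tests compare Monte-Carlo means against exhaustive
  permutation expectations rather than against 0 at small n.
- **Discreteness of the permutation p.** Pooled null scores are heavily
  tied (all zero-overlap clusters sit at −∞), so the verbatim p is
  conservative. Calibration is therefore assessed two ways: the verbatim
  p-values must not be anti-conservative (one-sided Kolmogorov–Smirnov
  D⁺ within the 95% band), and tie-randomized p-values
  (`randomized_permutation_pvalue`), which are exactly uniform under
  exchangeability, must pass the two-sided test.
- **Unreachable pairs** in closest-distance receive the finite penalty
  D + 1 (D = largest finite shortest-path distance) instead of being
  dropped, which would bias distances downward; the penalty is exposed.
- **Empty structures** fail loudly and specifically: empty negative pools
  name the remedy (more annotation sets), owners without sizable clusters
  or without null clusters carry an `excluded_reason` instead of raising,
  drugs with no on-network target are skipped with a notice.
- **Min–max normalization** of drug similarities within a disease maps a
  single (or all-tied) record to 1.0 by convention.
- **Fig-3C-style contrast** (CI probabilities of unannotated genes in
  enriched vs non-enriched clusters): a comparison of means cannot be a
  Fisher test, so the implementation reports a one-sided rank-sum p on the
  gene-level probabilities and, as a companion, a one-sided Fisher p on the
  2×2 of (above/below the pooled median) × (cluster call).

## Open design points, resolved

- The p-value formula's missing pseudo-count is kept verbatim (a
  documented flag restores the convention); the drug-side empirical p uses
  the +1 correction because its null has only 200 draws.
- Null E scores of clusters with zero CI overlap are included in the null
  pool (they are random-trait clusters like any other).
- Whether seed genes scoring below 0.80 should be dropped at expansion:
  they are retained; the annotation is treated as ground truth.
- Published proximity-based repurposing tools use an additional sigmoid
  "adjustment" of similarity by interactome co-membership whose exact form
  is not printed in our source; s = 1/(1+d) with the degree-matched
  empirical null is used instead and the field is called "similarity".
- Annotation enrichment uses a plain one-sided hypergeometric test with BH,
  not an ontology-decorrelating scheme: the artifact accepts arbitrary GMT
  collections and has no ontology graph to decorrelate over.

## Problem sizes used in the shipped checks

The acceptance checks run the default scenario with 1,000 random lists per
owner (the 5,000 default is a per-owner parameter; 1,000 gives a p-value
floor of ~1/(n+1) per pooled cluster well below the 0.05 call threshold),
10 scenario replicates for the trait specificity sweep (100 trait sets),
200 simulated clusters for the calibration check, and 200 null pairs per
drug–cluster score. These sizes are the package's own reduced-scale study
design; every number reported by `scripts/acceptance.py` is recomputed from
scratch at run time.

## Known limitations

- Adjacency rows are the only feature type for expansion (no diffusion or
  embedding features).
- The hypergeometric annotation test treats gene sets as independent;
  nested collections will show correlated enrichments.
- The generator's blocks are disjoint and equal-sized; recovery metrics on
  it are upper bounds on what overlapping real modules would allow.
- With small drug panels the FDR < 0.01 prediction threshold is rarely
  reachable (the empirical p floor of 1/201 times a BH factor exceeds it
  unless many drugs tie at the floor); rankings and their evaluation are
  unaffected.
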