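# Methods

This note documents the models and procedures `graphvar` implements, the
parameters that matter, the synthetic data the tests run on, and the design
choices made where the design was genuinely open. It states no empirical
number that the test suite or `scripts/acceptance.py` does not itself
compute.

## Protein graphs

A parsed structure is normalised to a single chain with residues renumbered
1..N, every residue carrying a Cα. Two graph scopes:

**Residue scope.** One node per residue located at its Cα. Node features
(25): coordinates (3), one-hot amino acid over the fixed 20-letter alphabet
(unknown residues get a zero block), and two flags for side-chain
hydrogen-bond donor/acceptor capability. The donor/acceptor lookup is
residue-level chemistry — donors {R, K, W}, acceptors {D, E}, both
{N, Q, H, S, T, Y, C, M}, neither {A, V, L, I, F, P, G} — because per-atom
hydrogen geometry is not available at Cα granularity.

Edge types and default thresholds (all configurable via `GraphConfig`, all
in Å, all evaluated on Cα–Cα distance unless noted):

| type | rule |
| --- | --- |
| peptide | sequence neighbours (i, i+1) |
| distance | ≤ 8.0, excluding sequence neighbours |
| hydrophobic | ≤ 5.0 between {A,V,L,I,M,F,W,P,Y} |
| aromatic | ≤ 7.0 between {F,Y,W,H} |
| aromatic_sulphur | ≤ 7.0 between {C,M} and {F,Y,W} |
| cation_pi | ≤ 6.0 between {K,R} and {F,Y,W} |
| hbond | ≤ 3.5 between a donor and an acceptor residue |
| disulfide | two cysteines with Sγ–Sγ ≤ 2.2 (Cα fallback ≤ 6.5 when Sγ absent) |

These are standard contact-graph conventions; pairs matched by several
rules collapse to a single undirected edge carrying the set of type tags,
because the encoder consumes an untyped adjacency (tags are kept for
inspection).

**Atomic scope.** One node per atom with coordinates plus a one-hot element
encoding over {C, N, O, S, H} (anything else gets a zero block). Edges are
covalent only: atoms bond iff their distance is at most the sum of their
single-bond covalent radii (H 0.31, C 0.76, N 0.71, O 0.66, S 1.05) plus a
0.56 Å tolerance. Edge features are the min–max-scaled bond lengths, scaled
per graph (a property of each graph, not of a dataset). Element rather than
PDB atom-name encoding was chosen to keep the feature width small and
structure-source independent.

Edge sets are invariant under rigid rotation/translation of the structure;
the coordinate node features are not. The encoders therefore are not
invariant to Euclidean transforms — the synthetic generator (like the
intended use with folding-model output) keeps wild type and variant in one
shared frame, so coordinate differences are meaningful.

## Graph autoencoder

Encoder layers compute, per graph,

```
H ← Â H W + b          Â = D^{-1/2}(A + I)D^{-1/2}
H ← LN_graph(H)        zero mean / unit variance over all node activations,
                       then a learned per-channel affine
H ← ReLU(H)            after every layer except the last
```

At atomic scope each layer additionally adds, per node, a linear map of the
scalar edge feature summed over the node's incident edges — the minimal
message-passing extension that lets bond lengths influence the update.
"Per graph" layer normalisation uses the statistics of that one graph's
activation matrix (never batch statistics); this keeps the forward pass
identical regardless of batch composition and makes the encoder
permutation-equivariant.

Hidden widths equal the embedding dimension throughout (the simplest chain;
the width schedule is otherwise unconstrained). Dimension 128 pairs with
two layers and 256 with three; both can be overridden, and the tests and
acceptance runs use dimension 16 with two layers to keep desk-scale runs in
seconds. Weights are Glorot-uniform, seeded.

The inner-product decoder scores a pair of node embeddings as
`σ(z_i · z_j)`. The reconstruction loss is
`mean(−log p_pos) + mean(−log(1 − p_neg))` over the graph's edges and an
equal number of uniformly sampled non-edges (probabilities clamped at
1e−15). Training: Adam at learning rate 0.005, mini-batches of 32 graphs,
at most 20 epochs, with a 70/20/10 structure-level split. Training
negatives are resampled every epoch; validation and test negatives are
fixed once per run so the early-stopping signal is stable. After each epoch
the validation edge accuracy (positives and negatives 1:1, threshold 0.5)
is measured; training stops after 3 consecutive epochs without an increase
and the best-epoch parameters are kept. Test-set quality is reported as
edge AUC (Mann–Whitney rank statistic) and average precision.

## Variant features

For each variant the wild-type and variant graphs are embedded; features
are concatenated in the fixed block order
`cadd | wt_pooled | var_pooled | wt_node | var_node | cos_pooled | cos_node`
(only requested blocks present). Pooled blocks are node-embedding means;
node blocks are the embedding rows at the mutated residue position (residue
scope only — atomic nodes have no 1:1 residue mapping, so atomic runs use
pooled blocks only); cosine distances compare wild type and variant at both
levels, with the convention that a zero vector has distance 1. A
`BlockRegistry` records each block's index span; it is what SHAP block
summation later ranges over. Features are not standardised — the downstream
model is tree-based and scale-invariant.

## Leakage control and classification

Two guards:

* **Family hold-out.** A protein family is blocked when any of its proteins
  occurs both in the cohort and in the external reference set; all variants
  of blocked-family proteins form the hold-out, used exactly once, after all
  training and tuning. Re-applying the filter to the remainder yields
  nothing (idempotence is tested).
* **Gene-exclusive folds.** Remaining genes are shuffled (seeded) and dealt
  round-robin into five folds, balanced by gene count (not variant count);
  a gene's variants never span folds. For evaluation fold *e* the
  validation fold defaults to *(e mod k) + 1*; training takes the other
  three. Fold class imbalance is tolerated without resampling.

Per fold, hyperparameters are tuned by seeded random search (default 100
trials; reduced-trial runs are used in tests) over: learning rate
log-uniform [0.01, 0.3], depth [2, 10], boosting rounds [50, 500], row and
column subsampling [0.5, 1], minimum child weight [1, 10], L2 penalty
log-uniform [1e−3, 10], split-gain threshold [0, 5]. Each trial fits with
early stopping on the fold's validation part and is scored by accuracy on
the fold's evaluation part — accuracy (not AUROC) is deliberately the
objective, imbalance notwithstanding. The five winners are averaged:
arithmetic mean (real), geometric mean (log-real), mean rounded half away
from zero (integer), mode with ties broken by declaration order
(categorical). One meta-model is trained on all non-hold-out variants with
the averaged parameters and evaluated once on the hold-out.

Metrics: AUROC via the rank statistic (equal to trapezoidal ROC
integration; tested to 1e−9), MCC with the 0-by-convention rule when a
confusion factor is zero, accuracy, sensitivity, specificity, PPV, NPV, the
confusion matrix at probability threshold 0.5, and the PR curve. The
reference baseline classifies pathogenic iff the proxy score ≥ 20
(boundary inclusive); the proxy's ranking quality is reported as the AUROC
of the raw score.

## SHAP attribution

Attributions are exact path-dependent tree SHAP values computed in double
precision directly from the fitted ensemble's trees (module `_treeshap`):
a feature subset fixes its features to the query row, other splits are
marginalised by the training cover fractions. The per-leaf factorisation
over the distinct features on a leaf's path reduces the Shapley sum to an
elementary-symmetric-polynomial recurrence in O(depth²) per leaf, so the
computation is polynomial and exact; additivity (base value + row sum =
margin) holds to ~1e−12, and the values agree with the booster's native
float32 contribution output to its own rounding. Branch decisions are
evaluated after quantizing query values and thresholds through float32,
reproducing the booster's comparisons exactly.

Block attribution sums the signed per-feature values over each registry
span (preserving row totals). The per-family summary takes, per variant,
the sum of absolute block values over the four structural blocks (pooled
and node, wild type and variant; the proxy and cosine blocks are excluded),
averages within family, and reports the mean, population standard
deviation, and median across family means. Absolute-of-sum is the default
reading (one signed value per embedding, then absolute); a
`absolute="of_each"` switch instead sums absolute per-feature values within
the block, since either reading is defensible. Variants without a family
mapping are dropped from this summary only.

## Synthetic cohorts

The generator emulates the *shape* of a folded variant cohort, not its
physics:

* **Backbones** are ideal α-helices (rise 1.5 Å, 100° turn, Cα radius
  2.3 Å → consecutive Cα–Cα ≈ 3.83 Å) with N, C, O (and CB for non-glycine)
  placed by fixed offsets in the per-residue rotated frame. No side-chain
  rotamers, no forcefield.
* **Variant pairs** share the wild-type coordinate frame; the variant
  changes one residue identity and adds Gaussian noise (sd =
  `noise_sd` + `effect_scale` for pathogenic, `noise_sd` for benign) to all
  atoms within 10 Å of the mutated Cα. The *planted signal* is thus a local
  geometric perturbation — the premise that structural change encodes
  pathogenicity, in a form embeddings can learn.
* **Proxy score**: Normal(15, `proxy_noise_sd`) for benign, shifted up by
  `proxy_effect` for pathogenic, clipped to [0, 40], so the conventional
  ≥ 20 cutoff separates the class centres when the effect is ≥ 10.
  `proxy_noise_sd` is a separate parameter from the coordinate `noise_sd`
  (different units; default 4.0 gives a realistically imperfect baseline
  with AUROC around 0.85 rather than a clean split).
* **Defaults** (the study conditions for tests and the acceptance script):
  50 genes × 10 variants, 20 families, 30-residue proteins, 50% pathogenic,
  `effect_scale` 2.0 Å, `noise_sd` 0.3 Å, `proxy_effect` 6.0. Genes map
  round-robin to families; the pathogenic count is `round(fraction · n)`.
  The "external reference set" used to carve the family hold-out is a
  seeded 20% sample of genes.

What passing tests do and do not show: they demonstrate that the pipeline
recovers a planted geometric signal without leakage, that a no-signal
cohort yields chance-level hold-out AUROC, and that every numerical
component matches an independent oracle. They say nothing about accuracy on
real folded structures, where the structural difference between benign and
pathogenic variant folds is unknown and certainly not an isotropic local
Gaussian.

## Numerical choices and degenerate inputs

* Layer-norm epsilon 1e−5; decoder probabilities clamped at 1e−15.
* `minmax_scale` of a constant vector returns zeros.
* A single-residue structure yields a 1-node, 0-edge graph; encoding it
  works (layer norm of a constant matrix returns the affine offset).
* Negative sampling enumerates non-edges exactly (graphs here are small)
  and raises on complete graphs; sample size is capped at the number of
  non-edges.
* Hold-out/fold splits with a single-class part skip that fold's tuning
  vote; if all folds are degenerate the run fails loudly.
* Cohort generation, GAE training, tuning, and xgboost fits are all seeded;
  identical seeds give bit-identical results (single-threaded xgboost).
* Fragment stitching concatenates residues and renumbers; coordinates are
  copied verbatim with no junction reconciliation (array concatenation, not
  re-superposition), and fragments are assumed non-overlapping.

## Scale choices

Tests and the acceptance script run the autoencoder at embedding dimension
16 on 30-residue proteins and tune with 10 trials per fold (3 for the null
cohort) — sizes chosen so the full pipeline runs in seconds while every
qualitative property (edge-reconstruction AUC ≥ 0.8, signal recovery,
chance-level null) is stable across seeds. The published-scale
configuration (dimension 128/256, 100 trials) is the library default.

## Known limitations

* Helical synthetic geometry only; no sheets, loops, or realistic packing,
  so graph edge-type variety is narrower than in real structures.
* Atomic scope carries covalent edges only, and no mutation-site node
  features (no 1:1 atom–residue mapping).
* The encoders are not invariant to Euclidean transforms (coordinates are
  node features); inputs must share a frame.
* Probabilities are raw classifier outputs; no clinical-threshold
  calibration is attempted.
* Family identifiers are consumed as given; no sequence-similarity
  clustering is performed.
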