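# Methods

## Profile construction

The substrate is a gene × species matrix of BLAST best-hit bitscores.
Bitscores strictly below 60 are zeroed (a value of exactly 60 is
kept); each gene row is then divided by the gene's self-hit bitscore,
which corrects for protein length and composition and puts values on
a [0, 1] scale. Hits that exceed the self-hit (isoform artifacts) are
capped at 1.0 by default (`cap=False` keeps raw ratios). Genes
without a positive self-hit are dropped with a warning, or rejected
in strict mode. A parallel binary presence matrix marks E-values
below 1e-3; it backs the Hamming and PrePhyloPro baselines, gene-age
calls and the conservation analyses. Species exclusion is done by
setting columns to NA; every downstream statistic skips NA entries
(covariances use pairwise-complete species, conservation fractions
renormalize their denominators).

Clades are derived from per-species lineages: every distinct lineage
name is a candidate clade; clades with fewer than 10 species are
dropped; the rest are scanned from largest to smallest (ties broken
by name, for determinism) and a clade is dropped as redundant when
its Jaccard similarity with an already-kept clade exceeds 0.8. The
kept, ordered clade set defines the feature columns everywhere.

## Pair features and labels

The feature of pair (i, j) in clade c is the sample covariance
(denominator n−1; a population-covariance switch exists) of the two
normalized profiles over the clade's unmasked species. Features are
symmetric in the pair by construction, and pairs are stored in
canonical lexicographic order. A clade with fewer than two usable
species yields a missing feature, imputed as 0 by default — zero
co-evolution evidence, which tree ensembles treat as absent signal.

Positive pairs come from GMT gene sets filtered to 3–50 members and
expanded as cliques; contexts (pathway types) keep only labels whose
pair union reaches 5000 pairs (configurable). Unlabeled "negative"
pairs are sampled from the genes that occur in positive pairs, so the
distinct-gene count of the negatives matches the positives within
±10% (rejection sampling, 1000 attempts, then relax with a warning).
Cross-validation uses gene-level holdout: per fold a fresh random 30%
of genes becomes test-exclusive, together with every gene whose
gene-vs-gene bitscore to a held-out gene exceeds 60 (paralog-leak
prevention); pairs touching held-out genes form the test set,
stratified C1/C2/C3 by whether both, one, or neither member still
occurs in a training pair.

## Positive-unlabeled ensembles

Four frameworks share the fit / predict_proba estimator surface:

* **rf** (default): 200 trees, row subsample 0.5, feature subsample
  0.5, 128 max leaves. It is backed by scikit-learn's
  RandomForestClassifier rather than a boosted library's
  random-forest mode: sklearn leaves store class fractions, so the
  ensemble probability is exactly the per-tree average and the
  additive attribution below holds on the probability scale to
  machine precision.
* **vanilla**: a 200-tree LightGBM classifier treating unlabeled as
  negative.
* **pubag**: PU bagging — positives constant, the unlabeled pool
  bootstrapped per bag to the size of the positive set; 20 bags of
  10-tree LightGBM learners with 0.5 row/feature sampling. The bag
  count is not pinned by any published value; 20 matches the
  adaptive-sampling ensemble size.
* **adasample**: adaptive sampling — two iterations; in each, 20
  ten-tree learners are trained on class-stratified subsamples
  (fraction 0.3) drawn with probability proportional to the previous
  iteration's predicted probability of the instance's own class,
  renormalized within class. The update rule is a faithful-intent
  re-implementation; the original is described only as an algorithm
  sketch.

Metrics: auROC and average precision come from scikit-learn; partial
auROC integrates the ROC over FPR < 0.1 and divides by 0.1, mapping
to [0, 1] (a perfect ranking scores 1, a random one ≈ 0.05) — the
McClish standardization was deliberately not used because it maps to
[0.5, 1]. Confidence intervals are percentile bootstrap with 1000
resamples of (score, label) rows. The pathway-level comparison
converts each method's scores to percentile ranks over the common
evaluated pair universe and reports the median within-pathway
percentile, optionally excluding paralog pairs.

## Additive clade attribution

Attribution uses exact path-dependent TreeSHAP, implemented in-package
against sklearn tree arrays and vectorized over samples (the EXTEND /
UNWIND path algorithm; the feature sequence along a tree path is
sample-independent, so per-element fractions and weights are carried
as (n_samples × path length) arrays and each tree is traversed once
per batch). Leaf values are class-1 fractions, so per-tree Shapley
values are probability contributions; averaging over trees gives
φ₀ + Σ_c φ_c = p exactly. Tests verify equality with an
exhaustive-coalition Shapley oracle on small trees at 1e-9 and
additivity at 1e-6 over 1000 random pairs (measured error is at
float precision, ~1e-15). Attribution requires per-tree structure and
raises for the boosted frameworks. The 0.002 display threshold on
mean contributions is a reporting filter only; stored attributions
are never thresholded.

Module extraction clusters the symmetric prediction matrix with
average-linkage hierarchical clustering on distance 1 − p, cut at a
user height (a scan utility reports cluster counts across heights);
asymmetric inputs are symmetrized by averaging with a warning.

## PathScore

Per context, the predicted-probability matrix is sparsified: the
diagonal is forced to zero and entries below the 75th percentile of
off-diagonal values are dropped. The walk is restricted to the
largest strongly connected component of the surviving graph (excluded
genes are reported and ranked last); rows are divided by their sums
(dangling rows, if any remain, become uniform). The stationary
distribution is computed by power iteration in lazy-walk form,
π ← (π + πP)/2, which has the same fixed point as P but converges
geometrically even on periodic (bipartite) graphs — plain power
iteration oscillates on, e.g., a 3-node chain. Convergence is an L1
change below 1e-10 (error raised after 1e5 iterations). Scores are
min–max scaled to [0, 1]; a span below 1e-12 is treated as degenerate
(all scores 0, tied ranks, warning). No teleportation by default; a
`damping` option mixes in uniform restarts. A context is vetted by
precision at rank 100 against its known genes, discarded below 10%.

## Parasite analysis

Conservation per organism is the column mean of the binary matrix
over unmasked genes. Loss genes are those present in **more than**
75% of all species and in **less than** 25% of the parasitic members
of at least one parasitic clade (strict inequalities; the 50%
clade-occurrence rule below is inclusive — a literal reading of the
thresholds). The occurrence matrix marks a gene "found" in a clade
when present in at least half its species; every gene then belongs to
exactly one clade combination, counted UpSet-style with deterministic
tie-breaking by combination bitmask, and exported as per-combination
GMT for external enrichment tools. Group comparisons use the
two-sided Mann–Whitney test (exact null for combined n ≤ 20 without
ties, tie-corrected normal approximation otherwise).

## Synthetic co-evolution generator

The generator produces the panel the tests and the acceptance script
run on: 60 species in 10 clades of 6 under a single root clade, 8
modules of 5–12 genes, 200 background genes, 10 paralog pairs, 5
young genes, 2 parasitic clades with half their species parasitic.

Two layers matter:

1. **Phylogeny confound.** Each species carries a normalized distance
   from the reference organism that grows with its clade index. Each
   gene has a loss propensity q ∈ [0.70, 0.98] and retention
   probability q^e(s) with exponent e(s) ∈ [1, 4] rising with
   distance, and an evolutionary rate ρ ∈ [0.1, 0.7] driving bitscore
   decay exp(−ρ·t(s)) (t ∈ [0.2, 1.6]) with lognormal noise (scale
   0.1) on a per-gene baseline of 150–300 bits. Slowly-evolving and
   fast-evolving genes therefore produce correlated whole-tree
   profiles regardless of function — the confound that limits
   whole-tree similarity on real panels. Without it, whole-tree NPP
   trivially matches the clade-wise model on planted data, which
   misrepresents the problem the method exists for.
2. **Planted clade-restricted co-evolution.** Each module draws 2
   signal clades; within them, members copy a shared latent
   retention pattern (per-species Bernoulli p = 0.5) with flip
   probability 0.05, and behave like background elsewhere.

Parasitic species lose retained genes with probability 0.5 across the
board; additionally, 25 planted loss genes per parasitic clade are
broadly conserved (presence 0.97, minimal rate) but lost with
probability 0.9 in that clade's parasites — exercising the loss-gene
filter with known truth. Paralog pairs are near-duplicate rows (flip
probability 0.05) of module genes, deliberately left out of the truth
gene sets so they act as unlabeled look-alikes for leak tests. Young
genes exist only inside an origin clade.

What the generator does **not** emulate: sequence evolution (no
substitution model), nested clade hierarchy beyond one root, biased
taxon sampling, assembly/annotation artifacts, horizontal transfer,
and realistic pathway-size or degree distributions. Passing tests
show that the machinery recovers clade-restricted co-evolution
against a distance-driven confound at these scales — not that it
reproduces published performance on real proteome panels.

One measured trade-off: with the confound in place, the 20-panel
median fraction of absolute attribution mass landing on the planted
signal clades for within-module pairs is ≈ 0.44 (uninformative
baseline 2/11 ≈ 0.18) — the whole-tree (root-clade) covariance and
confound-carrying clades legitimately absorb the rest. A generator
without the confound concentrates attribution more sharply but makes
the whole-tree baseline unrealistically competitive; the design
favors the honest comparison.

## Numerical and design choices

* Covariance features use pairwise-complete observations; ddof = 1.
* SVD-Phy keeps ceil(0.35·min(n, m)) components of a full
  deterministic SVD with a sign convention (largest-magnitude loading
  positive); when the requested count exceeds the matrix rank, the
  extra components carry exactly-zero scores (keeping the score
  vectors' length, so Pearson stays defined) and a warning is
  emitted. NPP adds half the smallest positive value before log2.
* PrePhyloPro ranks use average ranks for Jaccard ties; pairs whose
  profile correlation is undefined (constant profile) rank normally
  with correlation treated as 0; the forced-last block shares the
  trailing average rank. Directional similarities are symmetrized by
  the maximum.
* Hidden-positive experiments relabel the stated fraction of
  positives as unlabeled before training and report recovery auROC
  of hidden positives against true negatives plus the three
  probability distributions; hiding is seed-reproducible.
* The held-out evaluation in the acceptance script uses a random
  70/30 pair split; gene-level holdout (with C1/C2/C3 grading) is
  exercised by its own correctness checks and available throughout.
* All randomness flows through explicit integer seeds
  (numpy default_rng); identical config + seed reproduces
  byte-identical feature tables, predictions and PathScore outputs.
* Problem sizes in tests and the acceptance script (60-species
  panels, ~500 labeled pairs, 20 seeds) were chosen so the full suite
  completes in a few minutes on one CPU while keeping every
  statistical check well-powered.

## Known limitations

* The attribution path is exact but implemented in Python/numpy; on
  very large pair sets (millions) it is the slowest stage. Chunked
  streaming keeps memory flat; throughput is ~40 pairs/s·tree-hundred
  on one core.
* PathScore is undefined on graphs whose largest strongly connected
  component is a single gene, and intentionally restricts to that
  component rather than patching connectivity with teleportation.
* The PU frameworks other than `rf` do not support attribution (no
  probability-scale additive decomposition is exposed for boosted
  trees here).
* `select_pathway_types` requires an explicit set → top-level
  mapping; unmapped sets are counted and excluded rather than
  guessed.
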