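# mlpp — clade-wise machine-learning phylogenetic profiling

Phylogenetic profiling infers functional relationships between genes
from co-evolution: genes that work together tend to be lost and
retained together across species. Classic profiling compares two
genes' profiles over an entire species panel with a single similarity
(Pearson, Hamming, SVD-based), which dilutes co-evolution that is
confined to part of the tree and is confounded by the dominant
phylogenetic trend — every gene's similarity to its ortholog decays
with evolutionary distance, at a gene-specific rate, whether or not
two genes are functionally related.

`mlpp` instead measures co-evolution *per clade* and learns which
clades matter. For genes *i*, *j* with self-hit-normalized bitscore
profiles `x_i`, `x_j` (each entry `B_ik / B_ii`, thresholded at
bitscore 60), the feature vector of the pair is

```
f(i, j) = ( cov_c(x_i, x_j) )  for each clade c in the clade set,
```

the sample covariance restricted to the clade's species. A
positive-unlabeled random-forest ensemble (200 trees, row/feature
subsampling 0.5, 128 max leaves; known interacting pairs are
positives, everything else unlabeled) maps these per-clade covariances
to an interaction probability, one model per label (functional
interaction, or an interaction context such as a pathway type).
Each prediction is decomposed by exact TreeSHAP into a bias plus one
signed contribution per clade (`p = φ₀ + Σ_c φ_c`), turning a
prediction into an evolutionary statement about *where* in the tree
two genes co-evolve. Downstream, PathScore ranks genes per context by
the stationary distribution of a random walk on the thresholded
predicted-interaction network, and a parasite-loss analysis maps genes
broadly conserved in eukaryotes yet depleted in parasitic clades.

The package is aimed at comparative genomicists and network biologists
who have BLAST best-hit tables (or a gene × species bitscore matrix),
a species taxonomy, and gene sets in GMT form — and at anyone wanting
a testbed for clade-wise co-evolution methods: a built-in generator
produces synthetic panels with planted clade-restricted modules,
paralogs, parasite loss and young genes, plus ground truth.

## Worked example

```python
import numpy as np
from mlpp import (SimConfig, simulate, select_clades, threshold_bitscores,
                  self_hit_normalize, build_pair_features, sample_negatives,
                  pairs_from_sets, PURandomForestClassifier, evaluate,
                  attribute, npp_similarity)
from mlpp.labels import GeneSetCollection

panel = simulate(SimConfig(seed=0))                  # 60 species, 10 clades
pm = self_hit_normalize(threshold_bitscores(panel.bitscore_matrix),
                        panel.self_hits)
clades = select_clades(panel.taxonomy, min_size=5)   # 10 clades + whole tree

positives, _ = pairs_from_sets(GeneSetCollection(sets=panel.truth.modules))
negatives = sample_negatives(positives, list(pm.index), seed=0)
feats = build_pair_features(pm, clades, sorted(positives | negatives))
y = np.array([int(p in positives) for p in feats.index])

rng = np.random.default_rng(0)
test = rng.random(len(y)) < 0.3
model = PURandomForestClassifier(random_state=0).fit(
    feats.to_numpy()[~test], y[~test])
rep = evaluate(model.predict_proba(feats.to_numpy()[test])[:, 1], y[test],
               n_bootstrap=200, seed=0)
print(rep.auroc, rep.ci["auroc"])
```

prints a held-out auROC of `0.899` with bootstrap 95% CI
`(0.849, 0.945)`; the whole-tree NPP baseline on the same test pairs
scores `0.806`. Attributing one within-module pair:

```python
attr = attribute(model, feats.loc[[("g0000", "g0001")]])
print(attr.probability.iloc[0], attr.bias)
print(attr.contributions.iloc[0].sort_values(key=abs, ascending=False).head(3))
```

```
0.975 0.517
clade_05     0.277
clade_09     0.095
Eukaryota    0.088
```

The pair belongs to a module whose co-evolution was planted in
`clade_05` and `clade_09` — exactly the clades the additive
decomposition credits (bias 0.517 plus the per-clade contributions
sums to the predicted probability 0.975). This is the read-out that
distinguishes clade-wise profiling: the model not only predicts the
interaction, it localizes the supporting co-evolution in the tree.

## Command line

Every stage is also a subcommand of `mlpp`: `simulate`, `profiles`,
`clades`, `pairs`, `binarize`, `features`, `baseline`, `pathscore`,
and `run` (the whole pipeline from a YAML config, with per-stage
provenance manifests and hash-based caching). For example:

```bash
mlpp simulate --seed 0 --out fixtures/
mlpp clades --taxonomy fixtures/taxonomy.tsv --min-size 10 --out clades.tsv
mlpp run --config config.yaml --out results/
```

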