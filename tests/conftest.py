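import numpy as np
import pandas as pd
import pytest

from mlpp.features import build_pair_features
from mlpp.labels import GeneSetCollection, pairs_from_sets, sample_negatives
from mlpp.profiles import select_clades, self_hit_normalize, threshold_bitscores
from mlpp.simulate import SimConfig, simulate


SMALL_SIM = dict(
    n_species=30,
    n_clades=5,
    n_modules=4,
    module_size_range=(4, 7),
    n_background_genes=60,
    n_parasite_loss_genes_per_clade=10,
    n_paralog_pairs=4,
    n_young_genes=3,
)


@pytest.fixture(scope="session")
def small_sim():
    """Reduced synthetic panel for fast unit tests."""
    return simulate(SimConfig(seed=7, **SMALL_SIM))


@pytest.fixture(scope="session")
def small_profile(small_sim):
    raw = threshold_bitscores(small_sim.bitscore_matrix)
    return self_hit_normalize(raw, small_sim.self_hits)


@pytest.fixture(scope="session")
def small_clades(small_sim):
    return select_clades(small_sim.taxonomy, min_size=4)


@pytest.fixture(scope="session")
def small_binary(small_sim):
    return (threshold_bitscores(small_sim.bitscore_matrix) > 0).astype("int8")


@pytest.fixture(scope="session")
def small_training(small_sim, small_profile, small_clades):
    """Features + labels for the reduced panel."""
    positives, _ = pairs_from_sets(GeneSetCollection(sets=small_sim.truth.modules))
    negatives = sample_negatives(positives, list(small_profile.index), seed=7)
    pairs = sorted(positives | negatives)
    feats = build_pair_features(small_profile, small_clades, pairs)
    y = pd.Series([int(p in positives) for p in feats.index], index=feats.index)
    return feats, y, positives, negatives


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
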