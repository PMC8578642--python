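"""Additive per-clade attribution: exactness, axioms, module clustering."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from sklearn.tree import DecisionTreeClassifier

from mlpp._treeshap import forest_shap, tree_expected_value, tree_shap
from mlpp.attribution import AttributionTable, attribute, cluster_modules, \
    summarize_importance
from mlpp.models import PURandomForestClassifier, VanillaBoostedClassifier


# --- independent oracle: exhaustive-coalition Shapley on one tree ----------

def tree_conditional_expectation(tree, x, known_features):
    """Path-dependent E[f(x) | x_S]: follow x on known features, take the
    cover-weighted average over both children otherwise."""
    def value(node):
        v = tree.value[node, 0, :]
        return v[1] / v.sum() if v.shape[0] > 1 else v[0]

    def rec(node):
        if tree.children_left[node] == -1:
            return value(node)
        f = tree.feature[node]
        left, right = tree.children_left[node], tree.children_right[node]
        if f in known_features:
            nxt = left if x[f] <= tree.threshold[node] else right
            return rec(nxt)
        wl = tree.weighted_n_node_samples[left]
        wr = tree.weighted_n_node_samples[right]
        return (wl * rec(left) + wr * rec(right)) / (wl + wr)

    return rec(0)


def exhaustive_shapley(tree, x, n_features):
    phi = np.zeros(n_features)
    others = list(range(n_features))
    for i in range(n_features):
        rest = [j for j in others if j != i]
        for k in range(len(rest) + 1):
            for S in itertools.combinations(rest, k):
                w = (math.factorial(len(S)) * math.factorial(
                    n_features - len(S) - 1) / math.factorial(n_features))
                gain = (tree_conditional_expectation(tree, x, set(S) | {i})
                        - tree_conditional_expectation(tree, x, set(S)))
                phi[i] += w * gain
    return phi


class TestTreeShapExactness:
    @pytest.mark.parametrize("depth,n_features", [(2, 2), (3, 3), (4, 3)])
    def test_matches_exhaustive_coalition_shapley(self, rng, depth, n_features):
        X = rng.random((120, n_features))
        y = ((X[:, 0] + 0.6 * X[:, -1] + 0.1 * rng.random(120)) > 0.8).astype(int)
        dt = DecisionTreeClassifier(max_depth=depth, random_state=0).fit(X, y)
        Xq = rng.random((15, n_features))
        fast = tree_shap(dt.tree_, Xq)
        for row, x in zip(fast, Xq):
            slow = exhaustive_shapley(dt.tree_, x, n_features)
            assert np.allclose(row, slow, atol=1e-9)

    def test_repeated_feature_along_path(self, rng):
        # deep stump chain re-splitting the same feature exercises the
        # repeated-feature UNWIND branch
        X = rng.random((300, 2))
        y = ((X[:, 0] > 0.25) & (X[:, 0] < 0.75)).astype(int)
        dt = DecisionTreeClassifier(max_depth=4, random_state=0).fit(X, y)
        Xq = rng.random((10, 2))
        fast = tree_shap(dt.tree_, Xq)
        for row, x in zip(fast, Xq):
            slow = exhaustive_shapley(dt.tree_, x, 2)
            assert np.allclose(row, slow, atol=1e-9)

    def test_constant_tree_gives_zero_phi(self):
        X = np.random.default_rng(0).random((50, 3))
        y = np.zeros(50, dtype=int)
        y[0] = 1  # two classes, but an unsplittable majority is enough:
        dt = DecisionTreeClassifier(max_depth=1, min_samples_leaf=50,
                                    random_state=0).fit(X, y)
        phi = tree_shap(dt.tree_, X[:5])
        assert np.allclose(phi, 0.0)
        assert tree_expected_value(dt.tree_) == pytest.approx(1 / 50)


class TestForestAttribution:
    def test_local_accuracy_on_synthetic_pairs(self, small_training):
        feats, y, *_ = small_training
        model = PURandomForestClassifier(n_trees=60, random_state=0).fit(
            feats.to_numpy(), y.to_numpy())
        attr = attribute(model, feats.iloc[:150])
        total = attr.bias + attr.contributions.sum(axis=1)
        assert np.allclose(total, attr.probability, atol=1e-6)
        assert attr.check_additivity()

    def test_bias_is_shared_across_pairs(self, small_training):
        feats, y, *_ = small_training
        model = PURandomForestClassifier(n_trees=30, random_state=1).fit(
            feats.to_numpy(), y.to_numpy())
        a1 = attribute(model, feats.iloc[:5])
        a2 = attribute(model, feats.iloc[5:10])
        assert a1.bias == pytest.approx(a2.bias, abs=1e-12)

    def test_non_tree_framework_rejected(self, small_training):
        feats, y, *_ = small_training
        model = VanillaBoostedClassifier(random_state=0,
                                         min_child_samples=5).fit(
            feats.to_numpy(), y.to_numpy())
        with pytest.raises(TypeError, match="tree"):
            attribute(model, feats.iloc[:3])

    def test_signal_clades_dominate_attribution(self, small_sim,
                                                small_training):
        """Within-module pairs should owe most attribution mass to the
        clades where their co-evolution was planted."""
        feats, y, *_ = small_training
        model = PURandomForestClassifier(random_state=0).fit(
            feats.to_numpy(), y.to_numpy())
        pos_pairs = feats.index[y.to_numpy() == 1]
        attr = attribute(model, feats.loc[pos_pairs])
        gene_to_module = {g: m for m, gs in small_sim.truth.modules.items()
                          for g in gs}
        mass_signal = mass_total = 0.0
        for pair, row in attr.contributions.iterrows():
            mod = gene_to_module.get(pair[0])
            if mod is None or gene_to_module.get(pair[1]) != mod:
                continue
            signal = set(small_sim.truth.signal_clades[mod])
            mass_total += row.abs().sum()
            mass_signal += row[list(signal & set(row.index))].abs().sum()
        assert mass_signal / mass_total > 0.5


class TestSummaries:
    def make_attr(self, contribs, bias=0.4):
        df = pd.DataFrame(
            contribs, columns=["cladeA", "cladeB"],
            index=pd.MultiIndex.from_tuples(
                [(f"g{i}", f"h{i}") for i in range(len(contribs))]))
        prob = bias + df.sum(axis=1)
        return AttributionTable(df, bias, prob)

    def test_global_mean_absolute(self):
        attr = self.make_attr([[0.2, -0.1], [0.4, 0.1], [-0.2, 0.0],
                               [0.0, -0.2]])
        out = summarize_importance(attr, "global")
        assert out.loc["cladeA", "mean_abs_shap"] == pytest.approx(0.2)
        assert out.loc["cladeB", "mean_abs_shap"] == pytest.approx(0.1)

    def test_display_threshold_filters_report_only(self):
        attr = self.make_attr([[0.5, 0.001], [0.5, -0.001]])
        out = summarize_importance(attr, "global", display_threshold=0.002)
        assert list(out.index) == ["cladeA"]
        assert attr.contributions.shape[1] == 2  # storage untouched

    def test_per_pathway_signed_means(self):
        attr = self.make_attr([[0.2, -0.1], [0.4, 0.3]])
        pathways = {"pw": {("g0", "h0"), ("g1", "h1")}}
        out = summarize_importance(attr, "per-pathway", pathway_sets=pathways)
        assert out.loc["pw", "cladeA"] == pytest.approx(0.3)
        assert out.loc["pw", "cladeB"] == pytest.approx(0.1)
        assert out.loc["pw", "mean_probability"] == pytest.approx(
            float(attr.probability.mean()))


class TestClusterModules:
    def block_matrix(self, rng, sizes=(6, 6), p_in=0.9, p_out=0.1):
        genes = [f"g{i}" for i in range(sum(sizes))]
        m = np.full((len(genes), len(genes)), p_out)
        start = 0
        for s in sizes:
            m[start:start + s, start:start + s] = p_in
            start += s
        np.fill_diagonal(m, 0.0)
        return pd.DataFrame(m, index=genes, columns=genes)

    def test_two_planted_blocks_recovered(self, rng):
        pred = self.block_matrix(rng)
        mods = cluster_modules(pred, cut_height=0.5)
        memberships = sorted(tuple(m) for m in mods.values())
        assert len(memberships) == 2
        assert memberships[0] == tuple(f"g{i}" for i in range(6))

    def test_zero_cut_gives_singletons(self, rng):
        pred = self.block_matrix(rng)
        mods = cluster_modules(pred, cut_height=1e-9, min_size=1)
        assert all(len(m) == 1 for m in mods.values())
        assert len(mods) == len(pred)

    def test_gene_order_invariance(self, rng):
        pred = self.block_matrix(rng)
        perm = rng.permutation(len(pred))
        shuffled = pred.iloc[perm, :].iloc[:, perm]
        a = {frozenset(m) for m in cluster_modules(pred, 0.5).values()}
        b = {frozenset(m) for m in cluster_modules(shuffled, 0.5).values()}
        assert a == b

    def test_asymmetric_input_warns(self, rng):
        pred = self.block_matrix(rng)
        pred.iloc[0, 1] += 0.2
        with pytest.warns(UserWarning, match="symmetrized"):
            cluster_modules(pred, 0.5)
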