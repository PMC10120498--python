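"""Stage 2: greedy CART on CATEs, conservation laws, rendering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bartcate import default_schema
from bartcate.cate import CateResult
from bartcate.subgroup_tree import (
    attach_subgroup_intervals,
    fit_cart,
    parse_tree_json,
    render_tree,
    tree_depth,
)

SCHEMA = default_schema()


def make_features(n, rng):
    df = pd.DataFrame()
    for e in SCHEMA.entries:
        if e.kind == "continuous":
            df[e.name] = rng.normal(60, 12, n)
        elif e.kind == "binary":
            df[e.name] = (rng.random(n) < 0.3).astype(float)
        else:
            df[e.name] = rng.choice(list(e.levels), n)
    return df


def make_cate_result(t, rng, spread=0.5, ids=None):
    n = len(t)
    draws = t[None, :] + rng.normal(0, spread, size=(200, n))
    return CateResult(
        ids=ids if ids is not None else np.array([f"P{i}" for i in range(n)]),
        mean=draws.mean(axis=0),
        lower=np.percentile(draws, 2.5, axis=0),
        upper=np.percentile(draws, 97.5, axis=0),
        draws=draws,
        scale="days",
    )


class TestFit:
    def test_constant_response_gives_root_only_tree(self, rng):
        X = make_features(100, rng)
        tree = fit_cart(X, np.full(100, 3.3), SCHEMA)
        assert tree.root.is_leaf
        assert tree.root.value == pytest.approx(3.3)
        assert tree.root.proportion == 1.0

    def test_perfectly_separable_binary_split(self, rng):
        X = make_features(200, rng)
        t = np.where(X["diabetes"].to_numpy() == 1, 2.0, 6.0)
        tree = fit_cart(X, t, SCHEMA, min_leaf=5)
        assert tree.root.var == "diabetes"
        leaf_vals = sorted(leaf.value for leaf in tree.leaves())
        assert leaf_vals == pytest.approx([2.0, 6.0])
        p_diab = (X["diabetes"] == 1).mean()
        props = {round(leaf.value): leaf.proportion for leaf in tree.leaves()}
        assert props[2] == pytest.approx(p_diab)
        assert props[6] == pytest.approx(1 - p_diab)

    def test_categorical_subset_split(self, rng):
        X = make_features(300, rng)
        rs = X["resp_support"].to_numpy()
        t = np.where(rs == "open", 1.0, 5.0)  # open vs {niv_cpap, imv}
        tree = fit_cart(X, t, SCHEMA, min_leaf=5)
        assert tree.root.var == "resp_support"
        assert set(tree.root.left_levels) in ({"open"}, {"niv_cpap", "imv"})

    def test_depth_cap_respected(self, rng):
        X = make_features(400, rng)
        t = rng.normal(size=400)  # pure noise, cp=0 forces deep growth
        tree = fit_cart(X, t, SCHEMA, max_depth=3, min_leaf=5, cp=0.0)
        assert tree_depth(tree) <= 3
        for leaf in tree.leaves():
            assert len(leaf.member_rows) >= 5

    def test_small_node_returns_root(self, rng):
        X = make_features(10, rng)
        tree = fit_cart(X, rng.normal(size=10), SCHEMA, min_leaf=20)
        assert tree.root.is_leaf

    def test_greedy_first_split_matches_brute_force(self, rng):
        # exhaustive oracle over every (variable, cutpoint/subset) pair
        for rep in range(20):
            n = int(rng.integers(20, 50))
            X = make_features(n, rng)
            t = rng.normal(size=n)
            tree = fit_cart(X, t, SCHEMA, max_depth=1, min_leaf=1, cp=0.0)
            best_gain, best = -np.inf, None
            total = t.sum()
            base = total**2 / n
            for e in SCHEMA.entries:
                xv = X[e.name].to_numpy()
                masks = []
                if e.kind == "categorical":
                    masks = [(np.isin(xv, c), e.name) for c in
                             ((e.levels[0],), (e.levels[1],), (e.levels[0], e.levels[1]))]
                else:
                    vals = np.unique(xv.astype(float))
                    for cut in (vals[:-1] + vals[1:]) / 2:
                        masks.append((xv.astype(float) <= cut, e.name))
                for mask, name in masks:
                    nl = mask.sum()
                    if nl == 0 or nl == n:
                        continue
                    sl = t[mask].sum()
                    gain = sl**2 / nl + (total - sl) ** 2 / (n - nl) - base
                    if gain > best_gain + 1e-12:
                        best_gain, best = gain, name
            if tree.root.is_leaf:
                assert best is None or best_gain <= 1e-12
            else:
                assert tree.root.var == best
                # equal SSE reduction to the oracle's best
                left = tree.root.left.member_rows
                sl = t[left].sum()
                nl = len(left)
                gain = sl**2 / nl + (total - sl) ** 2 / (n - nl) - base
                assert gain == pytest.approx(best_gain, abs=1e-9)

    def test_matches_sklearn_cart_sse(self, rng):
        # independent cross-check: identical total SSE to sklearn's optimal
        # greedy tree on numeric-only features
        from sklearn.tree import DecisionTreeRegressor

        n = 300
        X = make_features(n, rng)
        t = (X["age"].to_numpy() > 60) * 3.0 + X["diabetes"].to_numpy() * 2.0 \
            + rng.normal(0, 0.5, n)
        tree = fit_cart(X, t, SCHEMA, max_depth=2, min_leaf=10, cp=0.0)
        num_cols = [e.name for e in SCHEMA.entries if e.kind != "categorical"]
        sk = DecisionTreeRegressor(max_depth=2, min_samples_leaf=10).fit(X[num_cols], t)
        mine = sum(
            np.sum((t[leaf.member_rows] - leaf.value) ** 2) for leaf in tree.leaves()
        )
        theirs = np.sum((sk.predict(X[num_cols]) - t) ** 2)
        assert mine == pytest.approx(theirs, rel=0.02)

    def test_standardized_and_original_unit_fits_are_equivalent(self, rng):
        # fitting on z-scored age and back-translating the cutpoint equals
        # fitting on raw years directly
        n = 200
        X = make_features(n, rng)
        t = np.where(X["age"].to_numpy() <= 58.0, 1.0, 4.0) + rng.normal(0, 0.1, n)
        tree_raw = fit_cart(X, t, SCHEMA, max_depth=1, min_leaf=5)
        mu, sd = X["age"].mean(), X["age"].std(ddof=1)
        Xz = X.copy()
        Xz["age"] = (X["age"] - mu) / sd
        tree_std = fit_cart(Xz, t, SCHEMA, max_depth=1, min_leaf=5)
        assert tree_raw.root.var == tree_std.root.var == "age"
        assert tree_std.root.cut * sd + mu == pytest.approx(tree_raw.root.cut, abs=1e-9)


class TestConservation:
    @given(seed=st.integers(0, 500))
    @settings(max_examples=20)
    def test_proportions_and_means_conserved(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(30, 150))
        X = make_features(n, rng)
        t = rng.normal(size=n) + 2.0 * X["diabetes"].to_numpy()
        tree = fit_cart(X, t, SCHEMA, max_depth=3, min_leaf=2, cp=0.0)
        leaves = tree.leaves()
        assert sum(leaf.proportion for leaf in leaves) == pytest.approx(1.0, abs=1e-9)
        weighted = sum(leaf.proportion * leaf.value for leaf in leaves)
        assert weighted == pytest.approx(tree.root.value, abs=1e-9)
        for nd in tree.nodes():
            if not nd.is_leaf:
                assert nd.left.proportion + nd.right.proportion == pytest.approx(
                    nd.proportion, abs=1e-12
                )


class TestIntervals:
    def test_whole_sample_leaf_equals_overall_interval(self, rng):
        X = make_features(80, rng)
        cate = make_cate_result(np.full(80, 2.0), rng)
        tree = fit_cart(X, cate.mean, SCHEMA)
        attach_subgroup_intervals(tree, cate)
        overall = cate.draws.mean(axis=1)
        assert tree.root.cri_lower == pytest.approx(np.percentile(overall, 2.5))
        assert tree.root.cri_upper == pytest.approx(np.percentile(overall, 97.5))

    def test_constant_effect_leaves_overlap(self, rng):
        X = make_features(300, rng)
        cate = make_cate_result(np.full(300, 3.0), rng, spread=1.0)
        tree = fit_cart(X, cate.mean, SCHEMA, min_leaf=30, cp=0.0, max_depth=2)
        attach_subgroup_intervals(tree, cate)
        leaves = tree.leaves()
        for a in leaves:
            for b in leaves:
                assert a.cri_lower <= b.cri_upper and b.cri_lower <= a.cri_upper

    def test_id_mismatch_rejected(self, rng):
        X = make_features(40, rng)
        cate = make_cate_result(rng.normal(size=40), rng)
        tree = fit_cart(X, cate.mean, SCHEMA, ids=np.array([f"Q{i}" for i in range(40)]))
        with pytest.raises(ValueError, match="ids"):
            attach_subgroup_intervals(tree, cate)


class TestRender:
    def test_root_only_rendering(self, rng):
        X = make_features(50, rng)
        tree = fit_cart(X, np.full(50, 1.5), SCHEMA)
        text = render_tree(tree, "text")
        assert "1.50" in text and "prop 1.00" in text

    def test_two_box_rendering_shows_proportions(self, rng):
        X = make_features(200, rng)
        t = np.where(X["diabetes"].to_numpy() == 1, 2.0, 6.0)
        tree = fit_cart(X, t, SCHEMA, min_leaf=5)
        text = render_tree(tree, "text")
        assert "diabetes" in text
        p = (X["diabetes"] == 1).mean()
        assert f"prop {p:.2f}" in text

    def test_json_round_trip(self, rng):
        X = make_features(250, rng)
        t = rng.normal(size=250) + 3 * X["diabetes"].to_numpy() \
            + (X["resp_support"].to_numpy() == "imv") * 2
        cate = make_cate_result(t, rng)
        tree = fit_cart(X, cate.mean, SCHEMA, min_leaf=10, cp=0.0)
        attach_subgroup_intervals(tree, cate)
        doc = render_tree(tree, "json")
        back = parse_tree_json(doc)
        assert render_tree(back, "json") == doc

    def test_dot_output_well_formed(self, rng):
        X = make_features(100, rng)
        t = np.where(X["copd"].to_numpy() == 1, 1.0, 2.0)
        dot = render_tree(fit_cart(X, t, SCHEMA, min_leaf=5), "dot")
        assert dot.startswith("digraph") and dot.rstrip().endswith("}")
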