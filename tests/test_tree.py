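"""Split enumeration, OBIG/OBIGR, CART induction and prediction.

The heart of this file is an *independent* split scorer
(:func:`oracle_best_split`): plain loops over every candidate condition,
recomputing the weighted-entropy gain from first principles.  Fitted
trees are then walked node by node and their chosen splits compared
against the oracle's exhaustive scan.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from obecart.core import ClassSpec, ValidationError, serialize_model
from obecart.entropy import SelectedClassStatistic
from obecart.tree import (
    GAIN_TOL,
    TrainConfig,
    enumerate_splits,
    fit,
    obig,
    obigr,
    predict,
    predict_dataset,
    tree_stats,
)

from conftest import build_dataset, random_mixed_dataset


# ---------------------------------------------------------------------------
# independent oracle: first-principles weighted-entropy gain
# ---------------------------------------------------------------------------


def oracle_obe(labels, n, weights):
    h = 0.0
    total = len(labels)
    for i in range(n):
        p = sum(1 for y in labels if y == i + 1) / total
        if p > 0:
            h -= weights[i] * p * math.log2(p)
    return h


def oracle_weights(n, s, alpha):
    raw = [abs(i - s) ** alpha for i in range(1, n + 1)]
    return [r / sum(raw) for r in raw]


def oracle_gain(y, mask, n, weights):
    left = [v for v, m in zip(y, mask) if m]
    right = [v for v, m in zip(y, mask) if not m]
    t = len(y)
    return (
        oracle_obe(y, n, weights)
        - len(left) / t * oracle_obe(left, n, weights)
        - len(right) / t * oracle_obe(right, n, weights)
    )


def oracle_best_split(data, idx, weights, min_leaf):
    """Exhaustive scan over all features/conditions; returns the best
    (gain, feature, condition) under the package's tie-break rules."""
    n = data.class_spec.n
    y = [int(v) for v in data.y[idx]]
    best = None
    for f in data.schema:
        col = data.X[f.name].to_numpy()[idx]
        if f.kind == "numeric":
            vals = sorted(set(float(v) for v in col))
            conds = [
                ("num", (a + b) / 2) for a, b in zip(vals[:-1], vals[1:])
            ]
        else:
            conds = [("cat", c) for c in sorted(set(str(v) for v in col))]
        for kind, c in conds:
            if kind == "num":
                mask = [float(v) <= c for v in col]
            else:
                mask = [str(v) == c for v in col]
            nl = sum(mask)
            if nl < min_leaf or len(mask) - nl < min_leaf:
                continue
            g = oracle_gain(y, mask, n, weights)
            if best is None or g > best[0] + GAIN_TOL:
                best = (g, f.name, c)
    return best


def walk_internal_nodes(model, data):
    """Yield (node, row indices reaching it) for every internal node."""
    stack = [(model.root, np.arange(data.T))]
    while stack:
        node, idx = stack.pop()
        if node.is_leaf:
            continue
        yield node, idx
        col = data.X[node.feature].to_numpy()[idx]
        if node.kind == "numeric":
            mask = col.astype(float) <= node.threshold
        else:
            mask = col.astype(str) == node.category
        stack.append((node.left, idx[mask]))
        stack.append((node.right, idx[~mask]))


# ---------------------------------------------------------------------------
# split enumeration
# ---------------------------------------------------------------------------


class TestEnumerateSplits:
    def test_numeric_midpoints(self):
        data = build_dataset({"x": [1.0, 2.0, 4.0]}, [1, 2, 3])
        cands = enumerate_splits(data, "x")
        assert [c.threshold for c in cands] == [1.5, 3.0]
        assert all(
            c.left_support + c.right_support == data.T for c in cands
        )

    def test_single_valued_categorical_has_no_split(self):
        data = build_dataset(
            {"c": ["yes", "yes", "yes"]}, [1, 2, 3], categorical={"c"}
        )
        assert enumerate_splits(data, "c") == []

    def test_candidate_count_equals_distinct_minus_one(self):
        rng = np.random.default_rng(0)
        vals = rng.integers(0, 12, 20).astype(float)
        data = build_dataset({"x": list(vals)}, rng.integers(1, 5, 20))
        cands = enumerate_splits(data, "x")
        assert len(cands) == len(set(vals)) - 1

    def test_unknown_feature_raises(self):
        data = build_dataset({"x": [1.0, 2.0]}, [1, 2])
        with pytest.raises(ValidationError):
            enumerate_splits(data, "nope")


# ---------------------------------------------------------------------------
# OBIG and OBIGR
# ---------------------------------------------------------------------------


class TestOBIG:
    def test_hand_worked_perfect_separation(self):
        # parent OBE 0.5; children OBE 5/12 and 1/12; gain 0.25
        data = build_dataset(
            {"a": [0, 0, 0, 0, 1, 1, 1, 1]}, [1, 1, 2, 2, 3, 3, 4, 4]
        )
        (cand,) = enumerate_splits(data, "a")
        assert obig(data, cand, s=4, alpha=1.0) == pytest.approx(0.25)

    def test_pure_parent_has_zero_gain(self):
        data = build_dataset({"a": [0, 0, 1, 1]}, [2, 2, 2, 2])
        (cand,) = enumerate_splits(data, "a")
        assert obig(data, cand, s=4, alpha=1.0) == pytest.approx(0.0, abs=1e-12)

    def test_children_reproducing_parent_have_zero_gain(self):
        data = build_dataset(
            {"a": [0, 0, 1, 1]}, [1, 3, 1, 3]
        )
        (cand,) = enumerate_splits(data, "a")
        assert obig(data, cand, s=4, alpha=2.0) == pytest.approx(0.0, abs=1e-12)

    def test_empty_child_raises(self):
        from obecart.tree import SplitCandidate

        data = build_dataset({"a": [1.0, 2.0]}, [1, 2])
        bad = SplitCandidate("a", "numeric", threshold=0.0)
        with pytest.raises(ValidationError):
            obig(data, bad, s=4, alpha=1.0)

    def test_non_negative_for_fixed_selected_class(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = int(rng.integers(2, 6))
            T = int(rng.integers(4, 40))
            y = rng.integers(1, n + 1, T)
            x = rng.random(T)
            data = build_dataset(
                {"x": list(x)}, y, class_spec=ClassSpec(tuple(f"k{i}" for i in range(n)))
            )
            cands = enumerate_splits(data, "x")
            if not cands:
                continue
            cand = cands[rng.integers(0, len(cands))]
            s = int(rng.integers(1, n + 1))
            alpha = float(rng.uniform(0.1, 5))
            assert obig(data, cand, s, alpha) >= -1e-12


class TestOBIGR:
    def test_two_equal_halves_denominator_one_bit(self):
        data = build_dataset(
            {"a": [0, 0, 0, 1, 1, 1]}, [1, 2, 3, 3, 4, 4]
        )
        (cand,) = enumerate_splits(data, "a")
        gain = obig(data, cand, 4, 1.0)
        assert obigr(data, "a", 4, 1.0) == pytest.approx(gain)

    def test_four_equal_quarters_denominator_two_bits(self):
        data = build_dataset(
            {"a": [0, 0, 1, 1, 2, 2, 3, 3]}, [1, 1, 2, 2, 3, 3, 4, 4]
        )
        # multiway gain: parent OBE 0.5 (alpha=1, s=4), pure parts -> gain 0.5
        assert obigr(data, "a", 4, 1.0) == pytest.approx(0.5 / 2.0)

    def test_matches_brute_force_on_random_data(self):
        rng = np.random.default_rng(5)
        vals = rng.integers(0, 5, 30).astype(float)
        y = rng.integers(1, 5, 30)
        data = build_dataset({"x": list(vals)}, y)
        n, s, alpha = 4, 4, 1.7
        w = oracle_weights(n, s, alpha)
        labels = [int(v) for v in y]
        g = oracle_obe(labels, n, w)
        h_k = 0.0
        for v in sorted(set(vals)):
            part = [l for l, x in zip(labels, vals) if x == v]
            frac = len(part) / len(labels)
            g -= frac * oracle_obe(part, n, w)
            h_k -= frac * math.log2(frac)
        assert obigr(data, "x", s, alpha) == pytest.approx(g / h_k, abs=1e-12)

    def test_single_valued_feature_raises(self):
        data = build_dataset({"x": [3.0, 3.0]}, [1, 2])
        with pytest.raises(ValidationError):
            obigr(data, "x", 4, 1.0)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


class TestFit:
    def test_constant_targets_yield_single_leaf(self):
        data = build_dataset({"x": [1.0, 2.0, 3.0]}, [3, 3, 3])
        model = fit(data, TrainConfig())
        assert model.root.is_leaf and model.root.predicted == 3
        assert tree_stats(model) == (1, 1, 0)

    def test_empty_dataset_raises(self, four_spec):
        data = build_dataset({"x": []}, [])
        with pytest.raises(ValidationError):
            fit(data, TrainConfig())

    def test_planted_perfect_split_found_at_root(self):
        rng = np.random.default_rng(3)
        T = 80
        planted = rng.random(T)
        noise1 = rng.random(T)
        noise2 = rng.integers(0, 3, T)
        y = np.where(planted <= 0.5, 1, 4)
        data = build_dataset(
            {"noise_a": list(noise1), "planted": list(planted),
             "noise_c": [str(v) for v in noise2]},
            y,
            categorical={"noise_c"},
        )
        model = fit(data, TrainConfig(alpha=2.0))
        assert model.root.feature == "planted"
        below = planted[planted <= 0.5].max()
        above = planted[planted > 0.5].min()
        assert below < model.root.threshold < above

    def test_training_accuracy_one_on_consistent_data(self):
        data = random_mixed_dataset(seed=11, T=60, value_grid=30)
        # deduplicate feature rows to guarantee consistency
        df = data.X.assign(_y=data.y).drop_duplicates(
            subset=list(data.X.columns), keep="first"
        )
        data = build_dataset(
            {c: df[c].tolist() for c in data.X.columns},
            df["_y"].to_numpy(),
            class_spec=data.class_spec,
            categorical={f.name for f in data.schema if f.kind == "categorical"},
        )
        model = fit(data, TrainConfig())
        pred, _ = predict_dataset(model, data)
        assert np.array_equal(pred, data.y)

    @pytest.mark.parametrize("stat", ["max", "mode"])
    def test_every_chosen_split_matches_exhaustive_oracle(self, stat):
        for seed in range(6):
            data = random_mixed_dataset(seed=seed, T=70, value_grid=12)
            cfg = TrainConfig(
                alpha=1.5,
                statistic=SelectedClassStatistic(stat),
                min_samples_leaf=3,
                min_samples_split=6,
            )
            model = fit(data, cfg)
            n = data.class_spec.n
            for node, idx in walk_internal_nodes(model, data):
                labels = [int(v) for v in data.y[idx]]
                if stat == "max":
                    s = n
                else:
                    counts = [labels.count(i + 1) for i in range(n)]
                    s = max(range(n), key=lambda i: (counts[i], i)) + 1
                w = oracle_weights(n, s, cfg.alpha)
                best = oracle_best_split(data, idx, w, cfg.min_samples_leaf)
                assert best is not None
                chosen = node.threshold if node.kind == "numeric" else node.category
                assert node.gain == pytest.approx(best[0], abs=1e-9)
                assert (node.feature, chosen) == (best[1], best[2])

    def test_uniform_weight_hook_recovers_classical_entropy_cart(self):
        """With the uniform-weights hook, split choices equal classical
        Shannon-entropy CART (oracle with weights = 1/n everywhere)."""
        for seed in range(6):
            data = random_mixed_dataset(seed=100 + seed, T=60, value_grid=10)
            cfg = TrainConfig(uniform_weights=True, min_samples_leaf=3,
                              min_samples_split=6)
            model = fit(data, cfg)
            n = data.class_spec.n
            w = [1.0 / n] * n
            for node, idx in walk_internal_nodes(model, data):
                best = oracle_best_split(data, idx, w, cfg.min_samples_leaf)
                chosen = node.threshold if node.kind == "numeric" else node.category
                assert (node.feature, chosen) == (best[1], best[2])

    def test_child_supports_sum_to_parent(self):
        data = random_mixed_dataset(seed=2, T=150)
        model = fit(data, TrainConfig(min_samples_leaf=2))

        def check(node):
            if node.is_leaf:
                return
            assert node.left.support + node.right.support == node.support
            check(node.left)
            check(node.right)

        check(model.root)

    def test_determinism_bit_identical_serialization(self, tmp_path):
        data = random_mixed_dataset(seed=9, T=120)
        cfg = TrainConfig(alpha=2.0, min_samples_leaf=2, seed=7)
        serialize_model(fit(data, cfg), tmp_path / "a.json")
        serialize_model(fit(data, cfg), tmp_path / "b.json")
        assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()


class TestPredict:
    def test_single_leaf_predicts_its_class_for_any_row(self):
        data = build_dataset({"x": [1.0, 2.0]}, [2, 2])
        model = fit(data, TrainConfig())
        cls, dist = predict(model, {"x": 99.0})
        assert cls == 2 and dist.probs[1] == 1.0

    def test_unseen_category_routes_to_false_branch(self):
        data = build_dataset(
            {"c": ["a", "a", "b", "b"]}, [1, 1, 4, 4], categorical={"c"}
        )
        model = fit(data, TrainConfig())
        assert not model.root.is_leaf and model.root.kind == "categorical"
        cls_unseen, _ = predict(model, {"c": "z"})
        # "z" != split category, so it must land where the non-matching rows go
        cls_b = predict(model, {"c": "b"})[0] if model.root.category == "a" else None
        if model.root.category == "a":
            assert cls_unseen == cls_b
        else:
            assert cls_unseen == predict(model, {"c": "a"})[0]

    def test_missing_feature_raises(self):
        data = build_dataset({"x": [1.0, 2.0]}, [1, 4])
        model = fit(data, TrainConfig())
        with pytest.raises(ValidationError):
            predict(model, {"other": 1.0})


class TestTreeStats:
    def test_one_split_tree(self):
        data = build_dataset({"x": [1.0, 2.0]}, [1, 4])
        assert tree_stats(fit(data, TrainConfig())) == (2, 3, 1)

    def test_binary_tree_identity_on_random_fits(self):
        for seed in range(5):
            data = random_mixed_dataset(seed=40 + seed, T=100)
            leaves, nodes, depth = tree_stats(fit(data, TrainConfig(min_samples_leaf=2)))
            assert nodes == 2 * leaves - 1
            assert depth <= nodes
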