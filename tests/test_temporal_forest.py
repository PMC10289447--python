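"""Tests for interval temporal decision trees and forests."""

import math

import numpy as np
import pytest

from eeglike.measures import FeatureTriple
from eeglike.temporal_forest import (
    ALLEN_RELATIONS,
    Interval,
    Proposition,
    TemporalDataset,
    TemporalSplit,
    TreeParams,
    accessible_intervals,
    build_dataset,
    coarsen,
    enumerate_intervals,
    eval_split,
    grow_forest,
    grow_tree,
    information_gain,
    predict,
)

# ---------------------------------------------------------------------------
# independent brute-force oracle for relation semantics
# ---------------------------------------------------------------------------


def brute_accessible(rel, cur, n):
    """Enumerate all intervals and keep those standing in `rel` to `cur`,
    using the textbook definitions written out case by case."""
    out = set()
    for x in range(1, n + 1):
        for y in range(x + 1, n + 1):
            o = (x, y)
            c = (cur.x, cur.y)
            keep = {
                "A": o[0] == c[1],
                "L": o[0] > c[1],
                "B": o[0] == c[0] and o[1] < c[1],
                "E": o[1] == c[1] and o[0] > c[0],
                "D": c[0] < o[0] and o[1] < c[1],
                "O": c[0] < o[0] < c[1] < o[1],
                "Abar": c[0] == o[1],
                "Lbar": o[1] < c[0],
                "Bbar": o[0] == c[0] and o[1] > c[1],
                "Ebar": o[1] == c[1] and o[0] < c[0],
                "Dbar": o[0] < c[0] and c[1] < o[1],
                "Obar": o[0] < c[0] < o[1] < c[1],
                "=": o == c,
            }[rel]
            if keep:
                out.add(Interval(x, y))
    return out


def random_dataset(rng, n_instances=30, n_features=3, w=6, p_like=0.5):
    n_int = w * (w - 1) // 2
    M = rng.standard_normal((n_instances, n_features, n_int))
    labels = np.where(rng.random(n_instances) < p_like, "like", "dislike")
    feats = [FeatureTriple(f"E{i + 1}", 9, "AVG") for i in range(n_features)]
    return TemporalDataset(M=M, features=feats, labels=labels, w=w,
                           keys=[(0, i) for i in range(n_instances)])


class TestAccessibleIntervals:
    def test_later_from_12_on_5_frames(self):
        got = accessible_intervals("L", Interval(1, 2), 5)
        assert got == {Interval(3, 4), Interval(3, 5), Interval(4, 5)}

    def test_during_15(self):
        got = accessible_intervals("D", Interval(1, 5), 5)
        assert got == {Interval(2, 3), Interval(2, 4), Interval(3, 4)}

    def test_equality_returns_current(self):
        assert accessible_intervals("=", Interval(2, 4), 6) == {Interval(2, 4)}

    @pytest.mark.parametrize("rel", ALLEN_RELATIONS)
    def test_matches_brute_force_enumeration(self, rel, rng):
        for _ in range(20):
            n = int(rng.integers(3, 9))
            ivs = enumerate_intervals(n)
            cur = ivs[int(rng.integers(len(ivs)))]
            assert accessible_intervals(rel, cur, n) == brute_accessible(rel, cur, n)

    def test_relations_partition_interval_pairs(self):
        """Any two intervals stand in exactly one of the 13 relations."""
        n = 6
        ivs = enumerate_intervals(n)
        for cur in ivs:
            seen = {}
            for rel in ALLEN_RELATIONS:
                for other in accessible_intervals(rel, cur, n):
                    assert other not in seen, f"{other} in both {seen.get(other)} and {rel}"
                    seen[other] = rel
            assert len(seen) == len(ivs)


class TestCoarsen:
    def test_identity_when_w_equals_frames(self, small_spectrograms):
        spec = small_spectrograms[0]
        coarse, edges = coarsen(spec, spec.n_frames)
        assert np.allclose(coarse, spec.values)
        assert np.array_equal(edges, np.arange(spec.n_frames + 1))

    def test_equal_span_arithmetic(self, small_spectrograms):
        spec = small_spectrograms[0]
        _, edges = coarsen(spec, 10)
        spans = np.diff(edges)
        assert spans.sum() == spec.n_frames
        assert spans.max() - spans.min() <= 1

    def test_whole_timeline_interval_covers_whole_series(self, small_spectrograms):
        from eeglike.measures import compute_measure

        spec = small_spectrograms[0]
        w = 10
        ds = build_dataset([spec], [FeatureTriple("E1", 9, "AVG")],
                           {spec.key: "like"}, w=w)
        k = ds.intervals.index(Interval(1, w))
        assert ds.M[0, 0, k] == pytest.approx(
            compute_measure("AVG", spec.series("E1", 9)))

    def test_w_larger_than_frames_rejected(self, small_spectrograms):
        with pytest.raises(ValueError, match="exceeds"):
            coarsen(small_spectrograms[0], small_spectrograms[0].n_frames + 1)


class TestEvalSplit:
    def test_unsatisfiable_proposition_goes_right(self, rng):
        ds = random_dataset(rng, n_instances=1)
        ds.M[0, 0, :] = 0.0
        split = TemporalSplit("L", Proposition(ds.features[0], ">=", 0.5))
        branch, witness = eval_split(ds.M[0, 0], split, Interval(1, 2), ds)
        assert branch == "right" and witness is None

    def test_witness_is_first_satisfying_interval(self, rng):
        ds = random_dataset(rng, n_instances=1, w=6)
        ds.M[0, 0, :] = 0.0
        hot = [Interval(3, 5), Interval(4, 6)]
        for iv in hot:
            ds.M[0, 0, ds.intervals.index(iv)] = 1.0
        split = TemporalSplit("L", Proposition(ds.features[0], ">=", 0.5))
        branch, witness = eval_split(ds.M[0, 0], split, Interval(1, 2), ds)
        assert branch == "left"
        assert witness == Interval(3, 5)  # lexicographically smallest

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(40):
            w = int(rng.integers(4, 9))
            ds = random_dataset(rng, n_instances=1, n_features=1, w=w)
            ivs = ds.intervals
            cur = ivs[int(rng.integers(len(ivs)))]
            rel = ALLEN_RELATIONS[int(rng.integers(13))]
            cmp_ = ">=" if rng.random() < 0.5 else "<"
            theta = float(rng.standard_normal())
            split = TemporalSplit(rel, Proposition(ds.features[0], cmp_, theta))
            branch, witness = eval_split(ds.M[0, 0], split, cur, ds)
            sats = sorted(
                iv for iv in brute_accessible(rel, cur, w)
                if (ds.M[0, 0, ivs.index(iv)] >= theta) == (cmp_ == ">=")
            )
            if sats:
                assert branch == "left" and witness == sats[0]
            else:
                assert branch == "right" and witness is None


class TestInformationGain:
    def test_perfect_split_of_balanced_parent_is_one_bit(self):
        assert information_gain(list("llrr"), list("ll"), list("rr")) == pytest.approx(1.0)

    def test_identical_child_distributions_give_zero(self):
        parent = ["a", "a", "b", "b"]
        assert information_gain(parent, ["a", "b"], ["a", "b"]) == pytest.approx(0.0)

    def test_matches_direct_entropy_arithmetic(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 30))
            labels = ["like" if v else "dislike" for v in rng.random(n) < 0.4]
            k = int(rng.integers(0, n + 1))
            left, right = labels[:k], labels[k:]

            def h(ls):
                if not ls:
                    return 0.0
                p = sum(1 for x in ls if x == "like") / len(ls)
                out = 0.0
                for q in (p, 1 - p):
                    if q > 0:
                        out -= q * math.log2(q)
                return out

            want = h(labels) - len(left) / n * h(left) - len(right) / n * h(right)
            assert information_gain(labels, left, right) == pytest.approx(want)
            assert information_gain(labels, left, right) >= -1e-12

    def test_empty_parent_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            information_gain([], [], [])


class TestGrowTree:
    def test_single_class_data_gives_single_leaf(self, rng):
        ds = random_dataset(rng, n_instances=12, p_like=1.0)
        tree = grow_tree(ds)
        from eeglike.temporal_forest import Leaf

        assert isinstance(tree.root, Leaf)
        assert tree.root.label == "like"

    def test_max_depth_zero_gives_majority_leaf(self, rng):
        ds = random_dataset(rng, n_instances=20, p_like=0.7)
        tree = grow_tree(ds, TreeParams(max_depth=0))
        from eeglike.temporal_forest import Leaf

        assert isinstance(tree.root, Leaf)
        n_like = int(np.sum(ds.labels == "like"))
        assert tree.root.label == ("like" if n_like > 20 - n_like else "dislike")

    def test_separable_planted_pattern_reaches_perfect_training_accuracy(self, rng):
        """One proposition separates the classes: like instances carry a high
        value on some later interval of feature 0."""
        ds = random_dataset(rng, n_instances=40, n_features=4, w=10)
        ds.M[:, 0, :] = rng.uniform(0.0, 0.4, ds.M[:, 0, :].shape)
        for i in np.flatnonzero(ds.labels == "like"):
            k = int(rng.integers(10, len(ds.intervals)))
            ds.M[i, 0, k] = 1.0
        tree = grow_tree(ds)
        assert np.mean(predict(tree, ds) == ds.labels) == 1.0

    def test_empty_data_rejected(self, rng):
        ds = random_dataset(rng)
        with pytest.raises(ValueError, match="empty"):
            grow_tree(ds, indices=[])

    def test_split_soundness_on_training_instances(self, rng):
        """Left-routed instances have a concrete witness satisfying the split's
        proposition; right-routed ones have none (exhaustive check, small W)."""
        from eeglike.temporal_forest import Leaf, Node

        ds = random_dataset(rng, n_instances=30, n_features=2, w=6)
        tree = grow_tree(ds)
        feat_pos = {f: j for j, f in enumerate(ds.features)}

        def walk(node, idx, cur):
            if isinstance(node, Leaf) or not idx:
                return
            lidx, ridx, lcur, rcur = [], [], [], []
            for i, c in zip(idx, cur):
                f = feat_pos[node.split.proposition.feature]
                branch, wit = eval_split(ds.M[i, f], node.split, c, ds)
                sats = [
                    iv for iv in brute_accessible(node.split.relation, c, ds.w)
                    if node.split.proposition.holds(ds.M[i, f, ds.intervals.index(iv)])
                ]
                if branch == "left":
                    assert wit in sats
                    lidx.append(i)
                    lcur.append(wit)
                else:
                    assert not sats
                    ridx.append(i)
                    rcur.append(c)
            walk(node.left, lidx, lcur)
            walk(node.right, ridx, rcur)

        walk(tree.root, list(range(30)), [Interval(1, 2)] * 30)

    def test_accepted_splits_do_not_increase_entropy(self, rng):
        """Monotone purity: at every internal node the weighted child entropy
        is no larger than the parent entropy."""
        from eeglike.temporal_forest import Leaf, Node

        ds = random_dataset(rng, n_instances=40, n_features=3, w=6)
        tree = grow_tree(ds)
        feat_pos = {f: j for j, f in enumerate(ds.features)}

        def h(labs):
            if len(labs) == 0:
                return 0.0
            p = np.mean(labs == "like")
            return -sum(q * math.log2(q) for q in (p, 1 - p) if q > 0)

        def walk(node, idx, cur):
            if isinstance(node, Leaf):
                return
            li, ri, lc, rc = [], [], [], []
            for i, c in zip(idx, cur):
                f = feat_pos[node.split.proposition.feature]
                branch, wit = eval_split(ds.M[i, f], node.split, c, ds)
                (li if branch == "left" else ri).append(i)
                (lc if branch == "left" else rc).append(wit if branch == "left" else c)
            labs = ds.labels[idx]
            ll, rl = ds.labels[li], ds.labels[ri]
            child = (len(ll) * h(ll) + len(rl) * h(rl)) / len(labs)
            assert child <= h(labs) + 1e-9
            walk(node.left, li, lc)
            walk(node.right, ri, rc)

        walk(tree.root, list(range(40)), [Interval(1, 2)] * 40)


class TestForest:
    def test_forest_has_requested_trees_and_is_deterministic(self, rng):
        ds = random_dataset(rng, n_instances=25)
        f1 = grow_forest(ds, n_trees=10, master_seed=5)
        f2 = grow_forest(ds, n_trees=10, master_seed=5)
        assert len(f1.trees) == 10
        assert np.array_equal(predict(f1, ds), predict(f2, ds))

    def test_single_tree_no_bootstrap_equals_plain_tree(self, rng):
        ds = random_dataset(rng, n_instances=25)
        forest = grow_forest(ds, n_trees=1, master_seed=0, bootstrap=False)
        tree = grow_tree(ds)
        assert np.array_equal(predict(forest, ds), predict(tree, ds))

    def test_different_seeds_differ_somewhere(self, rng):
        ds = random_dataset(rng, n_instances=40, n_features=3)
        f1 = grow_forest(ds, n_trees=5, master_seed=1)
        f2 = grow_forest(ds, n_trees=5, master_seed=2)
        r1 = [repr(t.root) for t in f1.trees]
        r2 = [repr(t.root) for t in f2.trees]
        assert r1 != r2
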