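"""Interval temporal decision trees and random forests.

A conventional decision tree asks whether a scalar feature of the whole
series exceeds a threshold.  An *interval temporal* tree relativizes the
question to time intervals: a split asks whether there EXISTS an interval,
reachable from the instance's current reference interval through one of
Allen's thirteen interval relations, on which a measure of one
electrode-band series satisfies a threshold proposition.  Instances for
which a witness interval exists go left (and carry that witness as their
new reference interval); the rest go right — which is exactly the
universal dual, "every reachable interval violates the proposition".

Interval semantics: the trial's frame timeline is coarsened into W spans
(default 10); an interval [x, y] with 1 <= x < y <= W covers coarse
frames x..y, and propositions are evaluated on the full-resolution frame
values inside that span.  Trees are grown greedily by Shannon
information gain with deterministic tie-breaking; forests are bagged
ensembles with per-node feature subsampling and majority vote (ties go
to "dislike").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .measures import FeatureTriple, compute_measure

__all__ = [
    "Interval",
    "ALLEN_RELATIONS",
    "Proposition",
    "TemporalSplit",
    "TreeParams",
    "TemporalTree",
    "TemporalForest",
    "TemporalDataset",
    "accessible_intervals",
    "coarsen",
    "build_dataset",
    "eval_split",
    "information_gain",
    "grow_tree",
    "grow_forest",
    "predict",
]

DISLIKE, LIKE = "dislike", "like"

#: the six direct relations, their inverses, and equality
ALLEN_RELATIONS: tuple[str, ...] = (
    "A", "L", "B", "E", "D", "O",
    "Abar", "Lbar", "Bbar", "Ebar", "Dbar", "Obar",
    "=",
)


@dataclass(frozen=True, order=True)
class Interval:
    """Strict interval [x, y], 1 <= x < y <= N, covering coarse frames x..y."""

    x: int
    y: int

    def __post_init__(self):
        if not (1 <= self.x < self.y):
            raise ValueError(f"invalid interval [{self.x}, {self.y}]")


def _relation_holds(rel: str, cur: Interval, other: Interval) -> bool:
    """Does ``other`` stand in relation ``rel`` to the current interval?"""
    x, y, x2, y2 = cur.x, cur.y, other.x, other.y
    if rel == "A":  # meets
        return x2 == y
    if rel == "L":  # later
        return x2 > y
    if rel == "B":  # begun-by (shares the start, ends earlier)
        return x2 == x and y2 < y
    if rel == "E":  # ended-by (shares the end, starts later)
        return y2 == y and x2 > x
    if rel == "D":  # during
        return x < x2 and y2 < y
    if rel == "O":  # overlaps
        return x < x2 < y < y2
    if rel == "=":
        return x2 == x and y2 == y
    base = rel[:-3]  # inverse: swap the roles of the two intervals
    return _relation_holds(base, other, cur)


def accessible_intervals(rel: str, current: Interval, n: int) -> set[Interval]:
    """All intervals on a timeline of ``n`` frames reachable from ``current``
    through ``rel``; the equality relation returns {current}."""
    if rel not in ALLEN_RELATIONS:
        raise ValueError(f"unknown Allen relation {rel!r}")
    if current.y > n:
        raise ValueError(f"{current} not valid on a timeline of {n} frames")
    return {
        Interval(x, y)
        for x in range(1, n)
        for y in range(x + 1, n + 1)
        if _relation_holds(rel, current, Interval(x, y))
    }


def enumerate_intervals(n: int) -> list[Interval]:
    """All strict intervals on n frames, in lexicographic (x, y) order."""
    return [Interval(x, y) for x in range(1, n) for y in range(x + 1, n + 1)]


def relation_masks(n: int) -> dict[str, np.ndarray]:
    """For each relation, boolean matrix R[i, j]: interval j is reachable
    from interval i; indices follow :func:`enumerate_intervals` order."""
    ivs = enumerate_intervals(n)
    k = len(ivs)
    masks = {}
    for rel in ALLEN_RELATIONS:
        m = np.zeros((k, k), dtype=bool)
        for i, cur in enumerate(ivs):
            for j, other in enumerate(ivs):
                m[i, j] = _relation_holds(rel, cur, other)
        masks[rel] = m
    return masks


# ---------------------------------------------------------------------------
# coarse timeline and dataset cache
# ---------------------------------------------------------------------------


@dataclass
class CoarseInstance:
    """One trial on the coarse timeline: native frame series per feature plus
    the cached measure value of every feature over every interval."""

    key: tuple
    n_frames: int  # W
    edges: np.ndarray  # W+1 native-frame boundaries
    values: np.ndarray  # n_features x n_intervals, measure per interval


def coarsen(spectrogram, w: int):
    """Split the native frame axis into ``w`` equal spans.

    Returns (coarse, edges): ``coarse`` is an electrodes x bands x w array of
    span means (a display-resolution view), ``edges`` the native-frame
    boundaries such that span s covers frames [edges[s], edges[s+1]).
    """
    t = spectrogram.n_frames
    if w < 2:
        raise ValueError("need at least 2 coarse frames")
    if w > t:
        raise ValueError(f"W={w} exceeds the native frame count {t}")
    edges = np.round(np.arange(w + 1) * t / w).astype(int)
    coarse = np.stack(
        [spectrogram.values[:, :, edges[s] : edges[s + 1]].mean(axis=2) for s in range(w)],
        axis=2,
    )
    return coarse, edges


@dataclass
class TemporalDataset:
    """Instance-major cache of interval measures for the learner.

    ``M[i, f, k]`` is feature f of instance i over interval k (NaN when the
    measure is undefined on that span); interval k follows
    :func:`enumerate_intervals` order on the W-frame timeline.
    """

    M: np.ndarray  # n_instances x n_features x n_intervals
    features: list[FeatureTriple]
    labels: np.ndarray  # array of 'like'/'dislike' strings
    w: int
    keys: list[tuple]
    intervals: list[Interval] = field(init=False)
    masks: dict = field(init=False)
    root_index: int = field(init=False)

    def __post_init__(self):
        self.intervals = enumerate_intervals(self.w)
        self.masks = relation_masks(self.w)
        self.root_index = self.intervals.index(Interval(1, 2))

    @property
    def n_instances(self) -> int:
        return self.M.shape[0]


def build_dataset(spectrograms, triples: Sequence[FeatureTriple], labels,
                  w: int = 10) -> TemporalDataset:
    """Evaluate every feature triple over every interval of every instance.

    ``labels`` maps spectrogram keys to 'like'/'dislike' (instances without a
    label are dropped — e.g. neutral-binned trials).
    """
    triples = list(triples)
    ivs = enumerate_intervals(w)
    rows, keys, labs = [], [], []
    for spec in spectrograms:
        if spec.key not in labels:
            continue
        _, edges = coarsen(spec, w)
        row = np.empty((len(triples), len(ivs)))
        series_cache = {}
        for f, tr in enumerate(triples):
            sb = (tr.electrode, tr.band)
            if sb not in series_cache:
                series_cache[sb] = spec.series(*sb)
            native = series_cache[sb]
            for k, iv in enumerate(ivs):
                row[f, k] = compute_measure(tr.measure, native[edges[iv.x - 1] : edges[iv.y]])
        rows.append(row)
        keys.append(spec.key)
        labs.append(labels[spec.key])
    if not rows:
        raise ValueError("no labelled instances")
    return TemporalDataset(M=np.stack(rows), features=triples,
                           labels=np.array(labs), w=w, keys=keys)


# ---------------------------------------------------------------------------
# splits and trees
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Proposition:
    """Threshold proposition on one feature: measure(electrode, band) cmp threshold."""

    feature: FeatureTriple
    comparator: str  # '>=' or '<'
    threshold: float

    def holds(self, value: float) -> bool:
        if math.isnan(value):
            return False  # undefined measure never satisfies a proposition
        return value >= self.threshold if self.comparator == ">=" else value < self.threshold


@dataclass(frozen=True)
class TemporalSplit:
    """<relation>(proposition): left iff some accessible interval satisfies it."""

    relation: str
    proposition: Proposition


@dataclass(frozen=True)
class TreeParams:
    min_leaf_size: int = 2
    purity_threshold: float = 0.95
    max_depth: int = 6
    w: int = 10  # coarse frames
    n_thresholds: int = 9  # decile candidates
    comparators: tuple[str, ...] = (">=", "<")
    feature_subsample: bool = False  # sqrt(F) features per node (forests)


@dataclass
class Leaf:
    label: str
    counts: dict[str, int]


@dataclass
class Node:
    split: TemporalSplit
    left: "Node | Leaf"
    right: "Node | Leaf"


@dataclass
class TemporalTree:
    root: "Node | Leaf"
    params: TreeParams
    features: list[FeatureTriple]
    w: int


@dataclass
class TemporalForest:
    trees: list[TemporalTree]
    master_seed: int
    vote_tie: str = DISLIKE


def information_gain(parent_labels, left_labels, right_labels) -> float:
    """Shannon information gain, in bits, of a binary partition."""
    parent = list(parent_labels)
    if not parent:
        raise ValueError("empty parent")
    if len(left_labels) + len(right_labels) != len(parent):
        raise ValueError("children must partition the parent")

    def h(labels):
        n = len(labels)
        if n == 0:
            return 0.0
        ent = 0.0
        for lab in set(labels):
            p = sum(1 for x in labels if x == lab) / n
            ent -= p * math.log2(p)
        return ent

    n = len(parent)
    wl, wr = len(left_labels) / n, len(right_labels) / n
    return h(parent) - wl * h(list(left_labels)) - wr * h(list(right_labels))


def _entropy_from_counts(n1: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Vectorized binary entropy given positive counts n1 out of n (n may be 0)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, n1 / np.maximum(n, 1), 0.0)
        ent = -(np.where(p > 0, p * np.log2(np.maximum(p, 1e-300)), 0.0)
                + np.where(p < 1, (1 - p) * np.log2(np.maximum(1 - p, 1e-300)), 0.0))
    return np.where(n > 0, ent, 0.0)


def eval_split(instance_values: np.ndarray, split: TemporalSplit, current: Interval,
               dataset: TemporalDataset):
    """Evaluate one split for one instance.

    ``instance_values`` is the instance's cached value vector for the split's
    feature (one entry per interval).  Returns ('left', witness_interval) when
    some accessible interval satisfies the proposition — the witness being the
    lexicographically smallest such interval — else ('right', None).
    """
    cur_idx = dataset.intervals.index(current)
    mask = dataset.masks[split.relation][cur_idx]
    vals = instance_values
    if split.proposition.comparator == ">=":
        sat = (vals >= split.proposition.threshold) & mask
    else:
        sat = (vals < split.proposition.threshold) & mask
    sat &= ~np.isnan(vals)
    hits = np.flatnonzero(sat)
    if hits.size == 0:
        return "right", None
    return "left", dataset.intervals[int(hits[0])]


def _grow(dataset: TemporalDataset, idx: np.ndarray, cur: np.ndarray, depth: int,
          params: TreeParams, rng: np.random.Generator | None) -> "Node | Leaf":
    labels = dataset.labels[idx]
    n = idx.size
    n_like = int(np.sum(labels == LIKE))
    counts = {DISLIKE: n - n_like, LIKE: n_like}
    majority = LIKE if n_like > n - n_like else DISLIKE
    purity = max(n_like, n - n_like) / n
    if n < params.min_leaf_size or purity >= params.purity_threshold or depth >= params.max_depth:
        return Leaf(majority, counts)

    n_feat = len(dataset.features)
    if params.feature_subsample and rng is not None:
        k = int(math.ceil(math.sqrt(n_feat)))
        feat_ids = np.sort(rng.choice(n_feat, size=k, replace=False))
    else:
        feat_ids = np.arange(n_feat)

    y = (labels == LIKE).astype(np.int64)
    parent_ent = _entropy_from_counts(np.array([n_like]), np.array([n]))[0]

    # Existence of a satisfying accessible interval reduces to a per-instance
    # extremum: some accessible value >= theta iff max over accessible >= theta
    # (dually min < theta), so each threshold candidate is O(n) to score.
    best = None  # (gain, split_descriptor)
    acc = {rel: dataset.masks[rel][cur] for rel in ALLEN_RELATIONS}  # n x I each
    for f in feat_ids:
        S = dataset.M[idx, f, :]  # n x I
        finite = ~np.isnan(S)
        pool = S[finite]
        if pool.size == 0:
            continue
        # decile thresholds from the node's pooled interval values of this feature
        qs = np.percentile(pool, np.linspace(10, 90, params.n_thresholds))
        for rel in ALLEN_RELATIONS:
            A = acc[rel] & finite
            if not A.any():
                continue
            mx = np.where(A, S, -np.inf).max(axis=1)
            mn = np.where(A, S, np.inf).min(axis=1)
            for cmp_ in params.comparators:
                sat_thr = (mx[:, None] >= qs[None, :]) if cmp_ == ">=" else (mn[:, None] < qs[None, :])
                nl = sat_thr.sum(axis=0)
                nl1 = (sat_thr & (y[:, None] == 1)).sum(axis=0)
                nr, nr1 = n - nl, n_like - nl1
                child = (nl * _entropy_from_counts(nl1, nl)
                         + nr * _entropy_from_counts(nr1, nr)) / n
                gains = np.where((nl > 0) & (nl < n), parent_ent - child, 0.0)
                t = int(np.argmax(gains))
                if gains[t] > 1e-12 and (best is None or gains[t] > best[0] + 1e-12):
                    best = (float(gains[t]), (f, rel, cmp_, float(qs[t])))
    if best is None:
        return Leaf(majority, counts)

    f, rel, cmp_, theta = best[1]
    split = TemporalSplit(rel, Proposition(dataset.features[f], cmp_, theta))
    S = dataset.M[idx, f, :]
    finite = ~np.isnan(S)
    A = acc[rel] & finite
    with np.errstate(invalid="ignore"):
        sat = ((S >= theta) if cmp_ == ">=" else (S < theta)) & A
    left_mask = sat.any(axis=1)
    wit = np.argmax(sat, axis=1)
    left_idx = idx[left_mask]
    right_idx = idx[~left_mask]
    left_cur = wit[left_mask]  # witness becomes the new reference interval
    right_cur = cur[~left_mask]  # reference unchanged on the universal branch
    left = _grow(dataset, left_idx, left_cur, depth + 1, params, rng)
    right = _grow(dataset, right_idx, right_cur, depth + 1, params, rng)
    return Node(split, left, right)


def grow_tree(dataset: TemporalDataset, params: TreeParams | None = None,
              seed: int | None = None, indices: Iterable[int] | None = None) -> TemporalTree:
    """Greedy interval temporal decision tree on (a subset of) the dataset."""
    params = params or TreeParams()
    idx = np.arange(dataset.n_instances) if indices is None else np.asarray(list(indices))
    if idx.size == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed) if seed is not None else None
    cur = np.full(idx.size, dataset.root_index)
    root = _grow(dataset, idx, cur, 0, params, rng)
    return TemporalTree(root=root, params=params, features=list(dataset.features), w=dataset.w)


def grow_forest(dataset: TemporalDataset, params: TreeParams | None = None,
                n_trees: int = 100, master_seed: int = 0,
                indices: Iterable[int] | None = None,
                bootstrap: bool = True) -> TemporalForest:
    """Bagged ensemble of temporal trees with per-node feature subsampling."""
    params = replace(params or TreeParams(), feature_subsample=bootstrap)
    base = np.arange(dataset.n_instances) if indices is None else np.asarray(list(indices))
    if base.size == 0:
        raise ValueError("empty training set")
    seeds = np.random.SeedSequence(master_seed).generate_state(2 * n_trees)
    trees = []
    for t in range(n_trees):
        rng = np.random.default_rng(int(seeds[2 * t]))
        idx = rng.choice(base, size=base.size, replace=True) if bootstrap else base
        trees.append(grow_tree(dataset, params, seed=int(seeds[2 * t + 1]), indices=idx))
    return TemporalForest(trees=trees, master_seed=master_seed)


def _predict_tree(tree: TemporalTree, values: np.ndarray, dataset: TemporalDataset) -> str:
    """Route one instance (its full M[i] feature x interval matrix) to a leaf."""
    node = tree.root
    current = Interval(1, 2)
    feat_pos = {f: j for j, f in enumerate(dataset.features)}
    while isinstance(node, Node):
        f = feat_pos.get(node.split.proposition.feature)
        if f is None:
            raise KeyError(f"instance lacks feature {node.split.proposition.feature}")
        branch, witness = eval_split(values[f], node.split, current, dataset)
        if branch == "left":
            current = witness
            node = node.left
        else:
            node = node.right
    return node.label


def predict(model: "TemporalTree | TemporalForest", dataset: TemporalDataset,
            indices: Iterable[int] | None = None) -> np.ndarray:
    """Predicted class per instance; forests take a majority vote with ties
    going to 'dislike'."""
    idx = np.arange(dataset.n_instances) if indices is None else np.asarray(list(indices))
    out = []
    for i in idx:
        vals = dataset.M[i]
        if isinstance(model, TemporalTree):
            out.append(_predict_tree(model, vals, dataset))
        else:
            votes = sum(1 for t in model.trees if _predict_tree(t, vals, dataset) == LIKE)
            half = len(model.trees) / 2
            if votes > half:
                out.append(LIKE)
            elif votes < half:
                out.append(DISLIKE)
            else:
                out.append(model.vote_tie)
    return np.array(out)
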