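"""Leave-p-out evaluation of temporal forests.

The protocol mirrors small-dataset practice: per repetition, p instances
(default 10) are drawn uniformly without replacement as the validation
set, a forest is trained on the remainder, and four metrics are recorded
as percentages — overall accuracy, sensitivity (fraction of likes
recognized), specificity (fraction of dislikes recognized), and average
accuracy, the mean of sensitivity and specificity, which is the more
informative summary when classes are imbalanced.  Repetitions are
independent Monte-Carlo draws, not an exhaustive enumeration of all
p-subsets.  A label-shuffle control re-runs the same protocol after
permuting the labels; on informative data its accuracy collapses to
chance while the unshuffled run does not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .temporal_forest import (
    LIKE,
    DISLIKE,
    TemporalDataset,
    TreeParams,
    grow_forest,
    predict,
)

__all__ = [
    "CVConfig",
    "Metrics",
    "CVResult",
    "confusion_metrics",
    "leave_p_out",
    "experiment_grid",
    "shuffle_control",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVConfig:
    p: int = 10
    repetitions: int = 10
    n_trees: int = 100
    seeds: tuple[int, ...] | None = None  # one per repetition; derived when None

    def repetition_seeds(self, master_seed: int) -> tuple[int, ...]:
        if self.seeds is not None:
            if len(self.seeds) != self.repetitions:
                raise ValueError("need one seed per repetition")
            return self.seeds
        ss = np.random.SeedSequence(master_seed).generate_state(self.repetitions)
        return tuple(int(s) for s in ss)


@dataclass(frozen=True)
class Metrics:
    """Percent metrics of one validation round; NaN marks an undefined metric
    (e.g. sensitivity when the held-out set contains no likes)."""

    acc: float
    avg_acc: float
    sens: float
    spec: float

    def as_dict(self) -> dict[str, float]:
        return {"acc": self.acc, "avg_acc": self.avg_acc,
                "sens": self.sens, "spec": self.spec}


def confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> Metrics:
    """Four percent metrics from confusion counts ('like' is the positive class)."""
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("empty held-out set")
    acc = 100.0 * (tp + tn) / total
    if tp + fn > 0:
        sens = 100.0 * tp / (tp + fn)
    else:
        log.warning("held-out set has no positive instances; sensitivity undefined")
        sens = float("nan")
    if tn + fp > 0:
        spec = 100.0 * tn / (tn + fp)
    else:
        log.warning("held-out set has no negative instances; specificity undefined")
        spec = float("nan")
    avg = (sens + spec) / 2.0
    return Metrics(acc=acc, avg_acc=avg, sens=sens, spec=spec)


@dataclass
class CVResult:
    per_repetition: list[Metrics]
    config: dict = field(default_factory=dict)

    def _stack(self) -> np.ndarray:
        return np.array([[m.acc, m.avg_acc, m.sens, m.spec] for m in self.per_repetition])

    @property
    def mean(self) -> Metrics:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            v = np.nanmean(self._stack(), axis=0)
        return Metrics(*v)

    @property
    def sd(self) -> Metrics:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            v = np.nanstd(self._stack(), axis=0, ddof=1)
        return Metrics(*v)

    def summary(self) -> str:
        m, s = self.mean, self.sd
        return (f"acc {m.acc:.0f}±{s.acc:.0f}  avg-acc {m.avg_acc:.0f}±{s.avg_acc:.0f}  "
                f"sens {m.sens:.0f}±{s.sens:.0f}  spec {m.spec:.0f}±{s.spec:.0f}")


def _round_metrics(labels_true: np.ndarray, labels_pred: np.ndarray) -> Metrics:
    tp = int(np.sum((labels_true == LIKE) & (labels_pred == LIKE)))
    tn = int(np.sum((labels_true == DISLIKE) & (labels_pred == DISLIKE)))
    fp = int(np.sum((labels_true == DISLIKE) & (labels_pred == LIKE)))
    fn = int(np.sum((labels_true == LIKE) & (labels_pred == DISLIKE)))
    return confusion_metrics(tp, tn, fp, fn)


def leave_p_out(dataset: TemporalDataset, params: TreeParams, cv: CVConfig,
                master_seed: int = 0, labels: np.ndarray | None = None,
                config: dict | None = None) -> CVResult:
    """Monte-Carlo leave-p-out cross-validation of a temporal forest.

    ``labels`` overrides the dataset's labels (used by the shuffle control).
    """
    n = dataset.n_instances
    if n < cv.p + 2:
        raise ValueError(f"dataset of {n} instances too small for p={cv.p}")
    y = dataset.labels if labels is None else np.asarray(labels)
    seeds = cv.repetition_seeds(master_seed)
    work = dataset if labels is None else _relabel(dataset, y)
    per_rep = []
    for r in range(cv.repetitions):
        rng = np.random.default_rng(seeds[r])
        held = rng.choice(n, size=cv.p, replace=False)
        train = np.setdiff1d(np.arange(n), held)
        forest = grow_forest(work, params, n_trees=cv.n_trees,
                             master_seed=seeds[r], indices=train)
        pred = predict(forest, work, indices=held)
        per_rep.append(_round_metrics(y[held], pred))
    return CVResult(per_repetition=per_rep, config=dict(config or {}))


def _relabel(dataset: TemporalDataset, labels: np.ndarray) -> TemporalDataset:
    clone = TemporalDataset(M=dataset.M, features=dataset.features,
                            labels=np.asarray(labels), w=dataset.w, keys=dataset.keys)
    return clone


def experiment_grid(datasets=("D25", "D34", "D41"),
                    band_sets=("all", "beta", "gamma", "betagamma"),
                    electrode_counts=(1, 5, 10),
                    measure_counts=(5,)) -> list[dict]:
    """Cartesian product of experimental configurations; 3 x 4 x 3 = 36 per
    measure-count setting."""
    return [
        {"binning": d, "bands": b, "n_electrodes": e, "n_measures": m}
        for m, d, b, e in product(measure_counts, datasets, band_sets, electrode_counts)
    ]


def shuffle_control(dataset: TemporalDataset, params: TreeParams, cv: CVConfig,
                    n_shuffles: int = 5, master_seed: int = 0) -> list[CVResult]:
    """Re-run leave-p-out after uniformly permuting the labels (class counts
    preserved); one CVResult per shuffle seed."""
    seeds = np.random.SeedSequence(master_seed).generate_state(n_shuffles)
    results = []
    for s in range(n_shuffles):
        rng = np.random.default_rng(seeds[s])
        perm = rng.permutation(dataset.n_instances)
        shuffled = dataset.labels[perm]
        res = leave_p_out(dataset, params, cv, master_seed=int(seeds[s]),
                          labels=shuffled, config={"shuffle_seed": int(seeds[s])})
        results.append(res)
    return results
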