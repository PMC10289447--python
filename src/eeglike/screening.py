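"""Score binning and variance-based electrode / measure screening.

Liking scores are discretized into like/dislike under one of three
threshold pairs (D25: <25 / >=25; D34: <17 / >=34; D41: <10 / >=41),
with the middle ("neutral") range excluded.  Feature screening is
label-blind: the sample variance of every (electrode, band, measure)
feature across the whole dataset is min-max normalized jointly across
all features, and electrodes (e-score) and measures (m-score) are ranked
by their average normalized variance — the assumption being that, for a
given measure, a band is more informative where it varies more across
instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BinningRule",
    "BINNING_RULES",
    "ScreeningReport",
    "bin_scores",
    "label_for",
    "normalized_variance",
    "e_scores",
    "m_scores",
    "select",
    "screen",
]


@dataclass(frozen=True)
class BinningRule:
    name: str
    dislike_below: int
    like_at_least: int

    def __post_init__(self):
        if self.dislike_below > self.like_at_least:
            raise ValueError("dislike_below must not exceed like_at_least")


BINNING_RULES: dict[str, BinningRule] = {
    "D25": BinningRule("D25", 25, 25),
    "D34": BinningRule("D34", 17, 34),
    "D41": BinningRule("D41", 10, 41),
}


def label_for(score: int, rule: BinningRule) -> str | None:
    """'dislike', 'like', or None when the score falls in the neutral gap."""
    if not (0 <= score <= 50):
        raise ValueError(f"score {score} outside [0, 50]")
    if score < rule.dislike_below:
        return "dislike"
    if score >= rule.like_at_least:
        return "like"
    return None


def bin_scores(scores: dict, rule: BinningRule) -> dict:
    """Binary-labelled instance set: keys mapped to 'like'/'dislike'; neutral dropped."""
    out = {}
    for key, score in scores.items():
        lab = label_for(score, rule)
        if lab is not None:
            out[key] = lab
    return out


def _parse_columns(columns) -> pd.MultiIndex:
    parts = []
    for c in columns:
        elec, band, meas = c.rsplit(".", 2)
        parts.append((elec, int(band.lstrip("F")), meas))
    return pd.MultiIndex.from_tuples(parts, names=["electrode", "band", "measure"])


def normalized_variance(matrix: pd.DataFrame) -> pd.Series:
    """Per-feature sample variance (n-1 denominator), min-max rescaled jointly
    across all features into [0, 1].

    Index: (electrode, band, measure) parsed from ``electrode.Fband.MEASURE``
    column names.  Features whose variance is undefined (fewer than two
    defined values) stay NaN and are skipped by the score averages.
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 instances to compute variances")
    var = matrix.var(axis=0, ddof=1, skipna=True)
    lo, hi = var.min(skipna=True), var.max(skipna=True)
    nv = (var - lo) / (hi - lo) if hi > lo else pd.Series(0.0, index=var.index) + var * 0
    nv.index = _parse_columns(matrix.columns)
    return nv


def _check_full_grid(nv: pd.Series) -> None:
    per_elec = {
        e: frozenset(zip(g.index.get_level_values("band"),
                         g.index.get_level_values("measure")))
        for e, g in nv.groupby(level="electrode")
    }
    if len(set(per_elec.values())) != 1:
        raise ValueError("incomplete electrode x band x measure grid")


def e_scores(nv: pd.Series) -> pd.Series:
    """Average normalized variance per electrode, ranked best (highest) first;
    ties broken lexicographically by electrode id."""
    _check_full_grid(nv)
    means = nv.groupby(level="electrode").mean()
    order = sorted(means.index, key=lambda e: (-means[e], e))
    return means.loc[order]


def m_scores(nv: pd.Series, electrode_group) -> pd.Series:
    """Average normalized variance per measure over the selected electrodes and
    all their bands, ranked best first; ties broken lexicographically by symbol.
    NaN cells (undefined measures) are excluded from the averages."""
    group = list(electrode_group)
    if not group:
        raise ValueError("electrode group must be non-empty")
    have = set(nv.index.get_level_values("electrode"))
    missing = set(group) - have
    if missing:
        raise KeyError(f"electrodes not in the grid: {sorted(missing)}")
    sub = nv[nv.index.get_level_values("electrode").isin(group)]
    means = sub.groupby(level="measure").mean()
    order = sorted(means.index, key=lambda m: (-means[m], m))
    return means.loc[order]


def select(ranking, k: int) -> list:
    """Top-k prefix of a ranking (pandas Series index order or plain list)."""
    items = list(ranking.index) if isinstance(ranking, pd.Series) else list(ranking)
    if k > len(items):
        raise ValueError(f"k={k} exceeds ranking length {len(items)}")
    return items[:k]


@dataclass
class ScreeningReport:
    """Outcome of the variance screen over a full feature grid."""

    normalized_variance: pd.Series
    e_scores: pd.Series
    electrode_ranking: list[str]
    m_scores: dict[int, pd.Series]  # electrode-group size -> ranked measure scores
    electrode_groups: dict[int, list[str]]
    measure_sets: dict[tuple[int, int], list[str]]  # (group size, n measures) -> symbols
    undefined_features: list[tuple] = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for gsize, ms in sorted(self.m_scores.items()):
            for rank, (sym, val) in enumerate(ms.items(), start=1):
                rows.append((gsize, rank, sym, val))
        return pd.DataFrame(rows, columns=["electrode_group", "rank", "measure", "m_score"])


def screen(matrix: pd.DataFrame,
           group_sizes=(1, 5, 10),
           measure_counts=(1, 5)) -> ScreeningReport:
    """Run the full screening procedure on an instances x features table.

    Steps: per-feature normalized variance; e-score ranking of electrodes;
    nested top-k electrode groups; per-group m-score ranking of measures and
    top-k measure sets.
    """
    nv = normalized_variance(matrix)
    es = e_scores(nv)
    ranking = list(es.index)
    group_sizes = tuple(k for k in group_sizes if k <= len(ranking))
    groups = {k: select(es, k) for k in group_sizes}
    ms = {k: m_scores(nv, groups[k]) for k in group_sizes}
    sets = {}
    for k, ranked in ms.items():
        for mcount in measure_counts:
            if mcount <= len(ranked):
                sets[(k, mcount)] = select(ranked, mcount)
    return ScreeningReport(
        normalized_variance=nv,
        e_scores=es,
        electrode_ranking=ranking,
        m_scores=ms,
        electrode_groups=groups,
        measure_sets=sets,
        undefined_features=[tuple(ix) for ix in nv.index[nv.isna()]],
    )
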