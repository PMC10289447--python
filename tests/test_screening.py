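"""Tests for score binning and variance-based screening."""

import numpy as np
import pandas as pd
import pytest

from eeglike.screening import (
    BINNING_RULES,
    bin_scores,
    e_scores,
    label_for,
    m_scores,
    normalized_variance,
    screen,
    select,
)


def _grid_frame(rng, electrodes, bands, measures, n=8):
    cols = [f"{e}.F{b}.{m}" for e in electrodes for b in bands for m in measures]
    return pd.DataFrame(rng.standard_normal((n, len(cols))), columns=cols)


class TestBinning:
    def test_d25_boundary(self):
        rule = BINNING_RULES["D25"]
        assert label_for(24, rule) == "dislike"
        assert label_for(25, rule) == "like"

    def test_d34_excludes_neutral(self):
        assert label_for(20, BINNING_RULES["D34"]) is None
        binned = bin_scores({("s", 1): 20, ("s", 2): 40, ("s", 3): 5},
                            BINNING_RULES["D34"])
        assert binned == {("s", 2): "like", ("s", 3): "dislike"}

    def test_all_max_scores_all_like(self):
        scores = {i: 50 for i in range(10)}
        for rule in BINNING_RULES.values():
            binned = bin_scores(scores, rule)
            assert len(binned) == 10
            assert set(binned.values()) == {"like"}

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            label_for(51, BINNING_RULES["D25"])

    def test_rule_thresholds(self):
        assert (BINNING_RULES["D25"].dislike_below, BINNING_RULES["D25"].like_at_least) == (25, 25)
        assert (BINNING_RULES["D34"].dislike_below, BINNING_RULES["D34"].like_at_least) == (17, 34)
        assert (BINNING_RULES["D41"].dislike_below, BINNING_RULES["D41"].like_at_least) == (10, 41)


class TestNormalizedVariance:
    def test_bounds_and_brute_force(self, rng):
        mat = _grid_frame(rng, ["a"], [1], [f"M{i}" for i in range(7)], n=5)
        nv = normalized_variance(mat)
        # brute-force two-pass variance then joint min-max rescale
        raw = []
        for c in mat.columns:
            x = mat[c].to_numpy()
            m = x.mean()
            raw.append(((x - m) ** 2).sum() / (len(x) - 1))
        raw = np.array(raw)
        want = (raw - raw.min()) / (raw.max() - raw.min())
        assert np.allclose(nv.to_numpy(), want)
        assert nv.min() == 0.0 and nv.max() == 1.0

    def test_constant_column_is_minimum(self, rng):
        mat = _grid_frame(rng, ["a"], [1], ["M0", "M1"], n=6)
        mat["a.F1.M0"] = 3.14
        nv = normalized_variance(mat)
        assert nv[("a", 1, "M0")] == 0.0

    def test_single_instance_rejected(self, rng):
        with pytest.raises(ValueError, match="2 instances"):
            normalized_variance(_grid_frame(rng, ["a"], [1], ["M0"], n=1))


class TestEScores:
    def test_dominant_electrode_ranks_first(self, rng):
        mat = _grid_frame(rng, ["hi", "lo"], [1, 2], ["M0", "M1"], n=10)
        for c in mat.columns:
            if c.startswith("hi"):
                mat[c] *= 10.0
        ranked = e_scores(normalized_variance(mat))
        assert list(ranked.index) == ["hi", "lo"]

    def test_brute_force_mean(self, rng):
        bands, measures = [1, 2, 3], ["M0", "M1"]
        mat = _grid_frame(rng, ["a", "b"], bands, measures, n=9)
        nv = normalized_variance(mat)
        es = e_scores(nv)
        for e in ("a", "b"):
            vals = [nv[(e, b, m)] for b in bands for m in measures]
            assert es[e] == pytest.approx(sum(vals) / len(vals))

    def test_all_equal_ties_break_lexicographically(self):
        cols = [f"{e}.F1.M0" for e in ["c", "a", "b"]]
        mat = pd.DataFrame(np.tile([[0.0], [1.0]], (1, 3)), columns=cols)
        ranked = e_scores(normalized_variance(mat))
        assert list(ranked.index) == ["a", "b", "c"]

    def test_incomplete_grid_rejected(self, rng):
        mat = _grid_frame(rng, ["a", "b"], [1], ["M0", "M1"], n=5)
        with pytest.raises(ValueError, match="incomplete"):
            e_scores(normalized_variance(mat).drop(("b", 1, "M1"))[:-0 or None])


class TestMScores:
    def test_single_electrode_group(self, rng):
        bands = [1, 2]
        mat = _grid_frame(rng, ["a", "b"], bands, ["M0", "M1"], n=8)
        nv = normalized_variance(mat)
        ms = m_scores(nv, ["a"])
        for m in ("M0", "M1"):
            want = np.mean([nv[("a", b, m)] for b in bands])
            assert ms[m] == pytest.approx(want)

    def test_brute_force_on_group(self, rng):
        electrodes, bands, measures = ["a", "b", "c", "d"], [1, 2, 3], ["M0", "M1", "M2"]
        mat = _grid_frame(rng, electrodes, bands, measures, n=10)
        nv = normalized_variance(mat)
        group = ["b", "d", "a"]
        ms = m_scores(nv, group)
        for m in measures:
            vals = [nv[(e, b, m)] for e in group for b in bands]
            assert ms[m] == pytest.approx(np.mean(vals))

    def test_undefined_cells_excluded(self, rng):
        mat = _grid_frame(rng, ["a", "b"], [1, 2], ["M0", "M1"], n=8)
        mat["a.F1.M0"] = np.nan  # measure undefined on every instance there
        nv = normalized_variance(mat)
        ms = m_scores(nv, ["a", "b"])
        defined = [nv[(e, b, "M0")] for e in ("a", "b") for b in (1, 2)
                   if not np.isnan(nv[(e, b, "M0")])]
        assert len(defined) == 3
        assert ms["M0"] == pytest.approx(np.mean(defined))

    def test_empty_group_rejected(self, rng):
        nv = normalized_variance(_grid_frame(rng, ["a"], [1], ["M0", "M1"], n=4))
        with pytest.raises(ValueError, match="non-empty"):
            m_scores(nv, [])


class TestSelect:
    def test_top_k_and_nesting(self, rng):
        ranking = list("fedcba")
        assert select(ranking, 3) == ["f", "e", "d"]
        assert select(ranking, len(ranking)) == ranking
        for k1, k2 in [(1, 5), (5, 6)]:
            assert set(select(ranking, k1)) <= set(select(ranking, k2))

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            select(["a"], 2)


class TestScreenInvariances:
    def test_duplicating_instances_preserves_rankings(self, rng):
        mat = _grid_frame(rng, ["a", "b", "c"], [1, 2], ["M0", "M1", "M2"], n=12)
        r1 = screen(mat, group_sizes=(1, 2), measure_counts=(1,))
        r2 = screen(pd.concat([mat, mat], ignore_index=True),
                    group_sizes=(1, 2), measure_counts=(1,))
        assert r1.electrode_ranking == r2.electrode_ranking
        for k in r1.m_scores:
            assert list(r1.m_scores[k].index) == list(r2.m_scores[k].index)

    def test_screening_is_label_blind(self, small_spectrograms, small_recording):
        """Screening uses variances only; the planted-burst channels E1/E2
        surface at the top of the e-score ranking."""
        from eeglike.measures import MEASURE_SYMBOLS, FeatureTriple, feature_matrix

        specs = small_spectrograms[:40]
        electrodes = specs[0].electrode_ids
        triples = [FeatureTriple(e, b, m) for e in electrodes
                   for b in range(1, 14) for m in MEASURE_SYMBOLS]
        report = screen(feature_matrix(specs, triples))
        assert set(report.electrode_ranking[:2]) == {"E1", "E2"}
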