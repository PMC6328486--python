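"""Z-scoring, Spearman rho, exact permutation p-values and group correlation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from gliameta import (
    ConstantInputError,
    DatasetRecord,
    GeneModule,
    apply_exclusions,
    correlate_group,
    correlations_frame,
    score_all,
    significance_stars,
    spearman,
    zscore,
)
from gliameta.module_scores import ModuleScoreTable


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def oracle_rho(x, y):
    """Pearson correlation of mid-ranks, computed via scipy.pearsonr."""
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    return float(scipy.stats.pearsonr(rx, ry).statistic)

def oracle_exact_p(x, y):
    """Two-sided p by explicit enumeration of every permutation of y."""
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    obs = abs(oracle_rho(x, y))
    hits = total = 0
    for perm in itertools.permutations(ry):
        r = scipy.stats.pearsonr(rx, np.array(perm)).statistic
        hits += abs(r) >= obs - 1e-12
        total += 1
    return hits / total


class TestZscore:
    def test_forced_values(self):
        np.testing.assert_allclose(zscore(np.array([1.0, 2.0, 3.0])),
                                   [-1.0, 0.0, 1.0])

    def test_constant_vector_is_error(self):
        with pytest.raises(ConstantInputError):
            zscore(np.array([5.0, 5.0, 5.0]))

    def test_short_vector_is_error(self):
        with pytest.raises(ValueError):
            zscore(np.array([1.0]))

    def test_random_normals_standardized(self):
        rng = np.random.default_rng(0)
        z = zscore(rng.normal(3, 7, size=100))
        assert abs(z.mean()) < 1e-9
        assert abs(z.std(ddof=1) - 1.0) < 1e-9


class TestSpearmanRho:
    @pytest.mark.parametrize("y,expected", [
        ([10, 20, 30, 40], 1.0),
        ([4, 3, 2, 1], -1.0),
        ([2, 1, 4, 3], 0.6),   # 1 - 6*4/(4*15) by the d^2 formula
    ])
    def test_anchor_cases(self, y, expected):
        res = spearman([1, 2, 3, 4], y)
        assert res.rho == pytest.approx(expected, abs=1e-12)

    def test_exact_p_for_0p6_case(self):
        # 10 of the 24 rank permutations reach |rho| >= 0.6
        res = spearman([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.p == pytest.approx(10 / 24, abs=1e-12)
        assert res.method == "exact_permutation"

    def test_constant_input_is_error(self):
        with pytest.raises(ConstantInputError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [1, 2, 3, 4])

    def test_rho_matches_midrank_pearson_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(300):
            n = int(rng.integers(3, 30))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            if rng.random() < 0.3:  # inject ties
                x = np.round(x)
                y = np.round(y)
            try:
                res = spearman(x, y, exact_threshold=0)
            except ConstantInputError:
                continue
            assert res.rho == pytest.approx(oracle_rho(x, y), abs=1e-12)

    def test_exact_p_matches_enumeration_small_n(self):
        rng = np.random.default_rng(321)
        for _ in range(40):
            n = int(rng.integers(3, 8))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            if rng.random() < 0.4:
                y = np.round(y * 2) / 2  # force ties in y
            if np.unique(y).size < 2:
                continue
            res = spearman(x, y)
            assert res.method == "exact_permutation"
            assert res.p == pytest.approx(oracle_exact_p(x, y), abs=1e-12)

    def test_dp_exact_equals_enumeration_at_n8(self):
        """The subset-DP exact path (tie-free) agrees with full enumeration."""
        rng = np.random.default_rng(5)
        x = rng.permutation(8).astype(float)
        y = rng.permutation(8).astype(float)
        res = spearman(x, y, exact_threshold=8)
        assert res.p == pytest.approx(oracle_exact_p(x, y), abs=1e-12)

    def test_t_approximation_above_threshold(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=20), rng.normal(size=20)
        res = spearman(x, y)
        assert res.method == "t_approximation"
        # cross-check against scipy's Spearman t approximation
        ref = scipy.stats.spearmanr(x, y)
        assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    @given(st.integers(0, 10_000))
    @settings(max_examples=150, derandomize=True)
    def test_invariant_under_increasing_transforms(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        x, y = rng.normal(size=n), rng.normal(size=n)
        base = spearman(x, y)
        f = lambda v: np.exp(v) + 2.0
        g = lambda v: v ** 3 + 0.5 * v
        res = spearman(f(x), g(y))
        assert res.rho == pytest.approx(base.rho, abs=1e-12)
        assert res.p == pytest.approx(base.p, abs=1e-12)

    def test_zscore_step_is_correlation_neutral(self):
        """Z-scoring both vectors must change neither rho nor p."""
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = int(rng.integers(4, 15))
            x, y = rng.normal(size=n), rng.normal(size=n)
            base = spearman(x, y)
            res = spearman(zscore(x), zscore(y))
            assert res.rho == pytest.approx(base.rho, abs=1e-12)
            assert res.p == pytest.approx(base.p, abs=1e-12)


def _score_table(ids, columns, values, target="Oprm1"):
    frame = pd.DataFrame(values, index=ids, columns=columns)
    empty = pd.DataFrame()
    return ModuleScoreTable(target, frame, empty,
                            frame.drop(columns=[target]) * 0 + 1.0,
                            frame.drop(columns=[target]) < np.inf)


class TestApplyExclusions:
    def _table(self, n=12):
        rng = np.random.default_rng(1)
        ids = [f"D{i:02d}" for i in range(n)]
        vals = rng.normal(size=(n, 3))
        return _score_table(ids, ["Microglia", "Neuron", "Oprm1"], vals)

    def _records(self, ids, excluded=()):
        return [DatasetRecord(i, f"{i}.tsv", "rnaseq", "mouse", "brain",
                              "g", include_in_correlation=i not in excluded)
                for i in ids]

    def test_flagged_dataset_removed_and_logged(self):
        table = self._table(12)
        recs = self._records(table.dataset_scores.index, excluded={"D05"})
        zm = apply_exclusions(table, recs, group="g")
        assert len(zm.frame) == 11
        assert "D05" not in zm.frame.index
        assert [e["dataset_id"] for e in zm.exclusions] == ["D05"]

    def test_none_flagged_identity(self):
        table = self._table(6)
        zm = apply_exclusions(table, self._records(table.dataset_scores.index))
        assert len(zm.frame) == 6 and zm.exclusions == []

    def test_minimum_n_rule(self):
        table = self._table(3)
        recs = self._records(table.dataset_scores.index, excluded={"D00"})
        with pytest.raises(ValueError, match="at least 3"):
            apply_exclusions(table, recs)

    def test_retained_columns_standardized(self):
        table = self._table(10)
        zm = apply_exclusions(table, self._records(table.dataset_scores.index))
        for col in zm.frame.columns:
            v = zm.frame[col].to_numpy()
            assert abs(v.mean()) < 1e-9
            assert abs(v.std(ddof=1) - 1.0) < 1e-9

    def test_extreme_microglia_z_is_advisory_not_removal(self):
        table = self._table(10)
        table.dataset_scores.loc["D00", "Microglia"] = 40.0
        zm = apply_exclusions(table, self._records(table.dataset_scores.index))
        assert "D00" in zm.frame.index
        assert any(a["dataset_id"] == "D00" for a in zm.advisories)


class TestCorrelateGroup:
    def test_one_result_per_module(self):
        rng = np.random.default_rng(2)
        names = [f"M{i}" for i in range(11)]
        table = _score_table([f"D{i}" for i in range(8)], names + ["Oprm1"],
                             rng.normal(size=(8, 12)))
        zm = apply_exclusions(table, {})
        results = correlate_group(zm, "Oprm1")
        assert len(results) == 11
        assert {r.module for r in results} == set(names)

    def test_planted_monotone_link_gives_rho_one(self):
        vals = np.arange(6, dtype=float)
        table = _score_table([f"D{i}" for i in range(6)],
                             ["Microglia", "Oprm1"],
                             np.column_stack([vals * 2 + 1, vals ** 2]))
        zm = apply_exclusions(table, {})
        res = correlate_group(zm, "Oprm1")[0]
        assert res.rho == pytest.approx(1.0)

    def test_absent_target_column_is_error(self):
        table = _score_table(["a", "b", "c"], ["M", "Oprm1"],
                             np.random.default_rng(0).normal(size=(3, 2)))
        zm = apply_exclusions(table, {})
        with pytest.raises(ValueError, match="Nope"):
            correlate_group(zm, "Nope")

    def test_nan_rows_dropped_pairwise_with_n_logged(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(8, 2))
        table = _score_table([f"D{i}" for i in range(8)], ["M", "Oprm1"], vals)
        table.dataset_scores.loc["D3", "Oprm1"] = np.nan
        zm = apply_exclusions(table, {})
        res = correlate_group(zm, "Oprm1")[0]
        assert res.n == 7

    def test_stars_and_holm_column(self):
        stars = [significance_stars(p) for p in (0.2, 0.05, 0.01, 1e-3, 1e-5)]
        assert stars == ["", "*", "**", "***", "****"]
        rng = np.random.default_rng(4)
        table = _score_table([f"D{i}" for i in range(9)],
                             ["A", "B", "Oprm1"], rng.normal(size=(9, 3)))
        zm = apply_exclusions(table, {})
        frame = correlations_frame(correlate_group(zm, "Oprm1"))
        assert "p_holm_nonpaper" in frame.columns
        assert (frame["p_holm_nonpaper"] >= frame["p"] - 1e-15).all()
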