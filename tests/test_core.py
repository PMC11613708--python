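"""Unit and property tests for the scoring pipeline."""

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from epichaos import (
    BinaryMatrix,
    DegenerateRunWarning,
    EpichaosWarning,
    InputError,
    binarize,
    centered_jaccard_pair,
    compute_epichaos,
    per_chromosome_scores,
    raw_group_score,
)
from epichaos.core import adjust_scores, finalize_scores, subsample_groups


# ---------------------------------------------------------------------------
# binarize
# ---------------------------------------------------------------------------

class TestBinarize:
    def test_thresholds_positive_counts(self):
        m = binarize(np.array([[0, 3], [1, 0]]))
        assert m.dense().tolist() == [[0, 1], [1, 0]]

    def test_all_zero(self):
        m = binarize(np.zeros((3, 4)))
        assert m.dense().sum() == 0

    def test_idempotent_on_binary(self, rng):
        arr = (rng.random((10, 5)) < 0.5).astype(np.uint8)
        assert np.array_equal(binarize(arr).dense(), arr)

    def test_rejects_negative(self):
        with pytest.raises(InputError):
            binarize(np.array([[-1.0, 2.0]]))

    def test_rejects_nonfinite(self):
        with pytest.raises(InputError):
            binarize(np.array([[np.nan, 2.0]]))

    def test_sparse_input(self, rng):
        import scipy.sparse as sp

        counts = sp.random(30, 10, density=0.2, random_state=0, data_rvs=lambda k: np.full(k, 5.0))
        m = binarize(counts)
        assert np.array_equal(m.dense(), (counts.toarray() > 0).astype(np.uint8))


# ---------------------------------------------------------------------------
# centered Jaccard
# ---------------------------------------------------------------------------

class TestCenteredJaccardPair:
    def test_independence_level_overlap(self):
        ps = centered_jaccard_pair([1, 1, 0, 0], [1, 0, 1, 0])
        assert ps.observed == pytest.approx(1 / 3)
        assert ps.expected == pytest.approx(1 / 3)
        assert ps.centered == pytest.approx(0.0)

    def test_identical_vectors(self):
        ps = centered_jaccard_pair([1, 0, 1, 0], [1, 0, 1, 0])
        assert ps.observed == pytest.approx(1.0)
        assert ps.expected == pytest.approx(1 / 3)
        assert ps.centered == pytest.approx(2 / 3)

    def test_one_empty_vector(self):
        ps = centered_jaccard_pair([0, 0, 0, 0], [1, 0, 1, 0])
        assert (ps.observed, ps.expected, ps.centered) == (0.0, 0.0, 0.0)

    def test_both_empty_warns(self):
        with pytest.warns(EpichaosWarning):
            ps = centered_jaccard_pair([0, 0], [0, 0])
        assert ps.centered == 0.0

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            centered_jaccard_pair([1, 0], [1, 0, 1])

    def test_empty_length(self):
        with pytest.raises(InputError):
            centered_jaccard_pair([], [])

    @pytest.mark.parametrize("n,density", [(200, d) for d in (0.05, 0.3, 0.7)])
    def test_expectation_matches_permutation_oracle(self, n, density):
        # Monte-Carlo oracle: E should match the mean Jaccard over random
        # permutations of one vector (density-preserving null)
        rng = np.random.default_rng(n + int(1000 * density))
        x = (rng.random(n) < density).astype(np.uint8)
        y = (rng.random(n) < density).astype(np.uint8)
        ps = centered_jaccard_pair(x, y)
        sims = np.empty(10_000)
        s1, s2 = x.sum(), y.sum()
        for t in range(10_000):
            yp = y[rng.permutation(n)]
            a = int((x & yp).sum())
            sims[t] = a / (s1 + s2 - a) if s1 + s2 else 0.0
        assert abs(ps.expected - sims.mean()) < 0.01
        assert abs(ps.centered - (ps.observed - sims.mean())) < 0.01

    @given(
        x=arrays(np.uint8, 30, elements=st.integers(0, 1)),
        y=arrays(np.uint8, 30, elements=st.integers(0, 1)),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounds_and_symmetry(self, x, y):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = centered_jaccard_pair(x, y)
            b = centered_jaccard_pair(y, x)
        assert 0.0 <= a.observed <= 1.0
        assert 0.0 <= a.expected <= 1.0
        assert -1.0 < a.centered <= 1.0
        assert a.centered == pytest.approx(b.centered)
        assert a.centered == pytest.approx(a.observed - a.expected)


# ---------------------------------------------------------------------------
# raw group score
# ---------------------------------------------------------------------------

class TestRawGroupScore:
    def test_identical_cells_share_pair_value(self):
        col = np.array([1, 0, 1, 1, 0], dtype=np.uint8)
        m = BinaryMatrix.from_dense(np.tile(col[:, None], 3))
        raw, _ = raw_group_score(m, list(m.cell_ids))
        pair = centered_jaccard_pair(col, col)
        assert raw == pytest.approx(pair.centered)

    def test_matches_bruteforce_enumeration(self, toy_matrix):
        cells = list(toy_matrix.cell_ids)
        raw, mean_count = raw_group_score(toy_matrix, cells)
        dense = toy_matrix.dense()
        vals = [
            centered_jaccard_pair(dense[:, i], dense[:, j]).centered
            for i, j in combinations(range(len(cells)), 2)
        ]
        assert raw == pytest.approx(np.mean(vals), abs=1e-12)
        assert mean_count == pytest.approx(dense.sum(axis=0).mean())

    def test_duplicated_group_keeps_mean_count(self, rng):
        arr = (rng.random((20, 4)) < 0.5).astype(np.uint8)
        doubled = np.hstack([arr, arr])
        m1 = BinaryMatrix.from_dense(arr)
        m2 = BinaryMatrix.from_dense(doubled)
        _, mc1 = raw_group_score(m1, list(m1.cell_ids))
        _, mc2 = raw_group_score(m2, list(m2.cell_ids))
        assert mc1 == pytest.approx(mc2)

    def test_rejects_single_cell(self, toy_matrix):
        with pytest.raises(InputError):
            raw_group_score(toy_matrix, [toy_matrix.cell_ids[0]])


# ---------------------------------------------------------------------------
# adjustment
# ---------------------------------------------------------------------------

class TestAdjustScores:
    def test_two_records_fall_back_to_centering(self):
        adj, fallback = adjust_scores([0.1, 0.5], [10.0, 20.0])
        assert fallback
        np.testing.assert_allclose(adj, [-0.2, 0.2])

    def test_perfectly_linear_gives_zero_residuals(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        raw = 0.3 + 0.05 * x
        adj, fallback = adjust_scores(raw, x)
        assert not fallback
        np.testing.assert_allclose(adj, 0.0, atol=1e-12)

    def test_matches_normal_equations(self, rng):
        x = rng.random(5) * 100
        raw = rng.random(5)
        adj, fallback = adjust_scores(raw, x)
        assert not fallback
        # closed-form OLS oracle via the normal equations
        X = np.column_stack([np.ones(5), x])
        beta = np.linalg.solve(X.T @ X, X.T @ raw)
        np.testing.assert_allclose(adj, raw - X @ beta, atol=1e-10)

    def test_constant_covariate_falls_back(self):
        adj, fallback = adjust_scores([0.1, 0.2, 0.6], [5.0, 5.0, 5.0])
        assert fallback
        np.testing.assert_allclose(adj, [-0.2, -0.1, 0.3])

    def test_empty_errors(self):
        with pytest.raises(InputError):
            adjust_scores([], [])


class TestFinalizeScores:
    def test_arithmetic(self):
        np.testing.assert_allclose(
            finalize_scores([-0.2, 0.0, 0.3]), [1.0, 0.6, 0.0]
        )

    def test_single_value_degenerates(self):
        with pytest.warns(DegenerateRunWarning):
            out = finalize_scores([0.7])
        assert out.tolist() == [0.5]

    @given(st.lists(st.floats(-10, 10), min_size=2, max_size=20, unique=True))
    @settings(max_examples=100, deadline=None)
    def test_order_reversal_and_bounds(self, adjusted):
        final = finalize_scores(adjusted)
        assert np.all((final >= 0) & (final <= 1))
        assert final.min() == 0.0 and final.max() == 1.0
        # the ordering of final reverses the ordering of adjusted (ties in
        # final may appear when scaling collapses values at float precision)
        order = np.argsort(np.asarray(adjusted))
        assert np.all(np.diff(final[order]) <= 0)


# ---------------------------------------------------------------------------
# subsampling
# ---------------------------------------------------------------------------

class TestSubsampleGroups:
    def _grouping(self, n, label="g"):
        return {f"{label}{i}": label for i in range(n)}

    def test_large_group_yields_replicates(self):
        reps = subsample_groups(self._grouping(250), n_subsamples=5, size=100, seed=1)
        assert len(reps) == 5
        for r in reps:
            assert len(r.cell_ids) == 100
            assert len(set(r.cell_ids)) == 100  # without replacement

    def test_small_group_scored_once_on_all_cells(self):
        reps = subsample_groups(self._grouping(40), n_subsamples=5, size=100, seed=1)
        assert len(reps) == 1
        assert len(reps[0].cell_ids) == 40

    def test_deterministic_given_seed(self):
        g = {**self._grouping(150, "a"), **self._grouping(120, "b")}
        assert subsample_groups(g, seed=7) == subsample_groups(g, seed=7)
        assert subsample_groups(g, seed=7) != subsample_groups(g, seed=8)

    def test_rejects_tiny_size(self):
        with pytest.raises(InputError):
            subsample_groups(self._grouping(10), size=1)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

class TestComputeEpichaos:
    def test_row_raw_matches_independent_recomputation(self, toy_matrix, toy_grouping):
        df = compute_epichaos(toy_matrix, toy_grouping, subsample=False)
        for _, row in df.iterrows():
            cells = [c for c, g in toy_grouping.items() if g == row["group"]]
            raw, _ = raw_group_score(toy_matrix, cells)
            assert row["raw"] == pytest.approx(raw, abs=1e-12)

    def test_exchangeable_groups_score_alike(self, rng):
        arr = (rng.random((300, 90)) < 0.3).astype(np.uint8)
        m = BinaryMatrix.from_dense(arr)
        grouping = {c: f"g{i % 3}" for i, c in enumerate(m.cell_ids)}
        df = compute_epichaos(m, grouping, subsample=False)
        # identical composition: raw scores within noise of each other
        assert df["raw"].std() < 0.01

    def test_skips_singleton_group_with_warning(self, toy_matrix):
        grouping = {c: "big" for c in toy_matrix.cell_ids[:-1]}
        grouping[toy_matrix.cell_ids[-1]] = "lonely"
        with pytest.warns(EpichaosWarning, match="fewer than 2 cells"):
            df = compute_epichaos(toy_matrix, grouping, subsample=False)
        row = df.set_index("group").loc["lonely"]
        assert row["flags"] == "skipped_too_small"
        assert np.isnan(row["epichaos"])

    def test_errors_without_scorable_group(self, toy_matrix):
        grouping = {toy_matrix.cell_ids[0]: "a", toy_matrix.cell_ids[1]: "b"}
        with pytest.raises(InputError), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            compute_epichaos(toy_matrix, grouping, subsample=False)

    def test_unknown_cell_rejected(self, toy_matrix):
        with pytest.raises(InputError, match="not present"):
            compute_epichaos(toy_matrix, {"nope": "g"}, subsample=False)

    def test_deterministic_given_seed(self, rng):
        arr = (rng.random((100, 260)) < 0.3).astype(np.uint8)
        m = BinaryMatrix.from_dense(arr)
        grouping = {c: f"g{i % 2}" for i, c in enumerate(m.cell_ids)}
        a = compute_epichaos(m, grouping, subsample=True, size=50, seed=3)
        b = compute_epichaos(m, grouping, subsample=True, size=50, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_exactly_one_zero_and_one_one(self, toy_matrix, toy_grouping):
        df = compute_epichaos(toy_matrix, toy_grouping, subsample=False)
        finals = df["epichaos"].dropna()
        assert (finals == 1.0).sum() >= 1
        assert (finals == 0.0).sum() >= 1


class TestPerChromosomeScores:
    def test_single_chromosome_collapses_to_global(self, toy_matrix, toy_grouping):
        features = pd.DataFrame(
            {
                "chrom": ["chr1"] * 50,
                "start": np.arange(50) * 1000,
                "end": np.arange(50) * 1000 + 500,
            }
        )
        per = per_chromosome_scores(
            toy_matrix, features, toy_grouping, min_features=20, subsample=False
        )
        glob = compute_epichaos(toy_matrix, toy_grouping, subsample=False)
        for col in ("raw", "adjusted", "epichaos", "mean_count"):
            np.testing.assert_allclose(per[col], glob[col], atol=1e-12)

    def test_two_chromosome_residuals_match_hand_ols(self, rng):
        arr = (rng.random((60, 30)) < 0.4).astype(np.uint8)
        m = BinaryMatrix.from_dense(arr)
        chrom = np.repeat(["chrA", "chrB"], 30)
        features = pd.DataFrame(
            {"chrom": chrom, "start": np.arange(60), "end": np.arange(60) + 1}
        )
        grouping = {c: f"g{i % 3}" for i, c in enumerate(m.cell_ids)}
        per = per_chromosome_scores(
            m, features, grouping, min_features=10, subsample=False
        )
        # oracle: per-stratum OLS residuals averaged by hand
        expected = {}
        for g in ("g0", "g1", "g2"):
            expected[g] = []
        for chrom_name, sl in (("chrA", slice(0, 30)), ("chrB", slice(30, 60))):
            sub = BinaryMatrix.from_dense(arr[sl], cell_ids=list(m.cell_ids))
            obs = {
                g: raw_group_score(sub, sorted(c for c, gg in grouping.items() if gg == g))
                for g in ("g0", "g1", "g2")
            }
            x = np.array([obs[g][1] for g in ("g0", "g1", "g2")])
            y = np.array([obs[g][0] for g in ("g0", "g1", "g2")])
            X = np.column_stack([np.ones(3), x])
            resid = y - X @ np.linalg.solve(X.T @ X, X.T @ y)
            for g, r in zip(("g0", "g1", "g2"), resid):
                expected[g].append(r)
        got = per.set_index("group")["adjusted"]
        for g in ("g0", "g1", "g2"):
            assert got[g] == pytest.approx(np.mean(expected[g]), abs=1e-10)

    def test_errors_without_qualifying_chromosome(self, toy_matrix, toy_features, toy_grouping):
        with pytest.raises(InputError, match="no chromosome"):
            per_chromosome_scores(
                toy_matrix, toy_features, toy_grouping, min_features=1000
            )
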