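"""Dynamics metrics: occupancy, dwell, transitions, contrasts, NBS."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from brainstates.dynamics import (
    dwell_times,
    empirical_transitions,
    fractional_occupancy,
    nbs_transition_contrast,
    paired_state_contrast,
    summarize_dynamics,
    threshold_transitions,
    visit_lengths,
)


class TestFractionalOccupancy:
    @pytest.mark.parametrize(
        "path,K,expected",
        [
            ([1, 1, 2, 2], 2, [0.5, 0.5]),
            ([1, 1, 1, 2], 3, [0.75, 0.25, 0.0]),
            ([2, 2, 2], 3, [0.0, 1.0, 0.0]),
        ],
    )
    def test_direct_counts(self, path, K, expected):
        assert fractional_occupancy(np.array(path), K) == pytest.approx(
            expected
        )

    def test_sums_to_one_and_conserves_time(self):
        rng = np.random.default_rng(0)
        path = rng.integers(1, 5, size=97)
        fo = fractional_occupancy(path, 4)
        assert fo.sum() == pytest.approx(1.0, abs=1e-10)
        visits = visit_lengths(path, 4)
        for k in range(4):
            assert sum(visits[k]) == pytest.approx(fo[k] * path.size)

    def test_out_of_range_state_rejected(self):
        with pytest.raises(ValueError):
            fractional_occupancy(np.array([1, 5]), 4)


class TestDwellTimes:
    def test_constant_path_single_visit(self):
        visits, mean_s = dwell_times(np.ones(10, dtype=int), 2.2, 2)
        assert visits[0] == [10]
        assert mean_s[0] == pytest.approx(22.0)
        assert np.isnan(mean_s[1])

    def test_run_length_arithmetic(self):
        visits, mean_s = dwell_times(
            np.array([1, 1, 2, 1, 1, 1]), 2.2, 2
        )
        assert sorted(visits[0]) == [2, 3]
        assert mean_s[0] == pytest.approx(5.5)
        assert mean_s[1] == pytest.approx(2.2)


class TestEmpiricalTransitions:
    def test_pure_alternation(self):
        P = empirical_transitions(np.array([1, 2, 1, 2, 1]), 2)
        assert P == pytest.approx(np.array([[0, 1], [1, 0]]))

    def test_count_and_normalize(self):
        P = empirical_transitions(np.array([1, 1, 2, 2]), 2)
        assert P[0] == pytest.approx([0.5, 0.5])
        assert P[1] == pytest.approx([0.0, 1.0])

    def test_unvisited_row_masked(self):
        P = empirical_transitions(np.array([1, 1, 1]), 3)
        assert np.isnan(P[1]).all() and np.isnan(P[2]).all()
        assert P[0] == pytest.approx([1.0, 0.0, 0.0])

    def test_long_chain_matches_generator(self):
        rng = np.random.default_rng(1)
        A = np.array([[0.8, 0.15, 0.05],
                      [0.2, 0.7, 0.1],
                      [0.1, 0.1, 0.8]])
        path = [0]
        for _ in range(30000):
            path.append(rng.choice(3, p=A[path[-1]]))
        P = empirical_transitions(np.array(path) + 1, 3)
        assert np.abs(P - A).max() < 0.02


class TestThresholdTransitions:
    def test_twenty_percent_of_90_edges(self):
        rng = np.random.default_rng(2)
        M = rng.random((10, 10))
        np.fill_diagonal(M, 0.99)   # diagonal must be ignored
        edges = threshold_transitions(M)
        assert len(edges) == 18
        assert all(i != j for i, j in edges)

    def test_all_equal_weights_all_retained(self):
        M = np.full((4, 4), 0.25)
        assert len(threshold_transitions(M)) == 12

    def test_dominant_edge_always_kept(self):
        M = np.full((5, 5), 0.01)
        M[2, 4] = 0.9
        assert (3, 5) in threshold_transitions(M)


class TestPairedStateContrast:
    @staticmethod
    def _table(n, K, shift_state=None, shift=0.0, noise=0.01, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n):
            for cond in ("rest", "movie"):
                base = rng.normal(0.5, noise, size=K)
                if cond == "movie" and shift_state is not None:
                    base[shift_state - 1] += shift
                for k in range(K):
                    rows.append(dict(subject=f"s{s}", session="A",
                                     condition=cond, state=k + 1,
                                     fo=base[k]))
        return pd.DataFrame(rows)

    def test_identical_conditions_not_significant(self):
        rng = np.random.default_rng(3)
        rows = []
        for s in range(6):
            vals = rng.normal(size=3)
            for cond in ("rest", "movie"):
                for k in range(3):
                    rows.append(dict(subject=f"s{s}", session="A",
                                     condition=cond, state=k + 1,
                                     fo=vals[k]))
        res = paired_state_contrast(pd.DataFrame(rows))
        assert (res["t"] == 0).all()
        assert not res["significant"].any()

    def test_planted_shift_detected(self):
        res = paired_state_contrast(
            self._table(14, 10, shift_state=3, shift=0.1)
        )
        assert res.loc[res.state == 3, "significant"].item()
        assert res.loc[res.state == 3, "t"].item() > 0

    def test_bonferroni_threshold_over_states(self):
        # K=10: borderline p just above 0.005 must not be flagged
        res = paired_state_contrast(
            self._table(14, 10, shift_state=2, shift=0.1)
        )
        for _, row in res.iterrows():
            assert row.significant == (row.p < 0.05 / 10)


class TestNbs:
    @staticmethod
    def _paired_stack(n, K, seed, planted=None, delta=0.0):
        rng = np.random.default_rng(seed)
        A = rng.normal(0.3, 0.05, size=(n, K, K))
        B = rng.normal(0.3, 0.05, size=(n, K, K))
        if planted:
            for (i, j) in planted:
                B[:, i, j] += delta
        for M in (A, B):
            M[:, np.arange(K), np.arange(K)] = np.nan
        return A, B

    def test_exhaustive_matches_signflip_enumeration(self):
        """n=6 permutation p equals the full 2^6 sign-flip null."""
        n, K = 6, 4
        A, B = self._paired_stack(n, K, seed=4,
                                  planted=[(0, 1), (1, 2), (2, 3)],
                                  delta=0.3)
        res = nbs_transition_contrast(B, A, primary_t=2.0, n_perm=5000,
                                      seed=0)
        assert res.exhaustive and res.n_perm == 64

        # independent oracle: enumerate sign flips and max component sizes
        off = np.where(~np.eye(K, dtype=bool))
        diffs = (B - A)[:, off[0], off[1]]

        def max_comp(d):
            tt = stats.ttest_1samp(d, 0.0, axis=0).statistic
            edges = [(off[0][e], off[1][e]) for e in np.flatnonzero(
                tt > 2.0)]
            # union-find over undirected components
            parent = list(range(K))

            def find(x):
                while parent[x] != x:
                    x = parent[x]
                return x

            for i, j in edges:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
            sizes = {}
            for i, j in edges:
                sizes[find(i)] = sizes.get(find(i), 0) + 1
            return max(sizes.values(), default=0)

        null = [
            max_comp(diffs * np.array(s)[:, None])
            for s in itertools.product([1.0, -1.0], repeat=n)
        ]
        obs = max_comp(diffs)
        expected_p = float(np.mean(np.array(null) >= obs))
        top = res.components_a_gt_b[0]
        assert top.size == obs
        assert top.p_fwe == pytest.approx(expected_p, abs=1e-12)

    def test_planted_component_detected(self):
        n, K = 14, 5
        detected = 0
        for rep in range(10):
            A, B = self._paired_stack(
                n, K, seed=100 + rep,
                planted=[(0, 1), (1, 2), (2, 0)], delta=0.12,
            )
            res = nbs_transition_contrast(B, A, primary_t=2.5, n_perm=500,
                                          seed=rep)
            sig = [c for c in res.components_a_gt_b
                   if c.p_fwe < 0.05 and c.size >= 3]
            detected += bool(sig)
        assert detected >= 8

    def test_small_n_perm_rejected(self):
        A, B = self._paired_stack(5, 3, seed=5)
        with pytest.raises(ValueError):
            nbs_transition_contrast(A, B, primary_t=2.0, n_perm=50)


class TestSummarize:
    def test_table_consistent_with_primitives(self):
        rng = np.random.default_rng(6)
        paths = {
            ("s1", "A", "rest"): rng.integers(1, 4, size=50),
            ("s1", "A", "movie"): rng.integers(1, 4, size=70),
        }
        df = summarize_dynamics(paths, 2.2, 3)
        for (sub, ses, cond), path in paths.items():
            sel = df[(df.subject == sub) & (df.condition == cond)]
            assert sel["fo"].to_numpy() == pytest.approx(
                fractional_occupancy(path, 3)
            )
            assert sel["fo"].sum() == pytest.approx(1.0)
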