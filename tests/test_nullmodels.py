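import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from assemblage.nullmodels import (
    DegenerateScoreError,
    FrozenMatrixError,
    bonferroni_threshold,
    cc_score,
    cc_score_bruteforce,
    it_fill_sequential,
    it_null,
    ma_score,
    null_test,
    sim9_null,
)
from assemblage.table import CommunityTable, PresenceAbsenceMatrix, to_proportions
from conftest import random_binary_matrix, random_counts_table


def pa_from(values):
    values = np.asarray(values)
    return PresenceAbsenceMatrix(
        [f"t{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
        values,
    )


def counts_table(values):
    values = np.asarray(values)
    return CommunityTable(
        pd.DataFrame(
            values,
            index=[f"t{i}" for i in range(values.shape[0])],
            columns=[f"s{j}" for j in range(values.shape[1])],
        ),
        mode="counts",
    )


class TestCCScore:
    def test_identical_presence_rows_give_one(self):
        assert cc_score(pa_from([[1, 1, 0], [1, 1, 0]])) == pytest.approx(1.0)

    def test_perfect_checkerboard_gives_minus_three(self):
        assert cc_score(pa_from([[1, 0], [0, 1]])) == pytest.approx(-3.0)

    def test_matches_bruteforce_pairwise_loop(self, rng):
        for _ in range(20):
            pa = random_binary_matrix(rng, n_taxa=8, n_samples=6)
            try:
                expected = cc_score_bruteforce(pa)
            except DegenerateScoreError:
                continue
            assert cc_score(pa) == pytest.approx(expected, abs=1e-12)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_invariant_to_row_and_column_permutations(self, seed):
        rng = np.random.default_rng(seed)
        pa = random_binary_matrix(rng, n_taxa=6, n_samples=5)
        try:
            base = cc_score(pa)
        except DegenerateScoreError:
            return
        rp = rng.permutation(6)
        cp = rng.permutation(5)
        shuffled = pa_from(pa.values[np.ix_(rp, cp)])
        assert cc_score(shuffled) == pytest.approx(base, abs=1e-12)

    def test_degenerate_all_full_matrix_rejected(self):
        with pytest.raises(DegenerateScoreError):
            cc_score(pa_from([[1, 1], [1, 1]]))


class TestMAScore:
    def test_identical_samples_give_one(self):
        t, _ = to_proportions(counts_table([[4, 2], [4, 2], [8, 4]]))
        assert ma_score(t) == pytest.approx(1.0)

    def test_perfect_segregation_gives_zero(self):
        t, _ = to_proportions(counts_table([[5, 0], [0, 3]]))
        assert ma_score(t) == pytest.approx(0.0)

    def test_two_sample_hand_value(self):
        t = CommunityTable(
            pd.DataFrame({"s1": [0.8, 0.2], "s2": [0.2, 0.8]},
                         index=["a", "b"]),
            mode="proportions",
        )
        assert ma_score(t) == pytest.approx(0.32 * 2 / 1.36, abs=1e-12)
        assert ma_score(t) == pytest.approx(0.470588, abs=1e-6)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_bounded_and_one_iff_proportional_columns(self, seed):
        rng = np.random.default_rng(seed)
        t, _ = to_proportions(random_counts_table(rng, n_taxa=5, n_samples=4))
        score = ma_score(t)
        assert -1e-12 <= score <= 1 + 1e-12
        P = t.values
        proportional = np.allclose(P, P.mean(axis=1, keepdims=True), atol=1e-12)
        if proportional:
            assert score == pytest.approx(1.0, abs=1e-9)
        if score > 1 - 1e-9:
            assert proportional

    def test_counts_mode_rejected(self):
        with pytest.raises(ValueError, match="proportions"):
            ma_score(counts_table([[1, 2], [3, 4]]))


class TestSim9Null:
    def test_marginals_preserved_exactly(self, rng):
        pa = random_binary_matrix(rng, n_taxa=10, n_samples=7)
        for m in sim9_null(pa, n_null=20, seed=4):
            assert (m.occupancy == pa.occupancy).all()
            assert (m.richness == pa.richness).all()

    def test_checkerboard_alternates_between_the_two_states(self):
        pa = pa_from([[1, 0], [0, 1]])
        states = {
            tuple(m.values.ravel())
            for m in sim9_null(pa, n_null=50, burn_in=1, thin=1, seed=0)
        }
        assert states == {(1, 0, 0, 1), (0, 1, 1, 0)}

    def test_frozen_matrix_detected(self):
        with pytest.raises(FrozenMatrixError):
            list(sim9_null(pa_from([[1, 1], [1, 0]]), n_null=1, seed=0))

    def test_chain_moves_between_emissions(self, rng):
        pa = random_binary_matrix(rng, n_taxa=10, n_samples=7)
        mats = [m.values.copy() for m in sim9_null(pa, n_null=10, seed=1)]
        distinct = {tuple(m.ravel()) for m in mats}
        assert len(distinct) > 1


def sequential_it_distribution(row_totals, col_totals):
    """Exact table distribution of the literal one-read-at-a-time
    remaining-quota placement, by recursion over placement paths."""
    from functools import lru_cache

    M, N = len(row_totals), len(col_totals)

    @lru_cache(maxsize=None)
    def rec(r, c):
        # returns dict: table (flat tuple) -> probability
        r = tuple(r)
        c = tuple(c)
        if sum(r) == 0:
            return {tuple([0] * (M * N)): 1.0}
        out: dict = {}
        rs, cs = sum(r), sum(c)
        for i in range(M):
            if r[i] == 0:
                continue
            for j in range(N):
                if c[j] == 0:
                    continue
                pr = (r[i] / rs) * (c[j] / cs)
                r2 = list(r)
                r2[i] -= 1
                c2 = list(c)
                c2[j] -= 1
                for tab, q in rec(tuple(r2), tuple(c2)).items():
                    tab2 = list(tab)
                    tab2[i * N + j] += 1
                    key = tuple(tab2)
                    out[key] = out.get(key, 0.0) + pr * q
        return out

    return rec(tuple(row_totals), tuple(col_totals))


class TestITNull:
    def test_marginals_preserved_exactly(self, rng):
        t = random_counts_table(rng, n_taxa=6, n_samples=4)
        R, C = t.values.sum(axis=1), t.values.sum(axis=0)
        for m in it_null(t, n_null=20, seed=9):
            assert (m.values.sum(axis=1) == R).all()
            assert (m.values.sum(axis=0) == C).all()

    def test_single_taxon_table_is_fixed(self):
        t = counts_table([[3, 5, 2]])
        for m in it_null(t, n_null=5, seed=0):
            assert (m.values == t.values).all()

    def test_matches_sequential_scheme_enumeration(self):
        # 2x2 with margins (2,2)/(2,2): 3 feasible tables
        t = counts_table([[2, 0], [0, 2]])
        exact = sequential_it_distribution((2, 2), (2, 2))
        n_draw = 30000
        counts: dict = {}
        for m in it_null(t, n_null=n_draw, seed=42):
            key = tuple(m.values.ravel().tolist())
            counts[key] = counts.get(key, 0) + 1
        assert set(counts) == set(k for k, p in exact.items() if p > 0)
        for key, p in exact.items():
            freq = counts.get(key, 0) / n_draw
            se = np.sqrt(p * (1 - p) / n_draw)
            assert abs(freq - p) < 4 * se

    def test_sequential_reference_agrees_with_token_shuffle(self, rng):
        # same margins, two independent route implementations
        t = counts_table([[1, 2], [2, 0]])
        exact = sequential_it_distribution((3, 2), (3, 2))
        draws: dict = {}
        n_draw = 4000
        for k in range(n_draw):
            tab = it_fill_sequential(t.values.astype(np.int64),
                                     np.random.default_rng(k))
            key = tuple(tab.ravel().tolist())
            draws[key] = draws.get(key, 0) + 1
        for key, p in exact.items():
            if p < 1e-6:
                continue
            freq = draws.get(key, 0) / n_draw
            se = np.sqrt(p * (1 - p) / n_draw)
            assert abs(freq - p) < 4 * se

    def test_non_integer_counts_rejected(self):
        t = CommunityTable(
            pd.DataFrame({"s1": [1.5], "s2": [1.0]}, index=["a"]),
            mode="counts",
        )
        with pytest.raises(ValueError, match="integer"):
            list(it_null(t, n_null=1, seed=0))


class TestNullTest:
    def test_extreme_low_tail(self, rng):
        # strongly segregated binary data: observed below every null score
        pa = pa_from(np.kron(np.eye(4, dtype=int), np.ones((3, 1), dtype=int)))
        res = null_test("cc", pa, "sim9", n_null=99, seed=0)
        if (res.null_scores > res.observed).all():
            assert res.p_low == pytest.approx(1 / 100)
        assert 0 < res.p_low <= 1
        assert res.p_low + res.p_high >= 1

    def test_ma_it_combination_runs_and_is_reproducible(self, rng):
        t = random_counts_table(rng, n_taxa=10, n_samples=5, max_count=30)
        r1 = null_test("ma", t, "it", n_null=49, seed=5)
        r2 = null_test("ma", t, "it", n_null=49, seed=5)
        assert r1.observed == r2.observed
        assert (r1.null_scores == r2.null_scores).all()

    def test_incompatible_combination_rejected(self, rng):
        t = random_counts_table(rng)
        with pytest.raises(ValueError):
            null_test("cc", t, "it", n_null=9, seed=0)


class TestBonferroni:
    @pytest.mark.parametrize(
        "n,printed",
        [(21, 0.0024), (7, 0.0071), (441, 0.00011)],
    )
    def test_printed_values(self, n, printed):
        value = bonferroni_threshold(0.05, n)
        ndigits = len(str(printed).split(".")[1])
        assert round(value, ndigits) == printed

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 3)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
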