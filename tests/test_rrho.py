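"""Hypergeometric tails, quadrant scores, and RRHO grids.

The tail implementation is checked against two independent oracles: an
exact integer-arithmetic tail sum (combinatorics in Python big ints) and
scipy.stats.hypergeom.
"""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import sigmatch as sm
from sigmatch.exceptions import ContractError, InvalidInputError, NoOverlapError
from sigmatch.rrho import load_rrho, write_rrho


def exact_tail_neglog(k, s1, s2, N):
    """Exact -log10 P(X >= k) via integer tail sums (independent oracle)."""
    if k <= max(0, s1 + s2 - N):
        return 0.0
    num = sum(math.comb(s1, i) * math.comb(N - s1, s2 - i) for i in range(k, min(s1, s2) + 1))
    return -math.log10(num / math.comb(N, s2))


class TestHypergeomTail:
    @pytest.mark.parametrize(
        "k,s1,s2,N,expected",
        [
            (2, 2, 2, 10, -math.log10(1 / 45)),       # C(2,2)C(8,0)/C(10,2)
            (0, 10, 10, 100, 0.0),
            (3, 10, 10, 100, 1.221714271),            # 1 - P0 - P1 - P2 ~ 0.0600
            (10, 10, 10, 100, math.log10(math.comb(100, 10))),
        ],
    )
    def test_spot_values(self, k, s1, s2, N, expected):
        assert sm.hypergeom_tail_neglog(k, s1, s2, N) == pytest.approx(expected, rel=1e-9)

    def test_matches_exact_oracle_on_sampled_grid(self, rng):
        for _ in range(300):
            N = int(rng.integers(1, 61))
            s1 = int(rng.integers(0, N + 1))
            s2 = int(rng.integers(0, N + 1))
            k = int(rng.integers(0, min(s1, s2) + 1))
            got = sm.hypergeom_tail_neglog(k, s1, s2, N)
            want = exact_tail_neglog(k, s1, s2, N)
            assert got == pytest.approx(want, rel=1e-9, abs=1e-12), (k, s1, s2, N)

    def test_matches_scipy_cross_check(self):
        # scipy's hypergeometric survival function as a second, library oracle
        for (k, s1, s2, N) in [(5, 50, 80, 500), (40, 100, 120, 1000), (3, 10, 10, 100)]:
            want = -np.log10(stats.hypergeom.sf(k - 1, N, s1, s2))
            assert sm.hypergeom_tail_neglog(k, s1, s2, N) == pytest.approx(want, rel=1e-6)

    def test_precision_near_p_equal_one(self):
        # P(X >= 1) for two half-universe lists: the tail is 1 - 1/C(100,50),
        # so -log10 p ~ 1e-30 — naive summation returns exactly 0 here.
        got = sm.hypergeom_tail_neglog(1, 50, 50, 100)
        want = 1.0 / (math.comb(100, 50) * math.log(10))  # first-order series, exact to ~1e-29
        assert got == pytest.approx(want, rel=1e-9)
        assert 0 < got < 1e-25

    @pytest.mark.parametrize(
        "k,s1,s2,N", [(3, 2, 5, 10), (1, 11, 5, 10), (1, 5, 11, 10), (-1, 2, 2, 10)]
    )
    def test_invalid_inputs_rejected(self, k, s1, s2, N):
        with pytest.raises(InvalidInputError):
            sm.hypergeom_tail_neglog(k, s1, s2, N)

    @given(
        st.integers(min_value=2, max_value=50).flatmap(
            lambda N: st.tuples(
                st.just(N),
                st.integers(min_value=1, max_value=N),
                st.integers(min_value=1, max_value=N),
            )
        )
    )
    def test_monotone_nondecreasing_in_k(self, args):
        N, s1, s2 = args
        vals = [sm.hypergeom_tail_neglog(k, s1, s2, N) for k in range(min(s1, s2) + 1)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
        assert vals[0] == 0.0


class TestQuadrantScore:
    def test_self_match_balanced(self, balanced_pair):
        a, _ = balanced_pair
        rs_a, rs_a2 = sm.top_ranked_sets(a, a, n_top=10)
        q = sm.quadrant_score(rs_a, rs_a2)
        expected = math.log10(math.comb(100, 10))
        assert q.A == pytest.approx(expected, rel=1e-9)
        assert q.D == pytest.approx(expected, rel=1e-9)
        assert q.B == 0.0 and q.C == 0.0
        assert q.score == pytest.approx(2 * expected, rel=1e-9)
        assert (q.kA, q.kB, q.kC, q.kD) == (10, 0, 0, 10)

    def test_sign_flip_antisymmetry(self, balanced_pair):
        a, b = balanced_pair
        rs_a, rs_b = sm.top_ranked_sets(a, b, n_top=10)
        q_ab = sm.quadrant_score(rs_a, rs_b)
        rs_a2, rs_bf = sm.top_ranked_sets(a, b.flipped(), n_top=10)
        q_flip = sm.quadrant_score(rs_a2, rs_bf)
        assert q_flip.score == pytest.approx(-q_ab.score, abs=1e-12)
        assert (q_flip.A, q_flip.D) == (q_ab.B, q_ab.C)

    def test_score_identity_holds(self, toy_pair):
        rs_a, rs_b = sm.top_ranked_sets(*toy_pair, n_top=5)
        q = sm.quadrant_score(rs_a, rs_b)
        assert q.score == q.A + q.D - q.B - q.C

    def test_independent_sets_score_near_zero(self, rng):
        from conftest import make_balanced_signature

        genes = [f"G{i:05d}" for i in range(10000)]
        a = make_balanced_signature("a", 10000, 10, 10, rng, genes)
        b = make_balanced_signature("b", 10000, 10, 10, rng, genes)
        rs_a, rs_b = sm.top_ranked_sets(a, b, n_top=10)
        q = sm.quadrant_score(rs_a, rs_b)
        # expected overlap per quadrant is 0.01; evidence should be negligible
        assert abs(q.score) < 3.0

    def test_mismatched_universes_rejected(self):
        rs1 = sm.RankedSets(frozenset({"G1", "G2"}), ("G1",), (), 1)
        rs2 = sm.RankedSets(frozenset({"G1", "G3"}), ("G1",), (), 1)
        with pytest.raises(ContractError):
            sm.quadrant_score(rs1, rs2)

    def test_moving_gene_to_concordant_quadrant_never_lowers_score(self):
        # one gene moved from the discordant up/down cell into up/up
        genes = {f"G{i:03d}": 0.0 for i in range(100)}
        base = dict(genes)
        for i in range(10):
            base[f"G{i:03d}"] = 5.0 - i * 0.1
        ref = dict(genes)
        for i in range(5):
            ref[f"G{i:03d}"] = 4.0
        for i in range(5, 10):
            ref[f"G{i:03d}"] = -4.0
        better = dict(ref)
        better["G005"] = 4.0  # discordant -> concordant
        a = sm.GeneSignature("a", base)
        for r, label in [(ref, "before"), (better, "after")]:
            rs_a, rs_r = sm.top_ranked_sets(a, sm.GeneSignature("r", r), n_top=10)
            sc = sm.quadrant_score(rs_a, rs_r).score
            if label == "before":
                before = sc
        assert sc >= before


class TestRRHOMatrix:
    def grid_pair(self, rng, n=100):
        genes = [f"G{i:03d}" for i in range(n)]
        a = sm.GeneSignature("a", dict(zip(genes, rng.normal(size=n))))
        b = sm.GeneSignature("b", dict(zip(genes, rng.normal(size=n))))
        return a, b

    def test_grid_dimensions(self, rng):
        a, b = self.grid_pair(rng)
        m = sm.rrho_matrix(a, b, step=10)
        assert m.cells.shape == (10, 10)
        assert list(m.steps_x) == list(range(10, 101, 10))

    def test_self_comparison_diagonal_overlap_equals_threshold(self, rng):
        a, _ = self.grid_pair(rng)
        m = sm.rrho_matrix(a, a, step=10)
        assert [int(m.counts[i, i]) for i in range(10)] == list(range(10, 101, 10))

    def test_transpose_symmetry(self, rng):
        a, b = self.grid_pair(rng)
        m_ab = sm.rrho_matrix(a, b, step=10)
        m_ba = sm.rrho_matrix(b, a, step=10)
        np.testing.assert_array_equal(m_ab.cells, m_ba.cells.T)
        np.testing.assert_array_equal(m_ab.counts, m_ba.counts.T)

    def test_full_corner_cell_is_zero(self, rng):
        a, b = self.grid_pair(rng)
        m = sm.rrho_matrix(a, b, step=10)
        assert int(m.counts[-1, -1]) == 100
        assert m.cells[-1, -1] == 0.0

    def test_all_cells_finite_and_signed_rule(self, rng):
        a, b = self.grid_pair(rng)
        m = sm.rrho_matrix(a, b, step=20)
        assert np.all(np.isfinite(m.cells))
        N = m.universe_size
        for i, ti in enumerate(m.steps_y):
            for j, tj in enumerate(m.steps_x):
                expected = ti * tj / N
                if m.counts[i, j] > expected:
                    assert m.cells[i, j] >= 0
                else:
                    assert m.cells[i, j] <= 0

    def test_default_step_gives_about_100_bins(self, rng):
        a, b = self.grid_pair(rng, n=1000)
        m = sm.rrho_matrix(a, b)
        assert m.cells.shape == (100, 100)

    def test_too_small_universe_rejected(self):
        a = sm.GeneSignature("a", {f"G{i}": float(i + 1) for i in range(5)})
        with pytest.raises(InvalidInputError):
            sm.rrho_matrix(a, a)
        b = sm.GeneSignature("b", {"X1": 1.0})
        with pytest.raises(NoOverlapError):
            sm.rrho_matrix(a, b)

    def test_tsv_round_trip(self, rng, tmp_path):
        a, b = self.grid_pair(rng)
        m = sm.rrho_matrix(a, b, step=25)
        path = write_rrho(m, tmp_path / "grid.tsv")
        sx, sy, cells = load_rrho(path)
        np.testing.assert_array_equal(sx, m.steps_x)
        np.testing.assert_array_equal(sy, m.steps_y)
        np.testing.assert_allclose(cells, m.cells, rtol=1e-5)
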