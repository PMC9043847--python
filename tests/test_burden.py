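"""Gene-burden statistics: collapsing, SKAT-type test, Fisher, OR, FDR, Q-Q."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import noarvas as na
from noarvas import ContingencyTable2x2, Effect, VariantRecord
from noarvas.burden import _exact_perm_pvalue, _perm_mean_var, beta_maf_weights

from conftest import make_genotypes


def variant(gene="GENE1", pos=100):
    return VariantRecord(
        chrom="chr1", pos=pos, ref="A", alt="G", gene=gene,
        hgvs_c=f"c.{pos}A>G", effect=Effect.NONSENSE, ref_af=None,
    )


class TestCollapseGene:
    def test_single_case_carrier(self):
        col = np.zeros(476, dtype=int)
        col[0] = 1  # first sample is a case
        g = make_genotypes(133, 343, [col], [variant()])
        _, table = na.collapse_gene(g, [0], "GENE1")
        assert (table.a, table.b, table.c, table.d) == (1, 132, 0, 343)

    def test_no_carriers(self):
        g = make_genotypes(133, 343, [np.zeros(476, dtype=int)], [variant()])
        _, table = na.collapse_gene(g, [0], "GENE1")
        assert (table.a, table.b, table.c, table.d) == (0, 133, 0, 343)

    def test_sample_hit_twice_counts_once(self):
        col1 = np.zeros(20, dtype=int)
        col2 = np.zeros(20, dtype=int)
        col1[0] = col2[0] = 1
        g = make_genotypes(10, 10, [col1, col2], [variant(pos=100), variant(pos=200)])
        carrier, table = na.collapse_gene(g, [0, 1], "GENE1")
        assert carrier.sum() == 1 and table.a == 1

    def test_unknown_gene_raises(self):
        g = make_genotypes(5, 5, [np.zeros(10, dtype=int)], [variant()])
        with pytest.raises(KeyError):
            na.collapse_gene(g, [0], "NOPE")


def permutation_oracle(G, y, w, n_perm, rng):
    """Monte-Carlo permutation null for Q = sum_j w_j^2 (g_j' r)^2."""
    mu = y.mean()
    r = y - mu
    q_obs = float(np.sum((w * (G.T @ r)) ** 2))
    n = len(y)
    q_perm = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(20000, n_perm - done)
        idx = np.argsort(rng.random((b, n)), axis=1)
        s = (y[idx] - mu) @ G
        q_perm[done:done + b] = ((s * w) ** 2).sum(axis=1)
        done += b
    tol = 1e-9 * max(q_obs, 1.0)
    return (1 + (q_perm >= q_obs - tol).sum()) / (n_perm + 1)


class TestSkat:
    def test_all_zero_matrix_is_degenerate_p_one(self):
        y = np.array([1, 1, 0, 0, 0])
        res = na.skat_test(np.zeros((5, 2)), y)
        assert res.p_value == 1.0 and res.degenerate

    def test_single_variant_reduces_to_score_test(self):
        rng = np.random.default_rng(2)
        g = rng.binomial(2, 0.25, size=60).astype(float)
        y = np.zeros(60)
        y[:20] = 1
        rng.shuffle(y)
        w = np.array([1.7])
        res = na.skat_test(g[:, None], y, weights=w, method="imhof")
        # 1-df score test on the same finite-sample variance
        r = y - y.mean()
        num = (w[0] * (g @ r)) ** 2
        den = w[0] ** 2 * ((g - g.mean()) ** 2).sum() * (r @ r) / (len(y) - 1)
        expected = stats.chi2.sf(num / den, 1)
        assert res.p_value == pytest.approx(expected, rel=1e-5)

    def test_exact_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            n, n1 = 14, 5
            m = int(rng.integers(1, 4))
            G = np.zeros((n, m))
            for j in range(m):
                k = int(rng.integers(1, 5))
                G[rng.choice(n, size=k, replace=False), j] = rng.choice([1, 2])
            y = np.zeros(n)
            y[rng.choice(n, size=n1, replace=False)] = 1
            w = rng.uniform(0.5, 2.0, size=m)
            mu = n1 / n
            B = G * w
            q = float(np.sum((B.T @ (y - mu)) ** 2))
            qs = []
            for combo in itertools.combinations(range(n), n1):
                z = np.zeros(n)
                z[list(combo)] = 1
                qs.append(float(np.sum((B.T @ (z - mu)) ** 2)))
            qs = np.array(qs)
            expected = float((qs >= q - 1e-9).mean())
            assert _exact_perm_pvalue(B, y, q, cap=10**6) == pytest.approx(expected, abs=1e-12)

    def test_exact_agrees_with_sampled_permutations(self):
        rng = np.random.default_rng(17)
        n_perm = 20000
        for _ in range(3):
            n, n1, m = 100, 30, int(rng.integers(1, 5))
            G = np.zeros((n, m))
            for j in range(m):
                k = 1 + int(rng.poisson(3))
                G[rng.choice(n, size=k, replace=False), j] = 1
            y = np.zeros(n)
            y[rng.choice(n, size=n1, replace=False)] = 1
            w = beta_maf_weights(G.sum(0) / (2 * n))
            res = na.skat_test(G, y, weights=w, method="exact")
            p_perm = permutation_oracle(G, y, w, n_perm, rng)
            se = math.sqrt(max(p_perm * (1 - p_perm), 1e-12) / n_perm)
            assert abs(res.p_value - p_perm) <= 3 * max(se, 1 / n_perm)

    def test_perm_moments_match_brute_force(self):
        rng = np.random.default_rng(4)
        for _ in range(3):
            n, n1, m = 12, int(rng.integers(3, 7)), int(rng.integers(1, 4))
            G = rng.binomial(2, rng.uniform(0.1, 0.4, size=m), size=(n, m)).astype(float)
            w = rng.uniform(0.5, 2.0, size=m)
            B = G * w
            mu = n1 / n
            qs = []
            for combo in itertools.combinations(range(n), n1):
                z = np.zeros(n)
                z[list(combo)] = 1
                qs.append(float(np.sum((B.T @ (z - mu)) ** 2)))
            qs = np.array(qs)
            mean, var = _perm_mean_var(B, n1)
            assert mean == pytest.approx(qs.mean(), rel=1e-8)
            assert var == pytest.approx(qs.var(), rel=1e-6)

    def test_requires_both_phenotype_classes(self):
        with pytest.raises(ValueError):
            na.skat_test(np.ones((4, 1)), np.ones(4))


def fisher_oracle(table: ContingencyTable2x2) -> float:
    """Exact-rational two-sided Fisher p: sum of tables as or less probable."""
    a, b, c, d = table.a, table.b, table.c, table.d
    row1, col1, n = a + b, a + c, a + b + c + d
    f = math.factorial

    def point(aa):
        bb, cc = row1 - aa, col1 - aa
        dd = n - row1 - cc
        if min(bb, cc, dd) < 0:
            return None
        return Fraction(
            f(row1) * f(n - row1) * f(col1) * f(n - col1),
            f(n) * f(aa) * f(bb) * f(cc) * f(dd),
        )

    p_obs = point(a)
    total = sum(
        p for aa in range(0, min(row1, col1) + 1)
        if (p := point(aa)) is not None and p <= p_obs
    )
    return float(total)


class TestBurdenFisher:
    def test_empty_table_p_one(self):
        assert na.burden_fisher(ContingencyTable2x2(0, 133, 0, 343)) == 1.0

    def test_matches_hypergeometric_enumeration(self):
        for table in [
            ContingencyTable2x2(5, 128, 0, 343),
            ContingencyTable2x2(8, 125, 3, 340),
            ContingencyTable2x2(2, 131, 2, 341),
        ]:
            assert na.burden_fisher(table) == pytest.approx(fisher_oracle(table), rel=1e-9)

    def test_symmetric_in_row_swap(self):
        t1 = ContingencyTable2x2(5, 128, 1, 342)
        t2 = ContingencyTable2x2(1, 342, 5, 128)
        assert na.burden_fisher(t1) == pytest.approx(na.burden_fisher(t2), rel=1e-12)


class TestOddsRatio:
    def test_zero_control_carriers_not_estimable(self):
        orr = na.odds_ratio(ContingencyTable2x2(5, 128, 0, 343))
        assert not orr.estimable and orr.estimate is None and orr.ci_low is None
        assert str(orr) == "Not estimable"

    def test_balanced_table_or_one(self):
        orr = na.odds_ratio(ContingencyTable2x2(10, 90, 10, 90))
        assert orr.estimate == pytest.approx(1.0)
        assert orr.ci_low < 1.0 < orr.ci_high

    def test_textbook_formula(self):
        a, b, c, d = 8, 125, 3, 340
        orr = na.odds_ratio(ContingencyTable2x2(a, b, c, d))
        expected = (a * d) / (b * c)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        assert orr.estimate == pytest.approx(expected, rel=1e-12)
        assert orr.ci_low == pytest.approx(expected * math.exp(-1.96 * se), rel=1e-12)
        assert orr.ci_high == pytest.approx(expected * math.exp(1.96 * se), rel=1e-12)
        assert orr.ci_low <= orr.estimate <= orr.ci_high

    @given(st.tuples(*[st.integers(0, 40)] * 4))
    def test_not_estimable_iff_zero_cell_and_swap_invariant(self, cells):
        a, b, c, d = cells
        orr = na.odds_ratio(ContingencyTable2x2(a, b, c, d))
        assert orr.estimable == (0 not in (a, b, c, d))
        swapped = na.odds_ratio(ContingencyTable2x2(d, c, b, a))
        if orr.estimable:
            # simultaneous row and column swap leaves the OR unchanged
            assert swapped.estimate == pytest.approx(orr.estimate, rel=1e-12)


def bh_oracle(pvals):
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    q = [0.0] * n
    running = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvals[i] * n / rank_from_top)
        q[i] = running
    return q


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert na.bh_fdr([0.037])[0] == pytest.approx(0.037)

    def test_all_equal_stay_equal(self):
        q = na.bh_fdr([0.2] * 5)
        assert np.allclose(q, 0.2)

    def test_step_up_hand_computation(self):
        q = na.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])
        q2 = na.bh_fdr([0.001, 0.02, 0.9, 0.04])
        assert np.allclose(q2, bh_oracle([0.001, 0.02, 0.9, 0.04]))

    def test_matches_independent_oracle_on_random_vectors(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            p = rng.random(int(rng.integers(1, 40)))
            assert np.allclose(na.bh_fdr(p), bh_oracle(list(p)))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            na.bh_fdr([0.5, 1.5])


class TestQqData:
    def test_single_point(self):
        exp, obs = na.qq_data([0.5])
        assert exp[0] == pytest.approx(-math.log10(0.5))
        assert obs[0] == pytest.approx(-math.log10(0.5))

    def test_uniform_near_diagonal(self):
        rng = np.random.default_rng(9)
        p = rng.random(2000)
        exp, obs = na.qq_data(p)
        # DKW-style bound on the p-scale discrepancy
        assert np.max(np.abs(10**-obs - 10**-exp)) < 0.05

    def test_inflated_set_departs_upward(self):
        exp, obs = na.qq_data([1e-6] * 20)
        assert (obs > exp + 2).all()


class TestRunRvas:
    def test_gene_without_expression_excluded(self, small_cohort, rvas_results):
        missing = {g for g, ne in small_cohort.ne_table.items() if math.isnan(ne)}
        reported = {r.gene for r in rvas_results}
        assert missing and not (missing & reported)

    def test_results_complete_and_ordered(self, rvas_results):
        ps = [r.p_value for r in rvas_results]
        assert ps == sorted(ps)
        for r in rvas_results:
            assert 0 < r.p_value <= 1
            assert 0 <= r.q_value <= 1
            assert r.odds_ratio.estimable == (
                0 not in (r.n_case_carriers, 133 - r.n_case_carriers,
                          r.n_control_carriers, 343 - r.n_control_carriers)
            )

    def test_planted_genes_rank_first(self, small_cohort, rvas_results):
        top = {r.gene for r in rvas_results[: len(small_cohort.truth) + 2]}
        assert len(top & set(small_cohort.truth)) >= len(small_cohort.truth) - 1
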