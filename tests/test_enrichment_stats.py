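"""Odds ratios with Woolf CIs, test selection, Fisher vs an exhaustive
hypergeometric oracle, Spearman and the additive linear model."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from tgrisk.enrichment_stats import (
    ContingencyTable2x2,
    additive_regression,
    bonferroni,
    odds_ratio_ci,
    select_and_run_test,
    spearman_corr,
)

# carriage counts reconstructed from published group sizes (342 HTG cases,
# 3,532 normolipidemic controls) with their reported ORs/CIs
PUBLISHED_TABLES = [
    ((78, 264, 467, 3065), 1.94, (1.48, 2.54)),  # common APOA5 variant
    ((43, 299, 383, 3149), 1.18, (0.84, 1.66)),  # rare functional variants
    ((59, 283, 354, 3178), 1.87, (1.38, 2.53)),  # top-10% PRS
    ((59, 283, 382, 3150), 1.72, (1.27, 2.32)),  # top-10% causal alleles
    ((174, 168, 1284, 2248), 1.81, (1.45, 2.27)),  # any genetic risk factor
]


def fisher_p_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration with exact arithmetic."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def point(x: int) -> Fraction:
        return Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), math.comb(n, c1))

    p_obs = point(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = point(x)
        if px <= p_obs * (1 + Fraction(1, 10**12)):
            total += px
    return float(total)


class TestOddsRatioCI:
    @pytest.mark.parametrize("cells,or_exp,ci_exp", PUBLISHED_TABLES)
    def test_published_tables_to_printed_rounding(self, cells, or_exp, ci_exp):
        or_, ci, corrected = odds_ratio_ci(ContingencyTable2x2(*cells))
        assert not corrected
        assert round(or_, 2) == or_exp
        assert (round(ci[0], 2), round(ci[1], 2)) == ci_exp

    def test_balanced_table(self):
        or_, ci, _ = odds_ratio_ci(ContingencyTable2x2(10, 10, 10, 10))
        assert or_ == pytest.approx(1.0)
        assert math.log(ci[0]) == pytest.approx(-math.log(ci[1]))

    def test_zero_cell_haldane(self):
        or_, ci, corrected = odds_ratio_ci(ContingencyTable2x2(0, 10, 5, 5))
        assert corrected
        a, b, c, d = 0.5, 10.5, 5.5, 5.5
        assert or_ == pytest.approx(a * d / (b * c))
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        assert math.log(ci[1]) - math.log(ci[0]) == pytest.approx(2 * stats.norm.ppf(0.975) * se)

    def test_ci_brackets_or(self):
        for cells, _, _ in PUBLISHED_TABLES:
            or_, ci, _ = odds_ratio_ci(ContingencyTable2x2(*cells))
            assert ci[0] <= or_ <= ci[1]

    def test_transpose_invariance_and_exposure_swap(self):
        t = ContingencyTable2x2(12, 30, 7, 55)
        or_, ci, _ = odds_ratio_ci(t)
        # swapping rows and columns simultaneously leaves the OR unchanged
        or_t, _, _ = odds_ratio_ci(ContingencyTable2x2(12, 7, 30, 55))
        assert or_t == pytest.approx(or_)
        # swapping exposure labels inverts the OR and flips/swaps the CI
        or_s, ci_s, _ = odds_ratio_ci(ContingencyTable2x2(30, 12, 55, 7))
        assert or_s == pytest.approx(1 / or_)
        assert ci_s[0] == pytest.approx(1 / ci[1]) and ci_s[1] == pytest.approx(1 / ci[0])

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)


class TestTestSelection:
    def test_small_cell_uses_fisher(self):
        assert select_and_run_test(ContingencyTable2x2(3, 17, 100, 900)).test_used == "fisher_exact"

    def test_all_cells_ge_5_use_chi_square(self):
        assert select_and_run_test(ContingencyTable2x2(78, 264, 467, 3065)).test_used == "chi_square"

    def test_boundary_cell_exactly_5(self):
        assert select_and_run_test(ContingencyTable2x2(5, 5, 5, 5)).test_used == "chi_square"

    def test_degenerate_margin_error(self):
        with pytest.raises(ValueError):
            select_and_run_test(ContingencyTable2x2(0, 0, 5, 5))

    def test_chi_square_statistic_matches_hand_computation(self):
        a, b, c, d = 78, 264, 467, 3065
        n = a + b + c + d
        expected_cells = [
            (a + b) * (a + c) / n,
            (a + b) * (b + d) / n,
            (c + d) * (a + c) / n,
            (c + d) * (b + d) / n,
        ]
        chi2 = sum((o - e) ** 2 / e for o, e in zip((a, b, c, d), expected_cells))
        p = select_and_run_test(ContingencyTable2x2(a, b, c, d)).p_value
        assert p == pytest.approx(float(stats.chi2.sf(chi2, df=1)))

    def test_fisher_matches_exhaustive_oracle_small_tables(self):
        rng = np.random.default_rng(1)
        checked = 0
        for total in range(4, 31, 2):
            for _ in range(6):
                cells = rng.multinomial(total, [0.25] * 4)
                a, b, c, d = (int(x) for x in cells)
                if a + b == 0 or c + d == 0 or min(a, b, c, d) >= 5:
                    continue
                res = select_and_run_test(ContingencyTable2x2(a, b, c, d))
                assert res.test_used == "fisher_exact"
                assert res.p_value == pytest.approx(fisher_p_oracle(a, b, c, d), abs=1e-10)
                checked += 1
        assert checked > 20

    def test_fisher_p_is_one_at_hypergeometric_mode(self):
        res = select_and_run_test(ContingencyTable2x2(2, 2, 2, 2))
        assert res.p_value == pytest.approx(1.0)


class TestSpearman:
    def test_monotone_maps(self):
        x = {f"p{i}": float(i) for i in range(10)}
        y = {k: math.exp(v) for k, v in x.items()}
        assert spearman_corr(x, y)[0] == pytest.approx(1.0)
        y_neg = {k: -v for k, v in y.items()}
        assert spearman_corr(x, y_neg)[0] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=20)
        y = rng.normal(size=20) + 0.5 * x
        y[3] = y[5]  # introduce a tie

        def midranks(v):
            order = np.argsort(v, kind="mergesort")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j + 1 < len(v) and sv[j + 1] == sv[i]:
                    j += 1
                ranks[order[i : j + 1]] = (i + j) / 2 + 1
                i = j + 1
            return ranks

        rho_oracle = np.corrcoef(midranks(x), midranks(y))[0, 1]
        assert spearman_corr(x, y)[0] == pytest.approx(rho_oracle)

    def test_constant_vector_error(self):
        with pytest.raises(ValueError):
            spearman_corr({"a": 1.0, "b": 1.0, "c": 1.0}, {"a": 1.0, "b": 2.0, "c": 3.0})

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            spearman_corr({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})


class TestAdditiveRegression:
    def test_noiseless_recovery(self):
        dosage = {f"p{i}": i % 3 for i in range(30)}
        tg = {k: math.exp(4.0 + 0.5 * v) for k, v in dosage.items()}
        beta, se, p = additive_regression(tg, dosage)
        assert beta == pytest.approx(0.5, abs=1e-10)
        assert p < 1e-12

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(11)
        dos = rng.integers(0, 3, size=200).astype(float)
        tg = np.exp(4.5 + 0.12 * dos + rng.normal(0, 0.4, 200))
        beta, se, p = additive_regression(tg, dos)
        fit = sm.OLS(np.log(tg), sm.add_constant(dos)).fit()
        assert beta == pytest.approx(fit.params[1])
        assert se == pytest.approx(fit.bse[1])
        assert p == pytest.approx(fit.pvalues[1])

    def test_missing_dosage_dropped(self):
        dos = {"a": 0, "b": 1, "c": 2, "d": -1}
        tg = {k: math.exp(4 + 0.3 * max(v, 0)) for k, v in dos.items()}
        beta, _, _ = additive_regression(tg, dos)
        assert beta == pytest.approx(0.3, abs=1e-10)

    def test_constant_dosage_error(self):
        with pytest.raises(ValueError):
            additive_regression({"a": 100.0, "b": 110.0, "c": 120.0}, {"a": 1, "b": 1, "c": 1})

    def test_permutation_null_p_uniform(self):
        rng = np.random.default_rng(2024)
        n = 120
        dos = rng.integers(0, 3, size=n).astype(float)
        tg = np.exp(rng.normal(4.7, 0.4, size=n))
        ps = []
        for _ in range(200):
            perm = rng.permutation(dos)
            if len(set(perm)) > 1:
                ps.append(additive_regression(tg, perm)[2])
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01


def test_bonferroni_helper():
    assert bonferroni([0.01, 0.5, 1.0]) == [0.03, 1.0, 1.0]
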