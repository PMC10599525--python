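import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codonenrich.enrichment import LogOddsEntry, LogOddsVector
from codonenrich.stats import (
    DegenerateInputError,
    correlate_vectors,
    cronbach_alpha,
    exact_binomial_two_sided,
    multivariate_fit,
    orthogonal_fit,
    pairwise_synonym_diffs,
    sign_binomial_test,
    third_base_subset,
)


def vec_from_values(values: dict, label="v") -> LogOddsVector:
    entries = {
        c: LogOddsEntry(c, math.nan, math.nan, math.nan, math.nan, v, math.nan)
        for c, v in values.items()
    }
    return LogOddsVector(label, entries)


class TestCorrelate:
    def test_perfect_linear(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2 * v + 1 for v in x]
        res = correlate_vectors(x, y)
        assert res.coefficient == pytest.approx(1.0)
        assert res.p_value < 1e-6

    def test_spearman_hand_ranks(self):
        res = correlate_vectors([1, 2, 3, 4], [1, 3, 2, 4], method="spearman")
        assert res.coefficient == pytest.approx(0.8)

    def test_nan_entries_pairwise_dropped(self):
        x = [1.0, 2.0, math.nan, 4.0, 5.0]
        y = [1.0, 2.0, 3.0, 4.0, math.nan]
        res = correlate_vectors(x, y)
        assert res.n == 3
        assert res.coefficient == pytest.approx(1.0)

    def test_zero_variance_error(self):
        with pytest.raises(DegenerateInputError):
            correlate_vectors([1, 1, 1, 1], [1, 2, 3, 4])

    @given(
        a=st.floats(0.1, 10),
        b=st.floats(-5, 5),
    )
    @settings(max_examples=25, deadline=None)
    def test_pearson_affine_invariance(self, a, b):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        r0 = correlate_vectors(x, y).coefficient
        r1 = correlate_vectors(a * x + b, y).coefficient
        assert r1 == pytest.approx(r0, abs=1e-9)
        r2 = correlate_vectors(-x, y).coefficient
        assert r2 == pytest.approx(-r0, abs=1e-9)

    def test_spearman_monotone_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        rho0 = correlate_vectors(x, y, "spearman").coefficient
        rho1 = correlate_vectors(np.exp(x), y, "spearman").coefficient
        assert rho1 == pytest.approx(rho0)


class TestOrthogonalFit:
    def test_collinear_slope_two(self):
        slope, intercept = orthogonal_fit([0, 1, 2], [0, 2, 4])
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(0.0)

    def test_collinear_slope_half(self):
        slope, intercept = orthogonal_fit([0, 2, 4], [0, 1, 2])
        assert slope == pytest.approx(0.5)
        assert intercept == pytest.approx(0.0)

    def test_eigen_oracle_on_random_cloud(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=20)
        y = 0.7 * x + rng.normal(scale=0.3, size=20)
        slope, intercept = orthogonal_fit(x, y)
        # independent oracle: eigen decomposition of the 2x2 covariance
        cov = np.cov(np.vstack([x, y]))
        evals, evecs = np.linalg.eigh(cov)
        v = evecs[:, np.argmax(evals)]
        assert slope == pytest.approx(v[1] / v[0], abs=1e-10)
        assert intercept == pytest.approx(np.mean(y) - slope * np.mean(x), abs=1e-10)

    def test_residuals_orthogonal_to_direction(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=30)
        y = -1.4 * x + rng.normal(scale=0.5, size=30)
        slope, intercept = orthogonal_fit(x, y)
        d = np.array([1.0, slope]) / math.hypot(1.0, slope)
        pts = np.column_stack([x - x.mean(), y - y.mean()])
        resid = pts - np.outer(pts @ d, d)
        assert np.allclose(resid @ d, 0.0, atol=1e-10)

    def test_isotropic_tie_error(self):
        with pytest.raises(DegenerateInputError):
            orthogonal_fit([0, 1, 0, -1], [1, 0, -1, 0])


class TestPairwiseDiffs:
    def test_standard_partition_has_87_pairs(self, code):
        rng = np.random.default_rng(2)
        x = vec_from_values({c: rng.normal() for c in code.scored_codons})
        y = vec_from_values({c: rng.normal() for c in code.scored_codons})
        diffs = pairwise_synonym_diffs(x, y, code)
        assert len(diffs) == 87
        assert np.all(diffs.dx >= 0)

    def test_pair_count_formula_any_partition(self, code):
        from codonenrich.genetic_code import arg_split_partition

        part = arg_split_partition()
        rng = np.random.default_rng(3)
        x = vec_from_values({c: rng.normal() for c in part.scored_codons})
        y = vec_from_values({c: rng.normal() for c in part.scored_codons})
        diffs = pairwise_synonym_diffs(x, y, part)
        expected = sum(
            len(b) * (len(b) - 1) // 2 for b in part.blocks if len(b) > 1
        )
        assert len(diffs) == expected == 79

    def test_two_fold_antisymmetric_pair(self, code):
        a = 0.9
        vals = {c: 0.0 for c in code.scored_codons}
        vals["AAA"], vals["AAG"] = a, -a
        x = vec_from_values(vals)
        yvals = {c: 0.1 for c in code.scored_codons}
        yvals["AAA"], yvals["AAG"] = 0.5, 0.2
        y = vec_from_values(yvals)
        diffs = pairwise_synonym_diffs(x, y, code)
        lys = [p for p in diffs.pairs if {p[0], p[1]} == {"AAA", "AAG"}]
        assert len(lys) == 1
        hi, lo, dx, dy = lys[0]
        assert (hi, lo) == ("AAA", "AAG")
        assert dx == pytest.approx(2 * a)
        assert dy == pytest.approx(0.3)

    def test_identity_vectors_give_perfect_correlation(self, code):
        rng = np.random.default_rng(4)
        x = vec_from_values({c: rng.normal() for c in code.scored_codons})
        diffs = pairwise_synonym_diffs(x, x, code)
        assert np.allclose(diffs.dx, diffs.dy)
        res = correlate_vectors(diffs.dx, diffs.dy)
        assert res.coefficient == pytest.approx(1.0)

    def test_undefined_entries_dropped(self, code):
        vals = {c: float(i) for i, c in enumerate(code.scored_codons)}
        vals["AAA"] = math.nan
        x = vec_from_values(vals)
        y = vec_from_values({c: 1.0 * i for i, c in enumerate(code.scored_codons)})
        diffs = pairwise_synonym_diffs(x, y, code)
        assert len(diffs) == 86  # the single Lys pair is dropped


def binomial_two_sided_oracle(k: int, n: int) -> float:
    """Exact enumeration with rational arithmetic."""
    pmf = [Fraction(math.comb(n, i), 2**n) for i in range(n + 1)]
    lower = sum(pmf[: k + 1])
    upper = sum(pmf[k:])
    return float(min(1, 2 * min(lower, upper)))


class TestSignBinomial:
    def test_22_of_30(self):
        assert exact_binomial_two_sided(22, 30) == pytest.approx(0.016124, abs=1e-5)

    def test_single_trial(self):
        assert exact_binomial_two_sided(1, 1) == pytest.approx(1.0)

    def test_22_of_29(self):
        p = exact_binomial_two_sided(22, 29)
        assert p == pytest.approx(binomial_two_sided_oracle(22, 29))
        assert p == pytest.approx(0.0081, abs=5e-4)

    def test_exhaustive_against_oracle(self):
        for n in range(1, 31):
            for k in range(n + 1):
                assert exact_binomial_two_sided(k, n) == pytest.approx(
                    binomial_two_sided_oracle(k, n), abs=1e-12
                )

    def test_sign_test_on_vector(self, code):
        vals = {c: (1.0 if c[2] in "AT" else -1.0) for c in code.scored_codons}
        # flip 8 of the 30 A/T-ending codons negative -> k=22, n=30
        at = [c for c in sorted(code.scored_codons) if c[2] in "AT"]
        assert len(at) == 30
        for c in at[:8]:
            vals[c] = -1.0
        vec = vec_from_values(vals)
        k, n, p, n_zero = sign_binomial_test(vec, third_base_subset("AT"), "positive")
        assert (k, n) == (22, 30)
        assert p == pytest.approx(exact_binomial_two_sided(22, 30))
        assert n_zero == 0

    def test_zero_entries_counted_as_nonmatching(self, code):
        vals = {c: 0.0 for c in code.scored_codons}
        vec = vec_from_values(vals)
        k, n, p, n_zero = sign_binomial_test(vec, third_base_subset("AT"), "positive")
        assert k == 0 and n == 30 and n_zero == 30


class TestMultivariateFit:
    def test_response_equals_predictor(self):
        rng = np.random.default_rng(5)
        x1 = rng.normal(size=30)
        x2 = rng.normal(size=30)
        fit = multivariate_fit(x1, {"x1": x1, "x2": x2})
        assert fit.coefficients["x1"] == pytest.approx(1.0, abs=1e-10)
        assert fit.coefficients["x2"] == pytest.approx(0.0, abs=1e-10)
        assert fit.adjusted_r2 == pytest.approx(1.0)

    def test_normal_equations_oracle(self):
        x1 = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        x2 = np.array([1.0, 0.0, 2.0, 1.0, 3.0, 2.0])
        y = np.array([0.5, 1.2, 3.1, 2.9, 5.4, 4.8])
        X = np.column_stack([np.ones(6), x1, x2])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        fit = multivariate_fit(y, {"x1": x1, "x2": x2})
        assert fit.coefficients["const"] == pytest.approx(beta[0], abs=1e-10)
        assert fit.coefficients["x1"] == pytest.approx(beta[1], abs=1e-10)
        assert fit.coefficients["x2"] == pytest.approx(beta[2], abs=1e-10)

    def test_quadratic_terms(self):
        x = np.linspace(0, 1, 40)
        y = 3.0 * x - 2.3 * x**2
        fit = multivariate_fit(y, {"x": x}, include_quadratic=["x"])
        assert fit.coefficients["x"] == pytest.approx(3.0, abs=1e-8)
        assert fit.coefficients["x^2"] == pytest.approx(-2.3, abs=1e-8)

    def test_rank_deficient_design_error(self):
        x = np.arange(10.0)
        with pytest.raises(DegenerateInputError):
            multivariate_fit(x, {"a": x, "b": 2 * x})


class TestCronbachAlpha:
    def test_identical_items(self):
        m = np.tile(np.array([[1.0], [2.0], [3.0], [5.0]]), (1, 2))
        res = cronbach_alpha(m)
        assert res.alpha == pytest.approx(1.0)

    def test_hand_computed_example(self):
        m = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 5.0]])
        res = cronbach_alpha(m)
        assert res.alpha == pytest.approx(18 / 19)
        assert res.ci_low <= res.alpha <= res.ci_high

    def test_duplicated_item_copies(self):
        rng = np.random.default_rng(6)
        col = rng.normal(size=12)
        m = np.tile(col[:, None], (1, 5))
        assert cronbach_alpha(m).alpha == pytest.approx(1.0)

    def test_zero_total_variance_error(self):
        m = np.array([[1.0, -1.0], [2.0, -2.0], [3.0, -3.0]])
        with pytest.raises(DegenerateInputError):
            cronbach_alpha(m)

    def test_shape_requirements(self):
        with pytest.raises(ValueError):
            cronbach_alpha(np.ones((2, 2)))
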