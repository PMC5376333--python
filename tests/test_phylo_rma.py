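import types

import numpy as np
import pytest
from scipy import integrate, stats

from phylorma import (
    PhyloGLSContext,
    VCVMatrix,
    estimate_lambda,
    gls_mean,
    lambda_lrt,
    lambda_transform,
    paper_r2,
    parse_newick,
    phyl_rma,
    profile_loglik,
    rma_line,
    slope_ci,
    slope_test,
    vcv_matrix,
)
from phylorma.synthetic_data import (
    rate_matrix_for_slope,
    sim_traits_lambda_bm,
    sim_yule_tree,
)


def sma_closed_form(x, y):
    """Textbook standardized-major-axis fit from ordinary sample moments."""
    sxx, syy = np.var(x, ddof=1), np.var(y, ddof=1)
    sxy = np.cov(x, y, ddof=1)[0, 1]
    b1 = np.sign(sxy) * np.sqrt(syy / sxx)
    b0 = y.mean() - b1 * x.mean()
    return b0, b1, sxy**2 / (sxx * syy)


class TestGLSMean:
    def test_identity_reduces_to_arithmetic_mean(self):
        C = VCVMatrix(("a", "b", "c"), np.eye(3))
        assert gls_mean(C, np.array([1.0, 2.0, 3.0]))[0] == pytest.approx(2.0)

    def test_scale_invariance(self, three_tip_tree):
        C = vcv_matrix(three_tip_tree)
        Ck = VCVMatrix(C.labels, 7.3 * C.values)
        x = np.array([0.2, 1.4, -0.5])
        assert gls_mean(C, x)[0] == pytest.approx(gls_mean(Ck, x)[0], abs=1e-12)

    def test_hand_computed_three_tip(self):
        """Against explicit 3x3 inversion: C=[[2,1,0],[1,2,0],[0,0,2]], x=(1,1,4)."""
        C = VCVMatrix(("a", "b", "c"), np.array([[2.0, 1, 0], [1, 2, 0], [0, 0, 2]]))
        x = np.array([1.0, 1.0, 4.0])
        Cinv = np.linalg.inv(C.values)
        ones = np.ones(3)
        oracle = (ones @ Cinv @ x) / (ones @ Cinv @ ones)
        a = gls_mean(C, x)[0]
        assert a == pytest.approx(oracle, abs=1e-10)
        assert a == pytest.approx(16 / 7, abs=1e-10)


class TestProfileLoglik:
    def test_closed_form_two_tips(self):
        C = VCVMatrix(("a", "b"), np.eye(2))
        ll = profile_loglik(C, np.array([-1.0, 1.0]))
        assert ll == pytest.approx(-np.log(2 * np.pi) - 1.0, abs=1e-12)

    def test_location_invariance(self, five_tip_tree):
        C = vcv_matrix(five_tip_tree)
        rng = np.random.default_rng(3)
        X = rng.standard_normal((5, 2))
        shifted = X + np.array([11.0, -4.0])
        assert profile_loglik(C, X) == pytest.approx(profile_loglik(C, shifted),
                                                     abs=1e-9)

    @pytest.mark.parametrize("lam", [0.0, 0.35, 1.0])
    def test_matrix_normal_density_oracle(self, lam, five_tip_tree):
        """Equals the matrix-normal density R_ML (x) C evaluated at the GLS means."""
        C = lambda_transform(vcv_matrix(five_tip_tree), lam)
        rng = np.random.default_rng(17)
        X = rng.standard_normal((5, 2)) * [0.5, 0.8] + [2.0, 1.0]
        a = gls_mean(C, X)
        E = X - a
        Cinv = np.linalg.inv(C.values)
        R_ml = E.T @ Cinv @ E / 5
        mean = np.repeat(a, 5)
        cov = np.kron(R_ml, C.values)
        oracle = stats.multivariate_normal(mean, cov).logpdf(X.flatten(order="F"))
        assert profile_loglik(C, X) == pytest.approx(oracle, abs=1e-8)

    def test_degenerate_trait_errors(self, five_tip_tree):
        C = vcv_matrix(five_tip_tree)
        X = np.column_stack([np.full(5, 2.0), np.arange(5.0)])
        with pytest.raises(ValueError, match="degenerate|rate matrix"):
            profile_loglik(C, X)


class TestEstimateLambda:
    def test_star_tree_unidentifiable(self):
        tree = parse_newick("(A:1,B:1,C:1,D:1);")
        X = np.column_stack([[0.0, 1, 2, 3], [0.0, 2, 1, 3]])
        lam, llh, ll0, identifiable = estimate_lambda(tree, X)
        assert lam == 0.0
        assert llh == ll0
        assert not identifiable

    def test_strong_signal_recovers_high_lambda(self):
        tree = sim_yule_tree(150, 1.0, seed=21)
        R = rate_matrix_for_slope(1.4, 0.09, 0.66)
        lams = []
        for rep in range(15):
            X = sim_traits_lambda_bm(tree, 1.0, R, [2.5, 1.3], seed=100 + rep)
            lams.append(estimate_lambda(tree, X)[0])
        assert np.mean(lams) > 0.85

    def test_no_signal_recovers_low_lambda(self):
        tree = sim_yule_tree(150, 1.0, seed=22)
        rng = np.random.default_rng(5)
        lams = []
        for _ in range(15):
            X = rng.standard_normal((150, 2))
            lams.append(estimate_lambda(tree, X)[0])
        assert np.median(lams) < 0.15


class TestRMALine:
    def test_sqrt_ratio(self):
        ctx = types.SimpleNamespace(R=np.array([[1.0, 1.9], [1.9, 4.0]]),
                                    a=np.array([0.0, 0.0]))
        b0, b1, r2 = rma_line(ctx)
        assert b1 == pytest.approx(2.0)
        assert b0 == pytest.approx(0.0)
        assert r2 == pytest.approx(1.9**2 / 4.0)

    def test_quartet_on_star_matches_sample_moments(self, star4, quartet_xy):
        x, y = quartet_xy
        fit = phyl_rma(star4, dict(zip("ABCD", x)), dict(zip("ABCD", y)),
                       fixed_lambda=0.0)
        assert fit.beta1 == pytest.approx(1.0, abs=1e-12)
        assert fit.beta0 == pytest.approx(0.0, abs=1e-12)
        assert fit.r2_corr == pytest.approx(0.64, abs=1e-12)

    def test_swap_symmetry(self, five_tip_tree):
        rng = np.random.default_rng(8)
        x = dict(zip(five_tip_tree.tips, rng.standard_normal(5)))
        y = {k: 1.3 * v + rng.standard_normal() * 0.2 for k, v in x.items()}
        fxy = phyl_rma(five_tip_tree, x, y, fixed_lambda=0.7)
        fyx = phyl_rma(five_tip_tree, y, x, fixed_lambda=0.7)
        assert fxy.beta1 * fyx.beta1 == pytest.approx(1.0, abs=1e-10)

    def test_unit_invariance(self, five_tip_tree):
        """Shifting x (a unit rescale before log10) moves only the intercept."""
        rng = np.random.default_rng(11)
        x = dict(zip(five_tip_tree.tips, rng.standard_normal(5) + 2))
        y = {k: 1.4 * v + rng.standard_normal() * 0.3 for k, v in x.items()}
        f1 = phyl_rma(five_tip_tree, x, y)
        shift = np.log10(10.0)  # cm -> mm
        f2 = phyl_rma(five_tip_tree, {k: v + shift for k, v in x.items()}, y)
        assert f2.beta1 == pytest.approx(f1.beta1, abs=1e-8)
        assert f2.r2_corr == pytest.approx(f1.r2_corr, abs=1e-8)
        assert f2.lambda_hat == pytest.approx(f1.lambda_hat, abs=1e-6)
        assert f2.p_slope == pytest.approx(f1.p_slope, abs=1e-8)
        assert f2.beta0 == pytest.approx(f1.beta0 - f1.beta1 * shift, abs=1e-6)


class TestPaperR2:
    def test_perfect_fit(self):
        x = np.array([0.0, 1, 2, 3])
        assert paper_r2(x, 2 * x + 1, 1.0, 2.0) == pytest.approx(1.0)

    def test_flat_line_through_mean(self):
        y = np.array([1.0, 2, 3, 4])
        assert paper_r2(np.zeros(4), y, y.mean(), 0.0) == pytest.approx(0.0)

    def test_quartet(self, quartet_xy):
        x, y = quartet_xy
        assert paper_r2(x, y, 0.0, 1.0) == pytest.approx(0.6)

    def test_zero_total_ss_errors(self):
        with pytest.raises(ValueError):
            paper_r2(np.arange(4.0), np.full(4, 2.0), 2.0, 0.0)


class TestSlopeTest:
    def test_null_slope_gives_p_one(self):
        t, df, p = slope_test(1.0, 0.5, 10, h=1.0)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_quadrature_oracle(self):
        """p equals 2x the integrated t density beyond T, df = n - 2."""
        t, df, p = slope_test(1.0, 0.64, 4, h=2.0)
        assert t == pytest.approx(np.log(2) / np.sqrt(0.36 / 2))
        assert df == 2
        tail, _ = integrate.quad(lambda u: stats.t.pdf(u, df), t, np.inf)
        assert p == pytest.approx(2 * tail, abs=1e-8)

    def test_reciprocal_invariance_at_isometry(self):
        _, _, p1 = slope_test(1.7, 0.5, 12, h=1.0)
        _, _, p2 = slope_test(1 / 1.7, 0.5, 12, h=1.0)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_degenerate_r2(self):
        with pytest.warns(UserWarning):
            _, _, p = slope_test(2.0, 1.0, 8, h=1.0)
        assert p == 0.0

    def test_nonpositive_h_errors(self):
        with pytest.raises(ValueError):
            slope_test(1.2, 0.4, 10, h=0.0)


class TestSlopeCI:
    def test_degenerate_interval(self):
        with pytest.warns(UserWarning):
            lo, hi = slope_ci(1.3, 1.0, 10)
        assert lo == hi == 1.3

    @pytest.mark.parametrize("b1,r2,n", [(1.4, 0.4, 20), (0.7, 0.9, 8), (2.2, 0.1, 50)])
    def test_contains_slope_and_product_identity(self, b1, r2, n):
        lo, hi = slope_ci(b1, r2, n)
        assert lo <= b1 <= hi
        assert lo * hi == pytest.approx(b1**2, rel=1e-12)

    def test_simulation_coverage(self):
        """95% CI covers the generating slope in >= 90% of lambda-BM draws."""
        R = rate_matrix_for_slope(1.4, 0.09, 0.66)
        hits = 0
        n_rep = 300
        for rep in range(n_rep):
            tree = sim_yule_tree(50, 1.0, seed=5000 + rep)
            X = sim_traits_lambda_bm(tree, 0.5, R, [2.5, 1.3], seed=9000 + rep)
            fit = phyl_rma(tree, dict(zip(tree.tips, X[:, 0])),
                           dict(zip(tree.tips, X[:, 1])))
            hits += fit.ci_low <= 1.4 <= fit.ci_high
        assert hits / n_rep >= 0.90


class TestLambdaLRT:
    def test_zero_difference(self):
        stat, p = lambda_lrt(-10.0, -10.0)
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_chi2_quantile(self):
        # loglik0 = loglik_hat - 3.841459/2 => Delta = 3.841459
        stat, p = lambda_lrt(-8.0, -8.0 - 3.841459 / 2)
        assert stat == pytest.approx(3.841459)
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_inverted_likelihoods_error(self):
        with pytest.raises(ValueError):
            lambda_lrt(-10.0, -5.0)


class TestPhylRMAOrchestration:
    def test_deterministic(self):
        tree = sim_yule_tree(20, 1.0, seed=42)
        R = rate_matrix_for_slope(1.4, 0.09, 0.66)
        X = sim_traits_lambda_bm(tree, 0.7, R, [2.5, 1.3], seed=42)
        x = dict(zip(tree.tips, X[:, 0]))
        y = dict(zip(tree.tips, X[:, 1]))
        f1, f2 = phyl_rma(tree, x, y), phyl_rma(tree, x, y)
        assert f1.to_dict() == f2.to_dict()

    def test_lambda_zero_star_equals_textbook_sma(self):
        rng = np.random.default_rng(0)
        tips = [f"s{i}" for i in range(12)]
        tree = parse_newick("(" + ",".join(f"{t}:1" for t in tips) + ");")
        x = rng.standard_normal(12) + 2
        y = 1.4 * x + rng.standard_normal(12) * 0.4
        fit = phyl_rma(tree, dict(zip(tips, x)), dict(zip(tips, y)),
                       fixed_lambda=0.0)
        b0, b1, r2 = sma_closed_form(x, y)
        assert fit.beta1 == pytest.approx(b1, abs=1e-10)
        assert fit.beta0 == pytest.approx(b0, abs=1e-10)
        assert fit.r2_corr == pytest.approx(r2, abs=1e-10)

    def test_mismatched_species_reported(self, five_tip_tree):
        x = {t: 1.0 for t in ["A", "B"]}
        with pytest.raises(ValueError, match="shared"):
            phyl_rma(five_tip_tree, x, x)

    def test_invariants_of_fit(self):
        tree = sim_yule_tree(25, 1.0, seed=3)
        R = rate_matrix_for_slope(1.4, 0.09, 0.66)
        X = sim_traits_lambda_bm(tree, 0.5, R, [2.5, 1.3], seed=3)
        fit = phyl_rma(tree, dict(zip(tree.tips, X[:, 0])),
                       dict(zip(tree.tips, X[:, 1])))
        assert fit.ci_low <= fit.beta1 <= fit.ci_high
        assert 0.0 <= fit.r2_corr <= 1.0
        assert 0.0 <= fit.lambda_hat <= 1.0
        assert fit.lrt_stat >= 0.0
        assert 0.0 <= fit.p_slope <= 1.0 and 0.0 <= fit.p_lambda <= 1.0


class TestAgainstReferenceImplementation:
    """Frozen cross-check against an independent phylogenetic RMA fit.

    Expected values were computed with the R reference implementation of
    lambda-based phylogenetic RMA (phytools::phyl.RMA) on exactly this tree
    and trait matrix; the tolerance reflects the two optimizers' stopping
    rules, not model disagreement.
    """

    NEWICK = (
        "((((t8:0.320742922537,t9:0.320742922537):0.262893156292,"
        "t4:0.583636078828):0.759954111957,((t5:0.57537565479,"
        "t6:0.57537565479):0.334429902129,(t1:0.777448543077,"
        "t2:0.777448543077):0.132357013842):0.433784633866):0.993334988006,"
        "((t7:0.450286667962,((t11:0.167794275476,t12:0.167794275476)"
        ":0.130178303769,t10:0.297972579245):0.152314088717):0.24037682758,"
        "t3:0.690663495542):1.64626168325);"
    )
    TIPS = ["t8", "t9", "t4", "t5", "t6", "t1", "t2", "t7", "t11", "t12",
            "t10", "t3"]
    X = [3.00515685, 2.32437399, 2.49328915, 2.38018989, 1.69897785,
         1.93456096, 2.03755216, 2.77350075, 2.37821563, 2.76258371,
         2.32843654, 2.24398379]
    Y = [2.15167887, 1.63438069, 1.33055613, 1.50596759, 0.57342674,
         1.44365599, 1.33641397, 1.52844761, 1.41413723, 1.73164796,
         0.65215767, 1.01989749]
    # phytools::phyl.RMA(x, y, tree, method="lambda")
    EXPECTED = {"beta0": -1.596623, "beta1": 1.250838, "lambda": 0.2568829,
                "r2": 0.5775619}

    def test_matches_reference(self):
        tree = parse_newick(self.NEWICK)
        fit = phyl_rma(tree, dict(zip(self.TIPS, self.X)),
                       dict(zip(self.TIPS, self.Y)))
        assert fit.beta0 == pytest.approx(self.EXPECTED["beta0"], abs=2e-4)
        assert fit.beta1 == pytest.approx(self.EXPECTED["beta1"], abs=2e-4)
        assert fit.lambda_hat == pytest.approx(self.EXPECTED["lambda"], abs=1e-3)
        assert fit.r2_corr == pytest.approx(self.EXPECTED["r2"], abs=1e-5)
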