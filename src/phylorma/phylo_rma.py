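"""Phylogenetic reduced-major-axis (RMA/SMA) regression with Pagel's lambda.

The model: a pair of log10-scale traits evolves by correlated Brownian
motion on a phylogeny, with between-tip covariance C(lambda) — the shared
root-to-tip path lengths, off-diagonals shrunk by Pagel's lambda.  The
n x 2 trait matrix X is matrix-normal,

    X ~ MN(1 a', R (x) C(lambda)),

where ``a`` is the 2-vector of root states (estimated by GLS) and R the
2 x 2 evolutionary rate (variance/covariance) matrix.  The RMA line through
the GLS means has slope sign(R_xy) * sqrt(R_yy / R_xx): the standardized
major axis of the evolutionary covariance, appropriate when both traits
carry error and the scaling exponent — not prediction of y from x — is the
quantity of interest.

lambda is estimated by maximizing the profile log-likelihood over [0, 1]
(R and a profiled out analytically); the fit against lambda = 0 is compared
by a likelihood-ratio test on one degree of freedom.  The slope is tested
against a predicted exponent h (isometry: h = 1 for length-on-length) with
the standard SMA log-slope t-test, and interval-estimated with the F-based
SMA confidence interval.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict, field

import numpy as np
from scipy import linalg, optimize, stats

from .treeio import PhyloTree, VCVMatrix, lambda_transform, prune_to_taxa, vcv_matrix

__all__ = [
    "PhyloGLSContext",
    "RMAFit",
    "gls_mean",
    "profile_loglik",
    "estimate_lambda",
    "rma_line",
    "paper_r2",
    "slope_test",
    "slope_ci",
    "lambda_lrt",
    "phyl_rma",
]

_LAMBDA_GRID = np.linspace(0.0, 1.0, 21)


def _cho_factor(C: VCVMatrix):
    try:
        return linalg.cho_factor(C.values, lower=True)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "phylogenetic covariance matrix is singular; check for tips at "
            "identical positions (zero-length terminal branches)"
        ) from exc


def gls_mean(C: VCVMatrix, X: np.ndarray) -> np.ndarray:
    """GLS phylogenetic mean (root-state estimate) per trait column.

    a = (1' C^-1 1)^-1 1' C^-1 X.  With C proportional to the identity this
    reduces to the ordinary arithmetic column mean, and it is invariant to
    rescaling C by any positive constant.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != C.n:
        X = X.T
    cf = _cho_factor(C)
    ones = np.ones(C.n)
    Ci1 = linalg.cho_solve(cf, ones)
    CiX = linalg.cho_solve(cf, X)
    return (ones @ CiX) / (ones @ Ci1)


def profile_loglik(C_lambda: VCVMatrix, X: np.ndarray) -> float:
    """Profile log-likelihood of the matrix-normal trait model.

    With a the GLS means, E = X - 1a' and R_ML = E' C^-1 E / n, returns

        -1/2 [ n m ln(2 pi) + n ln|R_ML| + m ln|C| + n m ]

    for n tips and m trait columns — the log of the matrix-normal density
    MN(1a', R_ML (x) C) evaluated at X with R and a at their maximizers
    given C.  Natural log throughout; the trait values themselves are on
    whatever (typically log10) scale the caller supplies.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, m = X.shape
    if n != C_lambda.n:
        raise ValueError(f"trait matrix has {n} rows but C has {C_lambda.n} tips")
    cf = _cho_factor(C_lambda)
    a = gls_mean(C_lambda, X)
    E = X - a
    CiE = linalg.cho_solve(cf, E)
    R_ml = E.T @ CiE / n
    sign, logdet_R = np.linalg.slogdet(R_ml)
    if sign <= 0 or not np.isfinite(logdet_R):
        bad = [j for j in range(m) if R_ml[j, j] <= 0]
        raise ValueError(
            f"degenerate trait column(s) {bad if bad else '(collinear pair)'}: "
            "evolutionary rate matrix is not positive definite"
        )
    logdet_C = 2.0 * np.sum(np.log(np.diag(cf[0])))
    return float(-0.5 * (n * m * np.log(2 * np.pi) + n * logdet_R + m * logdet_C + n * m))


def estimate_lambda(
    tree: PhyloTree | VCVMatrix,
    X: np.ndarray,
    tol: float = 1e-8,
) -> tuple[float, float, float, bool]:
    """Maximum-likelihood Pagel's lambda on [0, 1] for a trait matrix.

    Returns ``(lambda_hat, loglik_hat, loglik0, identifiable)``.  A 21-point
    grid pre-scan guards against local optima before bounded scalar
    refinement (Brent, absolute tolerance ``tol``); the endpoints 0 and 1
    are always evaluated.  On a star tree the likelihood is flat in lambda;
    lambda_hat = 0 is returned with ``identifiable=False``.
    """
    C = tree if isinstance(tree, VCVMatrix) else vcv_matrix(tree)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if C.n < 3:
        raise ValueError("lambda estimation requires at least 3 tips")
    diag = np.diag(C.values).copy()

    def C_at(lam: float) -> VCVMatrix:
        values = C.values * lam
        np.fill_diagonal(values, diag)
        return VCVMatrix(C.labels, values, lambda_applied=lam)

    def f(lam: float) -> float:
        return profile_loglik(C_at(lam), X)

    grid_ll = np.array([f(l) for l in _LAMBDA_GRID])
    if not np.all(np.isfinite(grid_ll)):
        raise ValueError("non-finite log-likelihood on the lambda grid")
    loglik0 = float(grid_ll[0])
    if np.ptp(grid_ll) < 1e-10:
        # off-diagonals all zero (star tree): lambda has no effect
        return 0.0, loglik0, loglik0, False

    best = int(np.argmax(grid_ll))
    lo = _LAMBDA_GRID[max(best - 1, 0)]
    hi = _LAMBDA_GRID[min(best + 1, len(_LAMBDA_GRID) - 1)]
    res = optimize.minimize_scalar(
        lambda l: -f(l), bounds=(lo, hi), method="bounded",
        options={"xatol": tol},
    )
    candidates = [(float(res.x), -float(res.fun)), (0.0, loglik0), (1.0, float(grid_ll[-1]))]
    lam_hat, ll_hat = max(candidates, key=lambda c: c[1])
    return lam_hat, ll_hat, loglik0, True


@dataclass
class PhyloGLSContext:
    """Aligned inputs and GLS summaries for one bivariate phylogenetic fit.

    ``X`` holds the predictor in column 0 and the response in column 1, rows
    aligned with ``C_lambda.labels``.  ``R`` is the evolutionary rate matrix
    E' C^-1 E / (n - 1); the RMA slope and correlation are invariant to the
    divisor.
    """

    C_lambda: VCVMatrix
    X: np.ndarray
    a: np.ndarray = field(init=False)
    E: np.ndarray = field(init=False)
    R: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != 2:
            raise ValueError("X must be an n x 2 matrix (predictor, response)")
        if self.X.shape[0] != self.C_lambda.n:
            raise ValueError("rows of X must align with C_lambda labels")
        cf = _cho_factor(self.C_lambda)
        self.a = gls_mean(self.C_lambda, self.X)
        self.E = self.X - self.a
        CiE = linalg.cho_solve(cf, self.E)
        self.R = self.E.T @ CiE / (self.n - 1)

    @property
    def n(self) -> int:
        return self.C_lambda.n

    @property
    def m(self) -> int:
        return 2


@dataclass
class RMAFit:
    """Complete result of one phylogenetic RMA regression."""

    beta0: float
    beta1: float
    r2_corr: float
    r2_paper: float
    lambda_hat: float
    loglik_hat: float
    loglik0: float
    ci_low: float
    ci_high: float
    t_stat: float
    df: int
    p_slope: float
    lrt_stat: float
    p_lambda: float
    h: float
    n: int
    lambda_identifiable: bool = True

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "RMAFit":
        return cls(**d)


def rma_line(ctx: PhyloGLSContext) -> tuple[float, float, float]:
    """RMA slope/intercept and squared evolutionary correlation.

    beta1 = sign(R_xy) sqrt(R_yy / R_xx); the line passes through the GLS
    phylogenetic means.  If R_xy is exactly 0 the slope sign is taken
    positive with a warning (log-morphometric slopes are positive in
    practice).
    """
    R = ctx.R
    if R[0, 0] <= 0 or R[1, 1] <= 0:
        raise ValueError("evolutionary variances must be positive for an RMA line")
    sign = np.sign(R[0, 1])
    if sign == 0:
        warnings.warn(
            "evolutionary covariance is exactly 0; slope sign set positive",
            UserWarning,
            stacklevel=2,
        )
        sign = 1.0
    beta1 = float(sign * np.sqrt(R[1, 1] / R[0, 0]))
    beta0 = float(ctx.a[1] - beta1 * ctx.a[0])
    r2_corr = float(R[0, 1] ** 2 / (R[0, 0] * R[1, 1]))
    return beta0, beta1, r2_corr


def paper_r2(
    x: np.ndarray,
    y: np.ndarray,
    beta0: float,
    beta1: float,
    ss: str = "ordinary",
    C: VCVMatrix | None = None,
) -> float:
    """Goodness of fit R^2 = 1 - SS_residual / SS_total around the RMA line.

    Residuals are e_i = y_i - (beta0 + beta1 x_i).  By default SS_total is
    taken around the ordinary arithmetic mean of y (``ss='ordinary'``);
    ``ss='gls'`` centers on the GLS phylogenetic mean and weights both sums
    by C^-1.  Because the line is not the least-squares line, R^2 can be
    negative for poor fits.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    e = y - (beta0 + beta1 * x)
    if ss == "ordinary":
        ss_res = float(e @ e)
        d = y - y.mean()
        ss_tot = float(d @ d)
    elif ss == "gls":
        if C is None:
            raise ValueError("ss='gls' requires the covariance matrix C")
        cf = _cho_factor(C)
        ybar = gls_mean(C, y[:, None])[0]
        d = y - ybar
        ss_res = float(e @ linalg.cho_solve(cf, e))
        ss_tot = float(d @ linalg.cho_solve(cf, d))
    else:
        raise ValueError("ss must be 'ordinary' or 'gls'")
    if ss_tot <= 0:
        raise ValueError("zero total sum of squares: response has no variation")
    return 1.0 - ss_res / ss_tot


def slope_test(
    beta1: float,
    r2_corr: float,
    n: int,
    h: float = 1.0,
    df: int | None = None,
) -> tuple[float, int, float]:
    """Two-sided SMA t-test of the slope against a predicted exponent h.

    T = |ln|beta1| - ln h| / sqrt((1 - r^2) / df), df = n - 2 by default,
    compared to a Student t distribution.  The statistic is symmetric in
    beta1 <-> 1/beta1 when h = 1 (direction of regression is irrelevant, as
    befits RMA).
    """
    if h <= 0:
        raise ValueError("predicted exponent h must be positive")
    if n < 3:
        raise ValueError("slope test requires n >= 3")
    df = int(n - 2 if df is None else df)
    if df < 1:
        raise ValueError("degrees of freedom must be >= 1")
    delta = abs(np.log(abs(beta1)) - np.log(h))
    if r2_corr >= 1.0:
        if delta == 0.0:
            return 0.0, df, 1.0
        warnings.warn("r^2 = 1 with beta1 != h: degenerate test, p = 0", UserWarning,
                      stacklevel=2)
        return float("inf"), df, 0.0
    t = float(delta / np.sqrt((1.0 - r2_corr) / df))
    p = float(2.0 * stats.t.sf(t, df))
    return t, df, p


def slope_ci(
    beta1: float,
    r2_corr: float,
    n: int,
    alpha: float = 0.05,
    df: int | None = None,
) -> tuple[float, float]:
    """F-based SMA confidence interval for the slope.

    B = F(1 - alpha; 1, df) (1 - r^2) / df;
    CI = beta1 * (sqrt(B + 1) -/+ sqrt(B)).  The interval always contains
    beta1 and satisfies ci_low * ci_high = beta1^2.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n < 3:
        raise ValueError("confidence interval requires n >= 3")
    df = int(n - 2 if df is None else df)
    if r2_corr >= 1.0:
        warnings.warn("r^2 >= 1: degenerate interval [beta1, beta1]", UserWarning,
                      stacklevel=2)
        return float(beta1), float(beta1)
    B = stats.f.ppf(1 - alpha, 1, df) * (1.0 - r2_corr) / df
    root = np.sqrt(B)
    return float(beta1 * (np.sqrt(B + 1) - root)), float(beta1 * (np.sqrt(B + 1) + root))


def lambda_lrt(loglik_hat: float, loglik0: float) -> tuple[float, float]:
    """Likelihood-ratio test of lambda_hat against lambda = 0.

    Delta = 2 (loglik_hat - loglik0), clipped at 0, referred to chi^2 with
    one degree of freedom.  Because lambda = 0 sits on the boundary of the
    parameter space the plain chi^2_1 reference is conservative; see
    ``lambda_lrt_boundary`` for the half-mixture alternative.
    """
    if loglik_hat < loglik0 - 1e-8:
        raise ValueError("loglik_hat below loglik0: lambda optimization failed")
    delta = max(0.0, 2.0 * (loglik_hat - loglik0))
    return delta, float(stats.chi2.sf(delta, 1))


def lambda_lrt_boundary(loglik_hat: float, loglik0: float) -> tuple[float, float]:
    """Boundary-corrected LRT using the 1/2 chi^2_0 + 1/2 chi^2_1 mixture."""
    delta, _ = lambda_lrt(loglik_hat, loglik0)
    p = 1.0 if delta == 0.0 else float(0.5 * stats.chi2.sf(delta, 1))
    return delta, p


def phyl_rma(
    tree: PhyloTree,
    x,
    y,
    h: float = 1.0,
    alpha: float = 0.05,
    fixed_lambda: float | None = None,
    df: int | None = None,
    r2_ss: str = "ordinary",
) -> RMAFit:
    """Fit a phylogenetic RMA regression of trait ``y`` on trait ``x``.

    ``x`` and ``y`` are species-keyed mappings (dict or pandas Series) of
    log10-scale trait values.  The tree is pruned internally to the species
    shared by the tree and both traits (>= 3 required).  lambda is estimated
    jointly on the bivariate data unless ``fixed_lambda`` is given.

    Parameters
    ----------
    h : predicted scaling exponent under the dimensional null (1 for
        length-on-length isometry).
    df : degrees of freedom for the slope test and CI; default n - 2.
    r2_ss : 'ordinary' or 'gls' sums of squares for the goodness-of-fit R^2.
    """
    x = dict(x)
    y = dict(y)
    tips = tree.tips
    shared = [t for t in tips if t in x and t in y]
    if len(shared) < 3:
        missing_x = sorted(set(tips) - set(x))
        missing_y = sorted(set(tips) - set(y))
        raise ValueError(
            f"only {len(shared)} species shared between tree and traits "
            f"(missing from x: {missing_x}; missing from y: {missing_y})"
        )
    sub = tree if len(shared) == len(tips) else prune_to_taxa(tree, shared)
    order = [t for t in sub.tips]
    X = np.column_stack([
        np.array([float(x[t]) for t in order]),
        np.array([float(y[t]) for t in order]),
    ])
    C = vcv_matrix(sub)

    if fixed_lambda is None:
        lam_hat, ll_hat, ll0, identifiable = estimate_lambda(C, X)
    else:
        lam_hat = float(fixed_lambda)
        ll_hat = profile_loglik(lambda_transform(C, lam_hat), X)
        ll0 = profile_loglik(lambda_transform(C, 0.0), X)
        identifiable = True

    C_lam = lambda_transform(C, lam_hat)
    ctx = PhyloGLSContext(C_lam, X)
    beta0, beta1, r2_corr = rma_line(ctx)
    r2 = paper_r2(X[:, 0], X[:, 1], beta0, beta1, ss=r2_ss, C=C_lam)
    t, df_used, p_slope = slope_test(beta1, r2_corr, ctx.n, h=h, df=df)
    lo, hi = slope_ci(beta1, r2_corr, ctx.n, alpha=alpha, df=df)
    lrt, p_lam = lambda_lrt(ll_hat, ll0)
    return RMAFit(
        beta0=beta0,
        beta1=beta1,
        r2_corr=r2_corr,
        r2_paper=r2,
        lambda_hat=lam_hat,
        loglik_hat=ll_hat,
        loglik0=ll0,
        ci_low=lo,
        ci_high=hi,
        t_stat=t,
        df=df_used,
        p_slope=p_slope,
        lrt_stat=lrt,
        p_lambda=p_lam,
        h=float(h),
        n=ctx.n,
        lambda_identifiable=identifiable,
    )
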