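"""Kinship estimation and mixed-model association tests.

Univariate model:  y = mu + x b + u + e,  u ~ N(0, sg2 K), e ~ N(0, se2 I).
Bivariate multi-trait model for an observed and a second (e.g. predicted)
trait:

    [y1; y2] = s1 mu1 + s2 mu2 + x beta + (x o s1) alpha + v

with Cov(v) built from a kinship-structured genetic part (variances sg1^2,
sg2^2, genetic correlation rho_g) and trait-specific residual variances
(se1^2, se2^2, optional residual correlation rho_e when both traits are
scored on the same individuals).  Variance components are estimated once by
REML under the no-marker null and held fixed for all SNP tests
(EMMAX/Korte-style approximation); each marker is then tested by generalized
least squares:

* 'common'  -- beta only vs null, F with 1 numerator df;
* 'full'    -- beta and alpha vs null, F with 2 numerator df.

Denominator df is N_obs minus the fixed-effect count of the larger model.
Monomorphic markers return p = 1 with a flag so ranked lists stay total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .io_core import GenotypeMatrix

__all__ = [
    "KinshipMatrix",
    "UnivariateVC",
    "MTMMFit",
    "SNPTestResult",
    "compute_kinship",
    "fit_null_lmm",
    "test_snp_univariate",
    "fit_mtmm_null",
    "test_snp_mtmm",
    "inflation_factor",
    "write_kinship",
    "read_kinship",
    "scan_univariate",
    "scan_mtmm",
]

_PSD_TOL = 1e-8


@dataclass
class KinshipMatrix:
    """Symmetric PSD marker-based relatedness matrix."""

    values: np.ndarray
    accession_ids: list[str]

    def __post_init__(self) -> None:
        K = np.asarray(self.values, dtype=float)
        if K.shape[0] != K.shape[1] or K.shape[0] != len(self.accession_ids):
            raise ValueError("kinship shape inconsistent with accession ids")
        if not np.allclose(K, K.T, atol=1e-10):
            raise ValueError("kinship not symmetric")
        self.values = (K + K.T) / 2.0
        self._eig: tuple[np.ndarray, np.ndarray] | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached eigendecomposition (eigenvalues clipped at 0)."""
        if self._eig is None:
            w, U = np.linalg.eigh(self.values)
            if w.min() < -_PSD_TOL * max(1.0, w.max()):
                raise ValueError("kinship matrix is not PSD")
            self._eig = (np.clip(w, 0.0, None), U)
        return self._eig

    def sqrt(self) -> np.ndarray:
        """Symmetric matrix square root (eigen-based, accepts singular K)."""
        w, U = self.eig()
        return (U * np.sqrt(w)) @ U.T


def compute_kinship(G: GenotypeMatrix, maf_min: float = 0.0) -> KinshipMatrix:
    """Scaled cross-product kinship K = Z Z'/m from standardized markers.

    Missing calls are mean-imputed per SNP; monomorphic and MAF-filtered
    SNPs are dropped.  K is made PSD by flooring negative eigenvalues at 0
    and rescaled so mean(diag K) = 1.
    """
    X = G.imputed_scores()
    sd = X.std(axis=0)
    maf = G.maf()
    keep = (sd > 0) & (maf >= maf_min)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 polymorphic SNPs after MAF filter")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    K = Z @ Z.T / keep.sum()
    w, U = np.linalg.eigh((K + K.T) / 2.0)
    K = (U * np.clip(w, 0.0, None)) @ U.T
    K = K / np.mean(np.diag(K))
    return KinshipMatrix(K, list(G.accession_ids))


# ---------------------------------------------------------------------------
# univariate LMM


@dataclass
class UnivariateVC:
    """REML variance components of the single-trait null model."""

    sigma_g2: float
    sigma_e2: float
    h2: float
    loglik: float
    boundary: bool = False
    # internal: rotated data reused by per-SNP tests
    _d: np.ndarray | None = None
    _U: np.ndarray | None = None


def _reml_neg_loglik_uni(h2: float, d: np.ndarray, ystar: np.ndarray, Xstar: np.ndarray):
    """Profile REML negative log-likelihood at heritability ratio h2.

    The total variance is profiled out; returns (nll, sigma_p2_hat, beta_hat).
    """
    n, q = Xstar.shape
    w = h2 * d + (1.0 - h2)
    Xw = Xstar / w[:, None]
    A = Xstar.T @ Xw
    b = Xw.T @ ystar
    beta = np.linalg.solve(A, b)
    r = ystar - Xstar @ beta
    quad = float(r @ (r / w))
    sp2 = quad / (n - q)
    sign, logdetA = np.linalg.slogdet(A)
    nll = 0.5 * ((n - q) * np.log(sp2) + np.log(w).sum() + logdetA + (n - q))
    return nll, sp2, beta


def fit_null_lmm(y: np.ndarray, K: KinshipMatrix, n_grid: int = 64) -> UnivariateVC:
    """REML fit of the no-marker univariate mixed model.

    One spectral decomposition of K, then a 1-D profile-likelihood search
    over h2 = sg2/(sg2+se2) (grid + bounded refinement).  Boundary estimates
    (h2 of 0 or 1) are flagged, not errors.
    """
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise ValueError("y must be complete on the analysis set")
    d, U = K.eig()
    ystar = U.T @ y
    Xstar = U.T @ np.ones((len(y), 1))

    eps = 1e-6
    grid = np.linspace(eps, 1 - eps, n_grid)
    vals = np.array([_reml_neg_loglik_uni(h, d, ystar, Xstar)[0] for h in grid])
    i = int(np.argmin(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, n_grid - 1)]
    res = optimize.minimize_scalar(
        lambda h: _reml_neg_loglik_uni(h, d, ystar, Xstar)[0],
        bounds=(lo, hi), method="bounded", options={"xatol": 1e-8},
    )
    h2 = float(res.x)
    nll, sp2, _ = _reml_neg_loglik_uni(h2, d, ystar, Xstar)
    boundary = h2 < 1e-4 or h2 > 1 - 1e-4
    fit = UnivariateVC(
        sigma_g2=h2 * sp2, sigma_e2=(1 - h2) * sp2, h2=h2, loglik=-nll,
        boundary=boundary, _d=d, _U=U,
    )
    return fit


@dataclass
class SNPTestResult:
    """Per-SNP association result (univariate and/or bivariate fields)."""

    snp_id: str = ""
    beta_common: float = np.nan
    alpha_specific: float = np.nan
    stat_common: float = np.nan
    p_common: float = np.nan
    stat_full: float = np.nan
    p_full: float = np.nan
    df_denom: int = 0
    monomorphic: bool = False
    # univariate
    beta_uni: float = np.nan
    stat_uni: float = np.nan
    p_uni: float = np.nan


def test_snp_univariate(
    y: np.ndarray,
    x: np.ndarray,
    K: KinshipMatrix,
    vc: UnivariateVC,
    snp_id: str = "",
    exact: bool = False,
    distribution: str = "f",
) -> SNPTestResult:
    """GLS F-test of a marker with covariance sg2 K + se2 I held at the null
    estimates.  Two-sided; a constant marker yields p = 1 with a flag.
    ``exact=True`` re-estimates h2 with the marker in the fixed effects;
    ``distribution='chi2'`` gives the 1-df chi-square p instead of F.
    """
    x = np.asarray(x, dtype=float)
    if np.all(x == x[0]):
        return SNPTestResult(snp_id=snp_id, p_uni=1.0, stat_uni=0.0, monomorphic=True)
    if vc._d is None:
        d, U = K.eig()
    else:
        d, U = vc._d, vc._U
    if exact:
        ystar = U.T @ y
        Xstar = U.T @ np.column_stack([np.ones_like(y), x])
        grid = np.linspace(1e-6, 1 - 1e-6, 64)
        vals = [_reml_neg_loglik_uni(h, d, ystar, Xstar)[0] for h in grid]
        i = int(np.argmin(vals))
        res = optimize.minimize_scalar(
            lambda h: _reml_neg_loglik_uni(h, d, ystar, Xstar)[0],
            bounds=(grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]),
            method="bounded", options={"xatol": 1e-8},
        )
        h2 = float(res.x)
    else:
        h2 = vc.h2
    w = h2 * d + (1.0 - h2)
    sw = np.sqrt(w)
    yt = (U.T @ y) / sw
    ones = (U.T @ np.ones_like(y)) / sw
    xt = (U.T @ x) / sw
    X0 = ones[:, None]
    X1 = np.column_stack([ones, xt])
    rss0 = _ols_rss(X0, yt)
    rss1, beta = _ols_rss(X1, yt, return_coef=True)
    n = len(y)
    dfd = n - 2
    F = max(rss0 - rss1, 0.0) / (rss1 / dfd)
    if distribution == "chi2":
        p = float(stats.chi2.sf(F, 1))
    elif distribution == "f":
        p = float(stats.f.sf(F, 1, dfd))
    else:
        raise ValueError(f"unknown test distribution {distribution!r}")
    return SNPTestResult(
        snp_id=snp_id, beta_uni=float(beta[1]), stat_uni=float(F),
        p_uni=max(p, np.finfo(float).tiny), df_denom=dfd,
    )


def _ols_rss(X, y, return_coef=False):
    coef, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if res.size:
        rss = float(res[0])
    else:
        r = y - X @ coef
        rss = float(r @ r)
    if return_coef:
        return rss, coef
    return rss


# ---------------------------------------------------------------------------
# bivariate MTMM


@dataclass
class MTMMFit:
    """REML variance components of the bivariate no-marker null model."""

    mu1: float
    mu2: float
    sigma_g1_2: float
    sigma_g2_2: float
    rho_g: float
    sigma_e1_2: float
    sigma_e2_2: float
    rho_e: float | None
    loglik: float
    converged: bool
    degenerate: bool = False
    n_obs: int = 0
    # bookkeeping for the SNP tests
    _mode: str = "fast"
    _d: np.ndarray | None = None
    _U: np.ndarray | None = None
    _obs1: np.ndarray | None = None  # boolean masks over accessions
    _obs2: np.ndarray | None = None
    _y1: np.ndarray | None = None
    _y2: np.ndarray | None = None
    _K: KinshipMatrix | None = None
    _Linv: np.ndarray | None = None  # dense-mode whitener

    def genetic_covariance_psd(self, tol: float = 1e-8) -> bool:
        """Check the implied 2n x 2n covariance of v is PSD."""
        Vg = np.array(
            [
                [self.sigma_g1_2, self.rho_g * np.sqrt(self.sigma_g1_2 * self.sigma_g2_2)],
                [self.rho_g * np.sqrt(self.sigma_g1_2 * self.sigma_g2_2), self.sigma_g2_2],
            ]
        )
        re = self.rho_e or 0.0
        Ve = np.array(
            [
                [self.sigma_e1_2, re * np.sqrt(self.sigma_e1_2 * self.sigma_e2_2)],
                [re * np.sqrt(self.sigma_e1_2 * self.sigma_e2_2), self.sigma_e2_2],
            ]
        )
        d, _ = self._K.eig() if self._K is not None else (np.array([1.0]), None)
        for dd in (float(d.min()), float(d.max())):
            w = np.linalg.eigvalsh(dd * Vg + Ve)
            if w.min() < -tol * max(1.0, w.max()):
                return False
        return True


def _theta_to_params(theta, include_rho_e):
    sg1, sg2, se1, se2 = np.exp(theta[:4])
    rg = np.tanh(theta[4])
    re = np.tanh(theta[5]) if include_rho_e else 0.0
    return sg1, sg2, rg, se1, se2, re


def _mtmm_nll_fast(theta, d, z1, z2, u1, include_rho_e):
    """REML negative log-likelihood, complete-overlap case.

    After rotating both traits by the eigenvectors of K the 2n x 2n system
    factorizes into n independent 2 x 2 blocks C_i = d_i Vg + Ve.
    """
    sg1, sg2, rg, se1, se2, re = _theta_to_params(theta, include_rho_e)
    a = d * sg1 + se1
    c = d * sg2 + se2
    b = d * rg * np.sqrt(sg1 * sg2) + re * np.sqrt(se1 * se2)
    det = a * c - b * b
    if np.any(det <= 0) or np.any(a <= 0):
        return np.inf
    # C^{-1} entries
    ia, ic, ib = c / det, a / det, -b / det
    quad = ia * z1 * z1 + 2 * ib * z1 * z2 + ic * z2 * z2
    # fixed effects X_i = u1_i * I2  ->  A = sum u1_i^2 C_i^{-1}
    u2 = u1 * u1
    A11 = float(np.sum(u2 * ia))
    A22 = float(np.sum(u2 * ic))
    A12 = float(np.sum(u2 * ib))
    b1 = float(np.sum(u1 * (ia * z1 + ib * z2)))
    b2 = float(np.sum(u1 * (ib * z1 + ic * z2)))
    detA = A11 * A22 - A12 * A12
    if detA <= 0:
        return np.inf
    quad_beta = (A22 * b1 * b1 - 2 * A12 * b1 * b2 + A11 * b2 * b2) / detA
    nll = 0.5 * (np.log(det).sum() + np.log(detA) + quad.sum() - quad_beta)
    return float(nll)


def _mtmm_build_dense(theta, K, obs1, obs2, include_rho_e):
    sg1, sg2, rg, se1, se2, re = _theta_to_params(theta, include_rho_e)
    Kv = K.values
    K11 = Kv[np.ix_(obs1, obs1)]
    K22 = Kv[np.ix_(obs2, obs2)]
    K12 = Kv[np.ix_(obs1, obs2)]
    cg = rg * np.sqrt(sg1 * sg2)
    n1, n2 = obs1.sum(), obs2.sum()
    V = np.block([[sg1 * K11, cg * K12], [cg * K12.T, sg2 * K22]])
    V[np.arange(n1), np.arange(n1)] += se1
    V[n1 + np.arange(n2), n1 + np.arange(n2)] += se2
    if include_rho_e and re != 0.0:
        ids1 = np.where(obs1)[0]
        ids2 = np.where(obs2)[0]
        pos2 = {a: j for j, a in enumerate(ids2)}
        ce = re * np.sqrt(se1 * se2)
        for i, a in enumerate(ids1):
            j = pos2.get(a)
            if j is not None:
                V[i, n1 + j] += ce
                V[n1 + j, i] += ce
    return V


def _mtmm_nll_dense(theta, K, y1o, y2o, obs1, obs2, include_rho_e, X_extra=None):
    """REML negative log-likelihood on the N_obs-sized stacked system."""
    V = _mtmm_build_dense(theta, K, obs1, obs2, include_rho_e)
    n1, n2 = obs1.sum(), obs2.sum()
    X = np.zeros((n1 + n2, 2))
    X[:n1, 0] = 1.0
    X[n1:, 1] = 1.0
    if X_extra is not None:
        X = np.column_stack([X, X_extra])
    y = np.concatenate([y1o, y2o])
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return np.inf
    sol = np.linalg.solve
    from scipy.linalg import solve_triangular

    yw = solve_triangular(L, y, lower=True)
    Xw = solve_triangular(L, X, lower=True)
    A = Xw.T @ Xw
    bvec = Xw.T @ yw
    try:
        beta = sol(A, bvec)
    except np.linalg.LinAlgError:
        return np.inf
    r = yw - Xw @ beta
    logdetV = 2.0 * np.log(np.diag(L)).sum()
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf
    return float(0.5 * (logdetV + logdetA + r @ r))


_START_GRID = [
    (h2, rg) for h2 in (0.3, 0.7) for rg in (-0.6, 0.0, 0.5, 0.9)
]


def fit_mtmm_null(
    y1: np.ndarray,
    y2: np.ndarray,
    K: KinshipMatrix,
    include_rho_e: bool = False,
    method: str = "auto",
    gtol: float = 1e-6,
    marker: np.ndarray | None = None,
) -> MTMMFit:
    """REML fit of the bivariate no-marker null model.

    ``y1`` and ``y2`` are aligned to ``K.accession_ids``; NaN marks an
    accession on which that trait is not scored (disjoint or partially
    overlapping designs are allowed).  ``include_rho_e`` adds the residual
    correlation, valid only when the overlap is non-empty; the default
    excludes it, which is the appropriate choice when the second trait is a
    deterministic function of environmental data.

    Optimization is quasi-Newton on (log variances, atanh correlations) from
    a fixed 8-point start grid over heritability and genetic correlation, so
    fits are deterministic.  ``method='fast'`` (complete overlap only) uses
    the spectral 2x2-block factorization; ``'dense'`` builds the N_obs
    system explicitly; ``'auto'`` picks fast when possible.
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    obs1, obs2 = ~np.isnan(y1), ~np.isnan(y2)
    if not obs1.any() or not obs2.any():
        raise ValueError("each trait needs at least one observation")
    overlap = obs1 & obs2
    if include_rho_e and not overlap.any():
        raise ValueError("rho_e requested but the two traits share no accessions")
    complete = bool(obs1.all() and obs2.all())
    if marker is not None:
        # exact per-SNP variance components: the marker (common + trait-1
        # specific columns) joins the fixed effects of the REML fit
        method = "dense"
    if method == "auto":
        method = "fast" if complete else "dense"
    if method == "fast" and not complete:
        raise ValueError("fast path requires both traits complete")

    v1 = float(np.var(y1[obs1]))
    v2 = float(np.var(y2[obs2]))
    if v1 == 0 or v2 == 0:
        raise ValueError("a trait is constant; variance components unidentifiable")

    if method == "fast":
        d, U = K.eig()
        z1 = U.T @ (y1 - 0.0)
        z2 = U.T @ (y2 - 0.0)
        u1 = U.T @ np.ones(len(y1))
        nll = lambda th: _mtmm_nll_fast(th, d, z1, z2, u1, include_rho_e)
    else:
        y1o, y2o = y1[obs1], y2[obs2]
        X_extra = None
        if marker is not None:
            x = np.asarray(marker, dtype=float)
            X_extra = np.column_stack(
                [
                    np.concatenate([x[obs1], x[obs2]]),
                    np.concatenate([x[obs1], np.zeros(int(obs2.sum()))]),
                ]
            )
        nll = lambda th: _mtmm_nll_dense(
            th, K, y1o, y2o, obs1, obs2, include_rho_e, X_extra
        )

    starts = []
    for h2, rg in _START_GRID:
        th0 = [
            np.log(max(h2 * v1, 1e-8)), np.log(max(h2 * v2, 1e-8)),
            np.log(max((1 - h2) * v1, 1e-8)), np.log(max((1 - h2) * v2, 1e-8)),
            np.arctanh(rg),
        ]
        if include_rho_e:
            th0.append(np.arctanh(0.0))
        starts.append(np.asarray(th0))
    # screen the fixed grid, polish the three most promising starts
    screened = sorted(starts, key=lambda th: nll(th))[:3]
    bounds = [(-12, 12)] * 4 + [(-6, 6)] * (len(starts[0]) - 4)
    best = None
    for th0 in screened:
        res = optimize.minimize(
            nll, th0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": gtol * 1e-2, "gtol": 1e-7, "maxiter": 400},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("MTMM REML optimization failed from every start")

    sg1, sg2, rg, se1, se2, re = _theta_to_params(best.x, include_rho_e)

    # GLS means at the optimum
    if method == "fast":
        mu1, mu2 = _mtmm_means_fast(best.x, d, z1, z2, u1, include_rho_e)
    else:
        mu1, mu2 = _mtmm_means_dense(best.x, K, y1[obs1], y2[obs2], obs1, obs2, include_rho_e)

    r12 = np.corrcoef(y1[overlap], y2[overlap])[0, 1] if overlap.sum() > 2 else 0.0
    degenerate = bool(overlap.sum() > 2 and abs(r12) > 0.9999)

    fit = MTMMFit(
        mu1=mu1, mu2=mu2, sigma_g1_2=sg1, sigma_g2_2=sg2, rho_g=rg,
        sigma_e1_2=se1, sigma_e2_2=se2, rho_e=(re if include_rho_e else None),
        loglik=-float(best.fun), converged=bool(best.success or best.fun < np.inf),
        degenerate=degenerate, n_obs=int(obs1.sum() + obs2.sum()), _mode=method,
        _obs1=obs1, _obs2=obs2, _y1=y1, _y2=y2, _K=K,
    )
    if method == "fast":
        fit._d, fit._U = d, U
    else:
        V = _mtmm_build_dense(best.x, K, obs1, obs2, include_rho_e)
        fit._Linv = np.linalg.cholesky(V)
    if not fit.genetic_covariance_psd():
        raise RuntimeError("fitted MTMM covariance not PSD")
    return fit


def _mtmm_means_fast(theta, d, z1, z2, u1, include_rho_e):
    sg1, sg2, rg, se1, se2, re = _theta_to_params(theta, include_rho_e)
    a = d * sg1 + se1
    c = d * sg2 + se2
    b = d * rg * np.sqrt(sg1 * sg2) + re * np.sqrt(se1 * se2)
    det = a * c - b * b
    ia, ic, ib = c / det, a / det, -b / det
    u2 = u1 * u1
    A = np.array(
        [[np.sum(u2 * ia), np.sum(u2 * ib)], [np.sum(u2 * ib), np.sum(u2 * ic)]]
    )
    bb = np.array(
        [np.sum(u1 * (ia * z1 + ib * z2)), np.sum(u1 * (ib * z1 + ic * z2))]
    )
    mu = np.linalg.solve(A, bb)
    return float(mu[0]), float(mu[1])


def _mtmm_means_dense(theta, K, y1o, y2o, obs1, obs2, include_rho_e):
    from scipy.linalg import solve_triangular

    V = _mtmm_build_dense(theta, K, obs1, obs2, include_rho_e)
    n1, n2 = obs1.sum(), obs2.sum()
    X = np.zeros((n1 + n2, 2))
    X[:n1, 0] = 1.0
    X[n1:, 1] = 1.0
    L = np.linalg.cholesky(V)
    yw = solve_triangular(L, np.concatenate([y1o, y2o]), lower=True)
    Xw = solve_triangular(L, X, lower=True)
    mu, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    return float(mu[0]), float(mu[1])


def _whiten_mtmm(fit: MTMMFit):
    """Return whitened (y, s1, s2, x-builder) for GLS at the null covariance."""
    obs1, obs2 = fit._obs1, fit._obs2
    if fit._mode == "fast":
        d, U = fit._d, fit._U
        sg1, sg2, rg = fit.sigma_g1_2, fit.sigma_g2_2, fit.rho_g
        se1, se2 = fit.sigma_e1_2, fit.sigma_e2_2
        re = fit.rho_e or 0.0
        a = d * sg1 + se1
        c = d * sg2 + se2
        b = d * rg * np.sqrt(sg1 * sg2) + re * np.sqrt(se1 * se2)
        # per-block 2x2 inverse Cholesky: C = [[a,b],[b,c]]
        # L = [[sqrt(a),0],[b/sqrt(a), sqrt(c-b^2/a)]]; whiten z -> L^{-1} z
        sa = np.sqrt(a)
        l21 = b / sa
        l22 = np.sqrt(np.maximum(c - l21 * l21, 1e-300))

        def whiten(v1, v2):
            w1 = v1 / sa
            w2 = (v2 - l21 * w1) / l22
            return np.concatenate([w1, w2])

        z1 = U.T @ fit._y1
        z2 = U.T @ fit._y2
        ones = U.T @ np.ones(len(fit._y1))
        zero = np.zeros_like(ones)
        yw = whiten(z1, z2)
        s1w = whiten(ones, zero)
        s2w = whiten(zero, ones)

        def xw(x):
            xr = U.T @ np.asarray(x, dtype=float)
            return whiten(xr, xr), whiten(xr, zero)

        return yw, s1w, s2w, xw
    else:
        from scipy.linalg import solve_triangular

        L = fit._Linv
        n1, n2 = obs1.sum(), obs2.sum()
        y = np.concatenate([fit._y1[obs1], fit._y2[obs2]])
        s1 = np.concatenate([np.ones(n1), np.zeros(n2)])
        s2 = 1.0 - s1
        W = lambda v: solve_triangular(L, v, lower=True)
        yw, s1w, s2w = W(y), W(s1), W(s2)

        def xw(x):
            x = np.asarray(x, dtype=float)
            xs = np.concatenate([x[obs1], x[obs2]])
            xs1 = np.concatenate([x[obs1], np.zeros(n2)])
            return W(xs), W(xs1)

        return yw, s1w, s2w, xw


def test_snp_mtmm(
    fit: MTMMFit,
    x: np.ndarray,
    snp_id: str = "",
    exact: bool = False,
    distribution: str = "f",
) -> SNPTestResult:
    """'common' (1 df) and 'full' (2 df) GLS F-tests of one marker.

    ``x`` is the per-accession marker vector; it is propagated to both trait
    blocks of the stacked system as in the model equation.  ``exact=True``
    re-estimates the variance components with the marker in the fixed
    effects (slower; intended for small marker panels) instead of reusing
    the null estimates.  ``distribution='chi2'`` returns likelihood-ratio-
    style chi-square p-values instead of finite-sample F p-values.
    """
    if exact:
        refit = fit_mtmm_null(
            fit._y1, fit._y2, fit._K,
            include_rho_e=fit.rho_e is not None, marker=x,
        )
        return test_snp_mtmm(refit, x, snp_id=snp_id, distribution=distribution)
    if fit.degenerate:
        raise ValueError(
            "MTMM fit is degenerate (the two traits are numerically identical); "
            "bivariate tests are not meaningful"
        )
    x = np.asarray(x, dtype=float)
    used = fit._obs1 | fit._obs2
    if np.all(x[used] == x[used][0]):
        return SNPTestResult(snp_id=snp_id, p_common=1.0, p_full=1.0,
                             stat_common=0.0, stat_full=0.0, monomorphic=True)
    yw, s1w, s2w, xw = _whiten_mtmm(fit)
    xcw, xs1w = xw(x)
    X0 = np.column_stack([s1w, s2w])
    X1 = np.column_stack([s1w, s2w, xcw])
    X2 = np.column_stack([s1w, s2w, xcw, xs1w])
    rss0 = _ols_rss(X0, yw)
    rss1, b1 = _ols_rss(X1, yw, return_coef=True)
    rss2, b2 = _ols_rss(X2, yw, return_coef=True)
    N = fit.n_obs
    df1 = N - 3
    df2 = N - 4
    F1 = max(rss0 - rss1, 0.0) / (rss1 / df1)
    F2 = (max(rss0 - rss2, 0.0) / 2.0) / (rss2 / df2)
    tiny = np.finfo(float).tiny
    if distribution == "chi2":
        p1 = float(stats.chi2.sf(F1, 1))
        p2 = float(stats.chi2.sf(2.0 * F2, 2))
    elif distribution == "f":
        p1 = float(stats.f.sf(F1, 1, df1))
        p2 = float(stats.f.sf(F2, 2, df2))
    else:
        raise ValueError(f"unknown test distribution {distribution!r}")
    return SNPTestResult(
        snp_id=snp_id,
        beta_common=float(b1[2]), alpha_specific=float(b2[3]),
        stat_common=float(F1), p_common=max(p1, tiny),
        stat_full=float(F2), p_full=max(p2, tiny),
        df_denom=df2,
    )


# ---------------------------------------------------------------------------
# scans and diagnostics


def scan_univariate(y, G: GenotypeMatrix, K: KinshipMatrix, maf_min: float = 0.0):
    """Univariate mixed-model scan over all SNPs; returns a DataFrame."""
    import pandas as pd

    vc = fit_null_lmm(np.asarray(y, dtype=float), K)
    X = G.imputed_scores()
    maf = G.maf()
    rows = []
    for j, sid in enumerate(G.snp_ids):
        if maf[j] < maf_min or np.all(X[:, j] == X[0, j]):
            rows.append((sid, G.chrom[j], G.pos[j], np.nan, np.nan, 1.0, True))
            continue
        r = test_snp_univariate(y, X[:, j], K, vc, snp_id=sid)
        rows.append((sid, G.chrom[j], G.pos[j], r.beta_uni, r.stat_uni, r.p_uni, r.monomorphic))
    return pd.DataFrame(
        rows, columns=["snp_id", "chrom", "pos", "beta", "stat", "p", "flag_monomorphic"]
    )


def scan_mtmm(y1, y2, G: GenotypeMatrix, K: KinshipMatrix,
              include_rho_e: bool = False, maf_min: float = 0.0):
    """Bivariate MTMM scan (common and full tests) over all SNPs."""
    import pandas as pd

    fit = fit_mtmm_null(y1, y2, K, include_rho_e=include_rho_e)
    X = G.imputed_scores()
    maf = G.maf()
    rows = []
    for j, sid in enumerate(G.snp_ids):
        if maf[j] < maf_min or np.all(X[:, j] == X[0, j]):
            rows.append((sid, G.chrom[j], G.pos[j], np.nan, np.nan, 1.0, 1.0, True))
            continue
        r = test_snp_mtmm(fit, X[:, j], snp_id=sid)
        rows.append(
            (sid, G.chrom[j], G.pos[j], r.beta_common, r.alpha_specific,
             r.p_common, r.p_full, r.monomorphic)
        )
    return pd.DataFrame(
        rows,
        columns=["snp_id", "chrom", "pos", "beta_common", "alpha_specific",
                 "p_common", "p_full", "flag_monomorphic"],
    )


def write_kinship(K: KinshipMatrix, path: str) -> None:
    """Write K as a delimited square matrix with accession ids on both axes."""
    import pandas as pd

    pd.DataFrame(K.values, index=K.accession_ids, columns=K.accession_ids).to_csv(path)


def read_kinship(path: str) -> KinshipMatrix:
    import pandas as pd

    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("kinship row and column accession ids differ")
    return KinshipMatrix(df.to_numpy(dtype=float), [str(a) for a in df.index])


def inflation_factor(p_values: np.ndarray):
    """Genomic inflation factor lambda_GC with QQ coordinates.

    lambda_GC = median of the 1-df chi-square quantiles of the p-values,
    divided by the null median (~0.4549).  Returns (lambda, qq) where qq is
    a (expected, observed) -log10 pair array sorted ascending.
    """
    p = np.asarray(p_values, dtype=float)
    if len(p) < 100:
        raise ValueError("need at least 100 p-values")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, df=1)
    lam = float(np.median(chi) / stats.chi2.isf(0.5, df=1))
    ps = np.sort(p)
    expected = -np.log10((np.arange(1, len(ps) + 1) - 0.5) / len(ps))[::-1]
    observed = -np.log10(ps)[::-1]
    return lam, np.column_stack([expected[::-1], observed[::-1]])
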