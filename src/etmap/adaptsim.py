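"""Generative simulator for environmentally driven adaptive traits.

A structured population (four subpopulations by default, emulating a
Eurasian accession panel) provides genotypes and a marker-based kinship
matrix K.  Each replicate then draws:

1. a latent "true" environment X_T (n x k), whose columns carry polygenic
   components: (G_env, G_trait) is matrix-variate normal with row covariance
   K and column covariance V_G, and X_T = G_env + E_env with iid residuals
   so each environmental variable has heritability ``env_h2``;
2. observed environments X_O = X_T + noise, calibrated so that
   corr(X_T_j, X_O_j) = ``r_obs``;
3. an environmental gradient y_T = X_T(S) beta over a random subset S of
   ``s_grad`` variables, with coefficients uniform on [-1, 1];
4. a causal SNP whose allele frequency follows the logistic map
   f = exp(lam * y_T) / (1 + exp(lam * y_T)) (one allele drawn per
   accession), or Bernoulli(0.5) in the non-adaptive mode;
5. an observed phenotype y_O = beta_snp * g + G_trait + E_trait with the
   SNP, polygenic and residual components holding prescribed variance
   fractions (beta_snp is scaled by the realized variance of g).

``run_power_experiment`` wraps the whole pipeline: per replicate it fits the
environment -> trait predictions, runs uni- and bivariate tests at the causal
SNP only, and aggregates exceedance fractions over -log10(p) thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .io_core import GenotypeMatrix
from .relatedness import (
    KinshipMatrix,
    compute_kinship,
    fit_mtmm_null,
    fit_null_lmm,
    test_snp_mtmm,
    test_snp_univariate,
)
from . import envpredict as ep

__all__ = [
    "SimulationScenario",
    "SimulatedWorld",
    "PowerTable",
    "make_structured_population",
    "build_genetic_covariance",
    "simulate_true_environment",
    "observe_environment",
    "simulate_gradient_and_snp",
    "simulate_phenotype",
    "simulate_world",
    "run_power_experiment",
]

ETM_METHODS = ("etm_corrvar", "etm_lm", "etm_en", "etm_rf", "etm_cca")
ALL_METHODS = ("univariate",) + ETM_METHODS + ("univariate_predicted",)


@dataclass
class SimulationScenario:
    """One simulation condition.

    Defaults reproduce the main study condition: 300 accessions in four
    subpopulations (100/100/50/50), 30 environmental variables of
    heritability 0.5 observed with correlation 0.8 to their true values, a
    10-variable gradient, trait heritability 0.5 with the causal SNP
    explaining 5% of phenotypic variance, logistic steepness 3.
    """

    n_per_pop: tuple[int, ...] = (100, 100, 50, 50)
    k_env: int = 30
    s_grad: int = 10
    env_h2: float = 0.5
    r_obs: float = 0.8
    rho_within: float = 0.5
    rho_trait_env: float = 0.0
    trait_h2: float = 0.5
    v_snp: float = 0.05
    lam: float = 3.0
    snp_mode: str = "adaptive"  # or "random"
    m_snps: int = 3000
    divergence: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s_grad > self.k_env:
            raise ValueError("s_grad cannot exceed k_env")
        if self.v_snp > self.trait_h2:
            raise ValueError("SNP variance fraction cannot exceed trait heritability")
        for r in (self.rho_within, self.rho_trait_env):
            if not -1 <= r <= 1:
                raise ValueError("correlations must lie in [-1, 1]")
        if self.snp_mode not in ("adaptive", "random"):
            raise ValueError(f"unknown snp_mode {self.snp_mode!r}")

    @property
    def n(self) -> int:
        return int(sum(self.n_per_pop))

    @property
    def poly_frac(self) -> float:
        return self.trait_h2 - self.v_snp

    @property
    def resid_frac(self) -> float:
        return 1.0 - self.trait_h2


@dataclass
class SimulatedWorld:
    """One replicate of the generative model."""

    X_T: np.ndarray
    X_O: np.ndarray
    S: np.ndarray
    beta_grad: np.ndarray
    y_T: np.ndarray
    f: np.ndarray
    g: np.ndarray
    G_env: np.ndarray
    E_env: np.ndarray
    G_trait: np.ndarray
    E_trait: np.ndarray
    y_O: np.ndarray
    V_G: np.ndarray
    beta_snp: float
    monomorphic_snp: bool


@dataclass
class PowerTable:
    """Exceedance fractions of -log10(p) at the causal SNP."""

    table: pd.DataFrame  # method, test, threshold, power, reps, se
    neglogp: pd.DataFrame  # per-replicate -log10 p, columns method:test

    def power(self, method: str, test: str, threshold: float) -> float:
        t = self.table
        row = t[(t.method == method) & (t.test == test) & (t.threshold == threshold)]
        return float(row["power"].iloc[0])


def make_structured_population(
    n_per_pop=(100, 100, 50, 50), m_snps: int = 3000,
    divergence: float = 0.4, seed: int = 0,
) -> tuple[GenotypeMatrix, KinshipMatrix]:
    """Balding-Nichols-style structured haploid genotypes plus kinship.

    Ancestral allele frequencies are uniform on (0.1, 0.9); each
    subpopulation's frequency is Beta-distributed around the ancestral value
    with divergence parameter F (variance F p(1-p)); haploid alleles are
    then drawn per accession.
    """
    if len(n_per_pop) < 2:
        raise ValueError("need at least 2 subpopulations")
    if divergence <= 0:
        raise ValueError("divergence must be positive")
    rng = np.random.default_rng(seed)
    n = int(sum(n_per_pop))
    p_anc = rng.uniform(0.1, 0.9, size=m_snps)
    a = p_anc * (1 - divergence) / divergence
    b = (1 - p_anc) * (1 - divergence) / divergence
    scores = np.empty((n, m_snps))
    row = 0
    for npop in n_per_pop:
        p_sub = rng.beta(a, b)
        scores[row : row + npop] = rng.binomial(1, p_sub, size=(npop, m_snps))
        row += npop
    acc = [f"acc{i:04d}" for i in range(n)]
    G = GenotypeMatrix(
        acc, [f"snp{j:05d}" for j in range(m_snps)],
        np.array(["1"] * m_snps, dtype=object), np.arange(1, m_snps + 1) * 100,
        scores, coding="01",
    )
    K = compute_kinship(G)
    return G, K


def population_labels(n_per_pop) -> np.ndarray:
    return np.repeat(np.arange(len(n_per_pop)), n_per_pop)


def build_genetic_covariance(sc: SimulationScenario) -> np.ndarray:
    """(k+1) x (k+1) genetic covariance of (G_env, G_trait).

    Columns 0..s-1 are the gradient set S, columns s..k-1 its complement,
    column k the trait.  Within S and within the complement the genetic
    correlation is ``rho_within``; across the two blocks it is zero.  The
    trait is correlated ``rho_trait_env`` with the S columns only.  Env
    genetic variances equal ``env_h2``; the trait's equals its polygenic
    variance fraction.
    """
    k, s = sc.k_env, sc.s_grad
    R = np.eye(k + 1)
    R[:s, :s] = sc.rho_within
    R[s:k, s:k] = sc.rho_within
    np.fill_diagonal(R, 1.0)
    R[:s, k] = R[k, :s] = sc.rho_trait_env
    w = np.linalg.eigvalsh(R)
    if w.min() < -1e-10:
        raise ValueError("requested correlation structure is not PSD")
    scale = np.sqrt(np.concatenate([np.full(k, sc.env_h2), [max(sc.poly_frac, 0.0)]]))
    return R * np.outer(scale, scale)


def _sym_sqrt(M: np.ndarray) -> np.ndarray:
    w, U = np.linalg.eigh((M + M.T) / 2.0)
    return (U * np.sqrt(np.clip(w, 0.0, None))) @ U.T


def simulate_true_environment(
    K: KinshipMatrix, V_G: np.ndarray, env_h2: float, rng: np.random.Generator,
    L_K: np.ndarray | None = None,
):
    """Draw (G_env, G_trait) matrix-variate normal and compose X_T.

    Matrix square roots are symmetric eigen-based so a singular K is
    accepted.  Returns (X_T, G_env, E_env, G_trait).
    """
    n = K.n
    k = V_G.shape[0] - 1
    if L_K is None:
        L_K = K.sqrt()
    L_V = _sym_sqrt(V_G)
    Z = rng.standard_normal((n, k + 1))
    Gm = L_K @ Z @ L_V.T
    G_env, G_trait = Gm[:, :k], Gm[:, k]
    E_env = rng.normal(0.0, np.sqrt(1.0 - env_h2), size=(n, k))
    X_T = G_env + E_env
    return X_T, G_env, E_env, G_trait


def observe_environment(X_T: np.ndarray, r_obs: float, rng: np.random.Generator) -> np.ndarray:
    """Add measurement noise so corr(true, observed) = r_obs per column."""
    if not 0 < r_obs <= 1:
        raise ValueError("r_obs must lie in (0, 1]")
    if r_obs == 1.0:
        return X_T.copy()
    var = X_T.var(axis=0) * (1.0 / r_obs**2 - 1.0)
    return X_T + rng.normal(0.0, np.sqrt(var), size=X_T.shape)


def simulate_gradient_and_snp(
    X_T: np.ndarray, S: np.ndarray, lam: float, snp_mode: str, rng: np.random.Generator
):
    """Gradient coefficients, latent adaptive trait, allele frequencies, SNP."""
    beta = rng.uniform(-1.0, 1.0, size=len(S))
    y_T = X_T[:, S] @ beta
    f = expit(lam * y_T)
    if snp_mode == "adaptive":
        g = rng.binomial(1, f).astype(float)
    else:
        g = rng.binomial(1, 0.5, size=len(y_T)).astype(float)
    return beta, y_T, f, g


def simulate_phenotype(
    g: np.ndarray, G_trait: np.ndarray, sc: SimulationScenario, rng: np.random.Generator
):
    """Observed phenotype with prescribed variance fractions.

    The SNP effect is scaled by the realized sample variance of g so its
    variance share holds per replicate; a monomorphic draw gets effect 0 and
    a flag.  Returns (y_O, E_trait, beta_snp, monomorphic).
    """
    vg = float(np.var(g, ddof=1)) if len(g) > 1 else 0.0
    mono = vg == 0.0
    beta_snp = 0.0 if mono else float(np.sqrt(sc.v_snp / vg))
    E_trait = rng.normal(0.0, np.sqrt(sc.resid_frac), size=len(g))
    y_O = beta_snp * g + G_trait + E_trait
    return y_O, E_trait, beta_snp, mono


def simulate_world(
    sc: SimulationScenario, K: KinshipMatrix, rng: np.random.Generator,
    L_K: np.ndarray | None = None, V_G: np.ndarray | None = None,
) -> SimulatedWorld:
    """One full replicate draw.

    The gradient set S is drawn uniformly per replicate; the canonical
    column order of V_G (S first) is mapped onto the drawn indices.
    """
    if V_G is None:
        V_G = build_genetic_covariance(sc)
    X_Tc, G_envc, E_envc, G_trait = simulate_true_environment(
        K, V_G, sc.env_h2, rng, L_K=L_K
    )
    # place canonical columns: first s columns of the draw -> random subset S
    S = np.sort(rng.choice(sc.k_env, size=sc.s_grad, replace=False))
    perm = np.empty(sc.k_env, dtype=int)
    perm[S] = np.arange(sc.s_grad)
    perm[np.setdiff1d(np.arange(sc.k_env), S)] = np.arange(sc.s_grad, sc.k_env)
    X_T, G_env, E_env = X_Tc[:, perm], G_envc[:, perm], E_envc[:, perm]
    X_O = observe_environment(X_T, sc.r_obs, rng)
    beta, y_T, f, g = simulate_gradient_and_snp(X_T, S, sc.lam, sc.snp_mode, rng)
    y_O, E_trait, beta_snp, mono = simulate_phenotype(g, G_trait, sc, rng)
    return SimulatedWorld(
        X_T=X_T, X_O=X_O, S=S, beta_grad=beta, y_T=y_T, f=f, g=g,
        G_env=G_env, E_env=E_env, G_trait=G_trait, E_trait=E_trait, y_O=y_O,
        V_G=V_G, beta_snp=beta_snp, monomorphic_snp=mono,
    )


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (v - v.mean(axis=0)) / sd


def _predict_trait(method: str, y: np.ndarray, X: np.ndarray, seed: int) -> np.ndarray:
    """Fit one prediction method on standardized data; return y_hat."""
    if method == "etm_corrvar":
        r = np.array([abs(np.corrcoef(X[:, j], y)[0, 1]) for j in range(X.shape[1])])
        return X[:, int(np.argmax(r))].copy()
    tag = method.split("_", 1)[1]
    model = ep.fit_prediction(tag, y, X, seed=seed)
    return model.fitted_values


def run_power_experiment(
    sc: SimulationScenario,
    methods=("univariate", "etm_cca"),
    tests=("common",),
    thresholds=(4.0, 5.0, 6.0),
    n_reps: int = 500,
    seed: int = 0,
    population: tuple[GenotypeMatrix, KinshipMatrix] | None = None,
    progress: bool = False,
) -> PowerTable:
    """Monte-Carlo power of each method/test at the causal SNP.

    The population (genotypes + kinship) is held fixed across replicates;
    each replicate uses a reproducible substream of ``seed``.  Replicates
    with a constant trait prediction fall back to the univariate p-value, as
    do bivariate tests for both 'common' and 'full'.
    """
    for m in methods:
        if m not in ALL_METHODS:
            raise ValueError(f"unknown method {m!r}")
    for t in tests:
        if t not in ("common", "full"):
            raise ValueError(f"unknown test {t!r}")
    if population is None:
        population = make_structured_population(
            sc.n_per_pop, sc.m_snps, sc.divergence, seed=sc.seed
        )
    _, K = population
    L_K = K.sqrt()
    V_G = build_genetic_covariance(sc)
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(n_reps)

    cols: dict[str, list[float]] = {}
    for rep in range(n_reps):
        rng = np.random.default_rng(child[rep])
        world = simulate_world(sc, K, rng, L_K=L_K, V_G=V_G)
        y = _standardize(world.y_O)
        X = _standardize(world.X_O)
        g = world.g
        mseed = int(rng.integers(2**31))  # per-replicate substream for CV folds / bootstraps

        vc = fit_null_lmm(y, K)
        res_uni = test_snp_univariate(y, g, K, vc)
        p_uni = res_uni.p_uni
        cols.setdefault("univariate:common", []).append(p_uni)

        for m in methods:
            if m == "univariate":
                continue
            if m == "univariate_predicted":
                # single-trait mapping on the (CCA) predicted trait alone
                yhat = _predict_trait("etm_cca", y, X, seed=mseed)
                if ep.is_constant_prediction(yhat):
                    p = p_uni
                else:
                    yh = _standardize(yhat)
                    p = test_snp_univariate(yh, g, K, fit_null_lmm(yh, K)).p_uni
                cols.setdefault(f"{m}:common", []).append(p)
                continue
            yhat = _predict_trait(m, y, X, seed=mseed)
            if ep.is_constant_prediction(yhat):
                for t in tests:
                    cols.setdefault(f"{m}:{t}", []).append(p_uni)
                continue
            fit = fit_mtmm_null(y, _standardize(yhat), K, include_rho_e=False)
            r = test_snp_mtmm(fit, g)
            for t in tests:
                cols.setdefault(f"{m}:{t}", []).append(
                    r.p_common if t == "common" else r.p_full
                )
        if progress and (rep + 1) % 50 == 0:
            print(f"  replicate {rep + 1}/{n_reps}")

    neglogp = pd.DataFrame({k: -np.log10(np.asarray(v)) for k, v in cols.items()})
    rows = []
    for m in methods:
        for t in tests if m not in ("univariate", "univariate_predicted") else ("common",):
            key = f"{m}:{t}"
            if key not in neglogp:
                continue
            v = neglogp[key].to_numpy()
            for thr in thresholds:
                pw = float(np.mean(v >= thr))
                rows.append(
                    (m, t, float(thr), pw, len(v), float(np.sqrt(pw * (1 - pw) / len(v))))
                )
    table = pd.DataFrame(rows, columns=["method", "test", "threshold", "power", "reps", "se"])
    # power must be non-increasing in threshold
    for (m, t), grp in table.groupby(["method", "test"]):
        p = grp.sort_values("threshold")["power"].to_numpy()
        assert np.all(np.diff(p) <= 1e-12), "power not monotone in threshold"
    return PowerTable(table=table, neglogp=neglogp)
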