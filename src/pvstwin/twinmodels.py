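"""Maximum-likelihood twin variance-component (ACE) models.

The classical twin design decomposes the phenotypic variance of paired
relatives into additive genetic (A), shared-environment (C) and
unique-environment (E) components using the different genetic relatedness of
monozygotic twins (r_A = 1) and dizygotic twins / nontwin siblings
(r_A = 0.5); C loads identically within every pair. With path coefficients
a, c, e the implied covariance of a pair is

    Var       = a^2 + c^2 + e^2
    Cov(pair) = r_A a^2 + c^2

and narrow-sense heritability is h^2 = a^2 / (a^2 + c^2 + e^2). Models are
fitted by maximizing the sum of bivariate-normal log densities over pairs
(4-variate for the two-trait Cholesky model), with group-specific r_A and a
single free mean per trait. Nested AE / CE / E submodels support
likelihood-ratio tests and AIC comparison.

The bivariate Cholesky parameterization uses lower-triangular path matrices
L_A, L_C, L_E (diagonals constrained nonnegative, cross paths free in sign),
so the implied component covariances A = L_A L_A', C, E are positive
semidefinite by construction. From the genetic paths,

    genetic correlation   r_g = a12 / sqrt(a12^2 + a22^2)
    shared heritability       = |a11 a12| / (|a11 a12| + |c11 c12| + |e11 e12|)

the latter using absolute values so it is a proportion of summed factor
contributions even when cross paths are negative (the signed ratio is also
reported when it differs).

Everything is computed from per-group sufficient statistics (n, sum, scatter)
so that a fit costs well under a millisecond per likelihood evaluation;
optimization is bounded quasi-Newton (L-BFGS-B) from a moment-based
(Falconer) start plus fixed-seed random restarts. Confidence intervals are
profile-likelihood by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .phenotype import AdjustedCohort

__all__ = [
    "ACEFit",
    "CholeskyFit",
    "ModelComparison",
    "pair_covariance_uni",
    "pair_covariance_biv",
    "pairs_by_group",
    "falconer_estimates",
    "fit_univariate",
    "compare_models",
    "fit_bivariate",
    "genetic_correlation",
    "shared_heritability",
    "confidence_interval",
]

RELATEDNESS = {"MZ": 1.0, "DZ": 0.5, "NT": 0.5}
_MODELS = ("ACE", "AE", "CE", "E")
_START_SEED = 20200908  # fixed so fits are deterministic given the data


# ---------------------------------------------------------------------------
# implied pair covariances
# ---------------------------------------------------------------------------

def pair_covariance_uni(a: float, c: float, e: float, r_A: float) -> np.ndarray:
    """2x2 implied covariance of a pair: diag a^2+c^2+e^2, off-diag r_A a^2 + c^2."""
    v = a**2 + c**2 + e**2
    cov = r_A * a**2 + c**2
    return np.array([[v, cov], [cov, v]])


def _check_lower(L, name: str) -> np.ndarray:
    L = np.asarray(L, dtype=float)
    if L.shape != (2, 2) or L[0, 1] != 0:
        raise ValueError(f"{name} must be 2x2 lower triangular")
    if L[0, 0] < 0 or L[1, 1] < 0:
        raise ValueError(f"{name} diagonal must be nonnegative")
    return L


def pair_covariance_biv(L_A, L_C, L_E, r_A: float) -> np.ndarray:
    """4x4 implied covariance, ordered (m1 trait1, m1 trait2, m2 trait1, m2 trait2).

    Within-person block A + C + E; cross-person block r_A A + C. Symmetric PSD
    by construction.
    """
    A = _check_lower(L_A, "L_A") @ np.asarray(L_A).T
    C = _check_lower(L_C, "L_C") @ np.asarray(L_C).T
    E = _check_lower(L_E, "L_E") @ np.asarray(L_E).T
    W = A + C + E
    X = r_A * A + C
    return np.block([[W, X], [X, W]])


# ---------------------------------------------------------------------------
# data plumbing and sufficient statistics
# ---------------------------------------------------------------------------

def pairs_by_group(cohort, traits) -> dict[str, np.ndarray]:
    """Wide per-pair arrays keyed by zygosity group.

    For k traits, rows are (m1 t1..tk, m2 t1..tk). Pairs with any missing
    trait value are dropped (count available via the returned arrays' sizes).
    """
    df = cohort.data if isinstance(cohort, AdjustedCohort) else cohort
    traits = [traits] if isinstance(traits, str) else list(traits)
    out = {}
    for group, gdf in df.groupby("group"):
        rows = []
        for _, fam in gdf.groupby("family_id"):
            if len(fam) != 2:
                raise ValueError(f"family with {len(fam)} members in group {group}")
            fam = fam.sort_values("member")
            vals = fam[traits].to_numpy(dtype=float).reshape(-1)
            if np.all(np.isfinite(vals)):
                rows.append(vals)
        if rows:
            out[group] = np.asarray(rows)
    unknown = set(out) - set(RELATEDNESS)
    if unknown:
        raise ValueError(f"unknown zygosity groups {sorted(unknown)}")
    return out


def _suffstats(pairs: dict[str, np.ndarray]) -> dict[str, tuple]:
    stats_ = {}
    for g, x in pairs.items():
        stats_[g] = (len(x), x.sum(axis=0), x.T @ x)
    return stats_


def _group_loglik(sigma: np.ndarray, mu: np.ndarray, stat) -> float:
    n, s, S0 = stat
    d = len(mu)
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return -np.inf
    M = S0 - np.outer(s, mu) - np.outer(mu, s) + n * np.outer(mu, mu)
    return -0.5 * (n * d * np.log(2 * np.pi) + n * logdet + np.trace(np.linalg.solve(sigma, M)))


# ---------------------------------------------------------------------------
# univariate fits
# ---------------------------------------------------------------------------

@dataclass
class ACEFit:
    """Fitted univariate twin model."""

    model: str
    a: float
    c: float
    e: float
    mu: float
    loglik: float
    n_pairs: dict
    converged: bool
    _stats: dict = field(repr=False, default=None)

    @property
    def a2(self) -> float:
        return self.a**2

    @property
    def c2(self) -> float:
        return self.c**2

    @property
    def e2(self) -> float:
        return self.e**2

    @property
    def variance(self) -> float:
        return self.a2 + self.c2 + self.e2

    @property
    def h2(self) -> float:
        return self.a2 / self.variance

    @property
    def n_free(self) -> int:
        return {"ACE": 4, "AE": 3, "CE": 3, "E": 2}[self.model]

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_free


def falconer_estimates(pairs: dict[str, np.ndarray]) -> tuple[float, float, float]:
    """Moment (Falconer) estimates of (a^2, c^2, e^2) on the variance scale.

    From pooled within-pair correlations: a^2 = 2 (r_MZ - r_0.5),
    c^2 = 2 r_0.5 - r_MZ, e^2 = 1 - r_MZ, each times the pooled variance and
    clipped to be nonnegative. Used as an optimizer start and as an
    independent oracle in tests.
    """
    allv = np.concatenate([x.reshape(-1) for x in pairs.values()])
    V = float(allv.var())

    def _corr(groups):
        xs = [pairs[g] for g in groups if g in pairs]
        if not xs:
            return 0.0
        x = np.concatenate(xs)
        # double-entered so the estimate is exchangeable in member order
        x = np.vstack([x, x[:, ::-1]])
        return float(np.corrcoef(x[:, 0], x[:, 1])[0, 1])

    r_mz = _corr(["MZ"])
    r_half = _corr(["DZ", "NT"])
    a2 = max(2.0 * (r_mz - r_half), 0.0) * V
    c2 = max(2.0 * r_half - r_mz, 0.0) * V
    e2 = max(V - a2 - c2, 0.05 * V)
    return a2, c2, e2


def _uni_negloglik(theta, model, stats_, relatedness):
    a = theta[0] if "A" in model else 0.0
    c = theta[1] if "C" in model else 0.0
    e, mu = theta[2], theta[3]
    ll = 0.0
    for g, stat in stats_.items():
        sigma = pair_covariance_uni(a, c, e, relatedness[g])
        ll += _group_loglik(sigma, np.array([mu, mu]), stat)
    return -ll if np.isfinite(ll) else 1e12


def fit_univariate(cohort, trait: str, model: str = "ACE", relatedness=None) -> ACEFit:
    """ML fit of an ACE/AE/CE/E model to one trait.

    Requires at least two groups with distinct r_A for the ACE model to be
    identified. Deterministic: multi-start from the Falconer moment estimate
    plus five fixed-seed random restarts.
    """
    if model not in _MODELS:
        raise ValueError(f"model must be one of {_MODELS}")
    relatedness = relatedness or RELATEDNESS
    pairs = cohort if isinstance(cohort, dict) else pairs_by_group(cohort, trait)
    if model == "ACE" and len({relatedness[g] for g in pairs}) < 2:
        raise ValueError("ACE needs groups with distinct relatedness (identifiability)")
    stats_ = _suffstats(pairs)
    a2, c2, e2 = falconer_estimates(pairs)
    allv = np.concatenate([x.reshape(-1) for x in pairs.values()])
    mu0, V = float(allv.mean()), float(allv.var())
    ub = 10.0 * max(np.sqrt(V), 1.0)
    bounds = [(0.0, ub), (0.0, ub), (1e-4, ub), (None, None)]
    starts = [np.array([np.sqrt(a2), np.sqrt(c2), np.sqrt(e2), mu0])]
    rng = np.random.default_rng(_START_SEED)
    for _ in range(5):
        frac = rng.dirichlet(np.ones(3)) * V
        starts.append(np.array([*np.sqrt(frac), mu0 + rng.normal(scale=0.1)]))
    best = None
    for x0 in starts:
        res = optimize.minimize(
            _uni_negloglik, x0, args=(model, stats_, relatedness),
            method="L-BFGS-B", bounds=bounds,
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    a = abs(best.x[0]) if "A" in model else 0.0
    c = abs(best.x[1]) if "C" in model else 0.0
    return ACEFit(
        model=model, a=a, c=c, e=abs(best.x[2]), mu=float(best.x[3]),
        loglik=-float(best.fun), n_pairs={g: len(x) for g, x in pairs.items()},
        converged=bool(best.success), _stats={"stats": stats_, "relatedness": relatedness},
    )


@dataclass
class ModelComparison:
    """Fits of the nested model ladder with LRTs against the full ACE model."""

    fits: dict

    _NESTED = {("ACE", "AE"), ("ACE", "CE"), ("ACE", "E"), ("AE", "E"), ("CE", "E")}

    def lrt(self, full: str = "ACE", reduced: str = "CE") -> tuple[float, int, float]:
        """(statistic, df, p) for a nested likelihood-ratio test.

        Boundary null values (variance components at 0) use the naive
        chi-square reference, which is conservative.
        """
        if (full, reduced) not in self._NESTED:
            raise ValueError(f"{reduced} is not nested in {full} (use AIC instead)")
        lf, lr = self.fits[full], self.fits[reduced]
        stat = max(0.0, 2.0 * (lf.loglik - lr.loglik))
        df = lf.n_free - lr.n_free
        return stat, df, float(stats.chi2.sf(stat, df))

    @property
    def aic(self) -> dict:
        return {m: f.aic for m, f in self.fits.items()}


def compare_models(cohort, trait: str, models=_MODELS) -> ModelComparison:
    return ModelComparison({m: fit_univariate(cohort, trait, m) for m in models})


# ---------------------------------------------------------------------------
# bivariate Cholesky model
# ---------------------------------------------------------------------------

@dataclass
class CholeskyFit:
    """Fitted bivariate Cholesky ACE model."""

    L_A: np.ndarray
    L_C: np.ndarray
    L_E: np.ndarray
    means: np.ndarray
    loglik: float
    n_pairs: dict
    converged: bool
    _stats: dict = field(repr=False, default=None)

    @property
    def A(self) -> np.ndarray:
        return self.L_A @ self.L_A.T

    @property
    def C(self) -> np.ndarray:
        return self.L_C @ self.L_C.T

    @property
    def E(self) -> np.ndarray:
        return self.L_E @ self.L_E.T

    @property
    def n_free(self) -> int:
        return 11  # 9 paths + 2 means

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_free

    @property
    def r_g(self) -> float:
        return genetic_correlation(self)

    @property
    def shared_h2(self) -> float:
        return shared_heritability(self)


def genetic_correlation(fit: CholeskyFit) -> float:
    """r_g = a12 / sqrt(a12^2 + a22^2); nan when both cross paths vanish.

    Equals the correlation implied by A = L_A L_A' (A12 / sqrt(A11 A22))
    whenever a11 > 0.
    """
    a12, a22 = fit.L_A[1, 0], fit.L_A[1, 1]
    denom = np.hypot(a12, a22)
    if denom == 0:
        return float("nan")
    return float(a12 / denom)


def shared_heritability(fit: CholeskyFit, signed: bool = False) -> float:
    """Genetic share of the cross-trait contribution, on absolute path products.

    |a11 a12| / (|a11 a12| + |c11 c12| + |e11 e12|); with signed=True the raw
    ratio a11a12 / (a11a12 + c11c12 + e11e12) is returned instead.
    """
    pa = fit.L_A[0, 0] * fit.L_A[1, 0]
    pc = fit.L_C[0, 0] * fit.L_C[1, 0]
    pe = fit.L_E[0, 0] * fit.L_E[1, 0]
    if signed:
        denom = pa + pc + pe
        return float(pa / denom) if denom != 0 else float("nan")
    denom = abs(pa) + abs(pc) + abs(pe)
    if denom == 0:
        return float("nan")
    return float(abs(pa) / denom)


def _theta_to_L(theta):
    a11, a12, a22, c11, c12, c22, e11, e12, e22 = theta[:9]
    L_A = np.array([[a11, 0.0], [a12, a22]])
    L_C = np.array([[c11, 0.0], [c12, c22]])
    L_E = np.array([[e11, 0.0], [e12, e22]])
    return L_A, L_C, L_E


def _biv_negloglik(theta, stats_, relatedness):
    L_A, L_C, L_E = _theta_to_L(theta)
    mu = np.tile(theta[9:11], 2)
    ll = 0.0
    for g, stat in stats_.items():
        sigma = pair_covariance_biv(L_A, L_C, L_E, relatedness[g])
        ll += _group_loglik(sigma, mu, stat)
    return -ll if np.isfinite(ll) else 1e12


def fit_bivariate(cohort, traits, relatedness=None, n_restarts: int = 5) -> CholeskyFit:
    """ML fit of the 2-trait Cholesky ACE model (9 paths + 2 means).

    Diagonal paths are bounded nonnegative; cross paths are free in sign (the
    data can genuinely prefer negative cross paths). Deterministic multi-start.
    """
    relatedness = relatedness or RELATEDNESS
    pairs = cohort if isinstance(cohort, dict) else pairs_by_group(cohort, traits)
    stats_ = _suffstats(pairs)
    allx = np.concatenate([x for x in pairs.values()])
    persons = np.vstack([allx[:, :2], allx[:, 2:]])
    mu0 = persons.mean(axis=0)
    v1, v2 = persons.var(axis=0)
    ub = 10.0 * max(np.sqrt(max(v1, v2)), 1.0)
    bounds = [
        (0.0, ub), (-ub, ub), (0.0, ub),   # L_A
        (0.0, ub), (-ub, ub), (0.0, ub),   # L_C
        (1e-4, ub), (-ub, ub), (1e-4, ub),  # L_E
        (None, None), (None, None),
    ]
    # moment start: equal thirds per component, small cross paths
    s1, s2 = np.sqrt(v1 / 3.0), np.sqrt(v2 / 3.0)
    starts = [np.array([s1, 0.1 * s2, s2, s1, 0.1 * s2, s2, s1, 0.1 * s2, s2, *mu0])]
    rng = np.random.default_rng(_START_SEED + 1)
    for _ in range(n_restarts):
        pert = starts[0].copy()
        pert[:9] *= rng.uniform(0.3, 1.7, size=9)
        pert[[1, 4, 7]] += rng.normal(scale=0.2 * s2, size=3)
        starts.append(pert)
    best = None
    for x0 in starts:
        res = optimize.minimize(
            _biv_negloglik, x0, args=(stats_, relatedness),
            method="L-BFGS-B", bounds=bounds, options={"maxiter": 500},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("bivariate fit failed to converge from any start")
    L_A, L_C, L_E = _theta_to_L(best.x)
    return CholeskyFit(
        L_A=L_A, L_C=L_C, L_E=L_E, means=np.asarray(best.x[9:11]),
        loglik=-float(best.fun), n_pairs={g: len(x) for g, x in pairs.items()},
        converged=bool(best.success), _stats={"stats": stats_, "relatedness": relatedness},
    )


# ---------------------------------------------------------------------------
# profile-likelihood confidence intervals
# ---------------------------------------------------------------------------

def _profile_uni_h2(fit: ACEFit, t: float) -> float:
    """Max loglik with h^2 fixed at t, over (V, c-share u, mu)."""
    stats_ = fit._stats["stats"]
    rel = fit._stats["relatedness"]

    def nll(phi):
        V, u, mu = phi
        a = np.sqrt(max(t * V, 0.0))
        c = np.sqrt(max(u * (1.0 - t) * V, 0.0))
        e = np.sqrt(max((1.0 - u) * (1.0 - t) * V, 1e-8))
        return _uni_negloglik(np.array([a, c, e, mu]), "ACE", stats_, rel)

    V0 = max(fit.variance, 1e-6)
    u0 = fit.c2 / max(fit.c2 + fit.e2, 1e-12)
    res = optimize.minimize(
        nll, np.array([V0, min(max(u0, 1e-4), 1 - 1e-4), fit.mu]),
        method="L-BFGS-B", bounds=[(1e-6, None), (0.0, 1.0 - 1e-6), (None, None)],
    )
    return -float(res.fun)


def _profile_biv(fit: CholeskyFit, quantity: str, q: float) -> float:
    """Max loglik with r_g or shared h^2 constrained to q (SLSQP)."""
    stats_ = fit._stats["stats"]
    rel = fit._stats["relatedness"]

    def gfun(theta):
        L_A, L_C, L_E = _theta_to_L(theta)
        f = CholeskyFit(L_A, L_C, L_E, theta[9:11], 0.0, {}, True)
        val = genetic_correlation(f) if quantity == "r_g" else shared_heritability(f)
        return (0.0 if np.isnan(val) else val) - q

    x0 = np.array([
        fit.L_A[0, 0], fit.L_A[1, 0], fit.L_A[1, 1],
        fit.L_C[0, 0], fit.L_C[1, 0], fit.L_C[1, 1],
        fit.L_E[0, 0], fit.L_E[1, 0], fit.L_E[1, 1],
        *fit.means,
    ])
    ub = 10.0
    bounds = [
        (0.0, ub), (-ub, ub), (0.0, ub),
        (0.0, ub), (-ub, ub), (0.0, ub),
        (1e-4, ub), (-ub, ub), (1e-4, ub),
        (None, None), (None, None),
    ]
    res = optimize.minimize(
        _biv_negloglik, x0, args=(stats_, rel), method="SLSQP", bounds=bounds,
        constraints=[{"type": "eq", "fun": gfun}], options={"maxiter": 300, "ftol": 1e-9},
    )
    return -float(res.fun)


def confidence_interval(fit, quantity: str = "h2", level: float = 0.95) -> tuple[float, float]:
    """Profile-likelihood interval for h2 (univariate) or r_g / shared_h2 (bivariate).

    The set of values whose profile deviance 2(loglik_max - loglik_profile)
    stays below the chi-square(1) quantile, found by bisection on each side
    and clipped to the quantity's natural range. Estimates at a range
    boundary yield one-sided intervals.
    """
    crit = stats.chi2.ppf(level, 1)
    if isinstance(fit, ACEFit):
        if quantity != "h2":
            raise ValueError("univariate fits support only the h2 interval")
        point = fit.h2
        lo_bound, hi_bound = 0.0, 1.0
        profile = lambda t: _profile_uni_h2(fit, t)
    elif isinstance(fit, CholeskyFit):
        if quantity == "r_g":
            point, lo_bound, hi_bound = genetic_correlation(fit), -1.0, 1.0
        elif quantity == "shared_h2":
            point, lo_bound, hi_bound = shared_heritability(fit), 0.0, 1.0
        else:
            raise ValueError("bivariate fits support 'r_g' or 'shared_h2'")
        profile = lambda q: _profile_biv(fit, quantity, q)
    else:
        raise TypeError("fit must be an ACEFit or CholeskyFit")

    llmax = fit.loglik

    def deviance(q):
        return 2.0 * (llmax - profile(q)) - crit

    eps = 1e-6

    def _search(bound):
        q_edge = bound + eps if bound < point else bound - eps
        if abs(point - bound) < eps or deviance(q_edge) <= 0:
            return bound  # one-sided: boundary inside the interval
        lo, hi = (q_edge, point) if bound < point else (point, q_edge)
        # deviance is ~0 at the MLE and positive at the edge; bisect the crossing
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if deviance(mid) > 0:
                if bound < point:
                    lo = mid
                else:
                    hi = mid
            else:
                if bound < point:
                    hi = mid
                else:
                    lo = mid
            if hi - lo < 1e-4:
                break
        return lo if bound < point else hi

    return _search(lo_bound), _search(hi_bound)


def bootstrap_interval(
    cohort, trait_or_traits, quantity: str = "h2", level: float = 0.95,
    n_boot: int = 1000, seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap over families (alternative to the profile interval)."""
    pairs = pairs_by_group(cohort, trait_or_traits)
    rng = np.random.default_rng(seed)
    vals = []
    univariate = quantity == "h2"
    for _ in range(n_boot):
        resampled = {g: x[rng.integers(len(x), size=len(x))] for g, x in pairs.items()}
        if univariate:
            vals.append(fit_univariate(resampled, trait_or_traits).h2)
        else:
            f = fit_bivariate(resampled, trait_or_traits)
            vals.append(genetic_correlation(f) if quantity == "r_g" else shared_heritability(f))
    alpha = (1.0 - level) / 2.0
    return tuple(np.quantile(vals, [alpha, 1.0 - alpha]))
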