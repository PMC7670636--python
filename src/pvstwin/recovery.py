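"""Parameter-recovery experiments for the twin ACE machinery.

These routines simulate cohorts at the study's group sizes (138 MZ / 79 DZ /
133 nontwin-sibling pairs), run the age/sex residual adjustment, fit the
models by maximum likelihood and collect the estimates — the self-contained
stand-in for re-estimating heritability on the restricted-access cohort.
"""

from __future__ import annotations

import numpy as np

from .phenotype import AdjustmentSpec, residualize
from .twinmodels import fit_bivariate, fit_univariate, genetic_correlation
from .twinsim import TwinSimSpec, simulate_twin_cohort

__all__ = ["univariate_recovery", "bivariate_recovery", "replicate_seeds"]


def replicate_seeds(seed: int, n: int) -> np.ndarray:
    """n independent sub-seeds (< 2^31) derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return ss.generate_state(n, dtype=np.uint32).astype(np.int64) % (2**31)


def univariate_recovery(
    a: float, c: float, e: float, n_reps: int = 200, seed: int = 0,
    n_mz: int = 138, n_dz: int = 79, n_nt: int = 133, adjust: bool = True,
) -> np.ndarray:
    """h^2 estimates from ``n_reps`` simulated cohorts with the given paths.

    Each replicate simulates a cohort with age/sex covariate effects,
    residual-adjusts the trait for age and sex (mirroring the study's
    'unadjusted' covariate set) and fits the univariate ACE model by ML.
    """
    h2 = np.empty(n_reps)
    for i, s in enumerate(replicate_seeds(seed, n_reps)):
        spec = TwinSimSpec(
            n_mz=n_mz, n_dz=n_dz, n_nt=n_nt,
            paths_a=a, paths_c=c, paths_e=e, seed=int(s),
        )
        cohort = simulate_twin_cohort(spec)
        if adjust:
            cohort = residualize(cohort, AdjustmentSpec("trait", ("age", "sex"))).data
        h2[i] = fit_univariate(cohort, "trait").h2
    return h2


def bivariate_recovery(
    L_A, L_C, L_E, n_reps: int = 100, seed: int = 0,
    n_mz: int = 138, n_dz: int = 79, n_nt: int = 133, adjust: bool = True,
) -> np.ndarray:
    """Genetic-correlation estimates from bivariate Cholesky ML fits.

    Traits are re-standardized by the residual adjustment before fitting
    (r_g is scale-invariant, so this only mirrors the study's workflow).
    """
    rg = np.empty(n_reps)
    for i, s in enumerate(replicate_seeds(seed, n_reps)):
        spec = TwinSimSpec(
            n_mz=n_mz, n_dz=n_dz, n_nt=n_nt,
            paths_a=L_A, paths_c=L_C, paths_e=L_E, seed=int(s),
        )
        cohort = simulate_twin_cohort(spec)
        if adjust:
            for t in ("trait1", "trait2"):
                cohort = residualize(cohort, AdjustmentSpec(t, ("age", "sex"))).data
        rg[i] = genetic_correlation(fit_bivariate(cohort, ["trait1", "trait2"]))
    return rg
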