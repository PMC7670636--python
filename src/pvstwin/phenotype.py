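"""Phenotype standardization and residual covariate adjustment.

Before heritability modelling, phenotypes and continuous covariates are
z-scored and the phenotype is replaced by the re-standardized residuals of an
ordinary least-squares fit on the chosen covariates, pooling all subjects
(family clustering enters only through the twin models downstream). The named
covariate sets mirror the study's adjustment ladder: unadjusted = age + sex,
partially adjusted adds regional volume or intracranial volume, completely
adjusted adds both; pulse pressure and ethnicity can be appended to any set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["AdjustmentSpec", "AdjustedCohort", "zscore", "residualize", "pulse_pressure"]

ADJUSTMENT_SETS = {
    "unadjusted": ("age", "sex"),
    "partial1": ("age", "sex", "regional_volume"),
    "partial2": ("age", "sex", "icv"),
    "complete": ("age", "sex", "regional_volume", "icv"),
}


def zscore(values) -> np.ndarray:
    """Standardize to mean 0, SD 1 (sample SD, ddof=1). Errors on constant input."""
    x = np.asarray(values, dtype=float)
    # tolerance-based: numerically constant input (e.g. residuals of an exact
    # fit, ~1e-16) must be rejected too
    if x.size < 2 or np.ptp(x) <= 1e-10 * max(1.0, float(np.abs(x).max())):
        raise ValueError("z-score requires at least two distinct values")
    return (x - x.mean()) / x.std(ddof=1)


def pulse_pressure(systolic, diastolic) -> np.ndarray:
    """Pulse pressure = systolic BP - diastolic BP (mmHg)."""
    return np.asarray(systolic, dtype=float) - np.asarray(diastolic, dtype=float)


@dataclass(frozen=True)
class AdjustmentSpec:
    """Which covariates to regress out of which phenotype."""

    phenotype: str
    covariates: tuple[str, ...] = ("age", "sex")
    label: str = ""

    def __post_init__(self) -> None:
        if len(set(self.covariates)) != len(self.covariates):
            raise ValueError("duplicate covariates in adjustment spec")

    @classmethod
    def named(cls, phenotype: str, label: str, **rename) -> "AdjustmentSpec":
        """Build one of the study's named sets; rename maps the placeholder
        column names ('regional_volume', 'icv') to actual cohort columns."""
        cols = tuple(rename.get(c, c) for c in ADJUSTMENT_SETS[label])
        return cls(phenotype, cols, label)


@dataclass
class AdjustedCohort:
    """Cohort with the phenotype replaced by standardized OLS residuals."""

    data: pd.DataFrame
    spec: AdjustmentSpec
    coefficients: pd.Series


def _encode(col: pd.Series) -> np.ndarray:
    """0/1-encode two-level categoricals (sex M/F, ethnicity White/nonWhite)."""
    if col.dtype == object or str(col.dtype) == "category":
        levels = sorted(col.astype(str).unique())
        if len(levels) != 2:
            raise ValueError(f"cannot 0/1-encode column with levels {levels}")
        return (col.astype(str) == levels[1]).to_numpy(dtype=float)
    return col.to_numpy(dtype=float)


def residualize(cohort: pd.DataFrame, spec: AdjustmentSpec) -> AdjustedCohort:
    """OLS residual adjustment with standardized values, then re-standardize.

    The phenotype and every non-binary covariate are z-scored; binary
    covariates are 0/1-coded. The design must be full rank. Deterministic.
    """
    missing = [c for c in (spec.phenotype, *spec.covariates) if c not in cohort.columns]
    if missing:
        raise KeyError(f"cohort table lacks columns {missing}")
    y = zscore(cohort[spec.phenotype].to_numpy(dtype=float))
    cols = []
    for c in spec.covariates:
        x = _encode(cohort[c])
        if np.unique(x).size > 2:
            x = zscore(x)
        cols.append(x)
    X = sm.add_constant(np.column_stack(cols)) if cols else np.ones((len(y), 1))
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design (rank {rank} < {X.shape[1]}); "
            f"check collinearity among {list(spec.covariates)}"
        )
    fit = sm.OLS(y, X).fit()
    resid = fit.resid
    adjusted = zscore(resid)  # errors on an exactly-perfect fit (constant residual)
    out = cohort.copy()
    out[spec.phenotype] = adjusted
    names = ["const", *spec.covariates]
    return AdjustedCohort(out, spec, pd.Series(fit.params, index=names))
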