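"""Simulated twin/sibling cohorts generated from an ACE model.

The classical twin design decomposes a phenotype into additive genetic (A),
shared environment (C) and unique environment (E) latent factors. Within a
pair, A correlates by the genetic relatedness r_A — 1 for monozygotic (MZ)
twins, 0.5 for dizygotic (DZ) twins and nontwin (NT) siblings — C is
identical and E is independent. Univariate traits use scalar path
coefficients a, c, e; bivariate traits use 2x2 lower-triangular Cholesky
path matrices per factor, which guarantees positive-semidefinite implied
covariances.

Cohort layout mirrors the study population this emulates: twins share age
and sex within a pair, nontwin siblings draw independent ages (22-35 years)
and sexes (so roughly half the NT pairs are opposite-sex).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TwinSimSpec", "simulate_twin_cohort", "DEFAULT_RELATEDNESS"]

DEFAULT_RELATEDNESS = {"MZ": 1.0, "DZ": 0.5, "NT": 0.5}


def _as_path(p, name: str) -> np.ndarray:
    """Validate a path coefficient: scalar, or 2x2 lower triangular."""
    arr = np.atleast_2d(np.asarray(p, dtype=float))
    if arr.shape == (1, 1):
        return arr
    if arr.shape != (2, 2):
        raise ValueError(f"path {name} must be a scalar or a 2x2 matrix, got {arr.shape}")
    if arr[0, 1] != 0:
        raise ValueError(f"path matrix {name} must be lower triangular")
    if arr[0, 0] < 0 or arr[1, 1] < 0:
        raise ValueError(f"path matrix {name} must have nonnegative diagonal")
    return arr


@dataclass(frozen=True)
class TwinSimSpec:
    """Generative ACE specification for a twin/sibling cohort.

    Default pair counts are 138 MZ, 79 DZ and 133 NT (700 subjects in 350
    pairs). Path coefficients default to a highly heritable standardized
    trait (a^2 = 0.902). Covariate slopes act on z-scored age and on a 0/1
    male indicator; both effects are modest and independent of A/C/E.
    """

    n_mz: int = 138
    n_dz: int = 79
    n_nt: int = 133
    paths_a: object = 0.9497
    paths_c: object = 0.1414
    paths_e: object = 0.2793
    relatedness: dict = field(default_factory=lambda: dict(DEFAULT_RELATEDNESS))
    covariate_effects: dict = field(default_factory=lambda: {"age": 0.3, "sex": 0.2})
    trait_names: tuple = None
    seed: int = 0

    def __post_init__(self) -> None:
        a = _as_path(self.paths_a, "a")
        c = _as_path(self.paths_c, "c")
        e = _as_path(self.paths_e, "e")
        if not (a.shape == c.shape == e.shape):
            raise ValueError("paths a, c, e must all be scalar or all 2x2")
        if self.relatedness.get("MZ") != 1.0:
            raise ValueError("MZ relatedness must be 1.0")
        for g in ("DZ", "NT"):
            if self.relatedness.get(g) != 0.5:
                raise ValueError(f"{g} relatedness must be 0.5")
        names = self.trait_names
        if names is None:
            names = ("trait",) if a.shape == (1, 1) else ("trait1", "trait2")
        if len(names) != a.shape[0]:
            raise ValueError("trait_names length must match path dimensionality")
        object.__setattr__(self, "trait_names", tuple(names))

    @property
    def n_traits(self) -> int:
        return _as_path(self.paths_a, "a").shape[0]


def _latent_pair(rng: np.random.Generator, n_pairs: int, k: int, r: float):
    """Latent factor values for both members with cross-member correlation r.

    Member 2 is r * member1 + sqrt(1-r^2) * independent, giving exact
    correlation r with unit marginal variance (for DZ/NT, A2 = 0.5 A1 +
    sqrt(0.75) Z).
    """
    z1 = rng.normal(size=(n_pairs, k))
    if r == 1.0:
        return z1, z1.copy()
    z2 = r * z1 + np.sqrt(1.0 - r**2) * rng.normal(size=(n_pairs, k))
    return z1, z2


def simulate_twin_cohort(spec: TwinSimSpec) -> pd.DataFrame:
    """Simulate a cohort; returns long-format rows (two per family).

    Columns: family_id, member (1/2), group, age (years), sex ('M'/'F'),
    then one column per trait. Deterministic given spec.seed.
    """
    rng = np.random.default_rng(spec.seed)
    a = _as_path(spec.paths_a, "a")
    c = _as_path(spec.paths_c, "c")
    e = _as_path(spec.paths_e, "e")
    k = a.shape[0]
    beta_age = np.broadcast_to(
        np.atleast_1d(np.asarray(spec.covariate_effects.get("age", 0.0), dtype=float)), (k,)
    )
    beta_sex = np.broadcast_to(
        np.atleast_1d(np.asarray(spec.covariate_effects.get("sex", 0.0), dtype=float)), (k,)
    )

    rows = []
    fam = 0
    for group, n_pairs in (("MZ", spec.n_mz), ("DZ", spec.n_dz), ("NT", spec.n_nt)):
        if n_pairs == 0:
            continue
        r = spec.relatedness[group]
        A1, A2 = _latent_pair(rng, n_pairs, k, r)
        C = rng.normal(size=(n_pairs, k))  # identical within pair
        E1 = rng.normal(size=(n_pairs, k))
        E2 = rng.normal(size=(n_pairs, k))
        if group == "NT":
            ages = rng.integers(22, 36, size=(n_pairs, 2)).astype(float)
            sexes = rng.integers(0, 2, size=(n_pairs, 2))
        else:
            shared_age = rng.integers(22, 36, size=n_pairs).astype(float)
            ages = np.stack([shared_age, shared_age], axis=1)
            shared_sex = rng.integers(0, 2, size=n_pairs)
            sexes = np.stack([shared_sex, shared_sex], axis=1)
        age_z = (ages - 28.5) / 3.6  # cohort is 22-35 years old
        for i in range(n_pairs):
            fam += 1
            for m, (Am, Em) in enumerate(((A1, E1), (A2, E2)), start=1):
                y = (
                    a @ Am[i]
                    + c @ C[i]
                    + e @ Em[i]
                    + beta_age * age_z[i, m - 1]
                    + beta_sex * sexes[i, m - 1]
                )
                row = {
                    "family_id": fam,
                    "member": m,
                    "group": group,
                    "age": ages[i, m - 1],
                    "sex": "M" if sexes[i, m - 1] == 1 else "F",
                }
                for t, name in enumerate(spec.trait_names):
                    row[name] = y[t]
                rows.append(row)
    return pd.DataFrame(rows)
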