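"""Regional dPVS volumetry, ICC reliability, and FP/FN validity fractions.

Volumes are voxel counts times the voxel volume (0.7 mm isotropic voxels give
0.343 mm^3). Agreement between paired measurements — test vs retest scans, or
the two members of a twin pair — is summarized by the intraclass correlation
coefficient from one-way random-effects ANOVA (single measure), which is
invariant to member order within a unit; a two-way absolute-agreement flavor
(ICC(2,1)) is available behind a flag. Validity against ground truth uses
false-positive volume normalized by automated volume and false-negative
volume normalized by truth volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import CandidateSet
from .volume import LabelVolume

__all__ = [
    "RegionalVolumes",
    "AgreementResult",
    "compute_volumes",
    "icc_oneway",
    "icc_twoway_agreement",
    "validity_fractions",
]


@dataclass(frozen=True)
class RegionalVolumes:
    subject_id: str
    bg_dpvs_mm3: float
    wm_dpvs_mm3: float
    voxel_volume_mm3: float


def compute_volumes(
    final: CandidateSet, spacing_mm=None, subject_id: str = ""
) -> RegionalVolumes:
    """Per-region volume: final voxel count x voxel volume."""
    spacing = tuple(spacing_mm) if spacing_mm is not None else final.spacing_mm
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing must be positive")
    vox = float(np.prod(spacing))
    counts = {"WM": 0, "BG": 0}
    for row in final.table.itertuples(index=False):
        counts[row.region] += row.n_voxels
    return RegionalVolumes(
        subject_id=subject_id,
        bg_dpvs_mm3=counts["BG"] * vox,
        wm_dpvs_mm3=counts["WM"] * vox,
        voxel_volume_mm3=vox,
    )


@dataclass(frozen=True)
class AgreementResult:
    icc: float
    n_units: int
    icc_model: str  # 'oneway-single' or 'twoway-agreement'


def _paired(values) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("expected an (n_units, 2) array of paired measurements")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 units")
    return x


def icc_oneway(values) -> AgreementResult:
    """One-way random-effects, single-measure ICC: (MSB - MSW) / (MSB + MSW).

    For k=2 measurements per unit; exchangeable in member order within a unit.
    """
    x = _paired(values)
    n, k = x.shape
    grand = x.mean()
    unit_means = x.mean(axis=1)
    msb = k * ((unit_means - grand) ** 2).sum() / (n - 1)
    msw = ((x - unit_means[:, None]) ** 2).sum() / (n * (k - 1))
    if msb == 0 and msw == 0:
        raise ValueError("ICC undefined: zero between- and within-unit variance")
    icc = (msb - msw) / (msb + (k - 1) * msw)
    return AgreementResult(float(icc), n, "oneway-single")


def icc_twoway_agreement(values) -> AgreementResult:
    """Two-way random-effects absolute-agreement single-measure ICC(2,1)."""
    x = _paired(values)
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_means - grand) ** 2).sum() / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    mse = (resid**2).sum() / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ValueError("ICC undefined: zero total variance")
    return AgreementResult(float((msr - mse) / denom), n, "twoway-agreement")


def validity_fractions(auto, truth) -> tuple[float, float]:
    """(false-positive fraction, false-negative fraction) against ground truth.

    FP = automated volume outside truth / total automated volume;
    FN = truth volume missed / total truth volume. An empty automated set
    makes FP undefined (returned as nan) while FN is still computed, and
    symmetrically for empty truth.
    """
    auto_mask = auto.to_mask() if isinstance(auto, CandidateSet) else np.asarray(auto) > 0
    if isinstance(truth, LabelVolume):
        truth_mask = truth.values == LabelVolume.DPVS
    else:
        truth_mask = np.asarray(truth) > 0
    if auto_mask.shape != truth_mask.shape:
        raise ValueError("automated and truth grids are misaligned")
    n_auto = int(auto_mask.sum())
    n_truth = int(truth_mask.sum())
    fp = float((auto_mask & ~truth_mask).sum() / n_auto) if n_auto else float("nan")
    fn = float((truth_mask & ~auto_mask).sum() / n_truth) if n_truth else float("nan")
    return fp, fn
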