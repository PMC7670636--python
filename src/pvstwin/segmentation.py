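"""Stage 1 of automated dPVS segmentation.

Intensity normalization inside the brain mask, multiscale Hessian-eigenvalue
(Frangi) vesselness for bright tubular structures, thresholding, and
restriction to white-matter / basal-ganglia region masks with 26-connected
component extraction.

The vesselness of a voxel with Hessian eigenvalues |l1| <= |l2| <= |l3| is

    V = (1 - exp(-R_A^2 / 2 alpha^2)) * exp(-R_B^2 / 2 beta^2)
        * (1 - exp(-S^2 / 2 gamma^2))

with R_A = |l2|/|l3| (plate vs line), R_B = |l1|/sqrt(|l2 l3|) (blob), and
S = sqrt(l1^2 + l2^2 + l3^2) (structure strength); the response is zero
wherever l2 > 0 or l3 > 0 (bright-structure polarity). Across scales the
per-voxel maximum is taken.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import ImageVolume, LabelVolume

__all__ = [
    "VesselnessParams",
    "CandidateSet",
    "normalize_intensity",
    "hessian_eigenvalues",
    "vesselness",
    "compute_vesselness",
    "extract_candidates",
]


@dataclass(frozen=True)
class VesselnessParams:
    """Tunable constants of the vesselness filter.

    Scales span the sub-3 mm dPVS diameter range at 0.7 mm voxels. gamma=None
    means adaptive: half the maximum structure strength S over the evaluated
    volume, a common choice when no fixed value is published.
    """

    scales_mm: tuple[float, ...] = (0.7, 1.05, 1.4)
    alpha: float = 0.5
    beta: float = 0.5
    gamma: float | None = None
    threshold: float = 0.10

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.scales_mm):
            raise ValueError("scales must be positive")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be positive (or None for adaptive)")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")


def normalize_intensity(img: ImageVolume, brain_mask) -> ImageVolume:
    """Z-score the image over the brain mask; voxels outside the mask become 0.

    Uses the population (divide-by-n) standard deviation for determinism.
    Raises on a constant (zero-SD) image.
    """
    mask = brain_mask.values > 0 if isinstance(brain_mask, LabelVolume) else np.asarray(brain_mask) > 0
    if mask.shape != img.shape:
        raise ValueError(f"brain mask grid {mask.shape} does not match image grid {img.shape}")
    if not mask.any():
        raise ValueError("brain mask is empty")
    vals = img.values[mask]
    mu, sd = float(vals.mean()), float(vals.std())  # population SD
    if sd == 0:
        raise ValueError("degenerate image: zero intensity standard deviation in brain mask")
    out = np.zeros_like(img.values)
    out[mask] = (vals - mu) / sd
    return ImageVolume(out, img.spacing_mm, img.affine)


def hessian_eigenvalues(img: ImageVolume, scale_mm: float) -> np.ndarray:
    """Ordered Hessian eigenvalues (|l1| <= |l2| <= |l3|) at one smoothing scale.

    Second derivatives are taken in physical (mm) units on the Gaussian-smoothed
    image and scale-normalized by scale^2. Returns an array of shape
    img.shape + (3,).
    """
    spacing = np.asarray(img.spacing_mm)
    if scale_mm < spacing.min():
        raise ValueError(f"scale {scale_mm} mm is below the voxel spacing {spacing.min()} mm")
    sigma_vox = scale_mm / spacing
    smoothed = ndimage.gaussian_filter(img.values, sigma=sigma_vox)
    H = np.empty(img.shape + (3, 3))
    for i in range(3):
        for j in range(i, 3):
            order = [0, 0, 0]
            order[i] += 1
            order[j] += 1
            d = ndimage.gaussian_filter(img.values, sigma=sigma_vox, order=order)
            if i == j:
                # the sampled second-derivative kernel has a small nonzero DC
                # response; remove it so constant volumes map exactly to zero
                n = int(8 * sigma_vox[i] + 3)
                dc = float(
                    ndimage.gaussian_filter1d(np.ones(2 * n + 1), sigma_vox[i], order=2)[n]
                )
                d -= dc * smoothed
            d *= scale_mm**2 / (spacing[i] * spacing[j])
            H[..., i, j] = d
            H[..., j, i] = d
    eigs = np.linalg.eigvalsh(H.reshape(-1, 3, 3))
    order_idx = np.argsort(np.abs(eigs), axis=1)
    eigs = np.take_along_axis(eigs, order_idx, axis=1)
    return eigs.reshape(img.shape + (3,))


def vesselness(eigs: np.ndarray, params: VesselnessParams) -> np.ndarray:
    """Single-scale bright-tube vesselness in [0, 1] from ordered eigenvalues."""
    l1, l2, l3 = eigs[..., 0], eigs[..., 1], eigs[..., 2]
    a1, a2, a3 = np.abs(l1), np.abs(l2), np.abs(l3)
    S2 = l1**2 + l2**2 + l3**2
    gamma = params.gamma
    if gamma is None:
        smax = float(np.sqrt(S2.max())) if S2.size else 0.0
        gamma = 0.5 * smax if smax > 0 else 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        RA2 = np.where(a3 > 0, (a2 / np.where(a3 > 0, a3, 1.0)) ** 2, 0.0)
        prod23 = a2 * a3
        RB2 = np.where(prod23 > 0, a1**2 / np.where(prod23 > 0, prod23, 1.0), 0.0)
    v = (
        (1.0 - np.exp(-RA2 / (2.0 * params.alpha**2)))
        * np.exp(-RB2 / (2.0 * params.beta**2))
        * (1.0 - np.exp(-S2 / (2.0 * gamma**2)))
    )
    # bright tubes on dark background need both principal curvatures negative
    v = np.where((l2 > 0) | (l3 > 0) | (a3 == 0), 0.0, v)
    return v


def compute_vesselness(
    img: ImageVolume, params: VesselnessParams | None = None, brain_mask=None
) -> np.ndarray:
    """Multiscale vesselness: per-voxel maximum of the single-scale responses.

    When gamma is adaptive, the structure-strength normalizer is computed per
    scale over the masked voxels (whole grid if no mask given).
    """
    params = params or VesselnessParams()
    mask = None
    if brain_mask is not None:
        mask = brain_mask.values > 0 if isinstance(brain_mask, LabelVolume) else np.asarray(brain_mask) > 0
    out = np.zeros(img.shape)
    for scale in params.scales_mm:
        eigs = hessian_eigenvalues(img, scale)
        p = params
        if params.gamma is None and mask is not None:
            S = np.sqrt((eigs**2).sum(axis=-1))
            smax = float(S[mask].max())
            p = VesselnessParams(
                scales_mm=params.scales_mm,
                alpha=params.alpha,
                beta=params.beta,
                gamma=0.5 * smax if smax > 0 else 1.0,
                threshold=params.threshold,
            )
        np.maximum(out, vesselness(eigs, p), out=out)
    return out


@dataclass
class CandidateSet:
    """Connected components of voxels flagged as potential dPVS.

    component_labels is 0 where no candidate; positive component ids
    otherwise. The table has one row per component: component_id, region
    ('WM'/'BG'), n_voxels, centroid (voxel indices).
    """

    component_labels: np.ndarray
    table: pd.DataFrame
    spacing_mm: tuple[float, float, float]

    @property
    def n_components(self) -> int:
        return len(self.table)

    @property
    def n_voxels(self) -> int:
        return int((self.component_labels > 0).sum())

    def to_mask(self) -> np.ndarray:
        return self.component_labels > 0

    def voxel_coordinates(self) -> np.ndarray:
        return np.argwhere(self.component_labels > 0)

    def subset(self, keep_ids) -> "CandidateSet":
        keep_ids = set(int(i) for i in keep_ids)
        labels = np.where(np.isin(self.component_labels, list(keep_ids)), self.component_labels, 0)
        table = self.table[self.table["component_id"].isin(keep_ids)].reset_index(drop=True)
        return CandidateSet(labels, table, self.spacing_mm)

    def save(self, mask_path=None, table_path=None, affine=None) -> None:
        if mask_path is not None:
            import nibabel as nib

            aff = affine if affine is not None else np.diag(list(self.spacing_mm) + [1.0])
            nib.save(
                nib.Nifti1Image((self.component_labels > 0).astype(np.uint8), aff),
                str(mask_path),
            )
        if table_path is not None:
            self.table.to_csv(table_path, index=False)


_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def extract_candidates(
    vesselness_field: np.ndarray,
    wm_mask: np.ndarray,
    bg_mask: np.ndarray,
    params: VesselnessParams | None = None,
    spacing_mm: tuple[float, float, float] = (0.7, 0.7, 0.7),
    threshold: float | None = None,
) -> CandidateSet:
    """Threshold the vesselness inside WM|BG and group into 26-connected components.

    Components straddling the WM/BG boundary are tagged by majority vote,
    ties broken toward WM.
    """
    params = params or VesselnessParams()
    thr = params.threshold if threshold is None else float(threshold)
    v = np.asarray(vesselness_field)
    wm = np.asarray(wm_mask) > 0
    bg = np.asarray(bg_mask) > 0
    if wm.shape != v.shape or bg.shape != v.shape:
        raise ValueError("mask grids are misaligned with the vesselness field")
    if (wm & bg).any():
        raise ValueError("WM and BG masks must be disjoint")
    keep = (v > thr) & (wm | bg)
    labels, n = ndimage.label(keep, structure=_STRUCT26)
    rows = []
    if n:
        ids = np.arange(1, n + 1)
        wm_counts = ndimage.sum_labels(wm.astype(np.int64), labels, ids)
        bg_counts = ndimage.sum_labels(bg.astype(np.int64), labels, ids)
        sizes = ndimage.sum_labels(np.ones_like(labels, dtype=np.int64), labels, ids)
        centroids = ndimage.center_of_mass(keep, labels, ids)
        for cid, nw, nb, sz, cen in zip(ids, wm_counts, bg_counts, sizes, centroids):
            region = "WM" if nw >= nb else "BG"  # tie -> WM
            rows.append(
                {
                    "component_id": int(cid),
                    "region": region,
                    "n_voxels": int(sz),
                    "centroid_x": cen[0],
                    "centroid_y": cen[1],
                    "centroid_z": cen[2],
                }
            )
    table = pd.DataFrame(
        rows,
        columns=["component_id", "region", "n_voxels", "centroid_x", "centroid_y", "centroid_z"],
    )
    return CandidateSet(labels.astype(np.int32), table, tuple(spacing_mm))
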