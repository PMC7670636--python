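"""Synthetic 3D T2-like phantoms with tubular dPVS ground truth.

The phantom is a schematic head: an ellipsoidal brain whose outer rind is a
bright CSF-like subarachnoid shell, two deep-grey (basal ganglia) blobs with
adjacent bright ventricles, and a white-matter compartment filling the rest.
Dilated perivascular spaces are rendered as bright capsules (cylinder with
hemispherical caps, diameter < 3 mm) placed entirely inside the WM or BG
compartment. Anatomy is schematic on purpose: the downstream pipeline only
consumes region masks, which are inputs in real data too.

Intensities follow T2 contrast (CSF bright, tissue mid, background dark).
Noise is additive Gaussian — adequate at the high SNR of 3D T2 SPACE — and a
smooth multiplicative bias field emulates coil inhomogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import ImageVolume, LabelVolume

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "generate_retest",
    "segmentation_masks",
    "segmentation_masks_from_labels",
    "render_capsule",
    "capsule_volume_mm3",
]

# label codes
BACKGROUND, WM, BG, DPVS, VENTRICLE, SUBARACHNOID = 0, 1, 2, 3, 4, 5


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic phantom.

    Defaults emulate the 0.7 mm isotropic 3D T2-weighted acquisitions the
    segmentation method targets; tube radii keep every dPVS below the 3 mm
    diameter that defines an MRI-visible dilated perivascular space.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size_mm: float = 0.7
    n_tubes_wm: int = 6
    n_tubes_bg: int = 3
    tube_radius_range_mm: tuple[float, float] = (0.35, 1.4)
    tube_length_range_mm: tuple[float, float] = (4.0, 12.0)
    intensity_tissue: float = 100.0
    intensity_csf: float = 200.0
    intensity_tube: float = 200.0
    noise_sd: float = 5.0
    bias_field_amplitude: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.grid_shape) or self.voxel_size_mm <= 0:
            raise ValueError("grid_shape and voxel_size must be positive")
        r_lo, r_hi = self.tube_radius_range_mm
        if not (0 < r_lo <= r_hi):
            raise ValueError("tube radius range must be positive and ordered")
        if 2.0 * r_hi >= 3.0:
            raise ValueError(
                f"max tube diameter {2 * r_hi:g} mm violates the dPVS definition (< 3 mm)"
            )
        if self.n_tubes_wm < 0 or self.n_tubes_bg < 0:
            raise ValueError("tube counts must be nonnegative")


@dataclass
class PhantomTruth:
    """Phantom image plus ground-truth labels and per-region dPVS volume."""

    image: ImageVolume
    labels: LabelVolume
    true_dpvs_volume_mm3: dict[str, float]
    spec: PhantomSpec
    # noise-free, bias-free intensity render used by generate_retest
    clean: np.ndarray = field(repr=False, default=None)
    # 0 = not dPVS, 1 = tube placed in WM, 2 = tube placed in BG
    dpvs_region: np.ndarray = field(repr=False, default=None)


class TubePlacementError(RuntimeError):
    pass


def capsule_volume_mm3(radius_mm: float, length_mm: float) -> float:
    """Analytic capsule volume: cylinder pi r^2 L plus spherical caps 4/3 pi r^3."""
    return float(np.pi * radius_mm**2 * length_mm + 4.0 / 3.0 * np.pi * radius_mm**3)


def render_capsule(
    shape: tuple[int, int, int],
    spacing_mm: float,
    p0_mm: np.ndarray,
    p1_mm: np.ndarray,
    radius_mm: float,
) -> np.ndarray:
    """Boolean mask of voxels whose centers lie within ``radius`` of segment p0-p1.

    Voxel (i,j,k) has its center at (i,j,k) * spacing (mm). Only a local
    bounding box is scanned.
    """
    p0 = np.asarray(p0_mm, dtype=float)
    p1 = np.asarray(p1_mm, dtype=float)
    lo = np.maximum(np.floor((np.minimum(p0, p1) - radius_mm) / spacing_mm).astype(int), 0)
    hi = np.minimum(
        np.ceil((np.maximum(p0, p1) + radius_mm) / spacing_mm).astype(int) + 1,
        np.asarray(shape),
    )
    mask = np.zeros(shape, dtype=bool)
    if np.any(lo >= hi):
        return mask
    grids = np.meshgrid(
        *(np.arange(lo[d], hi[d]) * spacing_mm for d in range(3)), indexing="ij"
    )
    pts = np.stack(grids, axis=-1)
    d = p1 - p0
    denom = float(d @ d)
    if denom == 0:
        dist = np.linalg.norm(pts - p0, axis=-1)
    else:
        t = np.clip(((pts - p0) @ d) / denom, 0.0, 1.0)
        proj = p0 + t[..., None] * d
        dist = np.linalg.norm(pts - proj, axis=-1)
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = dist <= radius_mm
    return mask


def _ellipsoid(shape, center, semi_axes) -> np.ndarray:
    idx = np.indices(shape, dtype=float)
    q = sum(((idx[d] - center[d]) / semi_axes[d]) ** 2 for d in range(3))
    return q <= 1.0


def _build_anatomy(shape: tuple[int, int, int]) -> np.ndarray:
    """Schematic label geometry: SAS rind, WM interior, two BG blobs, ventricles."""
    s = np.asarray(shape, dtype=float)
    c = (s - 1) / 2.0
    brain = _ellipsoid(shape, c, 0.44 * s)
    inner = _ellipsoid(shape, c, 0.44 * s - 2.5)  # ~2.5-voxel bright rind
    labels = np.zeros(shape, dtype=np.int16)
    labels[brain] = SUBARACHNOID
    labels[inner] = WM
    # two basal-ganglia blobs flanking the midline
    for sign in (-1.0, 1.0):
        bg_center = c + np.array([sign * 0.16 * s[0], 0.0, 0.0])
        labels[_ellipsoid(shape, bg_center, 0.11 * s) & inner] = BG
    # ventricles: smaller bright ellipsoids medial to the BG blobs
    for sign in (-1.0, 1.0):
        v_center = c + np.array([sign * 0.05 * s[0], 0.0, 0.0])
        labels[_ellipsoid(shape, v_center, np.array([0.04, 0.09, 0.14]) * s)] = VENTRICLE
    return labels


def _place_tubes(
    labels: np.ndarray,
    region_code: int,
    n_tubes: int,
    spec: PhantomSpec,
    rng: np.random.Generator,
    dpvs_region: np.ndarray,
    region_tag: int,
    max_retries: int = 400,
) -> int:
    """Carve ``n_tubes`` capsules fully inside ``region_code``; returns voxel count."""
    name = {WM: "WM", BG: "BG"}[region_code]
    spacing = spec.voxel_size_mm
    placed_voxels = 0
    coords = np.argwhere(labels == region_code)
    if n_tubes > 0 and coords.size == 0:
        raise TubePlacementError(f"region {name} is empty; cannot place tubes")
    for _ in range(n_tubes):
        for attempt in range(max_retries):
            center = coords[rng.integers(len(coords))] * spacing
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            radius = rng.uniform(*spec.tube_radius_range_mm)
            length = rng.uniform(*spec.tube_length_range_mm)
            p0 = center - 0.5 * length * direction
            p1 = center + 0.5 * length * direction
            cap = render_capsule(labels.shape, spacing, p0, p1, radius)
            n_cap = int(cap.sum())
            if n_cap == 0:
                continue
            if np.all(labels[cap] == region_code):  # entirely inside, no overlap
                labels[cap] = DPVS
                dpvs_region[cap] = region_tag
                placed_voxels += n_cap
                break
        else:
            raise TubePlacementError(
                f"could not place a tube inside region {name} after {max_retries} retries"
            )
    return placed_voxels


def _render_intensity(labels: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    img = np.zeros(labels.shape, dtype=np.float64)
    img[labels == WM] = spec.intensity_tissue
    img[labels == BG] = spec.intensity_tissue
    img[labels == DPVS] = spec.intensity_tube
    img[labels == VENTRICLE] = spec.intensity_csf
    img[labels == SUBARACHNOID] = spec.intensity_csf
    return img


def _bias_field(shape, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    if amplitude == 0:
        return np.ones(shape)
    field_ = ndimage.gaussian_filter(rng.normal(size=shape), sigma=min(shape) / 6.0)
    peak = np.abs(field_).max()
    if peak > 0:
        field_ = field_ / peak
    return 1.0 + amplitude * field_


def _corrupt(clean: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    img = clean * _bias_field(clean.shape, spec.bias_field_amplitude, rng)
    if spec.noise_sd > 0:
        img = img + rng.normal(scale=spec.noise_sd, size=clean.shape)
    return img


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Render a phantom with ground-truth labels; deterministic given spec.seed."""
    rng = np.random.default_rng(spec.seed)
    labels = _build_anatomy(spec.grid_shape)
    dpvs_region = np.zeros(spec.grid_shape, dtype=np.int8)
    vox_mm3 = spec.voxel_size_mm**3
    n_wm = _place_tubes(labels, WM, spec.n_tubes_wm, spec, rng, dpvs_region, 1)
    n_bg = _place_tubes(labels, BG, spec.n_tubes_bg, spec, rng, dpvs_region, 2)
    clean = _render_intensity(labels, spec)
    img = _corrupt(clean, spec, rng)
    spacing = (spec.voxel_size_mm,) * 3
    return PhantomTruth(
        image=ImageVolume(img, spacing),
        labels=LabelVolume(labels, spacing),
        true_dpvs_volume_mm3={"WM": n_wm * vox_mm3, "BG": n_bg * vox_mm3},
        spec=spec,
        clean=clean,
        dpvs_region=dpvs_region,
    )


def segmentation_masks(truth: PhantomTruth, dilation_voxels: int = 2):
    """(wm_mask, bg_mask) as a segmentation pipeline would receive them.

    Anatomical WM / BG compartments (tube voxels attributed back to the
    compartment they were carved from), dilated by a couple of voxels to
    emulate imperfect tissue masks that leak into the ventricle and
    subarachnoid borders — the source of the false positives the CNN stage
    exists to remove. Masks are kept disjoint (WM wins the overlap).
    """
    lab = truth.labels
    wm = lab.mask(LabelVolume.WM) | (truth.dpvs_region == 1)
    bg = lab.mask(LabelVolume.BG) | (truth.dpvs_region == 2)
    if dilation_voxels > 0:
        wm = ndimage.binary_dilation(wm, iterations=dilation_voxels)
        bg = ndimage.binary_dilation(bg, iterations=dilation_voxels)
    return wm, bg & ~wm


def segmentation_masks_from_labels(labels: LabelVolume, dilation_voxels: int = 2):
    """Like :func:`segmentation_masks` but from a saved label volume alone.

    Tube voxels carry their own label code, so each dPVS connected component
    is attributed to WM or BG by the majority region of its dilated shell
    (tubes are carved entirely inside one compartment, so this is exact for
    generated phantoms).
    """
    lv = labels.values
    wm = lv == WM
    bg = lv == BG
    dpvs = lv == DPVS
    comp, n = ndimage.label(dpvs, structure=np.ones((3, 3, 3), dtype=bool))
    for cid in range(1, n + 1):
        m = comp == cid
        shell = ndimage.binary_dilation(m, iterations=2) & ~m
        if (shell & bg).sum() > (shell & wm).sum():
            bg = bg | m
        else:
            wm = wm | m
    if dilation_voxels > 0:
        wm = ndimage.binary_dilation(wm, iterations=dilation_voxels)
        bg = ndimage.binary_dilation(bg, iterations=dilation_voxels)
    return wm, bg & ~wm


def generate_retest(truth: PhantomTruth, noise_seed: int) -> ImageVolume:
    """Second acquisition of the same anatomy: identical geometry, fresh noise/bias."""
    if truth.clean is None:
        raise ValueError("truth does not carry its noise-free render")
    rng = np.random.default_rng(noise_seed)
    img = _corrupt(truth.clean, truth.spec, rng)
    return ImageVolume(img, truth.image.spacing_mm)
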