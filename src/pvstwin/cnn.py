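"""Stage 2 of automated dPVS segmentation: CNN false-positive refinement.

Candidate components from stage 1 still include bright non-tubular structures
near the ventricles and subarachnoid space. A 3-class 3D patch classifier
(class 1 = dPVS, class 2 = ventricle-adjacent false positive, class 3 =
subarachnoid false positive) decides, per connected component, whether to
keep it; components classified 2 or 3 are removed entirely, so refinement can
only shrink the candidate set.

Patches are 24x24x24 blocks of the normalized image centered on component
centroids, zero-padded at the grid border. Training draws classes at uniform
frequency regardless of raw label counts, and augments with flips, additive
noise, additive bias and multiplicative scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Conv3DClassifier, NetworkSpec
from .segmentation import CandidateSet
from .volume import ImageVolume, LabelVolume

__all__ = [
    "PatchBatch",
    "AugmentParams",
    "extract_patches",
    "augment",
    "train_classifier",
    "refine_candidates",
    "label_components_from_truth",
    "NetworkSpec",
    "Conv3DClassifier",
]

PATCH_SIDE = 24
CLASS_NAMES = {1: "dPVS", 2: "ventricle FP", 3: "subarachnoid FP"}


@dataclass
class PatchBatch:
    """N patches (N, 24, 24, 24) with optional class labels in {1, 2, 3}."""

    patches: np.ndarray
    labels: np.ndarray | None = None
    component_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.patches = np.asarray(self.patches, dtype=np.float32)
        if self.patches.ndim != 4 or self.patches.shape[1:] != (PATCH_SIDE,) * 3:
            raise ValueError(f"patches must be (N, {PATCH_SIDE}, {PATCH_SIDE}, {PATCH_SIDE})")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(self.patches):
                raise ValueError("labels length mismatch")
            bad = set(np.unique(self.labels)) - {1, 2, 3}
            if bad:
                raise ValueError(f"labels must be in {{1,2,3}}, got extras {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.patches)


def _cut_patch(values: np.ndarray, center: np.ndarray, side: int) -> np.ndarray:
    """Zero-padded cube of the given side centered at a voxel index."""
    half = side // 2
    out = np.zeros((side,) * 3, dtype=np.float32)
    lo = center - half
    src_lo = np.maximum(lo, 0)
    src_hi = np.minimum(lo + side, values.shape)
    dst_lo = src_lo - lo
    dst_hi = dst_lo + (src_hi - src_lo)
    if np.any(src_hi <= src_lo):
        return out
    out[dst_lo[0] : dst_hi[0], dst_lo[1] : dst_hi[1], dst_lo[2] : dst_hi[2]] = values[
        src_lo[0] : src_hi[0], src_lo[1] : src_hi[1], src_lo[2] : src_hi[2]
    ]
    return out


def extract_patches(img: ImageVolume, candidates: CandidateSet, side: int = PATCH_SIDE) -> PatchBatch:
    """One patch per connected component, centered at its centroid (rounded)."""
    n = candidates.n_components
    patches = np.zeros((n, side, side, side), dtype=np.float32)
    ids = np.zeros(n, dtype=np.int64)
    for i, row in enumerate(candidates.table.itertuples(index=False)):
        center = np.rint([row.centroid_x, row.centroid_y, row.centroid_z]).astype(int)
        patches[i] = _cut_patch(img.values, center, side)
        ids[i] = row.component_id
    return PatchBatch(patches, component_ids=ids)


@dataclass(frozen=True)
class AugmentParams:
    """Amplitudes of the training-time patch perturbations (all zero = identity)."""

    flip_prob: float = 0.5
    noise_sd: float = 0.1
    bias_sd: float = 0.1
    scale_sd: float = 0.1


def augment(batch: PatchBatch, seed: int, params: AugmentParams | None = None) -> PatchBatch:
    """Randomly flip/noise/bias/scale each patch independently; labels unchanged."""
    params = params or AugmentParams()
    rng = np.random.default_rng(seed)
    out = batch.patches.copy()
    for i in range(len(out)):
        for axis in range(3):
            if rng.random() < params.flip_prob:
                out[i] = np.flip(out[i], axis=axis)
        if params.scale_sd > 0:
            out[i] *= 1.0 + rng.normal(scale=params.scale_sd)
        if params.bias_sd > 0:
            out[i] += rng.normal(scale=params.bias_sd)
        if params.noise_sd > 0:
            out[i] += rng.normal(scale=params.noise_sd, size=out[i].shape).astype(np.float32)
    labels = None if batch.labels is None else batch.labels.copy()
    ids = None if batch.component_ids is None else batch.component_ids.copy()
    return PatchBatch(out, labels, ids)


@dataclass
class TrainedModel:
    net: Conv3DClassifier
    loss_history: list

    @property
    def spec(self) -> NetworkSpec:
        return self.net.spec

    def save(self, path) -> None:
        self.net.save(path)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        return cls(Conv3DClassifier.load(path), [])


def train_classifier(
    labeled: PatchBatch,
    spec: NetworkSpec | None = None,
    epochs: int = 12,
    seed: int = 0,
    lr: float = 0.001,
    momentum: float = 0.9,
    batch_size: int = 8,
    augment_params: AugmentParams | None = None,
) -> TrainedModel:
    """Train the 3-class patch classifier with balanced class sampling.

    Every mini-batch draw first picks a class uniformly at random, then a
    patch uniformly within that class, so each class is fed to the network at
    uniform frequency regardless of raw label counts. An epoch is
    ceil(N / batch_size) steps. Augmentation amplitudes default to
    AugmentParams(); pass zero amplitudes to disable.
    """
    if labeled.labels is None:
        raise ValueError("training requires a labeled batch")
    spec = spec or NetworkSpec()
    by_class = {k: np.flatnonzero(labeled.labels == k) for k in (1, 2, 3)}
    for k, idx in by_class.items():
        if len(idx) == 0:
            raise ValueError(f"class {k} ({CLASS_NAMES[k]}) absent from training labels")
    rng = np.random.default_rng(seed)
    net = Conv3DClassifier(spec, seed=seed)
    aug = augment_params or AugmentParams()
    steps_per_epoch = max(1, int(np.ceil(len(labeled) / batch_size)))
    history = []
    for epoch in range(epochs):
        epoch_loss = 0.0
        for step in range(steps_per_epoch):
            classes = rng.integers(1, 4, size=batch_size)
            idx = np.array([by_class[k][rng.integers(len(by_class[k]))] for k in classes])
            sub = PatchBatch(labeled.patches[idx], labeled.labels[idx])
            sub = augment(sub, seed=int(rng.integers(2**31)), params=aug)
            loss = net.loss_and_grad(sub.patches, sub.labels - 1)
            net.sgd_step(lr, momentum)
            epoch_loss += loss
        history.append(epoch_loss / steps_per_epoch)
    return TrainedModel(net, history)


def refine_candidates(
    candidates: CandidateSet, model: TrainedModel | Conv3DClassifier, img: ImageVolume
) -> CandidateSet:
    """Keep only components the classifier calls class 1 (dPVS).

    Never adds voxels: the result is a subset of the input components.
    """
    net = model.net if isinstance(model, TrainedModel) else model
    if net.spec.input_side != PATCH_SIDE:
        raise ValueError(
            f"model expects {net.spec.input_side}^3 input, refinement uses {PATCH_SIDE}^3 patches"
        )
    if candidates.n_components == 0:
        return candidates
    batch = extract_patches(img, candidates)
    # classify in chunks to bound memory
    preds = np.concatenate(
        [net.predict(batch.patches[i : i + 16]) for i in range(0, len(batch), 16)]
    )
    keep = batch.component_ids[preds == 1]
    return candidates.subset(keep)


def label_components_from_truth(
    candidates: CandidateSet, truth_labels: LabelVolume, margin_voxels: int = 2
) -> np.ndarray:
    """Derive 3-class training labels from phantom ground truth.

    Class 1: component overlaps true dPVS voxels; class 2: within
    ``margin_voxels`` of a ventricle; class 3: within the margin of the
    subarachnoid shell. Components matching none of the rules are assigned to
    the nearer of ventricle / subarachnoid by Euclidean distance (they are
    false positives of some bright structure by construction).
    """
    from scipy import ndimage

    lv = truth_labels.values
    dpvs = lv == LabelVolume.DPVS
    near_vent = ndimage.binary_dilation(lv == LabelVolume.VENTRICLE, iterations=margin_voxels)
    near_sas = ndimage.binary_dilation(lv == LabelVolume.SUBARACHNOID, iterations=margin_voxels)
    dist_vent = ndimage.distance_transform_edt(lv != LabelVolume.VENTRICLE)
    dist_sas = ndimage.distance_transform_edt(lv != LabelVolume.SUBARACHNOID)
    labels = np.zeros(candidates.n_components, dtype=np.int64)
    comp = candidates.component_labels
    for i, cid in enumerate(candidates.table["component_id"].to_numpy()):
        mask = comp == cid
        if (dpvs & mask).any():
            labels[i] = 1
        elif (near_vent & mask).any():
            labels[i] = 2
        elif (near_sas & mask).any():
            labels[i] = 3
        else:
            labels[i] = 2 if dist_vent[mask].min() <= dist_sas[mask].min() else 3
    return labels
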