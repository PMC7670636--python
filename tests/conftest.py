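"""Shared fixtures.

Expensive imaging fixtures (a default phantom segmented end to end, and a
trained patch classifier) are session-scoped so the whole suite pays for them
once. Training data are capped at 15 patches per class — plenty for the
linearly separable phantom classes — to keep the CPU budget small.
"""

from __future__ import annotations

import numpy as np
import pytest

from pvstwin.cnn import PatchBatch, extract_patches, label_components_from_truth, train_classifier
from pvstwin.phantom import PhantomSpec, generate_phantom, segmentation_masks
from pvstwin.segmentation import (
    VesselnessParams,
    compute_vesselness,
    extract_candidates,
    normalize_intensity,
)
from pvstwin.twinsim import TwinSimSpec, simulate_twin_cohort


@pytest.fixture(scope="session")
def phantom_truth():
    """Default-size phantom with noise and bias field (seed fixed)."""
    return generate_phantom(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def segmented_phantom(phantom_truth):
    """Stage-1 products for the default phantom: normalized image, vesselness,
    candidate set from imperfect (dilated) masks, and truth-derived classes."""
    truth = phantom_truth
    brain = truth.labels.values > 0
    norm = normalize_intensity(truth.image, brain)
    params = VesselnessParams()
    v = compute_vesselness(norm, params, brain)
    wm, bg = segmentation_masks(truth)
    cand = extract_candidates(v, wm, bg, params, spacing_mm=truth.image.spacing_mm)
    classes = label_components_from_truth(cand, truth.labels)
    return {"truth": truth, "norm": norm, "vesselness": v, "candidates": cand, "classes": classes}


@pytest.fixture(scope="session")
def labeled_patches(segmented_phantom):
    batch = extract_patches(segmented_phantom["norm"], segmented_phantom["candidates"])
    return PatchBatch(batch.patches, segmented_phantom["classes"], batch.component_ids)


@pytest.fixture(scope="session")
def train_holdout_split(labeled_patches):
    """Per-class split: up to 15 training patches per class, the rest held out."""
    rng = np.random.default_rng(7)
    train_idx, hold_idx = [], []
    for k in (1, 2, 3):
        idx = rng.permutation(np.flatnonzero(labeled_patches.labels == k))
        train_idx.extend(idx[:15])
        hold_idx.extend(idx[15:])
    train = PatchBatch(labeled_patches.patches[train_idx], labeled_patches.labels[train_idx])
    hold = PatchBatch(labeled_patches.patches[hold_idx], labeled_patches.labels[hold_idx])
    return train, hold


@pytest.fixture(scope="session")
def trained_model(train_holdout_split):
    train, _ = train_holdout_split
    return train_classifier(train, epochs=12, seed=0)


@pytest.fixture(scope="session")
def univariate_cohort():
    """Paper-sized cohort, highly heritable trait (a^2 = 0.902)."""
    return simulate_twin_cohort(TwinSimSpec(seed=101))


@pytest.fixture(scope="session")
def bivariate_cohort():
    spec = TwinSimSpec(
        paths_a=[[0.8112, 0.0], [0.2850, 0.9064]],
        paths_c=[[0.4, 0.0], [0.06, 0.30]],
        paths_e=[[0.4266, 0.0], [0.05634, 0.28]],
        seed=202,
    )
    return simulate_twin_cohort(spec)
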