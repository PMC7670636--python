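"""End-to-end orchestration: simulate -> segment -> train-cnn -> volumes ->
adjust -> heritability, with a content-hash manifest for reproducibility.

A run is described by a plain YAML config (key: value blocks per stage). A
single global seed fans out deterministically to per-stage seeds so each
stage is independently reproducible; every file a stage writes is recorded
in ``manifest.json`` with its SHA-256.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cnn as cnn_mod
from . import phantom as phantom_mod
from . import phenotype as phen_mod
from . import segmentation as seg_mod
from . import twinmodels as tm
from . import twinsim as twin_mod
from . import volumetry as vol_mod
from .volume import load_image, load_labels

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("pvstwin")

STAGE_ORDER = ["simulate", "segment", "train-cnn", "volumes", "adjust", "heritability"]


@dataclass
class RunConfig:
    stages: list
    seed: int = 0
    outdir: Path = Path("pvstwin_run")
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        idx = [STAGE_ORDER.index(s) for s in self.stages]
        if sorted(idx) != idx or idx != list(range(idx[0], idx[0] + len(idx))) or (idx and idx[0] != 0):
            raise ValueError(f"stages must form a prefix of {STAGE_ORDER}")

    @classmethod
    def from_yaml(cls, path, seed=None, outdir=None) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            stages=raw.get("stages", STAGE_ORDER),
            seed=seed if seed is not None else raw.get("seed", 0),
            outdir=Path(outdir if outdir is not None else raw.get("outdir", "pvstwin_run")),
            params={k: v for k, v in raw.items() if k not in ("stages", "seed", "outdir")},
        )

    def stage_seed(self, stage: str) -> int:
        # fixed splitting rule: stages independently reproducible, < 2^31
        return (self.seed * 1000003 + STAGE_ORDER.index(stage) * 7919 + 17) % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_simulate(cfg: RunConfig, outdir: Path) -> list[Path]:
    p = cfg.params.get("simulate", {})
    seed = cfg.stage_seed("simulate")
    written = []
    n_phantoms = int(p.get("n_phantoms", 2))
    spec_kwargs = p.get("phantom", {})
    for i in range(n_phantoms):
        spec = phantom_mod.PhantomSpec(seed=seed + i, **spec_kwargs)
        truth = phantom_mod.generate_phantom(spec)
        img_path = outdir / f"phantom_{i:03d}_t2.nii"
        lab_path = outdir / f"phantom_{i:03d}_labels.nii"
        truth.image.save(img_path)
        truth.labels.save(lab_path)
        written += [img_path, lab_path]
    twin_kwargs = {k: v for k, v in p.get("twins", {}).items()}
    tspec = twin_mod.TwinSimSpec(seed=seed + 10007, **twin_kwargs)
    cohort = twin_mod.simulate_twin_cohort(tspec)
    cohort_path = outdir / "cohort.csv"
    cohort.to_csv(cohort_path, index=False)
    written.append(cohort_path)
    return written


def _segment_one(img_path: Path, lab_path: Path, params: seg_mod.VesselnessParams):
    img = load_image(img_path)
    labels = load_labels(lab_path)
    brain = labels.values > 0
    norm = seg_mod.normalize_intensity(img, brain)
    v = seg_mod.compute_vesselness(norm, params, brain)
    # imperfect (dilated) tissue masks, as a FreeSurfer-style segmentation
    # would supply them: they leak into ventricle/SAS borders, which is what
    # the CNN refinement stage exists to clean up
    wm, bg = phantom_mod.segmentation_masks_from_labels(labels)
    cand = seg_mod.extract_candidates(v, wm, bg, params, spacing_mm=img.spacing_mm)
    return img, labels, norm, cand


def _stage_segment(cfg: RunConfig, outdir: Path) -> list[Path]:
    p = cfg.params.get("segment", {})
    params = seg_mod.VesselnessParams(
        **{k: tuple(v) if k == "scales_mm" else v for k, v in p.items()}
    )
    written = []
    for img_path in sorted(outdir.glob("phantom_*_t2.nii")):
        stem = img_path.name.replace("_t2.nii", "")
        _, labels, norm, cand = _segment_one(img_path, outdir / f"{stem}_labels.nii", params)
        mask_path = outdir / f"{stem}_candidates.nii"
        table_path = outdir / f"{stem}_components.csv"
        cand.save(mask_path, table_path, affine=labels.affine)
        norm.save(outdir / f"{stem}_norm.nii")
        written += [mask_path, table_path, outdir / f"{stem}_norm.nii"]
    return written


def _stage_train_cnn(cfg: RunConfig, outdir: Path) -> list[Path]:
    p = cfg.params.get("train_cnn", {})
    seed = cfg.stage_seed("train-cnn")
    patches, labels = [], []
    for img_path in sorted(outdir.glob("phantom_*_norm.nii")):
        stem = img_path.name.replace("_norm.nii", "")
        norm = load_image(img_path)
        truth_labels = load_labels(outdir / f"{stem}_labels.nii")
        comp = pd.read_csv(outdir / f"{stem}_components.csv")
        import nibabel as nib

        cand_mask = np.asarray(nib.load(str(outdir / f"{stem}_candidates.nii")).dataobj) > 0
        from scipy import ndimage

        lab_arr, _ = ndimage.label(cand_mask, structure=np.ones((3, 3, 3)))
        cand = seg_mod.extract_candidates(
            (lab_arr > 0).astype(float), truth_labels.values > 0,
            np.zeros_like(cand_mask), threshold=0.5, spacing_mm=norm.spacing_mm,
        )
        batch = cnn_mod.extract_patches(norm, cand)
        patches.append(batch.patches)
        labels.append(cnn_mod.label_components_from_truth(cand, truth_labels))
    batch = cnn_mod.PatchBatch(np.concatenate(patches), np.concatenate(labels))
    model = cnn_mod.train_classifier(
        batch, epochs=int(p.get("epochs", 12)), seed=seed, lr=float(p.get("lr", 0.001))
    )
    model_path = outdir / "cnn_model.npz"
    model.save(model_path)
    return [model_path]


def _stage_volumes(cfg: RunConfig, outdir: Path) -> list[Path]:
    p = cfg.params.get("volumes", {})
    use_cnn = bool(p.get("use_cnn", True)) and (outdir / "cnn_model.npz").exists()
    model = cnn_mod.TrainedModel.load(outdir / "cnn_model.npz") if use_cnn else None
    seg_p = cfg.params.get("segment", {})
    params = seg_mod.VesselnessParams(
        **{k: tuple(v) if k == "scales_mm" else v for k, v in seg_p.items()}
    )
    rows = []
    for img_path in sorted(outdir.glob("phantom_*_t2.nii")):
        stem = img_path.name.replace("_t2.nii", "")
        _, labels, norm, cand = _segment_one(img_path, outdir / f"{stem}_labels.nii", params)
        final = cnn_mod.refine_candidates(cand, model, norm) if model else cand
        vols = vol_mod.compute_volumes(final, subject_id=stem)
        rows.append(
            {
                "subject_id": stem,
                "bg_dpvs_mm3": vols.bg_dpvs_mm3,
                "wm_dpvs_mm3": vols.wm_dpvs_mm3,
                "voxel_volume_mm3": vols.voxel_volume_mm3,
            }
        )
    path = outdir / "volumes.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return [path]


def _stage_adjust(cfg: RunConfig, outdir: Path) -> list[Path]:
    p = cfg.params.get("adjust", {})
    cohort = pd.read_csv(outdir / "cohort.csv")
    traits = p.get("traits")
    if traits is None:
        traits = [c for c in cohort.columns if c.startswith("trait")]
    covariates = tuple(p.get("covariates", ("age", "sex")))
    out = cohort
    coefs = {}
    for t in traits:
        adj = phen_mod.residualize(out, phen_mod.AdjustmentSpec(t, covariates))
        out = adj.data
        coefs[t] = adj.coefficients.to_dict()
    path = outdir / "cohort_adjusted.csv"
    out.to_csv(path, index=False)
    coef_path = outdir / "adjustment_coefficients.json"
    with open(coef_path, "w") as fh:
        json.dump(coefs, fh, indent=2)
    return [path, coef_path]


def _stage_heritability(cfg: RunConfig, outdir: Path) -> list[Path]:
    p = cfg.params.get("heritability", {})
    src = outdir / "cohort_adjusted.csv"
    cohort = pd.read_csv(src if src.exists() else outdir / "cohort.csv")
    traits = p.get("traits")
    if traits is None:
        traits = [c for c in cohort.columns if c.startswith("trait")]
    models = p.get("models", ["ACE", "AE", "CE", "E"])
    rows = []
    for t in traits:
        comp = tm.compare_models(cohort, t, models=tuple(models))
        for m, f in comp.fits.items():
            rows.append(
                {
                    "trait": t, "model": m, "a2": f.a2, "c2": f.c2, "e2": f.e2,
                    "h2": f.h2, "loglik": f.loglik, "aic": f.aic,
                    "converged": f.converged,
                }
            )
    if len(traits) == 2 and p.get("bivariate", True):
        f = tm.fit_bivariate(cohort, traits)
        rows.append(
            {
                "trait": "+".join(traits), "model": "Cholesky-ACE",
                "rg": tm.genetic_correlation(f), "shared_h2": tm.shared_heritability(f),
                "loglik": f.loglik, "aic": f.aic, "converged": f.converged,
            }
        )
    path = outdir / "heritability.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return [path]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "segment": _stage_segment,
    "train-cnn": _stage_train_cnn,
    "volumes": _stage_volumes,
    "adjust": _stage_adjust,
    "heritability": _stage_heritability,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stage prefix; returns (and writes) the manifest.

    A stage failure halts the run with the failing stage named; files already
    written are kept and recorded.
    """
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": config.seed,
        "stages": list(config.stages),
        "params": config.params,
        "files": {},
    }
    try:
        for stage in config.stages:
            log.info("running stage %s", stage)
            written = _STAGE_FUNCS[stage](config, outdir)
            for path in written:
                manifest["files"][path.name] = _sha256(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc
    finally:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
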