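"""End-to-end orchestration: phantoms → preprocessing → per-variant k-fold
training → STAPLE fold fusion → three-variant ensembling → binned evaluation.

The pipeline mirrors the clinical design at desk scale: three input
configurations of the same dual-pathway network (Orig: 1 channel / 25³
segments; Vess: 3 channels / 25³; LDim: 1 channel / 45³) are each trained
with k-fold cross-validation on a training cohort; on every evaluation case
the k sub-model outputs are fused by STAPLE, and the three fused variant
masks are combined into the ensemble (DLM-Ens). Detection and segmentation
metrics are reported overall and stratified by aneurysm volume.

Every stage derives its randomness from the master seed, so a rerun with
the same configuration reproduces fold assignments, trained weights and the
evaluation report exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .evaluation import (
    DetectionResult,
    match_detections,
    merge_results,
    reports_to_frame,
    volume_binned_report,
)
from .fusion import ensemble_combine, fuse_folds, make_folds
from .network import NetworkConfig, binarize, predict_volume, train_fold
from .phantom import PhantomCase, PhantomSpec, example_spec, generate_phantom, make_cohort, save_case
from .preprocess import ChannelStack, build_stack, resample_isotropic
from .volume import Volume3D, read_nifti, write_nifti

log = logging.getLogger(__name__)

VARIANTS = ("Orig", "Vess", "LDim")

__all__ = ["PipelineConfig", "run_pipeline", "VARIANTS", "smoke_config"]


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    master_seed: int = 0
    # cohort
    n_train: int = 4
    n_test: int = 2
    grid_shape: tuple[int, int, int] = (48, 48, 40)
    spacing_mm: tuple[float, float, float] = (0.75, 0.75, 1.0)
    noise_sd: float = 3.0
    volume_range_mm3: tuple[float, float] = (20.0, 500.0)
    multiplicity_prob: float = 0.16
    # preprocessing
    target_mm: float = 0.5
    # training (shared across variants; channels/segment vary per variant)
    k_folds: int = 5
    pathway_widths: tuple[int, ...] = (4, 4, 8, 8, 8, 8, 16, 16)
    fc_width: int = 16
    batch_size: int = 10
    epochs: int = 30
    batches_per_epoch: int = 5
    learning_rate: float = 3e-3
    segment_small: int = 25
    segment_large: int = 45
    # fusion / evaluation
    ensemble_rule: str = "staple"
    bins: tuple[float, ...] = (30.0, 50.0, 100.0)
    resume: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def network_config(self, variant: str, fold: int, seed: int) -> NetworkConfig:
        channels = 3 if variant == "Vess" else 1
        segment = self.segment_large if variant == "LDim" else self.segment_small
        return NetworkConfig(
            segment_size=segment,
            channels_in=channels,
            pathway_widths=tuple(self.pathway_widths),
            fc_width=self.fc_width,
            batch_size=self.batch_size,
            epochs=self.epochs,
            batches_per_epoch=self.batches_per_epoch,
            learning_rate=self.learning_rate,
            seed=seed,
        )


def smoke_config(out_dir: str, seed: int = 0) -> PipelineConfig:
    """A configuration sized for minutes-scale end-to-end runs."""
    return PipelineConfig(
        out_dir=out_dir,
        master_seed=seed,
        n_train=4,
        n_test=2,
        grid_shape=(44, 44, 36),
        spacing_mm=(0.75, 0.75, 1.0),
        k_folds=2,
        epochs=2,
        batches_per_epoch=3,
        batch_size=6,
        pathway_widths=(2, 2, 4, 4, 4, 4, 8, 8),
        fc_width=8,
        volume_range_mm3=(80.0, 400.0),
    )


def _derived_seed(master: int, *tokens) -> int:
    h = hashlib.sha256(("/".join(map(str, tokens)) + f"#{master}").encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


def _prep_case(case: PhantomCase, cfg: PipelineConfig) -> dict:
    """Build the per-case channel stacks and resampled labels."""
    stack1 = build_stack(case.image, "Orig", target_mm=cfg.target_mm)
    stack3 = build_stack(case.image, "Vess", target_mm=cfg.target_mm)
    labels = resample_isotropic(case.aneurysm_mask, cfg.target_mm, mode="label")
    return {"Orig": stack1, "Vess": stack3, "LDim": stack1, "labels": labels}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the evaluation reports.

    Artifacts (phantom cases, fused masks, reports, provenance) are written
    under ``config.out_dir``; with ``config.resume`` previously written
    fused masks are reused.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {"config_hash": config.config_hash(), "master_seed": config.master_seed}
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))

    # ---- stage 1: phantom cohorts
    base = example_spec(
        grid_shape=config.grid_shape, spacing_mm=config.spacing_mm, noise_sd=config.noise_sd
    )
    log.info("generating %d train / %d test phantoms", config.n_train, config.n_test)
    train_cases = make_cohort(
        config.n_train,
        base,
        config.volume_range_mm3,
        seed=_derived_seed(config.master_seed, "cohort", "train"),
        multiplicity_prob=config.multiplicity_prob,
    )
    test_cases = make_cohort(
        config.n_test,
        base,
        config.volume_range_mm3,
        seed=_derived_seed(config.master_seed, "cohort", "test"),
        multiplicity_prob=config.multiplicity_prob,
    )
    for c in train_cases:
        c.case_id = "train_" + c.case_id
    for c in test_cases:
        c.case_id = "test_" + c.case_id
        save_case(c, out / "phantoms")

    # ---- stage 2: preprocessing
    log.info("preprocessing %d cases", len(train_cases) + len(test_cases))
    train_prep = {c.case_id: _prep_case(c, config) for c in train_cases}
    test_prep = {c.case_id: _prep_case(c, config) for c in test_cases}

    # ---- stage 3: folds
    split = make_folds(
        [c.case_id for c in train_cases],
        seed=_derived_seed(config.master_seed, "folds"),
        k=config.k_folds,
    )
    split.to_json(out / "folds.json")

    # ---- stage 4: per-variant training + prediction + STAPLE fold fusion
    variant_masks: dict[str, dict[str, Volume3D]] = {v: {} for v in VARIANTS}
    for variant in VARIANTS:
        fold_preds: dict[str, list[Volume3D]] = {c.case_id: [] for c in test_cases}
        for fold in range(split.k):
            seed = _derived_seed(config.master_seed, "train", variant, fold)
            ncfg = config.network_config(variant, fold, seed)
            fold_dir = out / "models" / variant / f"fold{fold}"
            fold_dir.mkdir(parents=True, exist_ok=True)
            pred_paths = {
                c.case_id: fold_dir / f"{c.case_id}_pred.nii.gz" for c in test_cases
            }
            if config.resume and all(p.exists() for p in pred_paths.values()):
                log.info("%s fold %d: reusing existing predictions", variant, fold)
                for cid, p in pred_paths.items():
                    fold_preds[cid].append(read_nifti(p))
                continue
            train_ids = split.train_cases(fold)
            cases = [
                (train_prep[cid][variant], train_prep[cid]["labels"]) for cid in train_ids
            ]
            log.info("training %s fold %d on %d cases", variant, fold, len(cases))
            model = train_fold(cases, ncfg)
            np.savetxt(fold_dir / "loss_log.csv", model.loss_log, header="mean_loss")
            for case in test_cases:
                stack = test_prep[case.case_id][variant]
                pm = predict_volume(model, stack, provenance=(variant, str(fold)))
                mask = binarize(pm)
                write_nifti(mask, pred_paths[case.case_id])
                fold_preds[case.case_id].append(mask)
        (out / "fused" / variant).mkdir(parents=True, exist_ok=True)
        for case in test_cases:
            fused = fuse_folds(fold_preds[case.case_id])
            variant_masks[variant][case.case_id] = fused
            write_nifti(fused, out / "fused" / variant / f"{case.case_id}.nii.gz")

    # ---- stage 5: three-variant ensemble
    ensemble_masks: dict[str, Volume3D] = {}
    (out / "ensemble").mkdir(parents=True, exist_ok=True)
    for case in test_cases:
        masks = [variant_masks[v][case.case_id] for v in VARIANTS]
        ens = ensemble_combine(masks, rule=config.ensemble_rule)
        ensemble_masks[case.case_id] = ens
        write_nifti(ens, out / "ensemble" / f"{case.case_id}.nii.gz")

    # ---- stage 6: evaluation
    reports = {}
    detection_tables = {}
    for name, masks in [("Ens", ensemble_masks)] + [
        (v, variant_masks[v]) for v in VARIANTS
    ]:
        per_case: list[DetectionResult] = []
        for case in test_cases:
            labels = test_prep[case.case_id]["labels"]
            per_case.append(
                match_detections(masks[case.case_id], labels, case_id=case.case_id)
            )
        merged = merge_results(per_case)
        reps = volume_binned_report(merged, bins=tuple(config.bins))
        reports[name] = reps
        detection_tables[name] = merged
        frame = reports_to_frame(reps)
        (out / "reports").mkdir(exist_ok=True)
        frame.to_csv(out / "reports" / f"metrics_{name}.csv", index=False)
        (out / "reports" / f"metrics_{name}.json").write_text(
            json.dumps([r.to_dict() for r in reps], indent=2)
        )
    log.info("pipeline complete; reports under %s", out / "reports")
    return {
        "reports": reports,
        "detections": detection_tables,
        "out_dir": out,
        "folds": split,
    }
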