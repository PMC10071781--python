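"""End-to-end phantom study: train, normalize, quantify, compare.

Emulates the evaluation design of template-space PET quantification
studies on synthetic data with known ground truth. Two SUVR arms are
compared: the *network arm* (affine registration + cascade field + warp,
driven by PET alone) and the *reference arm*, which evaluates the
composite atlas in each subject's individual space through the phantom's
exact generation mapping — the stand-in for an individual-space MRI
parcellation. The network arm never reads a phantom's ground truth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .affine import register_affine
from .agreement import compare_methods
from .geometry import (apply_affine, invert_mapping, jacobian_determinant,
                       resample_chain, warp_volume)
from .network import (CascadeConfig, TrainConfig, TrainingSample,
                      build_model, spatially_normalize, train_model)
from .phantom import (PhantomPair, PhantomSpec, TemplateAssets, make_phantom_pair,
                      make_template)
from .quantification import (VOIAtlas, build_phantom_atlas, compute_suvr,
                             write_reports_csv)
from .volume import AffineTransform, DisplacementField

__all__ = ["StudyConfig", "StudyReport", "run_phantom_study",
           "gm_dice_template", "endpoint_error", "fold_fraction"]

log = logging.getLogger("petnorm")


@dataclass
class StudyConfig:
    """Parameters of a full synthetic evaluation study."""

    n_train: int = 20
    n_test: int = 10
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    deform_amplitude: float = 3.0
    ventricle_scale_range: tuple[float, float] = (1.0, 1.6)
    noise_sd: float = 0.05
    test_noise_sd: float | None = None
    positive_fraction: float = 0.5
    pose_rot_deg: float = 5.0
    pose_trans_vox: float = 2.0
    pose_scale: float = 0.05
    cascade: CascadeConfig = dc_field(default_factory=CascadeConfig)
    train: TrainConfig = dc_field(default_factory=TrainConfig)
    registration_levels: int = 2
    registration_max_iter: int = 400
    out_dir: str = "study_output"
    master_seed: int = 0
    write_volumes: bool = True

    def __post_init__(self) -> None:
        if self.n_train < 1 or self.n_test < 1:
            raise ValueError("n_train and n_test must be >= 1")

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["ventricle_scale_range"] = list(self.ventricle_scale_range)
        return d


@dataclass
class StudyReport:
    """Everything the study computed, plus where it was written."""

    config: StudyConfig
    agreement: pd.DataFrame
    reference_reports: list
    dnn_reports: list
    diagnostics: dict
    history: object
    out_dir: Path

    def summary(self) -> str:
        lines = ["Phantom study report",
                 f"  train/test subjects: {self.config.n_train}/{self.config.n_test}"
                 f" on {self.config.grid_shape} grids",
                 "  per-region agreement (reference arm as x):"]
        for _, row in self.agreement.iterrows():
            if row["flagged"]:
                lines.append(f"    {row['region']:<30s} flagged (n={row['n']})")
            else:
                lines.append(
                    f"    {row['region']:<30s} slope {row['slope']:+.3f}  "
                    f"R2 {row['r_squared']:.3f}  ICC {row['icc']:.3f}  "
                    f"bias {row['bias']:+.4f}")
        d = self.diagnostics
        lines.append(f"  GM Dice to template: affine-only {d['gm_dice_affine']:.3f}"
                     f" -> with field {d['gm_dice_dnn']:.3f}")
        lines.append(f"  endpoint error vs zero field: {100 * d['epe_ratio']:.1f}%")
        lines.append(f"  folding voxel fraction: {100 * d['fold_fraction']:.4f}%")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# evaluation helpers (ground truth available only here, the reference arm)
# ---------------------------------------------------------------------------

def gm_dice_template(pair: PhantomPair, assets: TemplateAssets,
                     affine: AffineTransform,
                     field: DisplacementField | None) -> float:
    """Dice of the subject's GM (carried to template space) vs template GM.

    The subject's gray-matter segment is resampled through the estimated
    affine (and optionally the predicted field) and thresholded at 0.5.
    """
    gm_aff = apply_affine(pair.gm_segment, affine, out_shape=assets.gm_probability.shape)
    moved = warp_volume(gm_aff, field) if field is not None else gm_aff
    a = moved.data >= 0.5
    b = assets.gm_probability.data >= 0.5
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def endpoint_error(pair: PhantomPair, affine: AffineTransform,
                   field: DisplacementField | None,
                   brain_mask: np.ndarray,
                   y_true: np.ndarray | None = None) -> float:
    """Mean distance between estimated and true template->individual maps.

    The estimated map is ``x -> M_reg (x + u(x)) + t_reg`` (``u = 0`` for
    the zero-field baseline); the true map is the numerical inverse of the
    phantom's generation mapping. Averaged over template brain voxels.
    """
    shape = pair.true_field.grid_shape
    if y_true is None:
        y_true = invert_mapping(pair.true_field, pair.true_affine)
    grids = np.stack(np.meshgrid(*(np.arange(n, dtype=np.float64) for n in shape),
                                 indexing="ij"), axis=-1)
    pts = grids if field is None else grids + field.u.astype(np.float64)
    y_est = pts @ affine.matrix.T + affine.translation
    err = np.sqrt(((y_est - y_true) ** 2).sum(axis=-1))
    return float(err[brain_mask].mean())


def fold_fraction(field: DisplacementField) -> float:
    """Fraction of interior voxels with non-positive Jacobian determinant."""
    det = jacobian_determinant(field).data[1:-1, 1:-1, 1:-1]
    return float((det <= 0).mean())


# ---------------------------------------------------------------------------
# study driver
# ---------------------------------------------------------------------------

def _stage(stage: str, subject: str = "-"):
    class _Ctx:
        def __enter__(self):
            log.info("stage=%s subject=%s status=start", stage, subject)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"stage {stage!r} failed for subject {subject!r}: {exc}") from exc
            log.info("stage=%s subject=%s status=done", stage, subject)
    return _Ctx()


def _make_specs(cfg: StudyConfig, count: int, rng: np.random.Generator,
                prefix: str) -> list[PhantomSpec]:
    specs = []
    n_pos = int(round(count * cfg.positive_fraction))
    for i in range(count):
        status = "positive" if i < n_pos else "negative"
        specs.append(PhantomSpec(
            grid_shape=cfg.grid_shape,
            seed=int(rng.integers(2 ** 31)),
            amyloid_status=status,
            deform_amplitude=cfg.deform_amplitude,
            ventricle_scale=float(rng.uniform(*cfg.ventricle_scale_range)),
            noise_sd=cfg.noise_sd,
            affine_rot_deg=cfg.pose_rot_deg,
            affine_trans_vox=cfg.pose_trans_vox,
            affine_scale=cfg.pose_scale,
        ))
    return specs


def run_phantom_study(config: StudyConfig) -> StudyReport:
    """Run the full synthetic evaluation; fully reproducible from the seed."""
    rng = np.random.default_rng(config.master_seed)
    seed_template = int(rng.integers(2 ** 31))
    seed_model = int(rng.integers(2 ** 31))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _stage("template"):
        assets = make_template(config.grid_shape, seed_template)
        atlas, voi_map = build_phantom_atlas(assets.tissue_labels)
        reg_target = assets.template_pet_average()
    brain_mask = assets.tissue_labels.data > 0

    train_specs = _make_specs(config, config.n_train, rng, "train")
    test_specs = _make_specs(config, config.n_test, rng, "test")
    if config.test_noise_sd is not None:
        for spec in test_specs:
            spec.noise_sd = config.test_noise_sd

    samples = []
    for i, spec in enumerate(train_specs):
        sid = f"train_{i:02d}"
        with _stage("train_phantom", sid):
            pair = make_phantom_pair(spec, assets)
        with _stage("train_affine", sid):
            reg = register_affine(pair.pet, reg_target,
                                  levels=config.registration_levels,
                                  max_iter=config.registration_max_iter)
            tf, shp = reg.transform, assets.template_mr.shape
            samples.append(TrainingSample(
                pet_affine=apply_affine(pair.pet, tf, shp),
                mr_affine=apply_affine(pair.mr, tf, shp),
                gm_affine=apply_affine(pair.gm_segment, tf, shp)))

    with _stage("train_network"):
        model = build_model(config.cascade, seed_model, grid_shape=config.grid_shape)
        history = train_model(model, samples, assets, config.train)
        model.save(out / "model.npz")
        history.to_csv(out / "training_log.csv")

    ref_reports, dnn_reports = [], []
    dice_affine, dice_dnn, epe_zero, epe_field, folds = [], [], [], [], []
    for i, spec in enumerate(test_specs):
        sid = f"test_{i:02d}"
        with _stage("test_phantom", sid):
            pair = make_phantom_pair(spec, assets)
        with _stage("normalize", sid):
            res = spatially_normalize(model, pair.pet, assets,
                                      levels=config.registration_levels,
                                      max_iter=config.registration_max_iter)
        with _stage("quantify_dnn", sid):
            dnn_reports.append(compute_suvr(res.pet_template, atlas, voi_map, sid))
        with _stage("quantify_reference", sid):
            # individual-space parcellation through the exact generation mapping
            labels_ind = resample_chain(atlas.labels, pair.true_affine,
                                        pair.true_field, mode="nearest")
            atlas_ind = VOIAtlas(labels=labels_ind, names=atlas.names)
            ref_reports.append(compute_suvr(pair.pet, atlas_ind, voi_map, sid))
        with _stage("diagnostics", sid):
            dice_affine.append(gm_dice_template(pair, assets, res.affine, None))
            dice_dnn.append(gm_dice_template(pair, assets, res.affine, res.field))
            y_true = invert_mapping(pair.true_field, pair.true_affine)
            epe_zero.append(endpoint_error(pair, res.affine, None, brain_mask, y_true))
            epe_field.append(endpoint_error(pair, res.affine, res.field, brain_mask, y_true))
            folds.append(fold_fraction(res.field))
        if config.write_volumes:
            sub = out / "test" / sid
            sub.mkdir(parents=True, exist_ok=True)
            pair.pet.to_nifti(sub / "pet_individual.nii")
            res.pet_template.to_nifti(sub / "pet_template.nii")
            res.field.to_nifti(sub / "field.nii")

    with _stage("agreement"):
        agreement = compare_methods(ref_reports, dnn_reports)

    diagnostics = {
        "gm_dice_affine": float(np.mean(dice_affine)),
        "gm_dice_dnn": float(np.mean(dice_dnn)),
        "epe_zero": float(np.mean(epe_zero)),
        "epe_dnn": float(np.mean(epe_field)),
        "epe_ratio": float(np.mean(epe_field) / max(np.mean(epe_zero), 1e-12)),
        "fold_fraction": float(np.mean(folds)),
        "per_subject": {
            "gm_dice_affine": dice_affine, "gm_dice_dnn": dice_dnn,
            "epe_zero": epe_zero, "epe_dnn": epe_field, "fold_fraction": folds,
        },
    }

    if config.write_volumes:
        assets.template_mr.to_nifti(out / "template_mr.nii")
        assets.tissue_labels.to_nifti(out / "template_labels.nii")
        atlas.to_files(out / "atlas.nii", out / "atlas_names.json")
        voi_map.to_json(out / "composite_map.json")
    write_reports_csv(ref_reports, out / "suvr_reference.csv")
    write_reports_csv(dnn_reports, out / "suvr_dnn.csv")
    agreement.to_csv(out / "agreement.csv", index=False, float_format="%.10g")
    (out / "study.json").write_text(json.dumps(
        {"config": config.to_json_dict(),
         "diagnostics": {k: v for k, v in diagnostics.items() if k != "per_subject"}},
        indent=2))

    return StudyReport(config=config, agreement=agreement,
                       reference_reports=ref_reports, dnn_reports=dnn_reports,
                       diagnostics=diagnostics, history=history, out_dir=out)
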