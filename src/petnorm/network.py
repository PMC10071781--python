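"""Cascaded displacement-field network, its losses, and training.

The model maps an affine-registered PET volume to a dense displacement
field that carries it onto the template grid. It is a cascade of small
3-D encoder-decoder (U-net style) stages: stage 1 predicts a field from
the PET alone; each later stage sees the PET warped by the accumulated
field concatenated with the original PET and predicts a refinement, which
is merged by displacement-field composition. The final field-producing
convolution of every stage is zero-initialized, so an untrained cascade
predicts the zero field and spatial normalization reduces exactly to the
affine resampling.

Training never needs spatially normalized PET: the predicted field is
applied to the co-registered MR (windowed cross-correlation loss against
the T1 template) and to the gray-matter segment (soft Dice loss against
the template gray matter), with a squared-gradient smoothness penalty on
the field. Only PET enters the forward path; MR and GM appear in the loss
alone. On-the-fly augmentation (small affine + elastic perturbation
applied identically to PET/MR/GM, intensity scaling on PET only) guards
against overfitting.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import ndimage

from . import _autodiff as ad
from .affine import register_affine
from .geometry import apply_affine, warp_volume
from .phantom import TemplateAssets
from .volume import AffineTransform, DisplacementField, Volume

__all__ = [
    "CascadeConfig", "TrainConfig", "TrainingSample", "CascadeModel",
    "TrainingHistory", "SpatialNormalizationResult",
    "build_model", "predict_displacement", "ncc_loss", "dice_loss", "total_loss",
    "augment_sample", "train_model", "spatially_normalize",
]

NCC_VAR_FLOOR = 1e-5
DICE_SMOOTH = 1.0


@dataclass
class CascadeConfig:
    """Architecture and loss weights of the cascade.

    ``n_stages`` U-net stages of encoder depth ``levels`` with
    ``base_channels`` features at full resolution (doubled per level);
    ``ncc_window`` is the cubic window of the local cross-correlation loss
    (odd, clipped to the grid at evaluation time); ``dice_weight`` (β) and
    ``field_smoothing_weight`` (λ) weight the Dice and smoothness terms.
    ``field_resolution`` = 2 predicts the field on a 2x-downsampled grid
    and upsamples (the target deformations are smooth, so a half-resolution
    field loses little while convolutions cost 8x less); 1 predicts at
    full resolution. ``ncc_presmooth_sigma`` Gaussian-smooths both images
    entering the similarity term, equalizing their blur levels: the moving
    image is blurred by resampling while the template is not, and without
    this a dense field can lower the loss by "deconvolving" that blur
    instead of recovering correspondence.
    """

    n_stages: int = 2
    base_channels: int = 6
    levels: int = 3
    field_smoothing_weight: float = 1.0
    dice_weight: float = 1.0
    ncc_window: int = 9
    field_resolution: int = 2
    ncc_presmooth_sigma: float = 1.0
    flow_gain: float = 1.0
    multiscale_ncc: bool = True
    loss_resolution: int = 1

    def __post_init__(self) -> None:
        if self.n_stages < 1:
            raise ValueError("n_stages must be >= 1")
        if self.field_resolution not in (1, 2):
            raise ValueError("field_resolution must be 1 or 2")
        if self.ncc_window < 3 or self.ncc_window % 2 == 0:
            raise ValueError("ncc_window must be odd and >= 3")
        if self.field_smoothing_weight < 0 or self.dice_weight < 0:
            raise ValueError("loss weights must be >= 0")


@dataclass
class TrainConfig:
    """Optimization schedule and augmentation ranges (all draws uniform)."""

    epochs: int = 30
    batch_size: int = 1
    learning_rate: float = 4e-3
    flow_lr_mult: float = 2.0
    grad_clip_norm: float = 1.0
    lr_decay: bool = True
    seed: int = 0
    aug_rotation_deg: float = 3.0
    aug_translation_vox: float = 1.5
    aug_scale: float = 0.03
    aug_intensity: float = 0.1
    aug_elastic_amplitude: float = 1.5
    aug_elastic_sigma: float = 4.0

    def __post_init__(self) -> None:
        for name in ("aug_rotation_deg", "aug_translation_vox", "aug_scale",
                     "aug_intensity", "aug_elastic_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class TrainingSample:
    """One affine-registered training triplet on the template grid.

    Only ``pet_affine`` ever enters the network; ``mr_affine`` and
    ``gm_affine`` exist purely as loss carriers.
    """

    pet_affine: Volume
    mr_affine: Volume
    gm_affine: Volume

    def __post_init__(self) -> None:
        if not (self.pet_affine.shape == self.mr_affine.shape == self.gm_affine.shape):
            raise ValueError("training sample volumes must share one grid")


class SpatialNormalizationResult(NamedTuple):
    pet_template: Volume
    field: DisplacementField
    affine: AffineTransform


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class _UNetStage:
    """One encoder-decoder stage predicting a 3-channel field.

    The first convolution always runs at full resolution, so fine image
    structure is encoded into features before any pooling; with
    ``stop_level`` = 1 the decoder stops at half resolution (the field is
    upsampled outside the stage).
    """

    def __init__(self, in_channels: int, base_channels: int, levels: int,
                 rng: np.random.Generator, stop_level: int = 0):
        self.in_channels = in_channels
        self.levels = levels
        self.stop_level = min(stop_level, levels - 1)
        enc_ch = [base_channels * 2 ** l for l in range(levels)]
        self.enc = []
        prev = in_channels
        for ch in enc_ch:
            self.enc.append(self._conv_params(prev, ch, rng))
            prev = ch
        self.dec = []
        for l in range(levels - 2, self.stop_level - 1, -1):
            self.dec.append(self._conv_params(enc_ch[l + 1] + enc_ch[l], enc_ch[l], rng))
        # zero-init: untrained stage predicts the zero field
        out_ch = enc_ch[self.stop_level] if levels > 1 else enc_ch[0]
        self.flow_w = ad.param(np.zeros((3, out_ch, 3, 3, 3), dtype=np.float32))
        self.flow_b = ad.param(np.zeros(3, dtype=np.float32))

    @staticmethod
    def _conv_params(cin: int, cout: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (cin * 27))
        w = ad.param((rng.standard_normal((cout, cin, 3, 3, 3)) * std).astype(np.float32))
        b = ad.param(np.zeros(cout, dtype=np.float32))
        return w, b

    def parameters(self) -> list[ad.Var]:
        out = []
        for w, b in self.enc + self.dec:
            out += [w, b]
        out += [self.flow_w, self.flow_b]
        return out

    def lr_multipliers(self, flow_mult: float) -> list[float]:
        out = [1.0] * (2 * len(self.enc + self.dec))
        out += [flow_mult, flow_mult]
        return out

    def forward(self, x: ad.Var) -> ad.Var:
        """Full-resolution input -> field at resolution level ``stop_level``."""
        feats = []
        for i, (w, b) in enumerate(self.enc):
            if i > 0:
                x = ad.avgpool2(x)
            x = ad.leaky_relu(ad.conv3d(x, w, b), 0.2)
            feats.append(x)
        x = feats[-1]
        for j, (w, b) in enumerate(self.dec):
            skip = feats[self.levels - 2 - j]
            x = ad.concat(ad.upsample2(x), skip)
            x = ad.leaky_relu(ad.conv3d(x, w, b), 0.2)
        return ad.conv3d(x, self.flow_w, self.flow_b)


class CascadeModel:
    """Model state: configuration plus per-stage parameters."""

    def __init__(self, config: CascadeConfig, seed: int):
        self.config = config
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        self.stages = []
        stop = 1 if config.field_resolution == 2 else 0
        for k in range(config.n_stages):
            in_ch = 1 if k == 0 else 2
            self.stages.append(_UNetStage(in_ch, config.base_channels, config.levels,
                                          rng, stop_level=stop))

    def parameters(self) -> list[ad.Var]:
        return [p for s in self.stages for p in s.parameters()]

    def validate_grid(self, shape: tuple[int, int, int]) -> None:
        fr = self.config.field_resolution
        div = fr * 2 ** (self.config.levels - 1)
        if min(shape) < fr * 2 ** self.config.levels:
            raise ValueError(
                f"grid {shape} smaller than {fr * 2 ** self.config.levels} per axis "
                f"({self.config.levels} levels at 1/{fr} field resolution)")
        if any(n % div for n in shape):
            raise ValueError(f"grid {shape} must be divisible by {div} "
                             f"for {self.config.levels} levels at 1/{fr} field resolution")

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state array count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("state array shape mismatch")
            p.data = a.copy()

    # -- checkpointing (single-file archive, config embedded) --------------
    def save(self, path: str | Path) -> None:
        meta = json.dumps({"config": asdict(self.config), "seed": self.seed})
        arrays = {f"p{i}": a for i, a in enumerate(self.state_arrays())}
        np.savez(str(path), meta=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "CascadeModel":
        with np.load(str(path)) as zf:
            meta = json.loads(bytes(zf["meta"]).decode())
            model = cls(CascadeConfig(**meta["config"]), meta["seed"])
            n = len(model.parameters())
            model.load_state_arrays([zf[f"p{i}"] for i in range(n)])
        return model


def build_model(config: CascadeConfig, seed: int,
                grid_shape: tuple[int, int, int] | None = None) -> CascadeModel:
    """Seeded model construction; optionally validates the target grid."""
    model = CascadeModel(config, seed)
    if grid_shape is not None:
        model.validate_grid(tuple(grid_shape))
    return model


# ---------------------------------------------------------------------------
# forward pass
# ---------------------------------------------------------------------------

def _identity_coords(shape, dtype=np.float32) -> np.ndarray:
    return np.stack(np.meshgrid(*(np.arange(n, dtype=dtype) for n in shape),
                                indexing="ij")).astype(dtype)


def _cascade_forward(model: CascadeModel, pet: np.ndarray) -> ad.Var:
    """Composed field (3, D, H, W) as a tape node; gradients reach all stages."""
    shape = pet.shape
    model.validate_grid(shape)
    pet_c = ad.const(pet[None].astype(np.float32))
    base = ad.const(_identity_coords(shape))
    fr = model.config.field_resolution

    gain = model.config.flow_gain

    def stage_field(stage, x):
        # the stage consumes the full-resolution input (its first
        # convolution runs before any pooling) and emits the field at
        # 1/fr resolution, in full-resolution voxel units
        u = stage.forward(x)
        if gain != 1.0:
            u = ad.scale(u, gain)
        if fr > 1:
            u = ad.upsample2_linear(u)
        return u

    acc = None
    for k, stage in enumerate(model.stages):
        if k == 0:
            acc = stage_field(stage, pet_c)
        else:
            coords = ad.add(base, acc)
            warped = ad.grid_sample(pet_c, coords)
            u = stage_field(stage, ad.concat(warped, pet_c))
            # compose: acc_new(x) = u(x) + acc(x + u(x))
            acc = ad.add(u, ad.grid_sample(acc, ad.add(base, u)))
    return acc


def predict_displacement(model: CascadeModel, pet_affine: Volume) -> DisplacementField:
    """Run the cascade on an affine-registered PET (no gradients kept)."""
    acc = _cascade_forward(model, np.asarray(pet_affine.data, dtype=np.float32))
    return DisplacementField(u=np.moveaxis(acc.data, 0, -1).astype(np.float32))


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _effective_window(window: int, shape) -> int:
    w = min(window, min(shape))
    if w % 2 == 0:
        w -= 1
    return max(w, 1)


def _valid_mask(shape, window: int) -> np.ndarray:
    """Voxels whose full NCC window lies inside the grid."""
    m = window // 2
    mask = np.zeros(shape, dtype=np.float64)
    mask[tuple(slice(m, n - m) for n in shape)] = 1.0
    if not mask.any():
        mask[:] = 1.0
    return mask


def _ncc_loss_var(a: ad.Var, b_data: np.ndarray, window: int,
                  support: np.ndarray | None = None) -> ad.Var:
    """1 − mean signed local NCC over valid-window voxels.

    Window means/variances use sliding box sums; variances are floored at
    ``NCC_VAR_FLOOR`` so locally constant patches contribute correlation 0.
    ``support`` optionally restricts the mean to a voxel mask (e.g. the
    template head), the usual practice so that empty background — whose
    correlation is undefined and field-independent — does not dilute the
    similarity and its gradient.
    """
    shape = a.data.shape
    w = _effective_window(window, shape)
    n = float(w ** 3)
    dtype = a.data.dtype
    b = b_data.astype(dtype)
    bc = ad.const(b)
    sa = ad.boxsum(a, w)
    sb_ = ndimage.uniform_filter(b, size=w, mode="constant", cval=0.0) * n
    sbb_ = ndimage.uniform_filter(b * b, size=w, mode="constant", cval=0.0) * n
    sab = ad.boxsum(ad.mul(a, bc), w)
    saa = ad.boxsum(ad.mul(a, a), w)

    mean_a = ad.scale(sa, 1.0 / n)
    mean_b = sb_ / n
    cross = ad.sub(ad.scale(sab, 1.0 / n), ad.mul(mean_a, ad.const(mean_b)))
    var_a = ad.sub(ad.scale(saa, 1.0 / n), ad.mul(mean_a, mean_a))
    var_b = np.maximum(sbb_ / n - mean_b ** 2, NCC_VAR_FLOOR)
    denom = ad.sqrt(ad.mul(ad.maximum_const(var_a, NCC_VAR_FLOOR), ad.const(var_b)))
    cc = ad.div(cross, denom)
    mask = _valid_mask(shape, w)
    if support is not None:
        mask = mask * support
        if not mask.any():
            mask = _valid_mask(shape, w)
    mask = mask.astype(dtype)
    mean_cc = ad.scale(ad.vsum(ad.mul(cc, ad.const(mask))), 1.0 / float(mask.sum()))
    return ad.add_const(ad.neg(mean_cc), 1.0)


def _dice_loss_var(p: ad.Var, q_data: np.ndarray) -> ad.Var:
    q = ad.const(q_data.astype(p.data.dtype))
    num = ad.add_const(ad.scale(ad.vsum(ad.mul(p, q)), 2.0), DICE_SMOOTH)
    den = ad.add_const(ad.add(ad.vsum(p), ad.vsum(q)), DICE_SMOOTH)
    return ad.add_const(ad.neg(ad.div(num, den)), 1.0)


def _smoothness_var(field: ad.Var) -> ad.Var:
    """Mean squared forward-difference gradient over components and axes."""
    total = None
    for ax in (1, 2, 3):
        d = ad.fdiff(field, ax)
        s = ad.vsum(ad.mul(d, d))
        total = s if total is None else ad.add(total, s)
    return ad.scale(total, 1.0 / (3.0 * field.data.size))


def ncc_loss(a: Volume, b: Volume, window: int = 9) -> float:
    """Windowed cross-correlation loss between two volumes, range [0, 2].

    0 for perfectly correlated, 2 for perfectly anticorrelated, 1 where
    the local variance floor declares the correlation undefined.
    """
    if a.shape != b.shape:
        raise ValueError("volumes must share a grid")
    if window % 2 == 0:
        raise ValueError("window must be odd")
    v = _ncc_loss_var(ad.const(a.data.astype(np.float64)), b.data, window)
    return float(v.data)


def dice_loss(p: Volume, q: Volume) -> float:
    """Soft Dice loss (smoothing 1) between [0, 1]-valued volumes."""
    if p.shape != q.shape:
        raise ValueError("volumes must share a grid")
    for name, vol in (("p", p), ("q", q)):
        if vol.data.min() < 0 or vol.data.max() > 1:
            raise ValueError(f"{name} has values outside [0, 1]")
    v = _dice_loss_var(ad.const(p.data.astype(np.float64)), q.data)
    return float(v.data)


def total_loss(field: DisplacementField, mr_affine: Volume, gm_affine: Volume,
               template_mr: Volume, template_gm: Volume,
               config: CascadeConfig) -> tuple[float, dict[str, float]]:
    """Full training objective for a given field (no gradients).

    NCC(warp(mr), template_mr) + β·Dice(warp(gm), template_gm)
    + λ·smoothness(field); returns the scalar total and its components.
    """
    f = ad.const(np.moveaxis(field.u.astype(np.float64), -1, 0))
    total, comps = _total_loss_var(
        f, mr_affine.data.astype(np.float64), np.clip(gm_affine.data, 0, 1).astype(np.float64),
        template_mr.data, template_gm.data, config)
    return float(total.data), {k: float(v.data) for k, v in comps.items()}


def _total_loss_var(field: ad.Var, mr: np.ndarray, gm: np.ndarray,
                    template_mr: np.ndarray, template_gm: np.ndarray,
                    config: CascadeConfig):
    dtype = field.data.dtype
    shape = field.data.shape[1:]
    base = ad.const(_identity_coords(shape, dtype=dtype))
    coords = ad.add(base, field)
    sig = config.ncc_presmooth_sigma
    mr_s = ndimage.gaussian_filter(mr, sig) if sig > 0 else mr
    template_mr_s = ndimage.gaussian_filter(np.asarray(template_mr, dtype=np.float64),
                                            sig) if sig > 0 else template_mr
    warped_mr = ad.grid_sample(ad.const(mr_s[None].astype(dtype)), coords)
    warped_gm = ad.grid_sample(ad.const(np.clip(gm, 0, 1)[None].astype(dtype)), coords)
    # similarity counts only windows that overlap the template head
    head = (np.abs(np.asarray(template_mr)) > 1e-3).astype(np.float64)
    support = ndimage.uniform_filter(head, size=config.ncc_window,
                                     mode="constant", cval=0.0) > 1e-6
    def _pool_np(arr, red=np.mean):
        return red(arr.reshape(shape[0] // 2, 2, shape[1] // 2, 2,
                               shape[2] // 2, 2), axis=(1, 3, 5))

    half_ok = min(shape) >= 16 and not any(n % 2 for n in shape)
    win_half = max(3, (config.ncc_window // 2) | 1)
    if half_ok:
        tmpl_half = _pool_np(template_mr_s)
        head_half = _pool_np(head, red=np.max)
        support_half = ndimage.uniform_filter(head_half, size=win_half,
                                              mode="constant", cval=0.0) > 1e-6
    if config.loss_resolution == 2 and half_ok:
        # evaluate similarity and Dice at the field's own (half) resolution:
        # sub-voxel intensity tricks the field cannot meaningfully represent
        # wash out under pooling, so the aligned state is a true optimum
        ncc = _ncc_loss_var(_squeeze_ch(ad.avgpool2(warped_mr)), tmpl_half,
                            win_half, support=support_half)
        dice = _dice_loss_var(_squeeze_ch(ad.avgpool2(warped_gm)),
                              np.clip(_pool_np(np.clip(template_gm, 0, 1)), 0, 1))
    else:
        ncc = _ncc_loss_var(_squeeze_ch(warped_mr), template_mr_s, config.ncc_window,
                            support=support)
        if config.multiscale_ncc and half_ok:
            # auxiliary half-resolution similarity: larger capture range,
            # better-conditioned gradients early in training
            ncc_half = _ncc_loss_var(_squeeze_ch(ad.avgpool2(warped_mr)), tmpl_half,
                                     win_half, support=support_half)
            ncc = ad.scale(ad.add(ncc, ncc_half), 0.5)
        dice = _dice_loss_var(_squeeze_ch(warped_gm), np.clip(template_gm, 0, 1))
    smooth = _smoothness_var(field)
    total = ad.add(ncc, ad.add(ad.scale(dice, config.dice_weight),
                               ad.scale(smooth, config.field_smoothing_weight)))
    return total, {"ncc": ncc, "dice": dice, "smooth": smooth}


def _squeeze_ch(x: ad.Var) -> ad.Var:
    out = ad.Var(x.data[0], (x,))
    out._backward = lambda g: ad._accum(x, g[None])
    return out


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def augment_sample(sample: TrainingSample, cfg: TrainConfig,
                   rng: np.random.Generator) -> TrainingSample:
    """One random spatial + intensity perturbation of a training triplet.

    The same affine + elastic warp is applied to PET, MR and GM (so the
    triplet stays mutually aligned); a random intensity scale is applied
    to PET only. All-zero ranges return the sample unchanged.
    """
    if (cfg.aug_rotation_deg == 0 and cfg.aug_translation_vox == 0
            and cfg.aug_scale == 0 and cfg.aug_elastic_amplitude == 0
            and cfg.aug_intensity == 0):
        return sample
    shape = sample.pet_affine.shape
    ang = np.deg2rad(rng.uniform(-cfg.aug_rotation_deg, cfg.aug_rotation_deg, 3))
    t = rng.uniform(-cfg.aug_translation_vox, cfg.aug_translation_vox, 3)
    s = np.exp(rng.uniform(-np.log1p(cfg.aug_scale), np.log1p(cfg.aug_scale), 3))
    amp = rng.uniform(0.0, cfg.aug_elastic_amplitude)
    gain = 1.0 + rng.uniform(-cfg.aug_intensity, cfg.aug_intensity)

    cx, sx = np.cos(ang[0]), np.sin(ang[0])
    cy, sy = np.cos(ang[1]), np.sin(ang[1])
    cz, sz = np.cos(ang[2]), np.sin(ang[2])
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    m = rz @ ry @ rx @ np.diag(s)
    c = (np.asarray(shape, dtype=np.float64) - 1) / 2

    elastic = np.zeros((3,) + shape)
    if amp > 0:
        noise = np.stack([ndimage.gaussian_filter(rng.standard_normal(shape),
                                                  sigma=cfg.aug_elastic_sigma)
                          for _ in range(3)])
        mag = np.sqrt((noise ** 2).sum(axis=0)).max()
        elastic = noise * (amp / max(mag, 1e-12))

    grids = np.stack(np.meshgrid(*(np.arange(n, dtype=np.float64) for n in shape),
                                 indexing="ij"))
    pts = grids + elastic
    coords = np.einsum("ab,b...->a...", m, pts - c[:, None, None, None])
    coords += (c + t)[:, None, None, None]

    def resample(vol: Volume, clip01: bool = False) -> Volume:
        out = ndimage.map_coordinates(vol.data.astype(np.float64), coords, order=1,
                                      mode="grid-constant", cval=0.0)
        if clip01:
            out = np.clip(out, 0.0, 1.0)
        return vol.copy(data=out)

    pet = resample(sample.pet_affine)
    pet.data *= gain
    return TrainingSample(pet_affine=pet, mr_affine=resample(sample.mr_affine),
                          gm_affine=resample(sample.gm_affine, clip01=True))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainingHistory:
    """Per-epoch mean loss components plus the index of the kept state."""

    rows: list[dict] = dc_field(default_factory=list)
    best_epoch: int = -1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["epoch", "total", "ncc", "dice", "smooth"])

    def summary(self) -> str:
        df = self.to_frame()
        lines = ["Cascade training history",
                 f"  epochs: {len(df)}   best epoch: {self.best_epoch}"]
        if len(df):
            first, last = df.iloc[0], df.iloc[-1]
            lines.append(f"  total loss: {first['total']:.4f} -> {last['total']:.4f}")
            lines.append(f"  ncc: {first['ncc']:.4f} -> {last['ncc']:.4f}"
                         f"   dice: {first['dice']:.4f} -> {last['dice']:.4f}")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def train_model(model: CascadeModel, samples: list[TrainingSample],
                assets: TemplateAssets, cfg: TrainConfig) -> TrainingHistory:
    """Jointly train all cascade stages by minibatch Adam.

    Each sample is re-augmented every epoch; the parameter state with the
    best epoch-mean loss is kept (training is restored to it on return).
    Raises on a non-finite loss, naming the offending epoch.
    """
    if not samples:
        raise ValueError("need at least one training sample")
    shape = samples[0].pet_affine.shape
    model.validate_grid(shape)
    for s in samples:
        if s.pet_affine.shape != shape:
            raise ValueError("all training samples must share the template grid")
    template_mr = assets.template_mr.data.astype(np.float32)
    template_gm = np.clip(assets.gm_probability.data, 0, 1).astype(np.float32)

    rng = np.random.default_rng(cfg.seed)
    mults = [m for s_ in model.stages for m in s_.lr_multipliers(cfg.flow_lr_mult)]
    opt = ad.Adam(model.parameters(), lr=cfg.learning_rate, lr_mults=mults)
    history = TrainingHistory()
    best = (np.inf, None)
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(samples))
        sums = {"total": 0.0, "ncc": 0.0, "dice": 0.0, "smooth": 0.0}
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            opt.zero_grad()
            if cfg.lr_decay:
                warm = min(cfg.epochs // 10 + 1, 3)
                if epoch < warm:
                    opt.lr = cfg.learning_rate * (epoch + 1) / warm
                else:
                    frac = (epoch - warm) / max(cfg.epochs - 1 - warm, 1)
                    opt.lr = cfg.learning_rate * (0.1 + 0.9 * 0.5 * (1 + np.cos(np.pi * frac)))
            for si in batch:
                aug = augment_sample(samples[si], cfg, rng)
                field = _cascade_forward(model, np.asarray(aug.pet_affine.data, dtype=np.float32))
                loss, comps = _total_loss_var(
                    field, aug.mr_affine.data.astype(np.float32),
                    aug.gm_affine.data.astype(np.float32),
                    template_mr, template_gm, model.config)
                if not np.isfinite(loss.data):
                    raise RuntimeError(f"non-finite training loss at epoch {epoch}")
                scaled = ad.scale(loss, 1.0 / len(batch))
                ad.backward(scaled)
                sums["total"] += float(loss.data)
                for k in ("ncc", "dice", "smooth"):
                    sums[k] += float(comps[k].data)
            if cfg.grad_clip_norm > 0:
                ad.clip_global_norm(model.parameters(), cfg.grad_clip_norm)
            opt.step()
        row = {"epoch": epoch}
        row.update({k: v / len(samples) for k, v in sums.items()})
        history.rows.append(row)
        if row["total"] < best[0]:
            best = (row["total"], model.state_arrays())
            history.best_epoch = epoch
    if best[1] is not None:
        model.load_state_arrays(best[1])
    return history


# ---------------------------------------------------------------------------
# inference pipeline
# ---------------------------------------------------------------------------

def spatially_normalize(model: CascadeModel, pet_individual: Volume,
                        assets: TemplateAssets, levels: int = 2,
                        max_iter: int = 400,
                        registration_target: Volume | None = None) -> SpatialNormalizationResult:
    """Individual-space PET -> template space, from PET alone.

    Affine registration to the template grid, cascade field prediction,
    and a final pull-warp. No subject MR is consulted anywhere on this
    path. The affine target defaults to the average amyloid PET template
    (same modality as the input; a T1 target biases the fit for
    amyloid-positive scans whose cortex is brighter than T1 gray matter).
    """
    if pet_individual.data.ndim != 3:
        raise ValueError("expected a 3-D PET volume")
    if registration_target is None:
        registration_target = assets.template_pet_average()
    reg = register_affine(pet_individual, registration_target, levels=levels,
                          max_iter=max_iter)
    pet_affine = apply_affine(pet_individual, reg.transform,
                              out_shape=assets.template_mr.shape)
    field = predict_displacement(model, pet_affine)
    pet_template = warp_volume(pet_affine, field, mode="linear")
    return SpatialNormalizationResult(pet_template=pet_template, field=field,
                                      affine=reg.transform)
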