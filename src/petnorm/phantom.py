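"""Procedural 3-D brain phantoms with known ground-truth deformations.

The generator emulates the data a PET spatial-normalization network is
trained on: a fixed T1-like template with tissue labels, and individual
"subjects" derived from it by a known smooth deformation, ventricular
enlargement, a random small affine, optional focal lesions and noise.
Amyloid-positive subjects show elevated cortical tracer uptake while the
cerebellar reference region is unaffected, so regional SUVR has an exact
analytic value on noise-free phantoms (cortex 1.3 / cerebellum 0.6).

Tissue label codes (template space): 0 background, 1 CSF/ventricle,
2 white matter, 3 cortical gray matter, 4 cerebellar gray matter,
5 subcortical gray matter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .geometry import compose_displacements, jacobian_determinant, resample_chain
from .volume import AffineTransform, DisplacementField, Volume

__all__ = [
    "BACKGROUND", "CSF", "WM", "CORTICAL_GM", "CEREBELLAR_GM", "SUBCORTICAL_GM",
    "PET_INTENSITY", "MR_INTENSITY",
    "PhantomSpec", "TemplateAssets", "PhantomPair",
    "make_template", "sample_deformation", "make_phantom_pair", "pet_from_labels",
    "save_phantom_pair",
]

BACKGROUND, CSF, WM, CORTICAL_GM, CEREBELLAR_GM, SUBCORTICAL_GM = 0, 1, 2, 3, 4, 5

# Tracer uptake per tissue class, in arbitrary activity units. Ratios are
# chosen so that a positive phantom's global cortical SUVR (1.3/0.6 ≈ 2.17)
# clears the 1.5 positivity threshold with margin while a negative phantom
# (0.6/0.6 = 1.0) falls well below it.
PET_INTENSITY = {
    "negative": {BACKGROUND: 0.0, CSF: 0.1, WM: 1.0, CORTICAL_GM: 0.6,
                 CEREBELLAR_GM: 0.6, SUBCORTICAL_GM: 0.6},
    "positive": {BACKGROUND: 0.0, CSF: 0.1, WM: 1.0, CORTICAL_GM: 1.3,
                 CEREBELLAR_GM: 0.6, SUBCORTICAL_GM: 0.9},
}

# T1-like contrast: CSF < GM < WM.
MR_INTENSITY = {BACKGROUND: 0.0, CSF: 0.2, WM: 1.0, CORTICAL_GM: 0.6,
                CEREBELLAR_GM: 0.6, SUBCORTICAL_GM: 0.6}


@dataclass
class PhantomSpec:
    """Parameters of one synthetic subject.

    ``deform_amplitude`` is the maximum ground-truth displacement magnitude
    in voxels; ``ventricle_scale`` ≥ 1 enlarges the ventricles radially;
    ``noise_sd`` is Gaussian noise expressed as a fraction of the cortical
    PET intensity; ``lesion`` is an optional ``(center, radius)`` sphere in
    individual-space voxel coordinates set to CSF-like intensity. The
    ``affine_*`` ranges bound the random subject pose (uniform draws).
    """

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    seed: int = 0
    amyloid_status: str = "negative"
    deform_amplitude: float = 3.0
    ventricle_scale: float = 1.2
    lesion: tuple[tuple[float, float, float], float] | None = None
    noise_sd: float = 0.05
    affine_rot_deg: float = 5.0
    affine_trans_vox: float = 2.0
    affine_scale: float = 0.05

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if self.amyloid_status not in ("positive", "negative"):
            raise ValueError(f"amyloid_status must be 'positive' or 'negative', got {self.amyloid_status!r}")
        if self.deform_amplitude < 0:
            raise ValueError("deform_amplitude must be >= 0")
        if self.ventricle_scale < 1:
            raise ValueError("ventricle_scale must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def to_json_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "grid_shape", "seed", "amyloid_status", "deform_amplitude",
            "ventricle_scale", "lesion", "noise_sd",
            "affine_rot_deg", "affine_trans_vox", "affine_scale")}
        d["grid_shape"] = list(self.grid_shape)
        if self.lesion is not None:
            d["lesion"] = [list(self.lesion[0]), self.lesion[1]]
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        d["grid_shape"] = tuple(d["grid_shape"])
        if d.get("lesion") is not None:
            d["lesion"] = (tuple(d["lesion"][0]), float(d["lesion"][1]))
        return cls(**d)


@dataclass
class TemplateAssets:
    """Template-space volumes shared by every phantom on one grid.

    ``texture`` is the smooth multiplicative intensity pattern (zero-mean,
    gyral-scale) shared by the MR and PET constructions; it provides the
    dense anatomical structure that makes inner-tissue correspondence
    observable, as in real images.
    """

    template_mr: Volume
    tissue_labels: Volume
    gm_probability: Volume
    texture: Volume

    def template_pet(self, amyloid_status: str) -> Volume:
        """Textured template-space PET for the given amyloid status."""
        base = pet_from_labels(self.tissue_labels, amyloid_status)
        return base.copy(data=np.clip(base.data * (1.0 + self.texture.data), 0.0, None),
                         id=f"template_pet_{amyloid_status}")

    def template_pet_average(self) -> Volume:
        """Average amyloid PET template (mean of the positive and negative
        uptake patterns).

        This is the affine-registration target: registering a PET scan to
        a same-modality average template avoids the status-dependent bias
        a T1 target would introduce (a bright amyloid-positive cortex
        correlates poorly with T1 gray-matter contrast).
        """
        pos = self.template_pet("positive").data
        neg = self.template_pet("negative").data
        return self.template_mr.copy(data=0.5 * (pos + neg), id="template_pet_average")


@dataclass
class PhantomPair:
    """One synthetic subject plus its ground truth.

    ``true_field``/``true_affine`` define the generation mapping
    ``g(x) = M (x + u(x)) + t`` under which every individual-space volume
    was pulled from template space, i.e.
    ``individual = warp(apply_affine(template, true_affine), true_field)``.
    ``tissue_labels`` are the template-space labels; ``individual_labels``
    the same tissues carried into individual space (nearest neighbour).
    """

    spec: PhantomSpec
    pet: Volume
    mr: Volume
    gm_segment: Volume
    true_field: DisplacementField
    true_affine: AffineTransform
    tissue_labels: Volume
    individual_labels: Volume


# ---------------------------------------------------------------------------
# template construction
# ---------------------------------------------------------------------------

def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.meshgrid(*(np.arange(n, dtype=np.float64) for n in shape), indexing="ij")
    rho2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return rho2


def make_template(grid_shape=(48, 48, 48), seed: int = 0) -> TemplateAssets:
    """Deterministic procedural brain template.

    Builds an ellipsoidal cerebrum with a cortical GM shell and WM
    interior, paired CSF ventricles, two subcortical GM nuclei, and an
    inferior cerebellar GM blob, then assigns T1-like mean intensities
    (CSF < GM < WM) plus a faint seeded smooth intensity texture. The GM
    probability map is 1 on GM labels with smoothed borders.
    """
    grid_shape = tuple(int(n) for n in grid_shape)
    if min(grid_shape) < 32:
        raise ValueError(f"template grid must be >= 32 per axis, got {grid_shape}")
    n = np.asarray(grid_shape, dtype=np.float64)
    labels = np.zeros(grid_shape, dtype=np.int16)

    # cerebrum: shell = cortical GM, interior = WM
    c_b = (0.50 * n[0], 0.52 * n[1], 0.56 * n[2])
    r_b = (0.35 * n[0], 0.40 * n[1], 0.31 * n[2])
    rho2 = _ellipsoid(grid_shape, c_b, r_b)
    labels[rho2 <= 1.0] = CORTICAL_GM
    labels[rho2 <= 0.8 ** 2] = WM

    # paired lateral ventricles (CSF), inside WM only
    for sx in (-1.0, 1.0):
        cv = (c_b[0] + sx * 0.095 * n[0], c_b[1] + 0.03 * n[1], c_b[2] + 0.02 * n[2])
        rv = (0.055 * n[0], 0.13 * n[1], 0.08 * n[2])
        vent = _ellipsoid(grid_shape, cv, rv) <= 1.0
        labels[vent & (labels == WM)] = CSF

    # subcortical GM nuclei, inside WM only
    for sx in (-1.0, 1.0):
        cs = (c_b[0] + sx * 0.16 * n[0], c_b[1] - 0.03 * n[1], c_b[2] - 0.06 * n[2])
        nuc = _ellipsoid(grid_shape, cs, (0.065 * n[0],) * 3) <= 1.0
        labels[nuc & (labels == WM)] = SUBCORTICAL_GM

    # cerebellar GM: inferior-posterior paired blobs, outside the cerebrum
    for sx in (-1.0, 1.0):
        cc = (c_b[0] + sx * 0.085 * n[0], 0.27 * n[1], 0.20 * n[2])
        cer = _ellipsoid(grid_shape, cc, (0.115 * min(grid_shape),) * 3) <= 1.0
        labels[cer & (labels == BACKGROUND)] = CEREBELLAR_GM

    mr = np.zeros(grid_shape, dtype=np.float64)
    for lab, val in MR_INTENSITY.items():
        mr[labels == lab] = val
    # multi-scale intensity texture: gyral-scale structure plus a broad
    # inhomogeneity component, shared by MR and PET so that dense
    # correspondence is observable inside tissue plateaus (real anatomy
    # is never flat)
    rng = np.random.default_rng(seed)
    fine = ndimage.gaussian_filter(rng.standard_normal(grid_shape), sigma=1.5)
    coarse = ndimage.gaussian_filter(rng.standard_normal(grid_shape), sigma=5.0)
    texture = 0.12 * fine / fine.std() + 0.05 * coarse / coarse.std()
    mr = np.clip(mr * (1.0 + texture), 0.0, None)

    gm_mask = np.isin(labels, (CORTICAL_GM, CEREBELLAR_GM, SUBCORTICAL_GM)).astype(np.float64)
    gm_prob = np.clip(ndimage.gaussian_filter(gm_mask, sigma=0.7), 0.0, 1.0)

    return TemplateAssets(
        template_mr=Volume(data=mr, id="template_mr"),
        tissue_labels=Volume(data=labels, id="template_tissue_labels"),
        gm_probability=Volume(data=gm_prob, id="template_gm_probability"),
        texture=Volume(data=texture, id="template_texture"),
    )


def pet_from_labels(tissue_labels: Volume, amyloid_status: str) -> Volume:
    """Piecewise-constant PET image from tissue labels (exact, unsmoothed).

    Keeping this exact makes the analytic SUVR of a noise-free positive
    phantom in template space equal to 1.3/0.6 for the global cortical VOI.
    """
    table = PET_INTENSITY[amyloid_status]
    out = np.zeros(tissue_labels.shape, dtype=np.float64)
    for lab, val in table.items():
        out[tissue_labels.data == lab] = val
    return tissue_labels.copy(data=out, id=f"pet_{amyloid_status}")


# ---------------------------------------------------------------------------
# deformations
# ---------------------------------------------------------------------------

def sample_deformation(grid_shape, amplitude: float, seed: int,
                       sigma: float = 4.0, max_retries: int = 20) -> DisplacementField:
    """Smooth random displacement field with guaranteed positive Jacobian.

    White Gaussian noise per component is smoothed (``sigma`` >= 4 voxels)
    and rescaled so the maximum displacement magnitude equals ``amplitude``.
    If the resulting map folds anywhere, a fresh field is drawn from the
    next seed-derived stream (bounded retries).
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    grid_shape = tuple(int(n) for n in grid_shape)
    if amplitude == 0:
        return DisplacementField.zeros(grid_shape)
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(max_retries):
        rng = np.random.default_rng(child)
        u = np.stack([ndimage.gaussian_filter(rng.standard_normal(grid_shape), sigma=sigma)
                      for _ in range(3)], axis=-1)
        mag = np.sqrt((u ** 2).sum(axis=-1)).max()
        u *= amplitude / max(mag, 1e-12)
        fld = DisplacementField(u=u.astype(np.float32))
        if jacobian_determinant(fld).data.min() > 0:
            return fld
    raise RuntimeError(
        f"no fold-free field with amplitude {amplitude} found in {max_retries} draws "
        f"(seed {seed}); reduce amplitude or increase smoothing")


def ventricle_expansion_field(tissue_labels: Volume, scale: float) -> DisplacementField:
    """Radial pull field enlarging the ventricles by ``scale``.

    Inside the ventricular radius the mapping samples the template at
    ``c + (x-c)/scale`` (pure magnification by ``scale``); the displacement
    is tapered to zero with a cosine window beyond the ventricle so the
    cortex is barely moved. Emulates hydrocephalus-like enlargement, the
    stress case conventional template registration handles poorly.
    """
    shape = tissue_labels.shape
    if scale == 1.0:
        return DisplacementField.zeros(shape)
    vent = tissue_labels.data == CSF
    if not vent.any():
        raise ValueError("tissue labels contain no ventricle (CSF) voxels")
    idx = np.argwhere(vent).astype(np.float64)
    center = idx.mean(axis=0)
    r_v = float(np.sqrt(((idx - center) ** 2).sum(axis=1)).max())
    r_out = r_v + max(6.0, 1.2 * r_v)
    grids = np.stack(np.meshgrid(*(np.arange(n, dtype=np.float64) for n in shape),
                                 indexing="ij"), axis=-1)
    d = grids - center
    r = np.sqrt((d ** 2).sum(axis=-1))
    w = np.zeros(shape)
    w[r <= r_v] = 1.0
    taper = (r > r_v) & (r < r_out)
    w[taper] = np.cos(0.5 * np.pi * (r[taper] - r_v) / (r_out - r_v)) ** 2
    u = d * ((1.0 / scale - 1.0) * w)[..., None]
    return DisplacementField(u=u.astype(np.float32))


def _random_pose(spec: PhantomSpec, rng: np.random.Generator) -> AffineTransform:
    """Small random rigid+scale pull transform about the grid center."""
    if spec.affine_rot_deg == 0 and spec.affine_trans_vox == 0 and spec.affine_scale == 0:
        return AffineTransform.identity()
    ang = np.deg2rad(rng.uniform(-spec.affine_rot_deg, spec.affine_rot_deg, size=3))
    t = rng.uniform(-spec.affine_trans_vox, spec.affine_trans_vox, size=3)
    s = np.exp(rng.uniform(-np.log1p(spec.affine_scale), np.log1p(spec.affine_scale), size=3))
    cx, sx = np.cos(ang[0]), np.sin(ang[0])
    cy, sy = np.cos(ang[1]), np.sin(ang[1])
    cz, sz = np.cos(ang[2]), np.sin(ang[2])
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    m = rz @ ry @ rx @ np.diag(s)
    c = (np.asarray(spec.grid_shape, dtype=np.float64) - 1) / 2
    return AffineTransform(matrix=m, translation=c - m @ c + t)


# ---------------------------------------------------------------------------
# subject generation
# ---------------------------------------------------------------------------

def make_phantom_pair(spec: PhantomSpec, assets: TemplateAssets) -> PhantomPair:
    """Generate one individual-space PET/MR/GM triplet with ground truth.

    The ground-truth mapping composes ventricular enlargement, a smooth
    random deformation and a random pose; every individual-space volume is
    pulled from template space through that single mapping (one
    interpolation pass). PET intensities follow the amyloid status, the
    optional lesion is punched out at CSF-like intensity, and Gaussian
    noise (fraction of cortical PET uptake) is added last and clipped at 0.
    """
    if assets.tissue_labels.shape != spec.grid_shape:
        raise ValueError("template assets are not on the spec's grid")
    rng = np.random.default_rng(spec.seed)
    seed_deform = int(rng.integers(2 ** 31))
    u_rand = sample_deformation(spec.grid_shape, spec.deform_amplitude, seed_deform)
    u_vent = ventricle_expansion_field(assets.tissue_labels, spec.ventricle_scale)
    # warp by the composite = apply random deformation, then enlargement
    true_field = compose_displacements(u_vent, u_rand)
    true_affine = _random_pose(spec, rng)

    status = spec.amyloid_status
    pet_t = assets.template_pet(status)
    pet = resample_chain(pet_t, true_affine, true_field)
    mr = resample_chain(assets.template_mr, true_affine, true_field)
    gm = resample_chain(assets.gm_probability, true_affine, true_field)
    ind_labels = resample_chain(assets.tissue_labels, true_affine, true_field, mode="nearest")

    pet_data = pet.data.astype(np.float64)
    mr_data = mr.data.astype(np.float64)
    if spec.lesion is not None:
        center, radius = spec.lesion
        rho2 = _ellipsoid(spec.grid_shape, center, (radius,) * 3)
        mask = rho2 <= 1.0
        if not mask.any() or (ind_labels.data[mask] == BACKGROUND).any():
            raise ValueError(f"lesion at {center} r={radius} is not fully inside the brain")
        pet_data[mask] = PET_INTENSITY[status][CSF]
        mr_data[mask] = MR_INTENSITY[CSF]
    if spec.noise_sd > 0:
        cortical = PET_INTENSITY[status][CORTICAL_GM]
        pet_data = pet_data + rng.normal(0.0, spec.noise_sd * cortical, spec.grid_shape)
        mr_data = mr_data + rng.normal(0.0, spec.noise_sd * MR_INTENSITY[WM], spec.grid_shape)
    pet_data = np.clip(pet_data, 0.0, None)
    mr_data = np.clip(mr_data, 0.0, None)

    sid = f"phantom_{status}_{spec.seed}"
    return PhantomPair(
        spec=spec,
        pet=Volume(data=pet_data, id=f"{sid}_pet"),
        mr=Volume(data=mr_data, id=f"{sid}_mr"),
        gm_segment=Volume(data=np.clip(gm.data, 0.0, 1.0), id=f"{sid}_gm"),
        true_field=true_field,
        true_affine=true_affine,
        tissue_labels=assets.tissue_labels,
        individual_labels=ind_labels.copy(id=f"{sid}_labels"),
    )


def save_phantom_pair(pair: PhantomPair, out_dir: str | Path) -> None:
    """Write all phantom components as NIfTI plus a JSON spec sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pair.pet.to_nifti(out / "pet.nii")
    pair.mr.to_nifti(out / "mr.nii")
    pair.gm_segment.to_nifti(out / "gm_segment.nii")
    pair.individual_labels.to_nifti(out / "individual_labels.nii")
    pair.true_field.to_nifti(out / "true_field.nii")
    sidecar = {"spec": pair.spec.to_json_dict(),
               "true_affine": pair.true_affine.to_json_dict()}
    (out / "phantom.json").write_text(json.dumps(sidecar, indent=2))
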