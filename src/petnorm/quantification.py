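"""Atlas-based regional SUVR quantification and amyloid positivity.

Regional tracer uptake is averaged over template-space volumes of
interest, grouped into the six standard composite regions (global
cerebral cortex, frontal, posterior cingulate-precuneus, lateral
parietal, lateral temporal, medial temporal), and divided by the mean
uptake of cerebellar gray matter to form SUVR. Global-cortex SUVR above
1.5 classifies a scan amyloid-positive (a tie is negative).

Real pipelines obtain the label atlas from an MRI parcellation of the
template; here :func:`build_phantom_atlas` derives an equivalent
geometric atlas from the phantom's tissue labels, and the label-to-
composite grouping is an editable JSON mapping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import phantom as ph
from .volume import Volume

__all__ = [
    "COMPOSITE_NAMES", "VOIAtlas", "CompositeVOIMap", "SUVRReport",
    "extract_regional_means", "compute_suvr", "classify_amyloid_status",
    "build_phantom_atlas", "reports_to_frame", "write_reports_csv", "read_reports_csv",
]

COMPOSITE_NAMES = (
    "global_cerebral_cortex",
    "frontal",
    "posterior_cingulate_precuneus",
    "lateral_parietal",
    "lateral_temporal",
    "medial_temporal",
)

POSITIVITY_THRESHOLD = 1.5


@dataclass
class VOIAtlas:
    """Integer label volume in template space plus label names."""

    labels: Volume
    names: dict[int, str]

    def __post_init__(self) -> None:
        if not self.labels.is_integer():
            raise ValueError("atlas labels must be integers")
        present = set(np.unique(self.labels.data).astype(int)) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"atlas labels without names: {sorted(missing)}")

    def to_files(self, nifti_path: str | Path, json_path: str | Path) -> None:
        self.labels.to_nifti(nifti_path)
        Path(json_path).write_text(json.dumps({str(k): v for k, v in self.names.items()},
                                              indent=2))

    @classmethod
    def from_files(cls, nifti_path: str | Path, json_path: str | Path) -> "VOIAtlas":
        names = {int(k): v for k, v in json.loads(Path(json_path).read_text()).items()}
        return cls(labels=Volume.from_nifti(nifti_path, id="atlas"), names=names)


@dataclass
class CompositeVOIMap:
    """Grouping of atlas labels into the six composites plus the reference.

    The reference (cerebellar gray matter) must be disjoint from every
    composite.
    """

    composites: dict[str, set[int]]
    reference: set[int]

    def __post_init__(self) -> None:
        self.composites = {k: set(int(v) for v in vals) for k, vals in self.composites.items()}
        self.reference = set(int(v) for v in self.reference)
        if set(self.composites) != set(COMPOSITE_NAMES):
            raise ValueError(f"composites must be exactly {COMPOSITE_NAMES}")
        for name, labels in self.composites.items():
            if self.reference & labels:
                raise ValueError(f"reference labels overlap composite {name!r}")

    def to_json(self, path: str | Path) -> None:
        payload = {"composites": {k: sorted(v) for k, v in self.composites.items()},
                   "reference": sorted(self.reference)}
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CompositeVOIMap":
        d = json.loads(Path(path).read_text())
        return cls(composites={k: set(v) for k, v in d["composites"].items()},
                   reference=set(d["reference"]))


@dataclass
class SUVRReport:
    """Per-composite SUVR for one subject, with the positivity call."""

    suvr: dict[str, float]
    reference_mean: float
    status: str
    subject_id: str = ""

    def __post_init__(self) -> None:
        for name, val in self.suvr.items():
            if not np.isfinite(val) or val <= 0:
                raise ValueError(f"SUVR for {name!r} must be positive and finite, got {val}")
        expected = classify_amyloid_status(self.suvr["global_cerebral_cortex"])
        if self.status != expected:
            raise ValueError(
                f"status {self.status!r} inconsistent with global SUVR "
                f"{self.suvr['global_cerebral_cortex']:.4f} (threshold {POSITIVITY_THRESHOLD})")


def extract_regional_means(pet_template: Volume, atlas: VOIAtlas,
                           labels: set[int]) -> tuple[float, int]:
    """Unweighted mean uptake and voxel count over a set of atlas labels."""
    if pet_template.shape != atlas.labels.shape:
        raise ValueError("PET and atlas must share the template grid")
    if not labels:
        raise ValueError("label set is empty")
    mask = np.isin(atlas.labels.data, sorted(labels))
    count = int(mask.sum())
    if count == 0:
        raise ValueError(f"no atlas voxels match labels {sorted(labels)}")
    return float(pet_template.data[mask].mean()), count


def classify_amyloid_status(global_suvr: float,
                            threshold: float = POSITIVITY_THRESHOLD) -> str:
    """'positive' iff global-cortex SUVR strictly exceeds the threshold."""
    if not np.isfinite(global_suvr) or global_suvr <= 0:
        raise ValueError(f"global SUVR must be positive, got {global_suvr}")
    return "positive" if global_suvr > threshold else "negative"


def compute_suvr(pet_template: Volume, atlas: VOIAtlas, voi_map: CompositeVOIMap,
                 subject_id: str = "") -> SUVRReport:
    """SUVR per composite: regional mean / cerebellar-gray reference mean."""
    ref_mean, _ = extract_regional_means(pet_template, atlas, voi_map.reference)
    if ref_mean <= 0:
        raise ValueError(f"reference mean must be positive, got {ref_mean}")
    suvr = {}
    for name, labels in voi_map.composites.items():
        mean, _ = extract_regional_means(pet_template, atlas, labels)
        suvr[name] = mean / ref_mean
    status = classify_amyloid_status(suvr["global_cerebral_cortex"])
    return SUVRReport(suvr=suvr, reference_mean=ref_mean, status=status,
                      subject_id=subject_id)


# ---------------------------------------------------------------------------
# phantom atlas
# ---------------------------------------------------------------------------

# cortical sector anchors in (|x|, y, z) direction space relative to the
# cortical centroid: frontal is anterior, the cingulate-precuneus composite
# posterior-medial, parietal superior-lateral, temporal inferior-lateral
_SECTOR_ANCHORS = {
    "frontal": (0.15, 1.0, 0.15),
    "posterior_cingulate_precuneus": (0.0, -1.0, 0.35),
    "lateral_parietal": (0.85, -0.25, 0.75),
    "lateral_temporal": (0.9, 0.15, -0.6),
}

SECTOR_LABELS = {"frontal": 11, "posterior_cingulate_precuneus": 12,
                 "lateral_parietal": 13, "lateral_temporal": 14,
                 "medial_temporal": 15, "cerebellar_reference": 20}


def build_phantom_atlas(tissue_labels: Volume) -> tuple[VOIAtlas, CompositeVOIMap]:
    """Geometric composite atlas from phantom tissue labels.

    The cortical GM shell is partitioned exhaustively into four lobar
    sectors by nearest-anchor assignment in normalized (|x|, y, z)
    direction space, the subcortical nuclei stand in for the medial
    temporal composite, cerebellar GM is the reference, and the global
    composite is the union of the cortical sectors.
    """
    lab = tissue_labels.data
    for cls_, name in ((ph.CORTICAL_GM, "cortical GM"), (ph.CEREBELLAR_GM, "cerebellar GM"),
                       (ph.SUBCORTICAL_GM, "subcortical GM")):
        if not (lab == cls_).any():
            raise ValueError(f"tissue labels contain no {name}")
    out = np.zeros(lab.shape, dtype=np.int16)

    cortex = np.argwhere(lab == ph.CORTICAL_GM).astype(np.float64)
    centroid = cortex.mean(axis=0)
    d = cortex - centroid
    d[:, 0] = np.abs(d[:, 0])  # fold left/right: lateral composites are bilateral
    d /= np.linalg.norm(d, axis=1, keepdims=True).clip(min=1e-9)
    anchors = np.array([_SECTOR_ANCHORS[k] for k in _SECTOR_ANCHORS])
    anchors /= np.linalg.norm(anchors, axis=1, keepdims=True)
    nearest = (d @ anchors.T).argmax(axis=1)
    sector_names = list(_SECTOR_ANCHORS)
    idx = tuple(cortex.astype(int).T)
    out[idx] = np.array([SECTOR_LABELS[sector_names[i]] for i in nearest], dtype=np.int16)

    out[lab == ph.SUBCORTICAL_GM] = SECTOR_LABELS["medial_temporal"]
    out[lab == ph.CEREBELLAR_GM] = SECTOR_LABELS["cerebellar_reference"]

    names = {v: k for k, v in SECTOR_LABELS.items()}
    atlas = VOIAtlas(labels=tissue_labels.copy(data=out, id="phantom_atlas"), names=names)
    cortical_sectors = {SECTOR_LABELS[k] for k in _SECTOR_ANCHORS}
    voi_map = CompositeVOIMap(
        composites={
            "global_cerebral_cortex": set(cortical_sectors),
            "frontal": {SECTOR_LABELS["frontal"]},
            "posterior_cingulate_precuneus": {SECTOR_LABELS["posterior_cingulate_precuneus"]},
            "lateral_parietal": {SECTOR_LABELS["lateral_parietal"]},
            "lateral_temporal": {SECTOR_LABELS["lateral_temporal"]},
            "medial_temporal": {SECTOR_LABELS["medial_temporal"]},
        },
        reference={SECTOR_LABELS["cerebellar_reference"]},
    )
    return atlas, voi_map


# ---------------------------------------------------------------------------
# report serialization (CSV, one row per subject x region)
# ---------------------------------------------------------------------------

def reports_to_frame(reports: list[SUVRReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        for region in COMPOSITE_NAMES:
            rows.append({"subject_id": r.subject_id, "region": region,
                         "suvr": r.suvr[region], "reference_mean": r.reference_mean,
                         "status": r.status})
    return pd.DataFrame(rows, columns=["subject_id", "region", "suvr",
                                       "reference_mean", "status"])


def write_reports_csv(reports: list[SUVRReport], path: str | Path) -> None:
    reports_to_frame(reports).to_csv(path, index=False, float_format="%.10g")


def read_reports_csv(path: str | Path) -> list[SUVRReport]:
    df = pd.read_csv(path)
    out = []
    for sid, grp in df.groupby("subject_id", sort=False):
        suvr = dict(zip(grp["region"], grp["suvr"]))
        out.append(SUVRReport(suvr=suvr, reference_mean=float(grp["reference_mean"].iloc[0]),
                              status=str(grp["status"].iloc[0]), subject_id=str(sid)))
    return out
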