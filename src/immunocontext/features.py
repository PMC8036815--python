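"""Per-patient feature assembly: 126 image + 60 spatial + 15 clinical = 201.

The image block counts and densities (per mm²) 21 cell populations in each
of the three slide regions (tumour core, invasive front-in, front-out):
six phenotype classes × three PD-L1 co-expression states (positive /
negative / any) plus three PD-L1⁺ populations (any cell, epithelial,
non-epithelial).  The spatial block carries cross-type L values for ten
(source, target) population pairs at six radii — immune and PD-L1⁺
populations around tumour buds, and PD-L1⁺ cells around each immune
marker population.  The clinical block one-hot encodes sex, stage, T, N
and M alongside age.

The exact composition within the published block totals is a documented
reconstruction (the original appendix-level feature list is not public);
the schema is a single source of truth, ordered and named identically
across patients and runs, and overridable in code.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .phenotyping import population_masks
from .regions import REGION_LABELS, RegionPartition, assign_regions
from .spatial import DEFAULT_RADII, cross_k

IMAGE_CLASSES = ("TB", "M1", "M2", "total_macrophage", "general_T", "cytotoxic_T")
PDL1_STATES = ("pdl1pos", "pdl1neg", "any")
EXTRA_POPULATIONS = ("PDL1_any", "PDL1_epithelial", "PDL1_nonepithelial")
METRICS = ("count", "density")

SPATIAL_PAIRS: tuple[tuple[str, str], ...] = (
    ("TB", "CD3"),
    ("TB", "CD8"),
    ("TB", "CD68"),
    ("TB", "CD163"),
    ("TB", "PDL1_epithelial"),
    ("TB", "PDL1_nonepithelial"),
    ("CD3", "PDL1"),
    ("CD8", "PDL1"),
    ("CD68", "PDL1"),
    ("CD163", "PDL1"),
)

CLINICAL_NAMES = (
    "age",
    "sex_male", "sex_female",
    "stage_II", "stage_IIIA", "stage_IIIB", "stage_IV",
    "T2", "T3", "T4",
    "N0", "N1", "N2",
    "M0", "M1",
)

FEATURE_SETS = (
    "image", "spatial", "clinical",
    "image_spatial", "image_clinical", "spatial_clinical",
    "image_spatial_clinical",
)


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered, named feature blocks; block sizes are 126 / 60 / 15."""

    radii: tuple[float, ...] = DEFAULT_RADII

    @property
    def image_names(self) -> tuple[str, ...]:
        pops = [f"{c}_{s}" for c in IMAGE_CLASSES for s in PDL1_STATES]
        pops += list(EXTRA_POPULATIONS)
        return tuple(
            f"{p}_{r}_{m}" for p in pops for r in REGION_LABELS for m in METRICS
        )

    @property
    def spatial_names(self) -> tuple[str, ...]:
        return tuple(
            f"L_{s}_{t}_r{int(r)}"
            for s, t in SPATIAL_PAIRS
            for r in self.radii
        )

    @property
    def clinical_names(self) -> tuple[str, ...]:
        return CLINICAL_NAMES

    @property
    def all_names(self) -> tuple[str, ...]:
        return self.image_names + self.spatial_names + self.clinical_names

    def set_names(self, set_name: str) -> tuple[str, ...]:
        """Column names of one of the seven feature sets."""
        if set_name not in FEATURE_SETS:
            raise KeyError(f"unknown feature set {set_name!r}; one of {FEATURE_SETS}")
        blocks = {
            "image": self.image_names,
            "spatial": self.spatial_names,
            "clinical": self.clinical_names,
        }
        out: tuple[str, ...] = ()
        for part in set_name.split("_"):
            out += blocks[part]
        return out


DEFAULT_SCHEMA = FeatureSchema()


def _image_populations(cells: pd.DataFrame) -> dict[str, np.ndarray]:
    masks = population_masks(cells)
    pdl1 = cells["pdl1"].to_numpy(dtype=bool)
    panck = cells["panck"].to_numpy(dtype=bool)
    pops: dict[str, np.ndarray] = {}
    for cls in IMAGE_CLASSES:
        m = masks[cls]
        pops[f"{cls}_pdl1pos"] = m & pdl1
        pops[f"{cls}_pdl1neg"] = m & ~pdl1
        pops[f"{cls}_any"] = m
    pops["PDL1_any"] = pdl1
    pops["PDL1_epithelial"] = pdl1 & panck
    pops["PDL1_nonepithelial"] = pdl1 & ~panck
    return pops


def _spatial_populations(cells: pd.DataFrame) -> dict[str, np.ndarray]:
    masks = population_masks(cells)
    pdl1 = cells["pdl1"].to_numpy(dtype=bool)
    panck = cells["panck"].to_numpy(dtype=bool)
    return {
        "TB": masks["TB"],
        "CD3": cells["cd3"].to_numpy(dtype=bool) & ~panck,
        "CD8": cells["cd8"].to_numpy(dtype=bool) & ~panck,
        "CD68": cells["cd68"].to_numpy(dtype=bool) & ~panck,
        "CD163": cells["cd163"].to_numpy(dtype=bool) & ~panck,
        "PDL1": pdl1,
        "PDL1_epithelial": pdl1 & panck,
        "PDL1_nonepithelial": pdl1 & ~panck,
    }


def image_features(
    cells: pd.DataFrame,
    partition: RegionPartition,
    schema: FeatureSchema = DEFAULT_SCHEMA,
) -> dict[str, float]:
    """Counts and densities (per mm²) of the 21 populations × 3 regions."""
    if "region" in cells.columns:
        region = cells["region"].to_numpy()
    else:
        region = assign_regions(cells["x_um"], cells["y_um"], partition)
    pops = _image_populations(cells)
    out: dict[str, float] = {}
    for pname, member in pops.items():
        for rg in REGION_LABELS:
            in_rg = member & (region == rg)
            count = int(in_rg.sum())
            area = partition.area_mm2(rg)
            out[f"{pname}_{rg}_count"] = float(count)
            out[f"{pname}_{rg}_density"] = count / area if area > 0 else 0.0
    return {name: out[name] for name in schema.image_names}


def spatial_features(
    cells: pd.DataFrame,
    partition: RegionPartition,
    schema: FeatureSchema = DEFAULT_SCHEMA,
) -> dict[str, float]:
    """Cross-type L values for the ten pairs at every radius.

    The observation window is the whole tumour plus the front-out band.
    Pairs with an empty source or target population are imputed to the
    CSR-neutral value L(r) = r, so missing spatial structure carries no
    prognostic signal.
    """
    if "region" in cells.columns:
        region = cells["region"].to_numpy()
    else:
        region = assign_regions(cells["x_um"], cells["y_um"], partition)
    in_window = region != "outside"
    window = cells.loc[in_window]
    pops = _spatial_populations(window)
    coords = window[["x_um", "y_um"]].to_numpy()
    area = partition.window_area_um2
    radii = np.asarray(schema.radii, dtype=float)

    out: dict[str, float] = {}
    for src, tgt in SPATIAL_PAIRS:
        xs = coords[pops[src]]
        ys = coords[pops[tgt]]
        if len(xs) == 0 or len(ys) == 0 or area <= 0:
            lvals = radii
        else:
            k = np.atleast_1d(cross_k(xs, ys, area, radii))
            lvals = np.sqrt(k / np.pi)
        for r, lv in zip(schema.radii, lvals):
            out[f"L_{src}_{tgt}_r{int(r)}"] = float(lv)
    return out


_STAGES = ("II", "IIIA", "IIIB", "IV")
_REQUIRED_CLINICAL = ("age", "sex", "T", "N", "M", "stage")


def clinical_features(record: Mapping) -> dict[str, float]:
    """One-hot clinical encoding; incomplete or unknown records error."""
    missing = [k for k in _REQUIRED_CLINICAL if k not in record or pd.isna(record[k])]
    if missing:
        raise ValueError(f"incomplete clinical record: missing {missing}")
    sex, stage = record["sex"], record["stage"]
    if sex not in ("male", "female"):
        raise ValueError(f"unknown sex token {sex!r}")
    if stage not in _STAGES:
        raise ValueError(f"unknown stage token {stage!r}")
    for axis, cats in (("T", ("T2", "T3", "T4")), ("N", ("N0", "N1", "N2")), ("M", ("M0", "M1"))):
        if record[axis] not in cats:
            raise ValueError(f"unknown {axis} token {record[axis]!r}")
    out = {name: 0.0 for name in CLINICAL_NAMES}
    out["age"] = float(record["age"])
    out[f"sex_{sex}"] = 1.0
    out[f"stage_{stage}"] = 1.0
    out[record["T"]] = 1.0
    out[record["N"]] = 1.0
    out[record["M"]] = 1.0
    return out


def patient_features(
    cells: pd.DataFrame,
    partition: RegionPartition,
    clinical: Mapping,
    schema: FeatureSchema = DEFAULT_SCHEMA,
) -> dict[str, float]:
    """All 201 named features for one patient."""
    vec = image_features(cells, partition, schema)
    vec.update(spatial_features(cells, partition, schema))
    vec.update(clinical_features(clinical))
    return vec


def assemble_features(cohort: Sequence, schema: FeatureSchema = DEFAULT_SCHEMA) -> pd.DataFrame:
    """Feature matrix (patients × 201) for a synthetic cohort.

    Each patient's region partition is derived from their tumour mask;
    cells are region-labelled by centre membership.
    """
    rows = {}
    for p in cohort:
        part = p.partition
        cells = p.cells.copy()
        cells["region"] = assign_regions(cells["x_um"], cells["y_um"], part)
        rows[p.patient_id] = patient_features(cells, part, p.clinical, schema)
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=list(schema.all_names))
    matrix.index.name = "patient_id"
    return matrix


def feature_subset(
    matrix: pd.DataFrame, set_name: str, schema: FeatureSchema = DEFAULT_SCHEMA
) -> pd.DataFrame:
    """Restrict a feature matrix to one of the seven feature sets."""
    return matrix.loc[:, list(schema.set_names(set_name))]
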