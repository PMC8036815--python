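"""Synthetic MIBC cohort generator with known ground truth.

Real whole-slide cohorts of this kind are rarely deposited, so every
downstream stage of the pipeline — phenotyping, region partitioning,
spatial statistics, feature assembly, survival labelling, learning and
reporting — is exercised against cohorts drawn from a fully specified
generative model:

* **Slide geometry** — one disc-shaped tumour mass per patient (radius
  drawn per patient), rasterised as a binary mask; the invasive front is
  the ±band_width μm band around its border.
* **Cell point patterns** — for each of six generative phenotype classes
  (TB, general_T, cytotoxic_T, M1, M2, PDL1_cell) and each region
  (core / frontin / frontout), a per-patient intensity (points per mm²)
  is drawn from a configured range and a point pattern is realised as
  either a homogeneous Poisson process or a Thomas cluster process.
  Tumour buds are placed as small objects of 1–4 nuclei.  Each cell
  carries ground-truth marker flags consistent with its class.
* **IF patches** — optional multi-channel rasters rendering each nucleus
  as a Gaussian blob per channel, for round-trip testing of the
  intensity-threshold classifier.
* **Clinical covariates** — age, sex and TNM categories drawn with
  frequencies matching a typical radical-cystectomy cohort; stage follows
  a deterministic TNM→stage mapping.
* **Survival** — disease-specific death time T_mibc ~ Exponential with a
  log-linear hazard h₀·exp(Σ β_k z_k) over z-scored ground-truth features,
  an independent other-cause death time T_otd ~ Exponential(otd_rate),
  and administrative censoring at ``admin_censor`` months.  The recorded
  time is the minimum of the three and ``event_cause`` records which.

Identical configuration + seed reproduces the cohort exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .regions import RegionPartition, partition_regions

GENERATIVE_CLASSES = ("TB", "general_T", "cytotoxic_T", "M1", "M2", "PDL1_cell")
REGIONS = ("core", "frontin", "frontout")
EVENT_CAUSES = ("mibc_death", "other_death", "alive_censored")

#: Ground-truth marker flags by generative class (cd3, cd8, cd68, cd163,
#: panck); PD-L1 is drawn per cell.  Cytotoxic T-cells are CD3⁺CD8⁺; M2
#: macrophages CD68⁺CD163⁺ so that M1 ∪ M2 spans total macrophages.
_CLASS_FLAGS: dict[str, dict[str, bool]] = {
    "TB": dict(cd3=False, cd8=False, cd68=False, cd163=False, panck=True),
    "general_T": dict(cd3=True, cd8=False, cd68=False, cd163=False, panck=False),
    "cytotoxic_T": dict(cd3=True, cd8=True, cd68=False, cd163=False, panck=False),
    "M1": dict(cd3=False, cd8=False, cd68=True, cd163=False, panck=False),
    "M2": dict(cd3=False, cd8=False, cd68=True, cd163=True, panck=False),
    "PDL1_cell": dict(cd3=False, cd8=False, cd68=False, cd163=False, panck=False),
    "tumour": dict(cd3=False, cd8=False, cd68=False, cd163=False, panck=True),
}

_DEFAULT_INTENSITY_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    # points (for TB: bud objects) per mm², drawn uniformly per patient
    # and region; TB enriched at the invasive front, where budding occurs.
    "TB": {"core": (1.0, 10.0), "frontin": (2.0, 25.0), "frontout": (1.0, 12.0)},
    "general_T": {r: (40.0, 350.0) for r in REGIONS},
    "cytotoxic_T": {r: (25.0, 250.0) for r in REGIONS},
    "M1": {r: (15.0, 150.0) for r in REGIONS},
    "M2": {r: (15.0, 180.0) for r in REGIONS},
    "PDL1_cell": {r: (10.0, 120.0) for r in REGIONS},
}

_DEFAULT_PDL1_FRACTION: dict[str, float] = {
    "TB": 0.15, "general_T": 0.10, "cytotoxic_T": 0.10,
    "M1": 0.20, "M2": 0.25, "tumour": 0.10, "PDL1_cell": 1.0,
}


@dataclass(frozen=True)
class ClusterSpec:
    """Point-process choice for one class: CSR or Thomas clustering."""

    process: str = "poisson"          # "poisson" | "thomas"
    offspring_mean: float = 8.0       # mean points per Thomas parent
    sigma_um: float = 15.0            # Gaussian offspring spread


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_patients: int = 78
    seed: int = 0
    pixel_size: float = 0.5           # μm/px for rendered IF patches (20× scan)
    mask_pixel_size: float = 8.0      # μm/px for whole-slide tumour masks
    slide_extent: tuple[float, float] = (5000.0, 5000.0)   # μm
    tumour_radius_range: tuple[float, float] = (1200.0, 1800.0)  # μm
    region_band: float = 500.0        # μm inside and outside the border
    class_intensity_ranges: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: _DEFAULT_INTENSITY_RANGES
    )
    clustering: Mapping[str, ClusterSpec] = field(
        default_factory=lambda: {
            "TB": ClusterSpec("poisson"),
            "general_T": ClusterSpec("thomas", offspring_mean=6.0, sigma_um=25.0),
            "cytotoxic_T": ClusterSpec("thomas", offspring_mean=6.0, sigma_um=25.0),
            "M1": ClusterSpec("poisson"),
            "M2": ClusterSpec("thomas", offspring_mean=5.0, sigma_um=30.0),
            "PDL1_cell": ClusterSpec("poisson"),
        }
    )
    pdl1_fraction: Mapping[str, float] = field(
        default_factory=lambda: _DEFAULT_PDL1_FRACTION
    )
    tumour_cell_intensity: float = 200.0   # PanCK⁺ non-bud cells per mm² of tumour
    bud_nuclei_jitter_um: float = 8.0      # nucleus scatter within one bud
    effect_sizes: Mapping[str, float] = field(default_factory=dict)
    baseline_hazard: float = 0.030         # MIBC-death events/month at z = 0
    otd_rate: float = 0.007                # other-cause death events/month
    admin_censor: float = 113.0            # follow-up horizon, months

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be ≥ 2")
        if self.pixel_size <= 0 or self.mask_pixel_size <= 0:
            raise ValueError("pixel sizes must be positive")
        if min(self.slide_extent) <= 0:
            raise ValueError("slide extent must be positive in both dimensions")
        if self.admin_censor <= 0:
            raise ValueError("admin_censor must be positive")
        if self.baseline_hazard < 0 or self.otd_rate < 0:
            raise ValueError("hazard rates must be ≥ 0")
        for name, beta in self.effect_sizes.items():
            if not np.isfinite(beta):
                raise ValueError(f"effect size for {name!r} is not finite")
        for cls, per_region in self.class_intensity_ranges.items():
            for rg, (lo, hi) in per_region.items():
                if lo < 0 or hi < lo:
                    raise ValueError(f"bad intensity range for {cls}/{rg}")


@dataclass
class SyntheticPatient:
    """One generated patient: slide, clinical record, outcome, truth."""

    patient_id: str
    cells: pd.DataFrame
    tumour_mask: np.ndarray
    mask_pixel_size: float
    tumour_radius_um: float
    clinical: dict
    survival_months: float
    event_cause: str
    ground_truth: dict

    @property
    def partition(self) -> RegionPartition:
        return partition_regions(self.tumour_mask, self.mask_pixel_size)


# ---------------------------------------------------------------------------
# Region geometries for point sampling


@dataclass(frozen=True)
class AnnulusRegion:
    """Annulus r_inner ≤ ρ ≤ r_outer around a centre (μm); r_inner may be 0."""

    centre: tuple[float, float]
    r_inner: float
    r_outer: float

    @property
    def area_um2(self) -> float:
        return np.pi * (self.r_outer**2 - self.r_inner**2)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        u = rng.uniform(self.r_inner**2, self.r_outer**2, size=n)
        rho = np.sqrt(u)
        theta = rng.uniform(0, 2 * np.pi, size=n)
        cx, cy = self.centre
        return np.column_stack([cx + rho * np.cos(theta), cy + rho * np.sin(theta)])

    def contains(self, pts: np.ndarray) -> np.ndarray:
        d = np.hypot(pts[:, 0] - self.centre[0], pts[:, 1] - self.centre[1])
        return (d >= self.r_inner) & (d <= self.r_outer)


def generate_point_pattern(
    intensity_per_mm2: float,
    region: AnnulusRegion,
    rng: np.random.Generator,
    cluster: ClusterSpec = ClusterSpec(),
) -> np.ndarray:
    """Realise one class's point pattern in one region.

    ``poisson`` draws a homogeneous Poisson process at the stated
    intensity; ``thomas`` draws Poisson parents at rate
    intensity / offspring_mean (over the region dilated by 3σ, so cluster
    mass is not lost at region edges), Gaussian offspring around each
    parent, and keeps offspring falling inside the region — the realised
    mean intensity matches the Poisson case.
    """
    if intensity_per_mm2 < 0:
        raise ValueError("intensity must be ≥ 0")
    if region.area_um2 <= 0:
        raise ValueError("region geometry is empty")
    lam_um2 = intensity_per_mm2 / 1e6  # points per μm²
    if intensity_per_mm2 == 0:
        return np.empty((0, 2))
    if cluster.process == "poisson":
        n = rng.poisson(lam_um2 * region.area_um2)
        return region.sample(n, rng)
    if cluster.process == "thomas":
        pad = 3.0 * cluster.sigma_um
        parent_region = AnnulusRegion(
            region.centre, max(0.0, region.r_inner - pad), region.r_outer + pad
        )
        parent_rate = lam_um2 / cluster.offspring_mean
        n_parents = rng.poisson(parent_rate * parent_region.area_um2)
        parents = parent_region.sample(n_parents, rng)
        counts = rng.poisson(cluster.offspring_mean, size=n_parents)
        pts = np.repeat(parents, counts, axis=0) + rng.normal(
            scale=cluster.sigma_um, size=(int(counts.sum()), 2)
        )
        return pts[region.contains(pts)] if len(pts) else pts.reshape(0, 2)
    raise ValueError(f"unknown process {cluster.process!r}")


# ---------------------------------------------------------------------------
# IF patch rendering

#: Gaussian blob spread of one nucleus, in pixels (≈2.5 μm at 0.5 μm/px).
BLOB_SIGMA_PX = 5.0
#: In-channel amplitude for marker-positive vs -negative cells.  The mean
#: of a positive blob over the 11 px calling disc is ≈ 0.38 of peak, well
#: above the 0.125 threshold; a negative cell's residual is ≈ 0.02.
POSITIVE_AMPLITUDE = 1.0
NEGATIVE_AMPLITUDE = 0.05


def render_if_patch(
    cells: pd.DataFrame,
    channels: Sequence[str],
    patch_extent_um: tuple[float, float],
    pixel_size: float = 0.5,
    noise_sd: float = 0.02,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Render cells as Gaussian blobs into one raster per channel.

    ``cells`` must carry ``x_um``, ``y_um`` and one lower-case boolean
    flag column per requested channel (e.g. ``cd8`` for channel "CD8").
    Returns un-normalised rasters; additive Gaussian noise (clipped at 0)
    with the stated SD is applied when ``noise_sd > 0``.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    w_px = int(round(patch_extent_um[0] / pixel_size))
    h_px = int(round(patch_extent_um[1] / pixel_size))
    min_side = int(np.ceil(6 * BLOB_SIGMA_PX)) + 1
    if min(w_px, h_px) < min_side:
        raise ValueError("patch smaller than one nucleus blob")

    yy, xx = np.mgrid[0:h_px, 0:w_px]
    out: dict[str, np.ndarray] = {}
    for ch in channels:
        flag_col = ch.lower()
        raster = np.zeros((h_px, w_px))
        for _, cell in cells.iterrows():
            cx = cell["x_um"] / pixel_size
            cy = cell["y_um"] / pixel_size
            amp = POSITIVE_AMPLITUDE if bool(cell[flag_col]) else NEGATIVE_AMPLITUDE
            d2 = (xx - cx) ** 2 + (yy - cy) ** 2
            raster += amp * np.exp(-d2 / (2 * BLOB_SIGMA_PX**2))
        if noise_sd > 0:
            raster = np.clip(raster + rng.normal(scale=noise_sd, size=raster.shape), 0, None)
        out[ch] = raster
    return out


# ---------------------------------------------------------------------------
# Clinical covariates and TNM→stage mapping

_T_CATS, _T_PROBS = ("T2", "T3", "T4"), (0.23, 0.50, 0.27)
_N_CATS, _N_PROBS = ("N0", "N1", "N2"), (0.73, 0.17, 0.10)
_M1_PROB = 0.35
_MALE_PROB = 0.55
_AGE_MEAN, _AGE_SD, _AGE_RANGE = 66.0, 11.0, (29.0, 87.0)


def stage_from_tnm(t: str, n: str, m: str) -> str:
    """Deterministic TNM→stage mapping for MIBC (T2–T4).

    M1 ⇒ IV; node-positive ⇒ IIIB if T4 else IIIA; node-negative T3/T4 ⇒
    IIIA; T2N0M0 ⇒ II.
    """
    if m == "M1":
        return "IV"
    if n in ("N1", "N2"):
        return "IIIB" if t == "T4" else "IIIA"
    if t in ("T3", "T4"):
        return "IIIA"
    return "II"


def _draw_clinical(rng: np.random.Generator) -> dict:
    t = str(rng.choice(_T_CATS, p=_T_PROBS))
    n = str(rng.choice(_N_CATS, p=_N_PROBS))
    m = "M1" if rng.random() < _M1_PROB else "M0"
    age = float(np.clip(rng.normal(_AGE_MEAN, _AGE_SD), *_AGE_RANGE))
    return {
        "age": round(age, 1),
        "sex": "male" if rng.random() < _MALE_PROB else "female",
        "T": t, "N": n, "M": m,
        "stage": stage_from_tnm(t, n, m),
    }


# ---------------------------------------------------------------------------
# Cohort generation


def _patient_cells(
    config: CohortConfig,
    radius_um: float,
    centre: tuple[float, float],
    intensities: dict[str, dict[str, float]],
    rng: np.random.Generator,
) -> pd.DataFrame:
    band = config.region_band
    geoms = {
        "core": AnnulusRegion(centre, 0.0, max(radius_um - band, 0.0)),
        "frontin": AnnulusRegion(centre, max(radius_um - band, 0.0), radius_um),
        "frontout": AnnulusRegion(centre, radius_um, radius_um + band),
    }
    rows: list[pd.DataFrame] = []
    bud_counter = 0

    def emit(points: np.ndarray, cls: str, bud_ids: np.ndarray | None = None) -> None:
        if len(points) == 0:
            return
        flags = _CLASS_FLAGS[cls]
        frame = pd.DataFrame({"x_um": points[:, 0], "y_um": points[:, 1]})
        frame["class"] = cls
        for k, v in flags.items():
            frame[k] = v
        frame["pdl1"] = rng.random(len(points)) < config.pdl1_fraction.get(cls, 0.0)
        frame["bud_id"] = bud_ids if bud_ids is not None else -1
        rows.append(frame)

    for cls in GENERATIVE_CLASSES:
        spec = config.clustering.get(cls, ClusterSpec())
        for rg, geom in geoms.items():
            if geom.area_um2 <= 0:
                continue
            lam = intensities[cls][rg]
            if cls == "TB":
                # one pattern point per bud object; 1–4 nuclei jittered
                # around it (each nucleus becomes one TB cell row)
                bud_centres = generate_point_pattern(lam, geom, rng, ClusterSpec("poisson"))
                if len(bud_centres):
                    ks = rng.integers(1, 5, size=len(bud_centres))
                    nuclei = np.repeat(bud_centres, ks, axis=0) + rng.normal(
                        scale=config.bud_nuclei_jitter_um, size=(int(ks.sum()), 2)
                    )
                    ids = np.repeat(np.arange(len(ks)) + bud_counter, ks)
                    emit(nuclei, "TB", ids)
                    bud_counter += len(ks)
            else:
                emit(generate_point_pattern(lam, geom, rng, spec), cls)

    # PanCK⁺ non-bud tumour cells (region geometry + PD-L1 epithelial signal)
    for rg in ("core", "frontin"):
        geom = geoms[rg]
        if geom.area_um2 > 0:
            emit(generate_point_pattern(config.tumour_cell_intensity, geom, rng), "tumour")

    if not rows:
        return pd.DataFrame(
            columns=["x_um", "y_um", "class", "cd3", "cd8", "cd68", "cd163",
                     "panck", "pdl1", "bud_id"]
        )
    cells = pd.concat(rows, ignore_index=True)
    cells["is_bud"] = cells["bud_id"] >= 0
    return cells


def generate_cohort(config: CohortConfig) -> list[SyntheticPatient]:
    """Draw a full synthetic cohort; deterministic in config.seed."""
    master = np.random.SeedSequence(config.seed)
    patient_seeds = master.spawn(config.n_patients)
    survival_seed = master.spawn(1)[0]

    w_um, h_um = config.slide_extent
    centre = (w_um / 2.0, h_um / 2.0)
    max_radius = min(centre) - config.region_band - 4 * config.mask_pixel_size
    if max_radius <= 0:
        raise ValueError("slide extent too small for the region band")

    drafts = []
    for i, seq in enumerate(patient_seeds):
        rng = np.random.default_rng(seq)
        lo, hi = config.tumour_radius_range
        radius = float(rng.uniform(min(lo, max_radius), min(hi, max_radius)))
        intensities = {
            cls: {
                rg: float(rng.uniform(*config.class_intensity_ranges[cls][rg]))
                for rg in REGIONS
            }
            for cls in GENERATIVE_CLASSES
        }
        cells = _patient_cells(config, radius, centre, intensities, rng)
        clinical = _draw_clinical(rng)

        shape = (
            int(round(h_um / config.mask_pixel_size)),
            int(round(w_um / config.mask_pixel_size)),
        )
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        px = config.mask_pixel_size
        mask = ((xx + 0.5) * px - centre[0]) ** 2 + ((yy + 0.5) * px - centre[1]) ** 2 <= radius**2

        truth = {
            f"{cls}_density_{rg}": intensities[cls][rg]
            for cls in GENERATIVE_CLASSES
            for rg in REGIONS
        }
        truth["age"] = clinical["age"]
        truth["stage_ordinal"] = float(["II", "IIIA", "IIIB", "IV"].index(clinical["stage"]))
        drafts.append((f"P{i:04d}", cells, mask, radius, clinical, truth))

    # Standardise ground-truth features across the cohort, then sample
    # survival from the log-linear exponential hazard.
    eff_names = list(config.effect_sizes)
    for name in eff_names:
        if name not in drafts[0][5]:
            raise ValueError(f"effect size refers to unknown feature {name!r}")
    z = np.zeros((config.n_patients, len(eff_names)))
    for j, name in enumerate(eff_names):
        vals = np.array([d[5][name] for d in drafts], dtype=float)
        sd = vals.std()
        z[:, j] = (vals - vals.mean()) / sd if sd > 0 else 0.0
    betas = np.array([config.effect_sizes[n] for n in eff_names], dtype=float)
    eta = z @ betas if eff_names else np.zeros(config.n_patients)

    srng = np.random.default_rng(survival_seed)
    patients = []
    for (pid, cells, mask, radius, clinical, truth), lp in zip(drafts, eta):
        hazard = config.baseline_hazard * np.exp(lp)
        t_mibc = srng.exponential(1.0 / hazard) if hazard > 0 else np.inf
        t_otd = srng.exponential(1.0 / config.otd_rate) if config.otd_rate > 0 else np.inf
        t = min(t_mibc, t_otd, config.admin_censor)
        if t_mibc <= t_otd and t_mibc <= config.admin_censor:
            cause = "mibc_death"
        elif t_otd <= config.admin_censor:
            cause = "other_death"
        else:
            cause = "alive_censored"
        truth = dict(truth, linear_predictor=float(lp))
        cells = cells.copy()
        cells.insert(0, "patient_id", pid)
        patients.append(
            SyntheticPatient(
                patient_id=pid,
                cells=cells,
                tumour_mask=mask,
                mask_pixel_size=config.mask_pixel_size,
                tumour_radius_um=radius,
                clinical=dict(clinical, patient_id=pid),
                survival_months=float(max(t, 1e-3)),
                event_cause=cause,
                ground_truth=truth,
            )
        )
    return patients


def clinical_table(cohort: Sequence[SyntheticPatient]) -> pd.DataFrame:
    """One clinical row per patient, including outcome columns."""
    rows = []
    for p in cohort:
        rows.append(
            dict(
                p.clinical,
                survival_months=p.survival_months,
                event_cause=p.event_cause,
            )
        )
    return pd.DataFrame(rows)


def write_cohort(cohort: Sequence[SyntheticPatient], config: CohortConfig, path) -> None:
    """Persist a cohort: per-patient cells.csv + mask.tiff, cohort-level
    clinical.csv and config.yaml."""
    import tifffile
    import yaml

    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    for p in cohort:
        pdir = root / p.patient_id
        pdir.mkdir(exist_ok=True)
        p.cells.to_csv(pdir / "cells.csv", index=False)
        tifffile.imwrite(pdir / "mask.tiff", p.tumour_mask.astype(np.uint8))
    clinical_table(cohort).to_csv(root / "clinical.csv", index=False)
    cfg = dataclasses.asdict(config)
    cfg["clustering"] = {k: dataclasses.asdict(v) for k, v in config.clustering.items()}
    with open(root / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, default_flow_style=None)
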