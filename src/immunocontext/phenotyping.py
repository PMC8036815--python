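"""Cell phenotyping from multiplex immunofluorescence intensities.

Six markers are measured per cell: PanCK (urothelial/epithelial cells),
CD3 (general T-cells), CD8 (cytotoxic T-cells), CD68 (total macrophages),
CD163 (M2 macrophages) and the immune-checkpoint ligand PD-L1.  A cell is
positive for a marker when the mean normalised channel intensity over a
circular neighbourhood of its nucleus (radius 11 px) reaches the threshold
32/256 = 0.125; ties count as positive.

Phenotype populations are boolean predicates over the flags (populations
overlap — e.g. every M2 macrophage is also a total macrophage); a separate
primary-class assignment gives each cell exactly one label for display and
for the synthetic generator's bookkeeping.

Tumour buds (TBs) are isolated epithelium objects containing one to four
nuclei — the histological correlate of early metastatic dissociation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

MARKERS = ("CD3", "CD8", "CD68", "CD163", "PDL1", "PanCK")

#: Circular-neighbourhood radius (pixels) for mean-intensity marker calls.
NEIGHBOURHOOD_RADIUS_PX = 11
#: Positivity threshold on mean normalised intensity (= 32/256).
INTENSITY_THRESHOLD = 0.125

#: Bounds on nuclei per epithelium object for it to count as a tumour bud.
BUD_MIN_NUCLEI = 1
BUD_MAX_NUCLEI = 4

PHENOTYPE_CLASSES = (
    "TB", "M1", "M2", "total_macrophage", "general_T", "cytotoxic_T", "PDL1_cell",
)


def normalize_channel(raster: np.ndarray) -> np.ndarray:
    """Min–max rescale a channel to [0, 1]; a constant raster maps to zeros."""
    arr = np.asarray(raster, dtype=float)
    if arr.size == 0:
        raise ValueError("empty raster")
    if not np.all(np.isfinite(arr)):
        raise ValueError("raster contains non-finite pixels")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def _disc_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    dy, dx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    keep = dy**2 + dx**2 <= radius**2
    return dy[keep], dx[keep]


def classify_markers(
    cell_centres: np.ndarray,
    channels: dict[str, np.ndarray],
    radius_px: int = NEIGHBOURHOOD_RADIUS_PX,
    threshold: float = INTENSITY_THRESHOLD,
) -> pd.DataFrame:
    """Call each marker positive/negative per cell.

    Parameters
    ----------
    cell_centres
        (n, 2) array of (col, row) pixel coordinates of nucleus centres.
    channels
        Mapping marker name → normalised 2-D intensity raster (shared shape).

    Returns
    -------
    DataFrame with one boolean column per channel plus an ``error`` column;
    cells whose centre falls outside the raster get ``error=True`` and
    all-False flags (skipped, not fatal).

    Notes
    -----
    The neighbourhood is a pixel disc of the given radius, clipped at
    raster edges.  The call is monotone in intensity: raising any pixel
    can only turn flags positive.
    """
    centres = np.asarray(cell_centres, dtype=float).reshape(-1, 2)
    shapes = {ch.shape for ch in channels.values()}
    if len(shapes) > 1:
        raise ValueError("channels must share one shape")
    h, w = shapes.pop()
    dy, dx = _disc_offsets(radius_px)

    out = {name: np.zeros(len(centres), dtype=bool) for name in channels}
    errors = np.zeros(len(centres), dtype=bool)
    for i, (cx, cy) in enumerate(centres):
        col, row = int(round(cx)), int(round(cy))
        if not (0 <= row < h and 0 <= col < w):
            errors[i] = True
            continue
        rr = row + dy
        cc = col + dx
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        rr, cc = rr[keep], cc[keep]
        for name, raster in channels.items():
            out[name][i] = raster[rr, cc].mean() >= threshold
    frame = pd.DataFrame(out)
    frame["error"] = errors
    return frame


def population_masks(cells: pd.DataFrame) -> dict[str, np.ndarray]:
    """Boolean membership per phenotype population from marker flags.

    ``cells`` carries lower-case flag columns (cd3, cd8, cd68, cd163,
    pdl1, panck) and ``is_bud``.  Immune populations require PanCK⁻ so
    that epithelial bleed-through never counts as immune; macrophage logic
    keeps M1 ∪ M2 ⊆ total_macrophage.
    """
    panck_neg = ~cells["panck"].to_numpy(dtype=bool)
    cd68 = cells["cd68"].to_numpy(dtype=bool)
    cd163 = cells["cd163"].to_numpy(dtype=bool)
    return {
        "TB": cells["is_bud"].to_numpy(dtype=bool),
        "M1": cd68 & ~cd163 & panck_neg,
        "M2": cd163 & panck_neg,
        "total_macrophage": (cd68 | cd163) & panck_neg,
        "general_T": cells["cd3"].to_numpy(dtype=bool) & panck_neg,
        "cytotoxic_T": cells["cd8"].to_numpy(dtype=bool) & panck_neg,
        "PDL1_cell": cells["pdl1"].to_numpy(dtype=bool),
    }


#: Primary-class priority: bud membership overrides everything (PanCK⁺
#: cells in buds are TBs); among immune classes the more specific wins.
_PRIMARY_ORDER = ("TB", "cytotoxic_T", "general_T", "M2", "M1", "PDL1_cell")


def assign_phenotypes(cells: pd.DataFrame) -> pd.DataFrame:
    """Attach a primary phenotype class and PD-L1 state to each cell.

    Every flag combination maps to exactly one primary class; PanCK⁺
    non-bud cells are ``tumour`` (region geometry only), and cells negative
    for everything are ``other`` (excluded from features).
    """
    masks = population_masks(cells)
    n = len(cells)
    primary = np.full(n, "other", dtype=object)
    panck = cells["panck"].to_numpy(dtype=bool)
    unset = np.ones(n, dtype=bool)
    for name in _PRIMARY_ORDER:
        m = masks[name] & unset
        primary[m] = name
        unset &= ~m
    primary[unset & panck] = "tumour"
    out = cells.copy()
    out["phenotype"] = primary.astype(str)
    out["pdl1_state"] = np.where(cells["pdl1"].to_numpy(dtype=bool), "pos", "neg")
    return out


@dataclass
class EpitheliumObject:
    """One 8-connected component of the epithelium mask."""

    label: int
    nuclei_count: int
    is_bud: bool
    centroid_um: tuple[float, float]
    area_px: int


def identify_tumour_buds(
    epithelium_mask: np.ndarray,
    cell_centres_um: np.ndarray,
    pixel_size: float = 1.0,
) -> list[EpitheliumObject]:
    """Find epithelium objects and flag tumour buds (1–4 enclosed nuclei).

    Components use 8-connectivity; a nucleus belongs to the component its
    centre pixel lies in.  Centroids are returned in μm (x, y) for spatial
    analysis.
    """
    mask = np.asarray(epithelium_mask).astype(bool)
    if not mask.any():
        return []
    labels, n_obj = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    centres = np.asarray(cell_centres_um, dtype=float).reshape(-1, 2)
    h, w = mask.shape
    counts = np.zeros(n_obj + 1, dtype=int)
    if len(centres):
        cols = np.floor(centres[:, 0] / pixel_size).astype(int)
        rows = np.floor(centres[:, 1] / pixel_size).astype(int)
        ok = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
        np.add.at(counts, labels[rows[ok], cols[ok]], 1)
    objects = []
    centroids = ndimage.center_of_mass(mask, labels, range(1, n_obj + 1))
    areas = ndimage.sum_labels(mask, labels, range(1, n_obj + 1))
    for lab in range(1, n_obj + 1):
        cy, cx = centroids[lab - 1]
        objects.append(
            EpitheliumObject(
                label=lab,
                nuclei_count=int(counts[lab]),
                is_bud=BUD_MIN_NUCLEI <= counts[lab] <= BUD_MAX_NUCLEI,
                centroid_um=((cx + 0.5) * pixel_size, (cy + 0.5) * pixel_size),
                area_px=int(areas[lab - 1]),
            )
        )
    return objects
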