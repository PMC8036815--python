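"""Marker calling, phenotype logic, tumour-bud identification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from immunocontext.phenotyping import (
    MARKERS,
    assign_phenotypes,
    classify_markers,
    identify_tumour_buds,
    normalize_channel,
    population_masks,
)
from immunocontext.synthetic import render_if_patch


def test_normalize_channel_basics():
    raster = np.array([[10.0, 210.0], [110.0, 10.0]])
    out = normalize_channel(raster)
    assert out.min() == 0.0 and out.max() == 1.0
    assert out[1, 0] == pytest.approx(0.5)  # midpoint maps to 0.5
    # constant raster → all zeros (degenerate rule)
    np.testing.assert_array_equal(normalize_channel(np.full((3, 3), 7.0)), 0.0)
    # idempotence
    np.testing.assert_allclose(normalize_channel(out), out)
    with pytest.raises(ValueError):
        normalize_channel(np.array([[np.nan, 1.0]]))


def _uniform_patch(value, shape=(40, 40)):
    return np.full(shape, float(value))


def test_classify_markers_threshold_rule():
    centres = np.array([[20.0, 20.0]])
    flags = classify_markers(centres, {"CD3": _uniform_patch(0.20)})
    assert flags["CD3"].iloc[0]            # mean 0.20 → positive
    flags = classify_markers(centres, {"CD3": _uniform_patch(0.0)})
    assert not flags["CD3"].iloc[0]        # mean 0 → negative
    flags = classify_markers(centres, {"CD3": _uniform_patch(0.125)})
    assert flags["CD3"].iloc[0]            # tie at threshold counts positive


def test_classify_markers_out_of_bounds_cell_skipped():
    centres = np.array([[20.0, 20.0], [500.0, 500.0]])
    flags = classify_markers(centres, {"CD8": _uniform_patch(0.5)})
    assert flags["CD8"].tolist() == [True, False]
    assert flags["error"].tolist() == [False, True]


def test_classifier_monotone_in_intensity():
    rng = np.random.default_rng(0)
    base = rng.uniform(0, 0.3, size=(40, 40))
    centres = np.array([[20.0, 20.0]])
    f0 = classify_markers(centres, {"m": base})["m"].iloc[0]
    f1 = classify_markers(centres, {"m": base + 0.2})["m"].iloc[0]
    assert f1 >= f0  # raising intensity never flips positive → negative


def _flag_frame(**kw):
    row = dict(cd3=False, cd8=False, cd68=False, cd163=False, pdl1=False,
               panck=False, is_bud=False)
    row.update(kw)
    return pd.DataFrame([row])


@pytest.mark.parametrize(
    "flags,expected",
    [
        (dict(cd68=True), "M1"),                        # CD68⁺CD163⁻PanCK⁻
        (dict(cd163=True, pdl1=True), "M2"),            # CD163⁺PD-L1⁺PanCK⁻
        (dict(cd68=True, cd163=True), "M2"),
        (dict(cd3=True), "general_T"),
        (dict(cd3=True, cd8=True), "cytotoxic_T"),
        (dict(pdl1=True), "PDL1_cell"),
        (dict(panck=True), "tumour"),
        (dict(panck=True, is_bud=True), "TB"),
        (dict(), "other"),                              # all-negative
    ],
)
def test_primary_phenotype_assignment(flags, expected):
    out = assign_phenotypes(_flag_frame(**flags))
    assert out["phenotype"].iloc[0] == expected
    assert out["pdl1_state"].iloc[0] == ("pos" if flags.get("pdl1") else "neg")


@given(
    cd3=st.booleans(), cd8=st.booleans(), cd68=st.booleans(),
    cd163=st.booleans(), pdl1=st.booleans(), panck=st.booleans(),
    is_bud=st.booleans(),
)
@settings(max_examples=128, deadline=None, derandomize=True)
def test_phenotype_logic_total_and_consistent(cd3, cd8, cd68, cd163, pdl1, panck, is_bud):
    """Every flag combination maps to exactly one class; macrophage
    subsets stay inside total_macrophage."""
    cells = _flag_frame(cd3=cd3, cd8=cd8, cd68=cd68, cd163=cd163,
                        pdl1=pdl1, panck=panck, is_bud=is_bud)
    out = assign_phenotypes(cells)
    assert out["phenotype"].iloc[0] in {
        "TB", "M1", "M2", "general_T", "cytotoxic_T", "PDL1_cell", "tumour", "other"
    }
    masks = population_masks(cells)
    assert not (masks["M1"][0] and masks["M2"][0])
    if masks["M1"][0] or masks["M2"][0]:
        assert masks["total_macrophage"][0]


def test_bud_rule_one_to_four_nuclei():
    mask = np.zeros((30, 60), dtype=bool)
    mask[5:10, 5:10] = True      # object A
    mask[20:26, 30:40] = True    # object B
    centres_a = [[7.0, 7.0], [8.0, 7.0], [6.0, 8.0]]          # 3 nuclei → bud
    centres_b = [[32.0, 22.0], [33.0, 22.0], [34.0, 23.0],
                 [35.0, 24.0], [36.0, 25.0]]                   # 5 nuclei → not bud
    objs = identify_tumour_buds(mask, np.array(centres_a + centres_b))
    by_count = {o.nuclei_count: o for o in objs}
    assert by_count[3].is_bud
    assert not by_count[5].is_bud


def test_bud_rule_zero_nuclei_and_empty_mask():
    mask = np.zeros((10, 10), dtype=bool)
    assert identify_tumour_buds(mask, np.empty((0, 2))) == []
    mask[2:5, 2:5] = True
    objs = identify_tumour_buds(mask, np.empty((0, 2)))
    assert len(objs) == 1 and objs[0].nuclei_count == 0 and not objs[0].is_bud


def test_bud_count_matches_bruteforce():
    rng = np.random.default_rng(1)
    mask = rng.random((40, 40)) < 0.2
    centres = rng.uniform(0, 40, size=(60, 2))
    objs = identify_tumour_buds(mask, centres)
    from scipy import ndimage
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), int))
    for o in objs:
        brute = 0
        for cx, cy in centres:
            r, c = int(np.floor(cy)), int(np.floor(cx))
            if 0 <= r < 40 and 0 <= c < 40 and labels[r, c] == o.label:
                brute += 1
        assert brute == o.nuclei_count


def _spaced_positions(rng, n, lo=15.0, hi=85.0, spacing=22.0):
    """Nucleus centres on a jittered grid: nuclei are solid bodies, so two
    centres never sit closer than a cell diameter (keeps one cell's blob
    out of a neighbour's calling disc)."""
    grid = np.arange(lo, hi, spacing)
    xs, ys = np.meshgrid(grid, grid)
    pts = np.column_stack([xs.ravel(), ys.ravel()])
    pts = pts[rng.permutation(len(pts))[:n]]
    return pts + rng.uniform(-3, 3, size=pts.shape)


def test_noiseless_roundtrip_recovers_all_flags():
    """Rendered noiseless patches → classifier recovers every flag."""
    rng = np.random.default_rng(5)
    n = 12
    pts = _spaced_positions(rng, n)
    cells = pd.DataFrame({"x_um": pts[:, 0], "y_um": pts[:, 1]})
    for m in ("cd3", "cd8", "pdl1"):
        cells[m] = rng.random(n) < 0.5
    channels = ["CD3", "CD8", "PDL1"]
    rasters = render_if_patch(cells, channels, (100.0, 100.0), noise_sd=0.0, rng=rng)
    norm = {ch: normalize_channel(rasters[ch]) for ch in channels}
    centres = np.column_stack([cells["x_um"] / 0.5, cells["y_um"] / 0.5])
    flags = classify_markers(centres, norm)
    for ch in channels:
        assert flags[ch].tolist() == cells[ch.lower()].tolist()


def test_noisy_roundtrip_recovery_rate():
    """With default rendering noise, ≥ 99% of flags recovered over 20 seeds."""
    total = correct = 0
    for seed in range(20):
        rng = np.random.default_rng(100 + seed)
        n = 10
        pts = _spaced_positions(rng, n)
        cells = pd.DataFrame({
            "x_um": pts[:, 0],
            "y_um": pts[:, 1],
            "cd8": rng.random(n) < 0.5,
        })
        rasters = render_if_patch(cells, ["CD8"], (100.0, 100.0), noise_sd=0.02, rng=rng)
        flags = classify_markers(
            np.column_stack([cells["x_um"] / 0.5, cells["y_um"] / 0.5]),
            {"CD8": normalize_channel(rasters["CD8"])},
        )
        total += n
        correct += int((flags["CD8"] == cells["cd8"]).sum())
    assert correct / total >= 0.99


def test_render_patch_validations():
    cells = pd.DataFrame({"x_um": [], "y_um": [], "cd3": []})
    rasters = render_if_patch(cells, ["CD3"], (60.0, 60.0), noise_sd=0.0)
    np.testing.assert_array_equal(rasters["CD3"], 0.0)  # zero cells → background
    with pytest.raises(ValueError, match="smaller than one nucleus"):
        render_if_patch(cells, ["CD3"], (5.0, 5.0))


def test_marker_panel_is_complete():
    assert set(MARKERS) == {"CD3", "CD8", "CD68", "CD163", "PDL1", "PanCK"}
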