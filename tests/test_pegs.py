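"""Peg component counting, depth transform, and area measurement."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from pericytometry import (
    ClassCode,
    PipelineConfig,
    SegmentedSection,
    closed_peg_mask,
    depth_map,
    peg_components,
    peg_max_depths,
)
from pericytometry.synthetic import SyntheticVesselSpec, generate_vessel

SMALL = dict(n_sections=1, grid_px=512, pixel_size_nm=40.0)


def _section(lab, px=20.0):
    return SegmentedSection(lab.astype(np.uint8), pixel_size_nm=px)


def brute_force_depth(mask: np.ndarray, pixel_size_nm: float) -> np.ndarray:
    """Independent oracle: min Euclidean distance to the nearest
    complement pixel, by KD-tree query over complement coordinates."""
    out = np.zeros(mask.shape)
    comp = np.argwhere(~mask)
    inside = np.argwhere(mask)
    if len(comp) == 0 or len(inside) == 0:
        return out
    d, _ = cKDTree(comp).query(inside)
    out[tuple(inside.T)] = d * pixel_size_nm
    return out


def test_component_count_and_min_size():
    lab = np.zeros((32, 32))
    lab[2:6, 2:6] = int(ClassCode.PEG)       # 16 px
    lab[10:12, 10:12] = int(ClassCode.PEG)   # 4 px (= min_component_px)
    lab[20, 20] = int(ClassCode.PEG)         # 1 px, dropped
    _, ids = peg_components(_section(lab))
    assert len(ids) == 2


def test_no_pegs_empty_list():
    lab = np.zeros((32, 32))
    lab[5:10, 5:10] = int(ClassCode.ENDOTHELIAL)
    _, ids = peg_components(_section(lab))
    assert ids == []
    assert peg_max_depths(_section(lab)) == []


def test_diagonal_touch_is_one_component_under_8_connectivity():
    lab = np.zeros((32, 32))
    lab[4:8, 4:8] = int(ClassCode.PEG)
    lab[8:12, 8:12] = int(ClassCode.PEG)  # touches only at one corner
    _, ids = peg_components(_section(lab))
    assert len(ids) == 1


def test_depth_map_slab():
    """A 1000-nm EC slab: depth at the far face ~ slab thickness."""
    lab = np.zeros((64, 64))
    lab[10:60, 2:52] = int(ClassCode.ENDOTHELIAL)  # 50 px = 1000 nm thick
    d = depth_map(_section(lab))
    assert d[9, 20] == 0.0  # just outside the mask
    # deep interior row, far from lateral faces
    assert d[35, 26] == pytest.approx(26 * 20.0, abs=20.0 * 1.5)


def test_depth_map_matches_brute_force_oracle():
    rng = np.random.default_rng(0)
    from scipy import ndimage as ndi

    for _ in range(5):
        noise = rng.random((48, 48))
        blob = ndi.gaussian_filter(noise, 3) > 0.5
        lab = np.where(blob, int(ClassCode.ENDOTHELIAL), 0)
        if not blob.any():
            continue
        sec = _section(lab)
        closed = closed_peg_mask(sec)
        np.testing.assert_allclose(
            depth_map(sec), brute_force_depth(closed, 20.0), atol=1e-9
        )


def test_closing_radius_clamp_warns():
    lab = np.zeros((32, 32))
    lab[10:20, 10:20] = int(ClassCode.ENDOTHELIAL)
    sec = SegmentedSection(lab.astype(np.uint8), pixel_size_nm=500.0)
    with pytest.warns(UserWarning, match="clamping"):
        depth_map(sec)


def test_synthetic_peg_depth_and_area(small_vessel):
    stack, gt = small_vessel
    sec = stack.sections[0]
    recs = peg_max_depths(sec)
    assert len(recs) == gt.peg_counts[0]
    px = sec.pixel_size_nm
    tol = px * np.sqrt(2) + px  # pixel diagonal + closing bias allowance
    for r, true_d in zip(recs, gt.peg_depths_nm):
        assert r.max_depth_nm == pytest.approx(true_d, abs=tol)
        assert not r.orphan
    meas_areas = np.array(sorted(r.area_nm2 for r in recs))
    true_areas = np.array(sorted(gt.peg_areas_nm2[0]))
    np.testing.assert_allclose(meas_areas, true_areas, rtol=0.05)


def test_peg_area_conservation(small_vessel):
    stack, _ = small_vessel
    sec = stack.sections[0]
    recs = peg_max_depths(sec)
    total_peg_px = (sec.labels == int(ClassCode.PEG)).sum()
    assert sum(r.area_nm2 for r in recs) == pytest.approx(
        total_peg_px * sec.pixel_size_nm**2
    )


def test_depth_monotone_in_programmed_depth():
    depths = []
    for d_nm in (200.0, 400.0, 600.0):
        spec = SyntheticVesselSpec(
            seed=6,
            ec_thickness_nm=1000.0,
            peg_depth_nm=d_nm,
            peg_count_per_section=1,
            **SMALL,
        )
        stack, _ = generate_vessel(spec)
        recs = peg_max_depths(stack.sections[0])
        depths.append(recs[0].max_depth_nm)
    assert depths[0] < depths[1] < depths[2]
    steps = np.diff(depths)
    tol = 40.0 * np.sqrt(2) + 40.0
    np.testing.assert_allclose(steps, 200.0, atol=tol)


def test_orphan_peg_flagged():
    lab = np.zeros((48, 48))
    lab[10:30, :] = int(ClassCode.ENDOTHELIAL)
    lab[12:20, 10:14] = int(ClassCode.PEG)  # no pericyte anywhere
    recs = peg_max_depths(_section(lab))
    assert len(recs) == 1 and recs[0].orphan
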