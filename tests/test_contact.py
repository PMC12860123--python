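"""Skeleton three-class coverage/contact measurement."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from pericytometry import (
    ClassCode,
    PipelineConfig,
    SegmentedSection,
    contact_mask,
    contact_profile,
    skeletonize_interface,
)
from pericytometry.contact import (
    CLASS_CONTACT,
    CLASS_COVERED,
    CLASS_UNCOVERED,
    _class_lengths_px,
    classify_skeleton,
)
from pericytometry.synthetic import SyntheticVesselSpec, generate_vessel

SMALL = dict(n_sections=1, grid_px=512, pixel_size_nm=40.0)


def _section(lab):
    return SegmentedSection(lab.astype(np.uint8), pixel_size_nm=20.0)


def test_contact_mask_requires_adjacency():
    lab = np.zeros((32, 32))
    lab[10] = int(ClassCode.ENDOTHELIAL)
    lab[11:13] = int(ClassCode.BASEMENT_MEMBRANE)  # 2-px separation
    lab[13] = int(ClassCode.PERICYTE)
    assert contact_mask(_section(lab)).sum() == 0

    lab2 = np.zeros((32, 32))
    lab2[10, :] = int(ClassCode.ENDOTHELIAL)
    lab2[11, :] = int(ClassCode.PERICYTE)
    m = contact_mask(_section(lab2))
    assert m.sum() == 32 and m[11].all()


def test_contact_mask_respects_peg_merge_flag():
    lab = np.zeros((32, 32))
    lab[10, :] = int(ClassCode.ENDOTHELIAL)
    lab[11, :16] = int(ClassCode.PEG)
    cfg_off = PipelineConfig(merge_peg_into_pericyte=False)
    assert contact_mask(_section(lab), cfg_off).sum() == 0
    assert contact_mask(_section(lab)).sum() == 16


def test_skeleton_of_annulus_is_single_loop():
    n = 256
    yy, xx = np.mgrid[:n, :n]
    r = np.hypot(yy - n / 2, xx - n / 2)
    lab = np.where((r >= 100) & (r <= 103), int(ClassCode.BASEMENT_MEMBRANE), 0)
    skel = skeletonize_interface(_section(lab))
    k = np.ones((3, 3), int)
    k[1, 1] = 0
    nb = ndi.convolve(skel.astype(int), k, mode="constant")
    assert (nb[skel] == 2).all()  # every loop pixel has exactly 2 neighbours
    _, n_comp = ndi.label(skel, structure=np.ones((3, 3)))
    assert n_comp == 1


def test_skeleton_of_bar_is_centerline():
    lab = np.zeros((20, 120))
    lab[8:13, 10:110] = int(ClassCode.BASEMENT_MEMBRANE)
    skel = skeletonize_interface(_section(lab))
    assert 90 <= skel.sum() <= 100  # ~96-px centreline of a 5x100 bar


def test_contact_gap_bridged_by_contact_mask_stays_connected(contact_vessel):
    """Where the BM film is absent (direct contact), the contact mask
    bridges the gap so the retained skeleton stays one closed loop."""
    stack, _ = contact_vessel
    sec = stack.sections[0]
    cmask = contact_mask(sec)
    skel = skeletonize_interface(sec)
    classes = classify_skeleton(sec, skel, cmask)
    retained = classes > 0  # the discarded abluminal loop is separate
    lbl, n_comp = ndi.label(retained, structure=np.ones((3, 3)))
    sizes = np.bincount(lbl.ravel())[1:]
    # one dominant closed loop; stray probe-boundary pixels are negligible
    assert sizes.max() / sizes.sum() > 0.99


def test_empty_interface_is_an_error():
    lab = np.zeros((16, 16))
    lab[5:8, 5:8] = int(ClassCode.ENDOTHELIAL)
    with pytest.raises(ValueError, match="skeletonize"):
        skeletonize_interface(_section(lab))


def test_no_coverage_classifies_all_uncovered():
    spec = SyntheticVesselSpec(
        seed=2, pericyte_arc_fraction=0.0, peg_count_per_section=0, **SMALL
    )
    stack, _ = generate_vessel(spec)
    prof = contact_profile(stack.sections[0])
    assert prof.L1_um == 0 and prof.L2_um == 0
    assert prof.coverage_pct == 0.0 and prof.contact_pct is None


def test_no_contact_arc_yields_zero_L1(clean_vessel):
    stack, _ = clean_vessel
    prof = contact_profile(stack.sections[0])
    assert prof.L1_um == 0.0
    assert prof.coverage_pct == pytest.approx(50.0, abs=3.0)


def test_full_contact_arc_yields_contact_100():
    spec = SyntheticVesselSpec(
        seed=3,
        pericyte_arc_fraction=0.5,
        contact_arc_fraction=1.0,
        peg_count_per_section=0,
        **SMALL,
    )
    stack, _ = generate_vessel(spec)
    prof = contact_profile(stack.sections[0])
    assert prof.contact_pct == pytest.approx(100.0, abs=3.0)
    assert prof.coverage_pct == pytest.approx(50.0, abs=3.0)


def test_contact_recovery(contact_vessel):
    stack, gt = contact_vessel
    prof = contact_profile(stack.sections[0])
    assert prof.coverage_pct == pytest.approx(gt.true_coverage_pct, abs=3.0)
    assert prof.contact_pct == pytest.approx(gt.true_contact_pct, abs=3.0)


def test_class_lengths_partition_total(contact_vessel):
    """L1 + L2 + L3 equals the total retained skeleton length exactly."""
    stack, _ = contact_vessel
    sec = stack.sections[0]
    cmask = contact_mask(sec)
    skel = skeletonize_interface(sec)
    classes = classify_skeleton(sec, skel, cmask)
    lengths = _class_lengths_px(classes, "chain")
    total = _class_lengths_px(np.where(classes > 0, CLASS_COVERED, 0), "chain")
    assert sum(lengths.values()) == pytest.approx(
        total[CLASS_COVERED], abs=1e-9
    )


def test_coverage_rotation_invariant(clean_vessel):
    stack, _ = clean_vessel
    sec = stack.sections[0]
    p0 = contact_profile(sec)
    rot = SegmentedSection(np.rot90(sec.labels).copy(), sec.pixel_size_nm)
    p1 = contact_profile(rot)
    assert p1.coverage_pct == pytest.approx(p0.coverage_pct, abs=2.0)


def test_coverage_scale_invariant():
    for px, grid in ((40.0, 512), (20.0, 1024)):
        spec = SyntheticVesselSpec(
            seed=4,
            pericyte_arc_fraction=0.6,
            contact_arc_fraction=0.0,
            peg_count_per_section=0,
            n_sections=1,
            grid_px=grid,
            pixel_size_nm=px,
        )
        stack, _ = generate_vessel(spec)
        prof = contact_profile(stack.sections[0])
        assert prof.coverage_pct == pytest.approx(60.0, abs=2.0)


def test_pixel_count_length_mode():
    spec = SyntheticVesselSpec(
        seed=5, contact_arc_fraction=0.0, peg_count_per_section=0, **SMALL
    )
    stack, _ = generate_vessel(spec)
    cfg = PipelineConfig(length_metric="pixel_count")
    prof = contact_profile(stack.sections[0], cfg)
    assert prof.coverage_pct == pytest.approx(50.0, abs=3.0)
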