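"""Diameter from perimeter, and volume-fraction arithmetic."""

import numpy as np
import pytest
from skimage import draw

from pericytometry import (
    ClassCode,
    PipelineConfig,
    SegmentedSection,
    VesselStack,
    section_circumference,
    vessel_diameter,
    volume_percentages,
)


def _disk_section(diameter_px: int, pixel_size_nm: float, pad: int = 10):
    n = diameter_px + 2 * pad
    lab = np.zeros((n, n), np.uint8)
    rr, cc = draw.disk((n / 2 - 0.5, n / 2 - 0.5), diameter_px / 2)
    lab[rr, cc] = int(ClassCode.ENDOTHELIAL)
    return SegmentedSection(lab, pixel_size_nm)


def _stack_of(sections):
    return VesselStack(sections=sections, vessel_id="v")


@pytest.mark.parametrize("diam_um", [4.0, 8.0, 12.0])
def test_circle_diameter_within_3pct(diam_um):
    px = 20.0
    sec = _disk_section(int(diam_um * 1000 / px), px)
    d = section_circumference(sec) / np.pi
    assert d == pytest.approx(diam_um, rel=0.03)


def test_circle_error_decreases_with_resolution():
    errs = []
    for px in (40.0, 20.0, 10.0):
        sec = _disk_section(int(4000 / px), px)
        d = section_circumference(sec) / np.pi
        errs.append(abs(d - 4.0))
    assert errs[0] > errs[1] > errs[2]


def test_square_perimeter_plain_chain_mode():
    """A filled 100x100 square walks 396 chain steps -> 7.92 um at 20 nm/px."""
    lab = np.zeros((120, 120), np.uint8)
    lab[10:110, 10:110] = int(ClassCode.ENDOTHELIAL)
    sec = SegmentedSection(lab, 20.0)
    cfg = PipelineConfig(perimeter_metric="chain")
    assert section_circumference(sec, cfg) == pytest.approx(7.92, abs=1e-9)


def test_single_pixel_region_has_unit_square_perimeter():
    lab = np.zeros((16, 16), np.uint8)
    lab[8, 8] = int(ClassCode.ENDOTHELIAL)
    sec = SegmentedSection(lab, 20.0)
    # 4 pixel edges at 20 nm -> 80 nm -> 0.08 um
    assert section_circumference(sec) == pytest.approx(0.08)


def test_empty_section_is_an_error():
    sec = SegmentedSection(np.zeros((16, 16), np.uint8), 20.0)
    with pytest.raises(ValueError, match="vessel region"):
        section_circumference(sec)


def test_diameter_formula_and_exclusion():
    sec_good = _disk_section(200, 20.0)
    noisy = np.zeros_like(sec_good.labels)
    noisy[4:8, 4:8] = int(ClassCode.ENDOTHELIAL)
    sec_bad = SegmentedSection(noisy, 20.0, section_index=1, excluded=True)
    stack = _stack_of([sec_good, sec_bad])
    m = vessel_diameter(stack)
    assert m.n_sections_used == 1
    assert m.diameter_um == pytest.approx(
        section_circumference(sec_good) / np.pi
    )


def test_diameter_rotation_invariant(small_vessel):
    stack, _ = small_vessel
    sec = stack.sections[0]
    d0 = section_circumference(sec)
    rot = SegmentedSection(np.rot90(sec.labels).copy(), sec.pixel_size_nm)
    assert section_circumference(rot) == pytest.approx(d0, rel=1e-6)


def test_synthetic_diameter_recovery(small_vessel):
    stack, gt = small_vessel
    m = vessel_diameter(stack)
    assert m.diameter_um == pytest.approx(gt.true_diameter_um, abs=0.25)


def test_volume_percentages_arithmetic():
    lab = np.zeros((32, 32), np.uint8)
    flat = lab.ravel()
    flat[:100] = int(ClassCode.PERICYTE)
    flat[100:200] = int(ClassCode.BASEMENT_MEMBRANE)
    flat[200:400] = int(ClassCode.ENDOTHELIAL)
    flat[400:500] = int(ClassCode.LUMEN)  # excluded from the denominator
    stack = _stack_of([SegmentedSection(lab, 20.0)])
    peri, bm, ec = volume_percentages(stack)
    assert (peri, bm, ec) == (25.0, 25.0, 50.0)


def test_volume_conservation_random_stacks():
    rng = np.random.default_rng(0)
    for _ in range(20):
        lab = rng.integers(0, 6, (24, 24)).astype(np.uint8)
        if not np.isin(lab, [1, 2, 3, 4]).any():
            continue
        stack = _stack_of([SegmentedSection(lab, 20.0)])
        assert sum(volume_percentages(stack)) == pytest.approx(100.0, abs=1e-9)


def test_volume_zero_denominator_is_an_error():
    lab = np.full((16, 16), int(ClassCode.LUMEN), np.uint8)
    with pytest.raises(ValueError, match="tissue"):
        volume_percentages(_stack_of([SegmentedSection(lab, 20.0)]))
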