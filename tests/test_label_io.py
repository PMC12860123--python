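"""Stack IO round-trips, validation, and the class-mask partition."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from pericytometry import (
    ClassCode,
    PipelineConfig,
    SegmentedSection,
    VesselStack,
    class_masks,
    read_stack,
    write_stack,
)


def _stack(labels_list, pixel_size_nm=20.0, excluded=()):
    sections = [
        SegmentedSection(
            labels=lab,
            pixel_size_nm=pixel_size_nm,
            section_index=i,
            excluded=i in excluded,
        )
        for i, lab in enumerate(labels_list)
    ]
    return VesselStack(sections=sections, vessel_id="v0", group="WT")


def test_write_read_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    labels = [rng.integers(0, 6, (24, 24)).astype(np.uint8) for _ in range(3)]
    stack = _stack(labels, excluded={1})
    tif, side = write_stack(stack, tmp_path / "v0.tif")
    back = read_stack(tif)
    assert back.vessel_id == "v0" and back.group == "WT"
    assert back.pixel_size_nm == 20.0 and back.z_spacing_nm == 80.0
    for orig, rec in zip(stack.sections, back.sections):
        np.testing.assert_array_equal(orig.labels, rec.labels)
        assert orig.excluded == rec.excluded
        assert orig.section_index == rec.section_index


def test_round_trip_many_sections(tmp_path):
    rng = np.random.default_rng(1)
    labels = [rng.integers(0, 6, (16, 16)).astype(np.uint8) for _ in range(25)]
    tif, side = write_stack(_stack(labels), tmp_path / "big")
    import tifffile

    assert tifffile.imread(tif).shape[0] == 25
    assert json.loads(side.read_text())["z_spacing_nm"] == 80.0


def test_unknown_label_is_named_in_error(tmp_path):
    labels = np.zeros((20, 20), np.uint8)
    labels[5, 5] = 7
    import tifffile

    tifffile.imwrite(tmp_path / "bad.tif", labels)
    (tmp_path / "bad.json").write_text(json.dumps({"pixel_size_nm": 20}))
    with pytest.raises(ValueError, match="7"):
        read_stack(tmp_path / "bad.tif")


def test_excluded_sections_skipped_by_aggregation(tmp_path):
    labels = [np.full((16, 16), int(ClassCode.LUMEN), np.uint8) for _ in range(4)]
    stack = _stack(labels, excluded={1, 3})
    tif, _ = write_stack(stack, tmp_path / "v")
    back = read_stack(tif)
    usable = back.usable_sections()
    assert [s.section_index for s in usable] == [0, 2]
    assert back.sections[1].excluded and back.sections[3].excluded


def test_missing_pixel_size_is_an_error(tmp_path):
    import tifffile

    tifffile.imwrite(tmp_path / "x.tif", np.zeros((16, 16), np.uint8))
    (tmp_path / "x.json").write_text("{}")
    with pytest.raises(ValueError, match="pixel_size_nm"):
        read_stack(tmp_path / "x.tif")


def test_stack_invariants():
    lab = np.zeros((16, 16), np.uint8)
    with pytest.raises(ValueError, match="increasing"):
        VesselStack(
            sections=[
                SegmentedSection(lab, 20.0, section_index=1),
                SegmentedSection(lab, 20.0, section_index=1),
            ]
        )
    with pytest.raises(ValueError, match="excluded"):
        VesselStack(
            sections=[SegmentedSection(lab, 20.0, section_index=0, excluded=True)]
        )


def test_class_masks_merges_peg_into_pericyte():
    lab = np.zeros((16, 16), np.uint8)
    lab[:5] = int(ClassCode.PERICYTE)
    lab[5, :10] = int(ClassCode.PEG)
    masks = class_masks(SegmentedSection(lab, 20.0))
    assert masks["pericyte_total"].sum() == 5 * 16 + 10
    assert masks["lumen"].sum() == 0


@settings(max_examples=30, derandomize=True)
@given(
    labels=hnp.arrays(
        np.uint8, (16, 16), elements=st.integers(min_value=0, max_value=5)
    )
)
def test_class_masks_partition_property(labels):
    """Per-class masks are disjoint and cover the grid exactly."""
    section = SegmentedSection(labels, pixel_size_nm=20.0)
    masks = class_masks(section)
    partition = [m for name, m in masks.items() if name != "pericyte_total"]
    total = np.zeros(labels.shape, int)
    for m in partition:
        total += m.astype(int)
    assert (total == 1).all()


def test_config_yaml_round_trip(tmp_path):
    cfg = PipelineConfig(closing_radius_nm=100.0, contact_dilation_px=2)
    cfg.to_yaml(tmp_path / "cfg.yaml")
    back = PipelineConfig.from_yaml(tmp_path / "cfg.yaml")
    assert back == cfg
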