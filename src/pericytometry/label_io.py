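"""Data model and IO for segmented capillary cross-section stacks.

A vessel is represented as an ordered stack of 2-D integer label maps
(one per ultrathin section, ~80 nm apart) in which every pixel belongs to
one of six classes: background, basement membrane, endothelial cell,
pericyte, pericyte peg, or lumen.  Stacks are stored on disk as multi-page
uint8 TIFFs with a JSON metadata sidecar carrying the physical calibration
(pixel size in nm, section spacing in nm), the experimental group, and the
list of sections excluded for image quality.

Every measurement module consumes the types defined here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile
import yaml

__all__ = [
    "ClassCode",
    "SegmentedSection",
    "VesselStack",
    "PipelineConfig",
    "read_stack",
    "write_stack",
    "class_masks",
]

MIN_GRID = 16


class ClassCode(IntEnum):
    """Semantic codes for the six-class segmentation.

    The on-disk integer values of a particular dataset are mapped onto
    these codes through :attr:`PipelineConfig.class_map`; the mapping is
    always explicit, never positional.
    """

    BACKGROUND = 0
    BASEMENT_MEMBRANE = 1
    ENDOTHELIAL = 2
    PERICYTE = 3
    PEG = 4
    LUMEN = 5


#: Lower-case mask names, in class-code order.
CLASS_NAMES = {c: c.name.lower() for c in ClassCode}


@dataclass
class SegmentedSection:
    """One z-section's label map plus physical calibration.

    Parameters
    ----------
    labels
        2-D integer grid of :class:`ClassCode` values (row-major, 0-based;
        a pixel is a unit square of edge ``pixel_size_nm``).
    pixel_size_nm
        Physical edge length of one pixel, in nm.  Mandatory: the source
        imagery's magnification does not determine it.
    section_index
        Position of the section within its stack.
    excluded
        True if the section was flagged (poor image quality, artifacts);
        excluded sections are retained but skipped by aggregation.
    """

    labels: np.ndarray
    pixel_size_nm: float
    section_index: int = 0
    excluded: bool = False

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D grid")
        if min(self.labels.shape) < MIN_GRID:
            raise ValueError(
                f"label grid must be at least {MIN_GRID}x{MIN_GRID}, "
                f"got {self.labels.shape}"
            )
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.section_index < 0:
            raise ValueError("section_index must be non-negative")
        bad = set(np.unique(self.labels)) - {int(c) for c in ClassCode}
        if bad:
            raise ValueError(
                f"section {self.section_index}: label values {sorted(bad)} "
                "do not map to any ClassCode"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class VesselStack:
    """Ordered sections of one vessel, with group metadata."""

    sections: list[SegmentedSection]
    z_spacing_nm: float = 80.0
    vessel_id: str = "vessel"
    group: str = ""

    def __post_init__(self) -> None:
        if not self.sections:
            raise ValueError("a VesselStack needs at least one section")
        if self.z_spacing_nm <= 0:
            raise ValueError("z_spacing_nm must be positive")
        shapes = {s.shape for s in self.sections}
        if len(shapes) > 1:
            raise ValueError(f"sections disagree on grid shape: {shapes}")
        sizes = {s.pixel_size_nm for s in self.sections}
        if len(sizes) > 1:
            raise ValueError(f"sections disagree on pixel_size_nm: {sizes}")
        idx = [s.section_index for s in self.sections]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("section_index must be strictly increasing")
        if not any(not s.excluded for s in self.sections):
            raise ValueError("all sections are excluded")

    @property
    def pixel_size_nm(self) -> float:
        return self.sections[0].pixel_size_nm

    def usable_sections(self) -> list[SegmentedSection]:
        """Sections that enter aggregation (excluded flag unset)."""
        return [s for s in self.sections if not s.excluded]


def _identity_class_map() -> dict[int, ClassCode]:
    return {int(c): c for c in ClassCode}


@dataclass
class PipelineConfig:
    """Knobs shared across the measurement pipeline.

    ``closing_radius_nm`` is the physical radius of the disk structuring
    element used to seal small clefts between a peg and its socket before
    the depth transform (default 134 nm).  ``contact_dilation_px`` is the
    dilation applied to the endothelial mask when detecting direct
    pericyte contact (default 1 px).
    """

    class_map: dict[int, ClassCode] = field(default_factory=_identity_class_map)
    closing_radius_nm: float = 134.0
    contact_dilation_px: int = 1
    merge_peg_into_pericyte: bool = True
    min_component_px: int = 4
    connectivity: int = 8
    # "corner_corrected": Vossepoel-Smeulders chain weights (default);
    # "chain": 1 per axis step, sqrt(2) per diagonal; "pixel_count": raw count.
    perimeter_metric: str = "corner_corrected"
    # skeleton class-length metric: "chain" (half-edge chain) or "pixel_count"
    length_metric: str = "chain"
    # whether the abluminal BM loop wrapping the pericyte soma is dropped
    # from the coverage denominator (sensitivity knob)
    discard_abluminal_loop: bool = True

    def __post_init__(self) -> None:
        if self.closing_radius_nm <= 0:
            raise ValueError("closing_radius_nm must be positive")
        if self.contact_dilation_px < 1:
            raise ValueError("contact_dilation_px must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.perimeter_metric not in ("corner_corrected", "chain", "pixel_count"):
            raise ValueError(f"unknown perimeter_metric {self.perimeter_metric!r}")
        if self.length_metric not in ("chain", "pixel_count"):
            raise ValueError(f"unknown length_metric {self.length_metric!r}")
        self.class_map = {int(k): ClassCode(v) for k, v in self.class_map.items()}
        if len(set(self.class_map.values())) != len(self.class_map):
            raise ValueError("class_map must be one-to-one")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "class_map" in data:
            data["class_map"] = {
                int(k): ClassCode(int(v)) for k, v in data["class_map"].items()
            }
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "class_map": {int(k): int(v) for k, v in self.class_map.items()},
            "closing_radius_nm": self.closing_radius_nm,
            "contact_dilation_px": self.contact_dilation_px,
            "merge_peg_into_pericyte": self.merge_peg_into_pericyte,
            "min_component_px": self.min_component_px,
            "connectivity": self.connectivity,
            "perimeter_metric": self.perimeter_metric,
            "length_metric": self.length_metric,
            "discard_abluminal_loop": self.discard_abluminal_loop,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(stack: VesselStack, path: str | Path) -> tuple[Path, Path]:
    """Write a stack as a multi-page uint8 TIFF plus a JSON sidecar.

    ``read_stack(write_stack(s))`` reproduces ``s`` bit-exactly (labels,
    calibration, and exclusion flags) under the identity class map.
    """
    path = Path(path)
    if path.suffix.lower() not in (".tif", ".tiff"):
        path = path.with_suffix(".tif")
    path.parent.mkdir(parents=True, exist_ok=True)
    pages = np.stack([s.labels.astype(np.uint8) for s in stack.sections])
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {
        "vessel_id": stack.vessel_id,
        "group": stack.group,
        "pixel_size_nm": stack.pixel_size_nm,
        "z_spacing_nm": stack.z_spacing_nm,
        "section_indices": [s.section_index for s in stack.sections],
        "excluded_sections": [
            s.section_index for s in stack.sections if s.excluded
        ],
    }
    side = _sidecar_path(path)
    with open(side, "w") as fh:
        json.dump(meta, fh, indent=2)
    return path, side


def read_stack(
    path: str | Path,
    meta: str | Path | Mapping | None = None,
    config: PipelineConfig | None = None,
) -> VesselStack:
    """Read a multi-page TIFF stack, remapping labels through the class map.

    Parameters
    ----------
    path
        Multi-page TIFF of integer label maps (one page per section).
    meta
        JSON sidecar path or an already-loaded metadata mapping.  Defaults
        to ``<path stem>.json``.  Must supply ``pixel_size_nm``; the other
        fields have defaults.
    config
        Pipeline configuration; its ``class_map`` translates on-disk
        integers to :class:`ClassCode`.  Unknown values are a hard error
        naming the value and the section.
    """
    config = config or PipelineConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if meta is None:
        meta = _sidecar_path(path)
    if not isinstance(meta, Mapping):
        with open(meta) as fh:
            meta = json.load(fh)
    if "pixel_size_nm" not in meta:
        raise ValueError("metadata must supply pixel_size_nm")
    pixel_size_nm = float(meta["pixel_size_nm"])
    z_spacing_nm = float(meta.get("z_spacing_nm", 80.0))
    vessel_id = str(meta.get("vessel_id", path.stem))
    group = str(meta.get("group", ""))

    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    indices = list(meta.get("section_indices", range(pages.shape[0])))
    excluded = set(meta.get("excluded_sections", []))

    # vectorized remap through the class map, with validation
    lut = np.full(256, -1, dtype=np.int16)
    for raw, code in config.class_map.items():
        lut[raw] = int(code)
    sections = []
    for i, page in enumerate(pages):
        raw = np.asarray(page)
        unknown = set(np.unique(raw)) - set(config.class_map)
        if unknown:
            raise ValueError(
                f"section {indices[i]} of {path.name} contains label value(s) "
                f"{sorted(int(u) for u in unknown)} absent from class_map"
            )
        mapped = lut[raw.astype(np.uint8)].astype(np.uint8)
        sections.append(
            SegmentedSection(
                labels=mapped,
                pixel_size_nm=pixel_size_nm,
                section_index=int(indices[i]),
                excluded=indices[i] in excluded,
            )
        )
    return VesselStack(
        sections=sections,
        z_spacing_nm=z_spacing_nm,
        vessel_id=vessel_id,
        group=group,
    )


def class_masks(
    section: SegmentedSection, config: PipelineConfig | None = None
) -> dict[str, np.ndarray]:
    """Boolean mask per class; masks partition the grid.

    When ``config.merge_peg_into_pericyte`` is set an extra
    ``"pericyte_total"`` mask (PERICYTE union PEG) is included; it is not
    part of the partition.
    """
    config = config or PipelineConfig()
    out = {
        CLASS_NAMES[c]: section.labels == int(c) for c in ClassCode
    }
    if config.merge_peg_into_pericyte:
        out["pericyte_total"] = out["pericyte"] | out["peg"]
    return out
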