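"""Peg-and-socket morphometry: depth, area, and per-section frequency.

A pericyte peg is the finger-like part of the pericyte protruding into an
endothelial-cell invagination (the socket).  Its maximum protrusion depth
is measured from the abluminal endothelial surface with a Euclidean
distance transform: the mask of endothelium + pegs + lumen is first
closed with a disk-shaped structuring element of physical radius
``closing_radius_nm`` (default 134 nm) to seal small clefts between the
peg and the socket wall, then each pixel's exact Euclidean distance to
the mask complement is computed.  Distances are zero outside the mask and
increase moving from the abluminal surface toward the lumen; the maximum
over a peg component's pixels is its depth.

Peg cross-sectional area is the component pixel count times the pixel
area, and the per-section number of components is the peg frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .label_io import ClassCode, PipelineConfig, SegmentedSection

__all__ = [
    "PegRecord",
    "peg_components",
    "closed_peg_mask",
    "depth_map",
    "peg_max_depths",
    "disk_footprint",
]


@dataclass
class PegRecord:
    """One 2-D peg component's measurements."""

    vessel_id: str
    section_index: int
    component_id: int
    area_nm2: float
    max_depth_nm: float
    centroid: tuple[float, float]
    #: set when the component touches no pericyte pixel (possible
    #: segmentation slip); such components are kept, never dropped
    orphan: bool = False


def disk_footprint(radius_px: int) -> np.ndarray:
    """Rasterized disk {(r, c): r^2 + c^2 <= R^2}."""
    rr, cc = np.ogrid[-radius_px : radius_px + 1, -radius_px : radius_px + 1]
    return (rr * rr + cc * cc) <= radius_px * radius_px


def _structure(connectivity: int) -> np.ndarray:
    return (
        np.ones((3, 3), bool)
        if connectivity == 8
        else ndi.generate_binary_structure(2, 1)
    )


def peg_components(
    section: SegmentedSection, config: PipelineConfig | None = None
) -> tuple[np.ndarray, list[int]]:
    """Connected components of the peg class.

    Returns ``(labels, ids)`` where ``labels`` is an integer grid (0 =
    not a peg) and ``ids`` lists components with at least
    ``min_component_px`` pixels; ``len(ids)`` is the section's peg
    frequency.
    """
    config = config or PipelineConfig()
    peg = section.labels == int(ClassCode.PEG)
    lbl, n = ndi.label(peg, structure=_structure(config.connectivity))
    if n == 0:
        return lbl, []
    sizes = ndi.sum_labels(peg, lbl, index=np.arange(1, n + 1))
    ids = [i + 1 for i, s in enumerate(sizes) if s >= config.min_component_px]
    return lbl, ids


def closed_peg_mask(
    section: SegmentedSection, config: PipelineConfig | None = None
) -> np.ndarray:
    """EC + peg + lumen mask after disk closing in physical units.

    The disk radius is ``round(closing_radius_nm / pixel_size_nm)``
    pixels; a radius below one pixel at the given calibration is clamped
    to 1 px with a warning.  Closing is extensive: the original mask is
    always contained in the result.
    """
    config = config or PipelineConfig()
    labels = section.labels
    ec = labels == int(ClassCode.ENDOTHELIAL)
    if not ec.any():
        raise ValueError(
            f"section {section.section_index}: empty endothelial mask"
        )
    mask = (
        ec
        | (labels == int(ClassCode.PEG))
        | (labels == int(ClassCode.LUMEN))
    )
    radius_px = int(round(config.closing_radius_nm / section.pixel_size_nm))
    if radius_px < 1:
        warnings.warn(
            f"closing radius {config.closing_radius_nm} nm is below one "
            f"pixel at {section.pixel_size_nm} nm/px; clamping to 1 px",
            stacklevel=2,
        )
        radius_px = 1
    closed = ndi.binary_closing(mask, structure=disk_footprint(radius_px))
    return closed | mask


def depth_map(
    section: SegmentedSection, config: PipelineConfig | None = None
) -> np.ndarray:
    """Per-pixel protrusion depth in nm.

    Exact Euclidean distance from each pixel of the closed
    EC + peg + lumen mask (see :func:`closed_peg_mask`) to the nearest
    complement pixel, converted to nm; zero outside the mask.
    """
    config = config or PipelineConfig()
    closed = closed_peg_mask(section, config)
    dist_px = ndi.distance_transform_edt(closed)
    return dist_px * section.pixel_size_nm


def peg_max_depths(
    section: SegmentedSection,
    config: PipelineConfig | None = None,
    vessel_id: str = "",
) -> list[PegRecord]:
    """Per-peg maximum depth and cross-sectional area."""
    config = config or PipelineConfig()
    lbl, ids = peg_components(section, config)
    if not ids:
        return []
    depths = depth_map(section, config)
    px_area_nm2 = section.pixel_size_nm**2
    pericyte = section.labels == int(ClassCode.PERICYTE)
    near_pericyte = ndi.binary_dilation(pericyte, np.ones((3, 3), bool))
    records = []
    for cid in ids:
        comp = lbl == cid
        n_px = int(comp.sum())
        r, c = ndi.center_of_mass(comp)
        records.append(
            PegRecord(
                vessel_id=vessel_id,
                section_index=section.section_index,
                component_id=int(cid),
                area_nm2=n_px * px_area_nm2,
                max_depth_nm=float(depths[comp].max()),
                centroid=(float(r), float(c)),
                orphan=not bool((comp & near_pericyte).any()),
            )
        )
    return records
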