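"""Per-vessel basic morphometry: diameter and volume fractions.

Vessel diameter follows the circle formula D = C / pi, with the
circumference C measured as the length of the outer perimeter of the
basement membrane.  Because the basement-membrane ring is interrupted
wherever pericyte and endothelium touch directly, the perimeter is taken
on the outer boundary of the filled vessel region (union of all
non-background classes, holes filled) -- the BM is the outermost tissue
layer, so the two boundaries coincide where the BM is present.

Volume fractions are voxel-count percentages of the vessel volume
excluding the lumen (erythrocytes and anything else inside the lumen are
labeled lumen and never enter the denominator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._boundary import region_perimeter_px
from .label_io import ClassCode, PipelineConfig, SegmentedSection, VesselStack

__all__ = [
    "VesselMorphometry",
    "section_circumference",
    "vessel_diameter",
    "volume_percentages",
]


@dataclass
class VesselMorphometry:
    """Per-vessel summary of the basic measurements."""

    vessel_id: str
    diameter_um: float
    circumference_um: float
    pericyte_volume_pct: float = float("nan")
    bm_volume_pct: float = float("nan")
    endothelial_volume_pct: float = float("nan")
    n_sections_used: int = 0


def section_circumference(
    section: SegmentedSection, config: PipelineConfig | None = None
) -> float:
    """Outer perimeter of the vessel region in µm.

    Raises if the section has no non-background pixel.
    """
    config = config or PipelineConfig()
    vessel = section.labels != int(ClassCode.BACKGROUND)
    if not vessel.any():
        raise ValueError(
            f"section {section.section_index} has no vessel region"
        )
    per_px = region_perimeter_px(vessel, config.perimeter_metric)
    return per_px * section.pixel_size_nm / 1000.0


def vessel_diameter(
    stack: VesselStack, config: PipelineConfig | None = None
) -> VesselMorphometry:
    """Vessel diameter D = C / pi, averaged over non-excluded sections."""
    config = config or PipelineConfig()
    used = stack.usable_sections()
    if not used:
        raise ValueError(f"{stack.vessel_id}: all sections excluded")
    circs = np.array([section_circumference(s, config) for s in used])
    return VesselMorphometry(
        vessel_id=stack.vessel_id,
        diameter_um=float(np.mean(circs) / np.pi),
        circumference_um=float(np.mean(circs)),
        n_sections_used=len(used),
    )


def volume_percentages(
    stack: VesselStack, config: PipelineConfig | None = None
) -> tuple[float, float, float]:
    """(pericyte %, basement-membrane %, endothelial %) of vessel volume.

    Voxels are pooled over non-excluded sections before dividing; the
    denominator excludes background and lumen.  Peg voxels count with the
    pericyte when ``merge_peg_into_pericyte`` is set (otherwise with the
    endothelial share, since the peg sits inside the EC wall).  The three
    percentages sum to 100 up to rounding.
    """
    config = config or PipelineConfig()
    used = stack.usable_sections()
    if not used:
        raise ValueError(f"{stack.vessel_id}: all sections excluded")
    counts = np.zeros(len(ClassCode), dtype=np.int64)
    for s in used:
        counts += np.bincount(s.labels.ravel(), minlength=len(ClassCode))
    pericyte = counts[int(ClassCode.PERICYTE)]
    peg = counts[int(ClassCode.PEG)]
    bm = counts[int(ClassCode.BASEMENT_MEMBRANE)]
    ec = counts[int(ClassCode.ENDOTHELIAL)]
    if config.merge_peg_into_pericyte:
        pericyte += peg
    else:
        ec += peg
    denom = pericyte + bm + ec
    if denom == 0:
        raise ValueError(f"{stack.vessel_id}: no tissue voxels")
    return (
        100.0 * pericyte / denom,
        100.0 * bm / denom,
        100.0 * ec / denom,
    )
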