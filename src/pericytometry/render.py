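"""Optional RGB overlay renders of the measurement intermediates.

These reproduce the conventional colour schemes: contact skeleton in red,
covered-but-separated in cyan, uncovered in dark blue over a grey
basement-membrane/lumen backdrop; and pegs coloured by protrusion depth.
Arrays are uint8 RGB, writable with ``imageio.imwrite``.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from .contact import (
    CLASS_CONTACT,
    CLASS_COVERED,
    CLASS_UNCOVERED,
    classify_skeleton,
    contact_mask,
    skeletonize_interface,
)
from .label_io import ClassCode, PipelineConfig, SegmentedSection
from .pegs import depth_map, peg_components

__all__ = ["contact_overlay", "peg_depth_overlay"]

_CLASS_COLORS = {
    CLASS_CONTACT: (230, 40, 40),  # direct contact: red
    CLASS_COVERED: (60, 220, 220),  # covered, BM in between: cyan
    CLASS_UNCOVERED: (40, 60, 160),  # uncovered: dark blue
}


def contact_overlay(
    section: SegmentedSection, config: PipelineConfig | None = None
) -> np.ndarray:
    """Skeleton classes coloured over grey tissue; lines dilated for visibility."""
    config = config or PipelineConfig()
    cmask = contact_mask(section, config)
    skel = skeletonize_interface(section, config)
    classes = classify_skeleton(section, skel, cmask, config)

    img = np.zeros(section.labels.shape + (3,), dtype=np.uint8)
    bm = section.labels == int(ClassCode.BASEMENT_MEMBRANE)
    lumen = section.labels == int(ClassCode.LUMEN)
    tissue = (section.labels != int(ClassCode.BACKGROUND)) & ~lumen
    img[tissue] = (90, 90, 90)
    img[bm] = (150, 150, 150)
    img[lumen] = (60, 60, 60)
    for cls, color in _CLASS_COLORS.items():
        line = ndi.binary_dilation(classes == cls, np.ones((3, 3), bool))
        img[line] = color
    return img


def peg_depth_overlay(
    section: SegmentedSection, config: PipelineConfig | None = None
) -> np.ndarray:
    """Pegs coloured blue (shallow) to red (deep) over grey tissue."""
    config = config or PipelineConfig()
    depths = depth_map(section, config)
    lbl, ids = peg_components(section, config)
    img = np.zeros(section.labels.shape + (3,), dtype=np.uint8)
    img[section.labels != int(ClassCode.BACKGROUND)] = (90, 90, 90)
    img[section.labels == int(ClassCode.ENDOTHELIAL)] = (140, 70, 70)
    if not ids:
        return img
    peg_any = np.isin(lbl, ids)
    dmax = depths[peg_any].max() or 1.0
    frac = np.clip(depths / dmax, 0, 1)
    rgb = np.stack(
        [255 * frac, 40 * np.ones_like(frac), 255 * (1 - frac)], axis=-1
    ).astype(np.uint8)
    img[peg_any] = rgb[peg_any]
    return img
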