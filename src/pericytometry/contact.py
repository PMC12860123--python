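"""Pericyte coverage and direct pericyte-endothelial contact lengths.

The measurement skeletonizes the union of the basement membrane and the
direct-contact mask, then assigns each skeleton pixel to one of three
classes:

* Class 1 -- lines of direct cell-cell contact (pericyte touching the
  endothelium with no intervening basement membrane),
* Class 2 -- lines of pericyte coverage separated from the endothelium by
  basement membrane,
* Class 3 -- uncovered vessel circumference.

Coverage is then (L1 + L2) / (L1 + L2 + L3) and direct contact is
L1 / (L1 + L2), both as percentages.

Class 1 is read straight off the contact mask (pericyte pixels within one
dilation step of the endothelial mask).  The remaining skeleton pixels
are classified with a radial probe from the vessel centroid: probing
outward through basement membrane, meeting pericyte means the pixel lies
under coverage (Class 2) and meeting background means it is uncovered
(Class 3).  Skeleton pixels whose inward probe meets pericyte before
endothelium belong to the abluminal BM loop wrapping the pericyte soma;
counting that loop would double-count covered arcs, so it is discarded
(configurable).  The probe is exact for star-shaped sections, which
capillary cross-sections approximately are.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import skeletonize

from .label_io import ClassCode, PipelineConfig, SegmentedSection, VesselStack

__all__ = [
    "ContactProfile",
    "CLASS_CONTACT",
    "CLASS_COVERED",
    "CLASS_UNCOVERED",
    "CLASS_DISCARD",
    "contact_mask",
    "skeletonize_interface",
    "classify_skeleton",
    "contact_profile",
    "stack_contact_profile",
]

CLASS_CONTACT = 1
CLASS_COVERED = 2
CLASS_UNCOVERED = 3
CLASS_DISCARD = -1

_SQUARE3 = np.ones((3, 3), bool)


@dataclass
class ContactProfile:
    """Per-section class lengths and the derived percentages.

    ``contact_pct`` is None when the section has no covered arc
    (L1 + L2 = 0).
    """

    section_index: int
    L1_um: float
    L2_um: float
    L3_um: float

    @property
    def total_um(self) -> float:
        return self.L1_um + self.L2_um + self.L3_um

    @property
    def coverage_pct(self) -> float:
        total = self.total_um
        if total == 0:
            return 0.0
        return 100.0 * (self.L1_um + self.L2_um) / total

    @property
    def contact_pct(self) -> float | None:
        covered = self.L1_um + self.L2_um
        if covered == 0:
            return None
        return 100.0 * self.L1_um / covered


def _pericyte_mask(section: SegmentedSection, config: PipelineConfig) -> np.ndarray:
    mask = section.labels == int(ClassCode.PERICYTE)
    if config.merge_peg_into_pericyte:
        mask = mask | (section.labels == int(ClassCode.PEG))
    return mask


def contact_mask(
    section: SegmentedSection, config: PipelineConfig | None = None
) -> np.ndarray:
    """Pericyte pixels within ``contact_dilation_px`` of the EC mask."""
    config = config or PipelineConfig()
    ec = section.labels == int(ClassCode.ENDOTHELIAL)
    dil = ndi.binary_dilation(ec, _SQUARE3, iterations=config.contact_dilation_px)
    return _pericyte_mask(section, config) & dil


def skeletonize_interface(
    section: SegmentedSection, config: PipelineConfig | None = None
) -> np.ndarray:
    """1-px skeleton of (basement membrane union contact mask)."""
    config = config or PipelineConfig()
    bm = section.labels == int(ClassCode.BASEMENT_MEMBRANE)
    region = bm | contact_mask(section, config)
    if not region.any():
        raise ValueError(
            f"section {section.section_index}: no basement membrane or "
            "contact region to skeletonize"
        )
    return skeletonize(region)


def _first_hit(labels: np.ndarray, starts: np.ndarray, dirs: np.ndarray,
               t_max: np.ndarray, step: float = 0.5) -> np.ndarray:
    """For each ray, the first non-BM class label met, else BACKGROUND.

    ``starts`` (N,2) pixel coordinates, ``dirs`` (N,2) unit vectors,
    ``t_max`` (N,) maximum parameter per ray.  Samples every ``step``
    pixels with nearest-neighbour lookup; out-of-grid counts as
    background.  Basement membrane (and the starting pixel itself) is
    transparent.
    """
    h, w = labels.shape
    n = starts.shape[0]
    out = np.full(n, int(ClassCode.BACKGROUND), dtype=np.int16)
    found = np.zeros(n, dtype=bool)
    k_max = int(np.ceil(t_max.max() / step)) if n else 0
    # march in chunks to bound memory
    chunk = 64
    t = step
    k = 0
    while k < k_max and not found.all():
        ks = np.arange(k, min(k + chunk, k_max))
        ts = (ks + 1) * step
        pos = starts[:, None, :] + dirs[:, None, :] * ts[None, :, None]
        rr = np.rint(pos[..., 0]).astype(np.int64)
        cc = np.rint(pos[..., 1]).astype(np.int64)
        inb = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        vals = np.full(rr.shape, int(ClassCode.BACKGROUND), dtype=np.int16)
        vals[inb] = labels[rr[inb], cc[inb]]
        valid = ts[None, :] <= t_max[:, None] + step
        # first sample along each ray that is not BM (background counts)
        interesting = (vals != int(ClassCode.BASEMENT_MEMBRANE)) & valid
        any_hit = interesting.any(axis=1)
        idx = np.argmax(interesting, axis=1)
        newly = any_hit & ~found
        out[newly] = vals[newly, idx[newly]]
        found |= any_hit
        k += chunk
    return out


def classify_skeleton(
    section: SegmentedSection,
    skeleton: np.ndarray,
    contact: np.ndarray,
    config: PipelineConfig | None = None,
) -> np.ndarray:
    """Assign every skeleton pixel to Class 1/2/3 or discard.

    Returns an int8 grid: 0 off-skeleton, 1/2/3 per class,
    ``CLASS_DISCARD`` for the dropped abluminal BM loop.
    """
    config = config or PipelineConfig()
    if not skeleton.any():
        raise ValueError("empty skeleton")
    labels = section.labels
    vessel = labels != int(ClassCode.BACKGROUND)
    filled = ndi.binary_fill_holes(vessel)
    if not filled.any():
        raise ValueError("degenerate section: background only")
    centroid = np.array(ndi.center_of_mass(filled))

    out = np.zeros(labels.shape, dtype=np.int8)

    coords = np.argwhere(skeleton).astype(float)
    # Class 1: within the dilated contact mask (the medial axis may sit a
    # pixel off the actual contact line)
    contact_dil = ndi.binary_dilation(
        contact, _SQUARE3, iterations=config.contact_dilation_px
    )
    is_c1 = contact_dil[tuple(np.argwhere(skeleton).T)]

    vec = coords - centroid[None, :]
    dist = np.hypot(vec[:, 0], vec[:, 1])
    dist[dist == 0] = 1.0
    dirs = vec / dist[:, None]

    pericyte_codes = (int(ClassCode.PERICYTE), int(ClassCode.PEG))

    # inward probe: does the ray toward the centroid meet pericyte before
    # endothelium?  (abluminal BM loop around the pericyte soma)
    inward = _first_hit(labels, coords, -dirs, dist)
    discard = np.isin(inward, pericyte_codes)

    # outward probe: first class beyond the basement membrane
    h, w = labels.shape
    t_out = np.full(len(coords), float(np.hypot(h, w)))
    outward = _first_hit(labels, coords, dirs, t_out)
    covered = np.isin(outward, pericyte_codes)

    cls = np.where(covered, CLASS_COVERED, CLASS_UNCOVERED).astype(np.int8)
    if config.discard_abluminal_loop:
        cls[discard] = CLASS_DISCARD
    cls[is_c1] = CLASS_CONTACT  # contact is the most specific observation

    out[tuple(np.argwhere(skeleton).T)] = cls
    return out


def _class_lengths_px(classes: np.ndarray, metric: str) -> dict[int, float]:
    """Length per class over the retained skeleton, in pixel units.

    Chain mode sums half-edge contributions between 8-adjacent retained
    skeleton pixels, so the per-class lengths always add up to the total
    retained skeleton length (partition property), whatever the classes
    of the two endpoints.
    """
    retained = classes > 0
    lengths = {CLASS_CONTACT: 0.0, CLASS_COVERED: 0.0, CLASS_UNCOVERED: 0.0}
    if metric == "pixel_count":
        for c in lengths:
            lengths[c] = float((classes == c).sum())
        return lengths
    contrib = np.zeros(classes.shape, dtype=float)
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        # neighbour at p + (dr, dc), without wraparound
        b = np.roll(np.roll(retained, -dr, axis=0), -dc, axis=1)
        if dr:
            b[-dr:, :] = False
        if dc > 0:
            b[:, -dc:] = False
        elif dc < 0:
            b[:, :-dc] = False
        pair = retained & b  # edge from p to p + d
        wt = 0.5 * np.hypot(dr, dc)
        contrib[pair] += wt
        partner = np.roll(np.roll(pair, dr, axis=0), dc, axis=1)
        contrib[partner] += wt
    for c in lengths:
        lengths[c] = float(contrib[classes == c].sum())
    return lengths


def contact_profile(
    section: SegmentedSection, config: PipelineConfig | None = None
) -> ContactProfile:
    """Run the full per-section coverage/contact measurement."""
    config = config or PipelineConfig()
    cmask = contact_mask(section, config)
    skel = skeletonize_interface(section, config)
    classes = classify_skeleton(section, skel, cmask, config)
    px_um = section.pixel_size_nm / 1000.0
    lengths = _class_lengths_px(classes, config.length_metric)
    return ContactProfile(
        section_index=section.section_index,
        L1_um=lengths[CLASS_CONTACT] * px_um,
        L2_um=lengths[CLASS_COVERED] * px_um,
        L3_um=lengths[CLASS_UNCOVERED] * px_um,
    )


def stack_contact_profile(
    stack: VesselStack, config: PipelineConfig | None = None
) -> dict:
    """Length-weighted pooling over non-excluded sections.

    Vessel-level contact % is sum(L1) / sum(L1 + L2), not the mean of
    per-section ratios, so sections with tiny covered arcs cannot
    destabilize the estimate.
    """
    config = config or PipelineConfig()
    profiles = [contact_profile(s, config) for s in stack.usable_sections()]
    L1 = sum(p.L1_um for p in profiles)
    L2 = sum(p.L2_um for p in profiles)
    L3 = sum(p.L3_um for p in profiles)
    total = L1 + L2 + L3
    return {
        "vessel_id": stack.vessel_id,
        "L1_um": L1,
        "L2_um": L2,
        "L3_um": L3,
        "coverage_pct": 100.0 * (L1 + L2) / total if total else 0.0,
        "contact_pct": 100.0 * L1 / (L1 + L2) if (L1 + L2) else None,
        "profiles": profiles,
    }
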