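"""Synthetic segmented capillaries and fluorescence networks with ground truth.

The generator emulates the statistical structure of segmented capillary
cross-section stacks: a roughly circular vessel of capillary calibre
(4-12 µm), an endothelial tube around the lumen, a basement membrane
sheath, a pericyte crescent spanning a target fraction of the
circumference (~50% by default), a sub-arc of direct pericyte-endothelial
contact where the basement membrane is locally absent, and finger-like
pericyte pegs protruding into endothelial invaginations, optionally
separated from the socket wall by a thin basement-membrane cleft.

All sections are star-shaped about the vessel centre: boundary
irregularity is a low-frequency radial perturbation, which keeps the
radial-probe classification of :mod:`pericytometry.contact` exact.

Ground truth is computed analytically from the generating geometry
(dense polar tables) before rasterization, so every measurement stage
can be validated against values the label maps never saw.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .label_io import ClassCode, SegmentedSection, VesselStack

__all__ = [
    "SyntheticVesselSpec",
    "GroundTruth",
    "generate_vessel",
    "generate_cohort",
    "generate_if_image",
]

_N_THETA = 4096
_TAPER_DEG = 3.0  # cosine taper of the pericyte thickness at the arc edges


@dataclass
class SyntheticVesselSpec:
    """Geometry and sampling parameters for one synthetic vessel.

    Defaults describe a typical wild-type capillary: 8 µm outer diameter,
    500 nm endothelial wall, 150 nm basement membrane with a 100 nm film
    separating pericyte from endothelium under coverage, ~50% pericyte
    coverage of which 2.3% is direct contact, and three 400 nm-deep pegs
    per section lined by a 60 nm basement-membrane cleft.
    """

    diameter_um: float = 8.0
    ec_thickness_nm: float = 500.0
    bm_thickness_nm: float = 150.0
    bm_film_nm: float = 100.0
    pericyte_thickness_nm: float = 400.0
    pericyte_arc_fraction: float = 0.5
    contact_arc_fraction: float = 0.023
    peg_count_per_section: int = 3
    peg_depth_nm: float = 400.0
    peg_width_nm: float = 300.0
    peg_cleft_nm: float = 60.0
    n_sections: int = 25
    grid_px: int = 1024
    pixel_size_nm: float = 20.0
    jitter_amplitude_nm: float = 150.0
    jitter_harmonics: tuple[int, ...] = (2, 3, 5)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.pericyte_arc_fraction <= 1:
            raise ValueError("pericyte_arc_fraction must be in [0, 1]")
        if not 0 <= self.contact_arc_fraction <= 1:
            raise ValueError("contact_arc_fraction must be in [0, 1]")
        for name in (
            "diameter_um",
            "ec_thickness_nm",
            "bm_thickness_nm",
            "pericyte_thickness_nm",
            "peg_depth_nm",
            "peg_width_nm",
            "pixel_size_nm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.bm_film_nm < 0 or self.peg_cleft_nm < 0:
            raise ValueError("film/cleft thickness must be non-negative")
        if self.peg_count_per_section < 0:
            raise ValueError("peg_count_per_section must be non-negative")
        if self.n_sections < 1:
            raise ValueError("n_sections must be positive")
        if self.peg_count_per_section and self.peg_depth_nm >= self.ec_thickness_nm:
            raise ValueError(
                "peg_depth_nm must be smaller than ec_thickness_nm "
                "(a peg cannot pierce the endothelial wall)"
            )


@dataclass
class GroundTruth:
    """Analytic values computed from the geometry before rasterization."""

    true_diameter_um: float
    true_pericyte_volume_pct: float
    true_bm_volume_pct: float
    true_coverage_pct: float
    true_contact_pct: float | None
    #: programmed maximum protrusion depth per peg, nm
    peg_depths_nm: np.ndarray
    #: analytic cross-sectional area per (section, peg), nm^2
    peg_areas_nm2: np.ndarray
    #: number of peg components per section
    peg_counts: np.ndarray


def _angdiff(theta: np.ndarray | float, center: float) -> np.ndarray:
    """Signed angular difference wrapped to [-pi, pi)."""
    return (np.asarray(theta) - center + np.pi) % (2 * np.pi) - np.pi


def _polyline_length(r: np.ndarray, theta: np.ndarray) -> float:
    x = r * np.cos(theta)
    y = r * np.sin(theta)
    return float(np.hypot(np.diff(x, append=x[:1]), np.diff(y, append=y[:1])).sum())


def _arc_length(r: np.ndarray, theta: np.ndarray, keep: np.ndarray) -> float:
    """Length of the closed curve r(theta) restricted to ``keep`` bins."""
    x = r * np.cos(theta)
    y = r * np.sin(theta)
    seg = np.hypot(np.diff(x, append=x[:1]), np.diff(y, append=y[:1]))
    return float(seg[keep].sum())


def _place_pegs(
    rng: np.random.Generator,
    n_pegs: int,
    cov_center: float,
    cov_half: float,
    contact_center: float,
    contact_half: float,
    slot_half: float,
) -> np.ndarray:
    """Peg centre angles inside the covered arc, avoiding the contact arc.

    Raises when the requested pegs cannot fit.
    """
    if n_pegs == 0:
        return np.array([])
    margin = slot_half * 1.3 + np.deg2rad(_TAPER_DEG)
    lo, hi = cov_center - cov_half + margin, cov_center + cov_half - margin
    intervals = [(lo, hi)]
    if contact_half > 0:
        c_lo = contact_center - contact_half - margin
        c_hi = contact_center + contact_half + margin
        new = []
        for a, b in intervals:
            # contact arc is inside the covered arc by construction
            if c_lo > a:
                new.append((a, min(b, c_lo)))
            if c_hi < b:
                new.append((max(a, c_hi), b))
        intervals = [(a, b) for a, b in new if b > a]
    total = sum(b - a for a, b in intervals)
    if total < n_pegs * 2.4 * slot_half:
        raise ValueError(
            f"cannot fit {n_pegs} pegs of half-width {slot_half:.3f} rad "
            "into the covered arc"
        )
    # evenly spaced along the concatenated free span, with jitter
    spacing = total / n_pegs
    positions = (np.arange(n_pegs) + 0.5) * spacing
    positions += rng.uniform(-0.25, 0.25, n_pegs) * (spacing - 2.2 * slot_half)
    angles = np.empty(n_pegs)
    for i, p in enumerate(positions):
        acc = 0.0
        for a, b in intervals:
            if p <= acc + (b - a):
                angles[i] = a + (p - acc)
                break
            acc += b - a
        else:  # pragma: no cover - numeric edge
            angles[i] = intervals[-1][1] - slot_half
    return np.sort(angles % (2 * np.pi))


def generate_vessel(spec: SyntheticVesselSpec) -> tuple[VesselStack, GroundTruth]:
    """Rasterize one vessel stack and its analytic ground truth."""
    rng = np.random.default_rng(spec.seed)
    px = spec.pixel_size_nm
    n = spec.grid_px
    theta = np.linspace(0, 2 * np.pi, _N_THETA, endpoint=False)

    R_out0 = spec.diameter_um * 1000.0 / 2.0  # uncovered outer BM radius, nm
    R_eo0 = R_out0 - spec.bm_thickness_nm  # EC outer radius, nm
    film = spec.bm_film_nm
    pc_th = spec.pericyte_thickness_nm
    cleft = spec.peg_cleft_nm

    max_r = R_out0 + film + pc_th + spec.jitter_amplitude_nm + 4 * px
    if max_r > (n / 2 - 4) * px:
        raise ValueError(
            f"vessel of diameter {spec.diameter_um} µm plus margins does not "
            f"fit a {n}x{n} grid at {px} nm/px"
        )
    if R_eo0 - spec.ec_thickness_nm < 4 * px:
        raise ValueError("lumen collapses: diameter too small for wall layers")

    # radial jitter: few low-frequency harmonics, bounded amplitude
    n_h = len(spec.jitter_harmonics)
    amps = (
        rng.uniform(0.4, 1.0, n_h)
        * spec.jitter_amplitude_nm
        / max(n_h, 1)
    )
    phases = rng.uniform(0, 2 * np.pi, n_h)
    phase_drift = rng.normal(0, 0.02, n_h)  # slow per-section wobble

    cov_frac = spec.pericyte_arc_fraction
    cov_center = float(rng.uniform(0, 2 * np.pi))
    cov_half = np.pi * cov_frac
    contact_half = cov_half * spec.contact_arc_fraction
    if cov_frac > 0 and spec.contact_arc_fraction < 1:
        max_off = max(cov_half - contact_half - np.deg2rad(_TAPER_DEG), 0.0)
        contact_center = cov_center + float(rng.uniform(-0.6, 0.6)) * max_off
    else:
        contact_center = cov_center

    n_pegs = spec.peg_count_per_section if cov_frac > 0 else 0
    slot_half = (spec.peg_width_nm / 2 + cleft) / R_eo0
    peg_angles = _place_pegs(
        rng, n_pegs, cov_center, cov_half, contact_center, contact_half, slot_half
    )
    peg_wobble = rng.normal(0, np.deg2rad(0.1), (spec.n_sections, max(n_pegs, 1)))

    taper = np.deg2rad(_TAPER_DEG)
    center_rc = (
        n / 2 - 0.5 + rng.uniform(-0.02, 0.02) * n,
        n / 2 - 0.5 + rng.uniform(-0.02, 0.02) * n,
    )

    rows, cols = np.mgrid[0:n, 0:n]
    dy = (rows - center_rc[0]) * px
    dx = (cols - center_rc[1]) * px
    rho = np.hypot(dy, dx)
    ang = np.arctan2(dy, dx) % (2 * np.pi)
    tbl_idx = np.minimum(
        (ang / (2 * np.pi) * _N_THETA).astype(np.int32), _N_THETA - 1
    )

    d_cov = np.abs(_angdiff(theta, cov_center))
    covered = (d_cov <= cov_half) & (cov_frac > 0)
    contact = (
        (np.abs(_angdiff(theta, contact_center)) <= contact_half)
        & covered
        & (spec.contact_arc_fraction > 0)
    )
    # pericyte thickness tapers to zero at the arc edges
    edge_dist = cov_half - d_cov
    w_taper = np.clip(edge_dist / taper, 0, 1)
    pc_profile = np.where(covered, pc_th * (0.5 - 0.5 * np.cos(np.pi * w_taper)) * 2, 0.0)
    pc_profile = np.where(covered, np.minimum(pc_profile, pc_th), 0.0)
    film_profile = np.where(covered & ~contact, film, 0.0)

    sections: list[SegmentedSection] = []
    areas = np.zeros((spec.n_sections, 6))  # per-class analytic, nm^2
    coverage_L = np.zeros(3)  # L1, L2, L3 analytic, nm (summed)
    peg_areas = np.zeros((spec.n_sections, n_pegs))
    diam_acc = 0.0

    for s in range(spec.n_sections):
        jit = np.zeros(_N_THETA)
        for a, h, p0, dp in zip(amps, spec.jitter_harmonics, phases, phase_drift):
            jit += a * np.cos(h * theta + p0 + s * dp)

        R_eo = R_eo0 + jit
        R_lum = R_eo - spec.ec_thickness_nm
        R_peri_lo = R_eo + film_profile
        R_peri_hi = R_peri_lo + pc_profile
        R_bm = np.where(
            covered, R_peri_hi + spec.bm_thickness_nm, R_eo + spec.bm_thickness_nm
        )

        # --- rasterize ---------------------------------------------------
        Reo_g = R_eo[tbl_idx]
        lab = np.zeros((n, n), dtype=np.uint8)
        lab[rho <= R_bm[tbl_idx]] = int(ClassCode.BASEMENT_MEMBRANE)
        peri_band = (
            (rho > R_peri_lo[tbl_idx])
            & (rho <= R_peri_hi[tbl_idx])
            & (pc_profile[tbl_idx] > 0)
        )
        lab[peri_band] = int(ClassCode.PERICYTE)
        lab[rho <= Reo_g] = int(ClassCode.ENDOTHELIAL)
        lab[rho <= R_lum[tbl_idx]] = int(ClassCode.LUMEN)

        sec_angles = peg_angles + (peg_wobble[s, : n_pegs] if n_pegs else 0)
        w_ang = spec.peg_width_nm / R_eo0  # full angular width of the peg
        c_ang = cleft / R_eo0
        for k, phi in enumerate(sec_angles):
            off = np.abs(_angdiff(ang, float(phi)))
            in_slot = off <= w_ang / 2 + c_ang
            in_peg = off <= w_ang / 2
            # carve socket (EC -> BM cleft), full slot width
            socket = (
                in_slot
                & (rho > Reo_g - spec.peg_depth_nm - cleft)
                & (rho <= Reo_g)
            )
            lab[socket] = int(ClassCode.BASEMENT_MEMBRANE)
            # cleft columns also run up through the film so the pericyte
            # bridge never touches the endothelium laterally
            if cleft > 0:
                upper = (
                    in_slot
                    & ~in_peg
                    & (rho > Reo_g)
                    & (rho <= Reo_g + film_profile[tbl_idx])
                )
                lab[upper] = int(ClassCode.BASEMENT_MEMBRANE)
            # pericyte bridge through the film, peg width only
            bridge = (
                in_peg
                & (rho > Reo_g)
                & (rho <= Reo_g + film_profile[tbl_idx])
            )
            lab[bridge] = int(ClassCode.PERICYTE)
            peg_px = (
                in_peg & (rho > Reo_g - spec.peg_depth_nm) & (rho <= Reo_g)
            )
            lab[peg_px] = int(ClassCode.PEG)

            Rk = R_eo0 + float(
                sum(
                    a * np.cos(h * phi + p0 + s * dp)
                    for a, h, p0, dp in zip(
                        amps, spec.jitter_harmonics, phases, phase_drift
                    )
                )
            )
            peg_areas[s, k] = (
                w_ang * (Rk**2 - (Rk - spec.peg_depth_nm) ** 2) / 2.0
            )

        sections.append(
            SegmentedSection(
                labels=lab, pixel_size_nm=px, section_index=s, excluded=False
            )
        )

        # --- analytic ground truth ---------------------------------------
        dtheta = 2 * np.pi / _N_THETA
        a_lum = float((R_lum**2).sum()) / 2 * dtheta
        a_ec = float((R_eo**2 - R_lum**2).sum()) / 2 * dtheta
        a_peri = float((R_peri_hi**2 - R_peri_lo**2).sum()) / 2 * dtheta
        a_bm = float((R_bm**2 - R_eo**2).sum()) / 2 * dtheta - a_peri
        a_peg = 0.0
        for k, phi in enumerate(sec_angles):
            Rk = R_eo0  # first-order: corrections use nominal radius
            a_pk = peg_areas[s, k]
            socket_full = (w_ang + 2 * c_ang) * (
                (Rk) ** 2 - (Rk - spec.peg_depth_nm - cleft) ** 2
            ) / 2.0
            bridge_k = w_ang * ((Rk + film) ** 2 - Rk**2) / 2.0 if film else 0.0
            upper_cleft = (
                (2 * c_ang) * ((Rk + film) ** 2 - Rk**2) / 2.0
                if (cleft > 0 and film)
                else 0.0
            )
            a_ec -= socket_full
            a_bm += (socket_full - a_pk) - bridge_k + upper_cleft
            a_peri += bridge_k - upper_cleft
            a_peg += a_pk
        areas[s] = (
            0.0,
            a_bm,
            a_ec,
            a_peri,
            a_peg,
            a_lum,
        )

        diam_acc += _polyline_length(R_bm, theta) / np.pi

        # analytic class-line lengths (centre lines of the interfaces)
        L1 = _arc_length(R_eo, theta, contact)
        L2 = _arc_length(R_eo + film / 2.0, theta, covered & ~contact)
        L3 = _arc_length(
            R_eo + spec.bm_thickness_nm / 2.0, theta, ~covered
        )
        coverage_L += (L1, L2, L3)

    L1, L2, L3 = coverage_L
    total_L = L1 + L2 + L3
    tissue = areas[:, 1:5].sum()
    gt = GroundTruth(
        true_diameter_um=diam_acc / spec.n_sections / 1000.0,
        true_pericyte_volume_pct=100.0 * areas[:, 3:5].sum() / tissue,
        true_bm_volume_pct=100.0 * areas[:, 1].sum() / tissue,
        true_coverage_pct=100.0 * (L1 + L2) / total_L if total_L else 0.0,
        true_contact_pct=100.0 * L1 / (L1 + L2) if (L1 + L2) else None,
        peg_depths_nm=np.full(n_pegs, spec.peg_depth_nm),
        peg_areas_nm2=peg_areas,
        peg_counts=np.full(spec.n_sections, n_pegs),
    )
    stack = VesselStack(
        sections=sections,
        z_spacing_nm=80.0,
        vessel_id=f"synthetic-{spec.seed}",
        group="",
    )
    return stack, gt


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: Study-sized cohort: wild type, diabetic, Notch3 knockout, conditional KO.
DEFAULT_COHORT = {"WT": 19, "Diabetic": 18, "N3KO": 16, "CondKO": 23}

_BETWEEN_VESSEL_SD = {
    "diameter_um": 1.5,
    "pericyte_arc_fraction": 0.08,
    "contact_arc_fraction": 0.5,  # relative to the mean
    "peg_depth_nm": 60.0,
    "peg_width_nm": 40.0,
}


def _draw_vessel_spec(
    base: SyntheticVesselSpec, rng: np.random.Generator, seed: int
) -> SyntheticVesselSpec:
    d = float(
        np.clip(rng.normal(base.diameter_um, _BETWEEN_VESSEL_SD["diameter_um"]), 4, 12)
    )
    cov = float(
        np.clip(
            rng.normal(
                base.pericyte_arc_fraction,
                _BETWEEN_VESSEL_SD["pericyte_arc_fraction"],
            ),
            0.05,
            0.95,
        )
    )
    con = float(
        np.clip(
            rng.normal(
                base.contact_arc_fraction,
                _BETWEEN_VESSEL_SD["contact_arc_fraction"]
                * max(base.contact_arc_fraction, 1e-9),
            ),
            0.0,
            0.9,
        )
    )
    depth = float(
        np.clip(
            rng.normal(base.peg_depth_nm, _BETWEEN_VESSEL_SD["peg_depth_nm"]),
            100.0,
            base.ec_thickness_nm - 100.0,
        )
    )
    width = float(
        max(rng.normal(base.peg_width_nm, _BETWEEN_VESSEL_SD["peg_width_nm"]), 150.0)
    )
    count = int(rng.poisson(base.peg_count_per_section)) if base.peg_count_per_section else 0
    return replace(
        base,
        diameter_um=d,
        pericyte_arc_fraction=cov,
        contact_arc_fraction=con,
        peg_depth_nm=depth,
        peg_width_nm=width,
        peg_count_per_section=count,
        seed=seed,
    )


def generate_cohort(
    n_per_group: Mapping[str, int] | None = None,
    base: SyntheticVesselSpec | None = None,
    effects: Mapping[str, Mapping[str, float]] | None = None,
    seed: int = 0,
) -> list[tuple[VesselStack, GroundTruth]]:
    """Generate a multi-group cohort of vessels.

    ``effects`` maps group name to additive offsets on spec fields (for
    example deeper pegs in a knockout group); per-vessel parameters are
    then drawn around the shifted base.  Reproducible given ``seed``.
    """
    n_per_group = dict(n_per_group or DEFAULT_COHORT)
    if any(v < 1 for v in n_per_group.values()):
        raise ValueError("group counts must be >= 1")
    base = base or SyntheticVesselSpec()
    effects = effects or {}
    ss = np.random.SeedSequence(seed)
    out: list[tuple[VesselStack, GroundTruth]] = []
    for group, count in n_per_group.items():
        grp_base = base
        for fname, off in effects.get(group, {}).items():
            grp_base = replace(grp_base, **{fname: getattr(grp_base, fname) + off})
        for i in range(count):
            child = ss.spawn(1)[0]
            rng = np.random.default_rng(child)
            vseed = int(child.generate_state(1)[0] % (2**31))
            vspec = _draw_vessel_spec(grp_base, rng, vseed)
            while True:
                try:
                    stack, gt = generate_vessel(vspec)
                    break
                except ValueError:
                    # drawn peg count does not fit the drawn covered arc;
                    # shed pegs until the geometry is feasible
                    if vspec.peg_count_per_section == 0:
                        raise
                    vspec = replace(
                        vspec,
                        peg_count_per_section=vspec.peg_count_per_section - 1,
                    )
            stack.vessel_id = f"{group}-{i:03d}"
            stack.group = group
            out.append((stack, gt))
    return out


# ---------------------------------------------------------------------------
# Fluorescence (alpha-SMA) image generation
# ---------------------------------------------------------------------------

def _dist_to_polyline(
    yy: np.ndarray, xx: np.ndarray, pts: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel distance to a polyline and arc-length of the nearest point."""
    best = np.full(yy.shape, np.inf)
    best_t = np.zeros(yy.shape)
    acc = 0.0
    for a, b in zip(pts[:-1], pts[1:]):
        ab = b - a
        L = float(np.hypot(*ab))
        if L == 0:
            continue
        t = ((yy - a[0]) * ab[0] + (xx - a[1]) * ab[1]) / (L * L)
        t = np.clip(t, 0.0, 1.0)
        d = np.hypot(yy - (a[0] + t * ab[0]), xx - (a[1] + t * ab[1]))
        closer = d < best
        best[closer] = d[closer]
        best_t[closer] = acc + t[closer] * L
        acc += L
    return best, best_t


def generate_if_image(
    width_px: int,
    height_px: int,
    pixel_size_um: float,
    branches: Sequence[tuple[np.ndarray, float, float]],
    background_level: float = 100.0,
    gradient_amplitude: float = 0.0,
    noise_sigma: float = 5.0,
    vessel_intensity: float = 60.0,
    sma_intensity: float = 400.0,
    seed: int = 0,
) -> tuple[np.ndarray, list[dict]]:
    """Render a fluorescence vessel network with per-branch ground truth.

    Each branch is ``(polyline_um, width_um, sma_coverage_fraction)`` with
    the polyline as an (N, 2) array of (y, x) points in µm.  Vessels are
    rendered at low intensity over the background; the mural-cell marker
    is rendered bright over the stated leading fraction of each tube's
    centreline.  Branch widths below 2 px are rejected.
    """
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:height_px, 0:width_px].astype(float)
    yy *= pixel_size_um
    xx *= pixel_size_um
    img = np.full((height_px, width_px), background_level, dtype=float)
    if gradient_amplitude:
        gx = rng.uniform(-1, 1, 2)
        img += gradient_amplitude * (
            gx[0] * yy / max(yy.max(), 1e-9) + gx[1] * xx / max(xx.max(), 1e-9)
        )
    vessel_any = np.zeros(img.shape, bool)
    sma_any = np.zeros(img.shape, bool)
    truth = []
    for polyline, width_um, frac in branches:
        if width_um / pixel_size_um < 2:
            raise ValueError("branch width must be at least 2 px")
        pts = np.asarray(polyline, dtype=float)
        d, t = _dist_to_polyline(yy, xx, pts)
        tube = d <= width_um / 2.0
        total_len = float(
            np.hypot(*np.diff(pts, axis=0).T).sum()
        )
        sma = tube if frac >= 1.0 else tube & (t < frac * total_len)
        vessel_any |= tube
        sma_any |= sma
        tube_area = int(tube.sum())
        truth.append(
            {
                "width_um": width_um,
                "coverage_fraction": frac,
                "tube_mask": tube,
                "sma_mask": sma,
                "pixel_coverage_fraction": (
                    float(sma.sum()) / tube_area if tube_area else 0.0
                ),
            }
        )
    img[vessel_any] += vessel_intensity
    img[sma_any] += sma_intensity - vessel_intensity
    if noise_sigma:
        img += rng.normal(0, noise_sigma, img.shape)
    return np.clip(img, 0, None).astype(np.float32), truth
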