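# Methods

This note documents the measurement models, the numerical choices behind
them, what the synthetic generator does and does not emulate, and the
known limitations.

## Data model

A vessel is an ordered stack of 2-D integer label maps, one per ultrathin
section (default z-spacing 80 nm), with six classes: background, basement
membrane (BM), endothelial cell (EC), pericyte, pericyte peg (only the
part protruding into the EC), and lumen. Pixels are unit squares of edge
`pixel_size_nm`; this calibration is mandatory metadata with no default,
because magnification alone does not determine it. Erythrocytes or other
content inside the lumen are labelled lumen: the lumen is excluded from
every volume denominator regardless of content. Sections flagged as
excluded (image-quality artifacts) are retained on disk but skipped by all
aggregation. The peg class is merged into the pericyte for coverage and
volume purposes (`merge_peg_into_pericyte`, default on).

## Diameter and volume fractions

Diameter uses the circle formula `D = C/π`. `C` is operationalized as the
outer boundary length of the filled vessel region (union of all
non-background classes, holes filled, largest component): the BM is the
outermost tissue layer, so this coincides with the BM outer perimeter
while remaining well defined where direct contacts interrupt the BM ring.

The perimeter estimator is a Moore boundary chain with
Vossepoel–Smeulders corner-corrected weights (0.980 per axis step, 1.406
per diagonal step, −0.091 per direction change). Plain (1, √2) chain
length overestimates digitized circles by ≈5.3% asymptotically; the
corrected weights measure 4–12 µm circles at 10–20 nm/px to well under 1%,
with error decreasing as pixels shrink (validated in the tests). The plain
chain and raw pixel count remain available as config modes
(`perimeter_metric`) for fidelity comparisons with tools that use them.
Degenerate regions whose chain has fewer than three steps fall back to the
unit-square exposed-edge count (a lone pixel has perimeter 4 edges).

Per-vessel diameter is the unweighted mean of per-section diameters over
non-excluded sections (whether the source studies averaged sections or
used one representative section is generally unstated; the mean is the
stabler choice). Volume fractions pool voxels over sections first, then
divide, matching their voxel-count definition; the three reported
fractions sum to 100 exactly.

## Coverage and direct contact

The contact mask is the pericyte(+peg) mask intersected with a
`contact_dilation_px` (default 1) dilation of the EC mask — pericyte
pixels within one step of the endothelium, i.e. no BM in between. The
skeleton of (BM ∪ contact mask) is computed with a topology-preserving
thinning, then every skeleton pixel receives exactly one label:

- **Class 1** — skeleton pixels within the contact mask dilated by the
  same `contact_dilation_px`: the medial axis can sit one pixel off the
  actual contact line, so contact attribution gets a one-pixel margin and
  takes precedence over Classes 2/3 (the most specific observation wins).
- **Class 2 / Class 3** — remaining pixels are classified by a radial
  probe from the vessel centroid through the pixel, sampled every 0.5 px
  with BM transparent: the first class met probing outward is pericyte/peg
  (⇒ covered, Class 2) or background (⇒ uncovered, Class 3).
- **Discard** — pixels whose inward probe meets pericyte before
  endothelium lie on the abluminal BM loop wrapping the pericyte soma;
  counting that loop would double-count covered arcs, so it is dropped.
  Whether that loop belongs in the coverage denominator is a genuine
  ambiguity of skeleton-based coverage definitions; the discard rule is
  one defensible reading and is exposed as a config switch
  (`discard_abluminal_loop`) for sensitivity analysis.

The radial probe is exact for sections that are star-shaped about the
centroid; the generator guarantees this and real capillary cross-sections
approximately satisfy it.

Class lengths are half-edge chain sums over 8-adjacent retained skeleton
pixels (each edge contributes half its Euclidean length to each endpoint),
so L1+L2+L3 equals the total retained skeleton length exactly whatever the
per-pixel labels. A raw pixel-count mode (`length_metric="pixel_count"`)
is retained for comparison with implementations that sum skeleton pixels;
the ratio measurements are insensitive to the common metric. Vessel-level
contact % pools lengths across sections (ΣL1 / Σ(L1+L2)) rather than
averaging per-section ratios, which would be unstable for sections with
tiny covered arcs.

Known bias: with a 1-px dilated contact attribution, a few pixels at each
contact-arc end are claimed from Class 2, inflating very small contact
fractions by roughly one percentage point at 40 nm/px. This is inherent to
the one-pixel attribution margin and is visible in the synthetic recovery
tests.

## Peg depth, area, frequency

The depth mask is EC ∪ peg ∪ lumen, morphologically closed with a disk of
physical radius `closing_radius_nm` (default 134 nm, rasterized as
{(r,c): r²+c² ≤ R²}, R = round(134/pixel_size)); the closing seals thin BM
clefts between a peg and its socket wall — a real feature of these
junctions — so depth is measured from the abluminal EC surface rather than
from the cleft. Clefts narrower than the element are sealed; gaps wider
than twice its radius are preserved (asserted in the tests). A closing
radius under one pixel is clamped to 1 px with a warning. The distance
transform is exact Euclidean (it matches a brute-force nearest-complement
search bit-for-bit on random grids); values convert to nm, are zero
outside the mask, and increase toward the lumen.

Per peg component (8-connected, ≥ `min_component_px` = 4 pixels):
max depth = maximum distance value over its pixels; area = pixel count ×
pixel area; the per-section component count is the frequency statistic.
Components touching no pericyte pixel are flagged (`orphan`) but never
silently dropped. Pegs are measured per 2-D section; no attempt is made to
link the same peg across sections.

## α-SMA branch coverage

The vasculature is detectable at low intensity in the α-SMA channel, so
the vessel mask comes from a white top-hat (disk radius
`tophat_radius_um`, default 15 µm — it must exceed the widest vessel
radius of interest) followed by a fixed absolute threshold
(`low_threshold`, default 20; no principled universal default exists, so
it is explicit, logged config). The thresholded mask is smoothed by a
1-px closing+opening and small objects are removed.

The α-SMA mask is an Otsu threshold of the top-hat image restricted to the
vessel mask (background pixels would dominate the histogram). Otsu's
criterion is degenerate on unimodal histograms; degeneracy is detected by
the split contrast (upper-class mean < 2× lower-class mean) and resolved
by absolute level: a single low mode means no mural signal (empty mask,
warning), a single mode above `min_sma_intensity` means fully covered
vasculature (whole vessel mask returned). This keeps both limits correct:
zero-SMA images yield 0% and saturated ones ~100%.

Branches: the vessel skeleton is spur-pruned (terminal spurs up to
`spur_prune_um`, default 10 µm, are eaten back — ragged mask edges
otherwise spawn spurious branches), branch points (more than two
8-neighbours) are removed, and the remaining segments become branches if
at least `min_branch_um` long; every mask pixel joins the branch of its
nearest surviving skeleton pixel, so the assignment partitions the mask
exactly and short segments' territory flows to their neighbours. Mean
branch diameter is 2× the mean distance-transform value along the branch
skeleton (median available via `diameter_stat`); on straight synthetic
tubes ≥4 px wide this recovers programmed widths to a few percent, with a
worst-case half-pixel bias from rasterization parity. Coverage per branch
is the SMA area on the branch over the branch area, ×100.

## Group statistics

Per-vessel values are the statistical units. Each metric is screened with
four normality tests (D'Agostino–Pearson, needs n ≥ 8; Anderson–Darling;
Shapiro–Wilk; the Lilliefors variant of Kolmogorov–Smirnov, needs n ≥ 4)
— reported for transparency, never used to switch tests. The omnibus test
is Kruskal–Wallis with tie correction; the all-ties degenerate case
returns H = 0, p = 1. Pairwise follow-up is Dunn's rank z-test with the
pooled-rank tie correction and Holm adjustment — the standard companion to
Kruskal–Wallis, made explicit because software defaults differ. Groups
with fewer than 3 values are excluded with a warning. No adjustment is
applied across metrics. The chi-square approximation to H agrees with the
exact permutation distribution in the decision-relevant tail for total
n ≤ 7 (tested); for mid-range p at such tiny n the permutation
distribution is inherently granular and deviations up to ~0.15 occur.

## Synthetic generator

Each section is built in polar coordinates about the vessel centre from
dense angular tables: lumen radius, EC outer radius (diameter minus BM
sheath), an optional BM film (default 100 nm) separating pericyte from EC
under coverage, a pericyte band (default 400 nm thick) spanning
`pericyte_arc_fraction` of the circumference (default 0.5, the typical
capillary coverage), a contact sub-arc with the film removed
(`contact_arc_fraction` of the covered arc, default 0.023 — matching the
~2.3% wild-type direct-contact fraction these junctions show), and an
outer BM layer enclosing everything. Boundary irregularity is a
low-frequency radial harmonic perturbation (bounded amplitude, default
150 nm), which keeps sections star-shaped — required for the radial-probe
classification and a fair approximation of capillary cross-sections.
Pegs are polar wedges (default 300 nm wide, 400 nm deep, 3 per section)
carved into the EC from the pericyte, connected through the film by a
pericyte bridge and lined by an optional BM cleft (default 60 nm — thin
enough that the 134 nm closing seals it, wide enough that pegs do not
register as direct-contact lines, consistent with the observation that
not all peg-and-sockets are direct contacts).

Ground truth is computed analytically from the same polar tables before
rasterization: diameter from the outer-BM curve length, volume fractions
from area integrals with per-peg corrections, coverage/contact from the
arc lengths of the interface centrelines, peg areas from the wedge
formula. Rasterized measurements agree with these to within discretization
error (≲2 pixel edges for lengths, ≲1 pixel diagonal for depths).

Cohorts draw per-vessel parameters around a base specification (diameter
N(8, 1.5) µm clipped to the 4–12 µm capillary range; coverage N(0.5,
0.08); contact with 50% relative spread; peg depth N(µ, 60 nm); Poisson
peg counts), with additive per-group offsets for programmed effects. A
drawn peg count that cannot fit the drawn covered arc is reduced until
feasible. Everything is reproducible from a single seed.

What the generator does **not** emulate: TEM texture (inputs are label
maps by construction), non-star-shaped or collapsed vessels, 3-D peg
continuity across sections, segmentation error of a human tracer, and
within-animal correlation between vessels. Passing recovery tests
therefore show correctness of the measurement algorithms on calibrated
geometry, not robustness to segmentation noise.

## Problem sizes and defaults

The generator's geometric defaults (20 nm/px, 1024² grid, layer
thicknesses: EC 500 nm, BM 150 nm, film 100 nm) describe a typical
capillary section at full working resolution. The cohort demonstration
and the acceptance script run at a reduced scale — 512² or 384² grids at
40 nm/px with 1–3 sections per vessel — chosen so a full 76-vessel,
four-group study completes in minutes while every layer stays several
pixels thick; the cohort sizes themselves (19 WT, 18 diabetic, 16 KO,
23 conditional KO) match a realistic four-group design. The demonstration cohort
uses a 1000 nm EC wall so its programmed deep-peg effect (+250 nm on a
400 nm base) has headroom — a peg cannot protrude deeper than the wall
that hosts it.

## Limitations

- Vessels sectioned obliquely are not corrected (no ellipse fitting);
  diameters of slanted cuts are overestimated.
- Coverage classification assumes approximate star-shape; strongly
  concave sections would need a different outer-perimeter rule.
- Contact % carries a ~+1 pp attribution bias for very small contact
  fractions (see above).
- Statistics treat vessels as independent; animal-level clustering is out
  of scope.
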