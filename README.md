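# pericytometry

Ultrastructural morphometry of pericyte–endothelial cell interactions in
capillaries, from six-class segmented cross-section stacks (serial-section
TEM style) and from α-SMA immunofluorescence images.

Pericytes are mural cells embedded in the capillary basement membrane (BM)
that contact the endothelium directly through openings in the BM — flat
contacts and finger-like **peg-and-socket** junctions, where a pericyte peg
protrudes into an endothelial invagination. These contact sites are
candidate loci of pericyte–endothelial signalling (e.g., Notch3), and their
geometry changes in disease models such as diabetic retinopathy and Notch3
knockouts. This package implements the measurements needed to quantify
those changes, given label maps with six classes: background, basement
membrane, endothelial cell, pericyte, pericyte peg, lumen.

## Measurements

Given a stack of calibrated label maps (pixel size in nm, ~80 nm section
spacing), the pipeline computes per vessel:

- **Diameter** `D = C / π`, with the circumference `C` the length of the
  outer perimeter of the basement membrane (corner-corrected boundary-chain
  estimator, validated on rasterized circles).
- **Volume fractions** — pericyte %, BM %, endothelial % of the vessel wall
  volume, lumen excluded.
- **Coverage and direct contact** — the skeleton of (BM ∪ contact lines) is
  classified per pixel into Class 1 (direct pericyte–EC contact, detected
  as pericyte pixels within a 1-px dilation of the EC mask), Class 2
  (covered, BM in between) and Class 3 (uncovered); then
  `coverage % = (L1+L2)/(L1+L2+L3)` and `contact % = L1/(L1+L2)`.
- **Peg-and-socket properties** — per 2-D peg component: cross-sectional
  area, per-section frequency, and maximum protrusion depth = max Euclidean
  distance-transform value over the peg, measured from the abluminal EC
  surface after morphological closing of the EC∪peg∪lumen mask with a
  134 nm-radius disk (seals thin BM clefts between peg and socket).
- **α-SMA branch coverage** (fluorescence) — top-hat + fixed low threshold
  → vessel mask; Otsu within the mask → α-SMA mask; skeleton branch-point
  decomposition → branches with mean diameter (2× mean distance transform
  along the skeleton) and `coverage % = SMA area on branch / branch area`.
- **Group statistics** — four normality screens (D'Agostino–Pearson,
  Anderson–Darling, Shapiro–Wilk, Lilliefors/KS), Kruskal–Wallis omnibus
  (tie-corrected), Dunn pairwise z-tests with Holm adjustment.

A first-class synthetic generator builds capillary stacks (4–12 µm
diameter, concentric wall layers, pericyte crescents, contact sub-arcs,
pegs with optional BM clefts) and fluorescence vessel networks, each with
analytic ground truth computed from the geometry before rasterization —
every measurement stage is validated against values the label maps never
saw.

## Worked example

```python
from pericytometry import contact_profile
from pericytometry.synthetic import SyntheticVesselSpec, generate_vessel

spec = SyntheticVesselSpec(
    pericyte_arc_fraction=0.5, contact_arc_fraction=0.10,
    peg_count_per_section=0, n_sections=1,
    grid_px=512, pixel_size_nm=40.0, seed=13,
)
stack, truth = generate_vessel(spec)
prof = contact_profile(stack.sections[0])
```

Running `python examples/02_coverage_and_contact.py`, which performs this
computation and formats the fields of `prof` against the ground truth,
prints:

```
L1 (direct contact):          1.46 um
L2 (covered, BM between):    11.36 um
L3 (uncovered):              13.54 um
coverage: measured  48.6 %   true  49.7 %
contact:  measured  11.4 %   true  10.0 %
```

i.e. a vessel programmed with 50% pericyte coverage and a 10% direct-contact
sub-arc is recovered to within ~1 percentage point of its analytic truth.
The other `examples/` scripts cover basic morphometry, peg depth and the
closing contract, fluorescence branch coverage, and the full four-group
study; a thin CLI (`pericytometry simulate|measure|stats|demo`) wraps the
same functions for shell use.

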