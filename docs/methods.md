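# Methods

## The workflow being modelled

A fresh-frozen tissue section mounted on a PEN-membrane slide is cut by a
laser microdissection system into a predefined array of 96 squares; each
cut drops by gravity into its own well of a 96-well plate, is extracted in
solvent and quantified by targeted LC-MS/MS. The package models every desk
step of that pipeline: grid construction and placement, template
serialization, well mapping, concentration conversion, sensitivity and
capture-efficiency arithmetic, spatial re-projection, and a forward
simulator for validation.

## Grid geometry

The grid is a regular lattice of `n_rows × n_cols` axis-aligned squares
(8 × 12 by default; the product must be 96 so the grid maps 1:1 onto a
standard plate, rows A–H × columns 1–12). With square side `s` and bridge
fraction `f`, the lattice pitch is `s·(1 + f)` on both axes, so the
edge-to-edge gap between neighbours — the bridge of intact tissue that
keeps the remaining section mechanically stable — is exactly `f·s`.
Coordinates are micrometres with x rightward and y downward (stage-image
convention); the template origin is the top-left corner of square (1, 1),
and each polygon is stored as its four corners starting at the top-left,
counter-clockwise as seen on screen.

Placement onto stage coordinates uses two reference points: the first
anchors square (1, 1)'s top-left corner, the second marks the end of the
first grid line. In the default *similarity* mode the segment sets
translation, rotation **and** isotropic scale (the first-row extent is
stretched onto the segment); a *rotation-only* mode keeps the physical
template size and uses the segment for orientation alone. Both behaviours
are offered because instrument software may do either; neither is asserted
as the instrument's. A similarity transform preserves angles and distance
ratios, which the property tests check to 10⁻⁹.

### Effective cut area

The laser kerf destroys a strip of tissue `w` wide along the cut path, so
the recovered piece is smaller than the drawn square. Three models:

- `nominal`: `s²` (ignore the kerf);
- `kerf_inset`: `(s − c·w)²` with inset coefficient `c` (default 0.5 — a
  kerf centred on the path removes half its width from the piece per
  edge);
- `measured`: use the empirically measured average recovered area
  verbatim.

The six bundled presets carry measured areas, and `measured` is the
default when a preset is selected, because the measured areas imply a
smaller empirical inset than any simple geometric model: the exact
relation between beam width and recovered area is not derivable from the
available data, so it is exposed as data, not a formula. The `kerf_inset`
model is cross-checked in tests against an independent polygon-inset
oracle (mitred negative buffer) to 0.5%.

Beam widths per objective are bundled for both the bare membrane
(7.8/4.5/2.6/1.8/0.8 µm at 5×/10×/20×/40×/63×) and tissue
(9.1/5.2/3.6/2.1/1.1 µm); tissue kerf ≥ membrane kerf always holds for
the presets.

## Template serialization

The vendor's native shape-list container is an undocumented binary
format, so the package defines an open XML dialect (root element with grid
attributes, two calibration-point elements, one `shape` element per square
holding four `vertex` elements and a `well` attribute) plus a flat CSV
equivalent (`row,col,well,x1,y1,…,x4,y4` with a `#`-prefixed metadata
preamble). Numbers are serialized with 6 decimal places and a period
separator, squares in row-major order, making output byte-stable for a
fixed metadata timestamp. Round-trips reproduce coordinates to 10⁻⁶ µm
and wells exactly. An XML file renamed `.txt` serves as the importable
plain-text form; no bit-compatibility with vendor software is claimed.

## Well mapping

Squares are visited in a traversal order — row-major (default),
column-major, or serpentine (even rows right-to-left) — and wells are
filled in canonical plate order A1…H12, giving a bijection for every
ordering (tested exhaustively). The traversal order of the original
instrument run is not documented, hence the configurable default. Well
labels are case-insensitive and zero-padded on input (`a01` → `A1`),
canonical on output.

## Quantification

Tissue mass of one cut: `m = A·t·10⁻¹²·ρ` grams, with area `A` in µm²,
thickness `t` in µm and density `ρ` in g/cm³ (the 10⁻¹² is the exact
µm³→cm³ conversion). Tissue concentration:
`C_tissue = C_extract·V/m/1000` µg/g, which conserves analyte mass by
construction (`C_tissue·m` equals the extract nanograms to 10⁻⁹
relative, a tested invariant).

**Liver density.** The default `ρ = 1.104 g/cm³` is *implied by the
published per-template LLOQ table*: a closed-form least-squares fit of
density against the six measured cut areas gives 1.1041, and 1.104
reproduces all six published LLOQs at one-decimal rounding. It is labelled
as such throughout and is always an explicit parameter — notably because
the source experiments mix 20 µm and 40 µm sections, thickness is never a
hidden default either.

**LLOQ table.** The assay's lower limit of quantification (0.1 ng/mL in
the extract for all three validation compounds) converts per template to a
tissue LLOQ that falls monotonically with cut area and scales exactly as
`1/(t·ρ)`. The computation assumes size-independent matrix effects and
100% extraction yield.

**Censoring.** The lower calibration bound is inclusive (the LLOQ is by
definition quantifiable); values above the upper bound are kept but raise
a warning recommending dilution. CV% uses the sample (n−1) standard
deviation — the convention of the source tables is unstated, and this is
the conservative choice.

**Lost vs BQL.** A *lost* well received no tissue (the cut never dropped
in); a *BQL* well received tissue whose analyte is below the calibration
range. Real-data ingestion takes an explicit per-well status column (in
practice loss is diagnosed by absence of the sprayed standards); the
simulator generates the distinction mechanistically. Capture efficiency is
`100·(n_total − n_lost)/n_total`, with an exact Clopper–Pearson interval
for the underlying capture probability. Report rounding follows the source
tables (integer %, one decimal µg/g); full precision is kept internally.

Two published brain-section capture rows (7 losses → 91%, 10 → 89%) are
arithmetically inconsistent with a 96-cut denominator ((96−7)/96 = 92.7%)
and are not reproduced; the 85% average is computed from the seven printed
percentages, which is insensitive to that inconsistency.

**Throughput.** Plate turnaround is
`(collection + extraction + n_cuts·runtime)/60` hours with defaults of
10 min extraction and 4 min LC run per cut — arithmetic on stated
durations, not a hardware benchmark.

## Synthetic plates

The simulator emulates the workflow's validation experiment: a section
uniformly sprayed with test compound, dissected with a template, extracted
and measured. Per square:

1. analyte mass = surface density × effective cut area × lognormal spray
   factor (mean 1, CV `spray_cv`);
2. capture ~ Bernoulli(p); a failure yields a `lost` well contributing
   nothing — cross-well contamination is not modelled, since double
   collection was not observed in practice;
3. extract concentration = mass / volume × lognormal measurement factor
   (mean 1, CV `measurement_cv`);
4. BQL censoring against the calibration range.

Defaults are the study conditions: 270×270 template, 40 µm sections,
`ρ = 1.104`, surface density 10 ng/mm² (the sprayer's deposition
arithmetic — 16 passes × 0.2 mL/min ÷ 1200 mm/min ÷ 3 mm track at
10 µg/mL — gives ≈ 8.9 ng/mm², and back-calculating the measured 500×500
well concentrations gives ≈ 12 ng/mm²), capture probability 0.85 (the
reported average efficiency), spray CV 25% and measurement CV 15%
(combined CV ≈ 29%, matching the observed ~30% well-to-well CVs at small
cut sizes). Lognormal noise was chosen for positivity — only CVs, not a
noise law, are reported — and the two factors are kept separate so tests
can isolate each. The seed is mandatory; identical configurations produce
byte-identical plates.

What the simulator does **not** emulate: spatially correlated spray
gradients, tissue heterogeneity, matrix effects, extraction-yield losses
and analyte degradation. Passing recovery tests therefore demonstrates the
correctness of the pipeline arithmetic and estimators under the stated
noise model, not robustness to those real-data effects.

At the default spray density the 30×30 µm² template's wells fall just
below the 0.1 ng/mL assay floor (923 µm² × 10 ng/mm² / 0.1 mL =
0.092 ng/mL) — the same behaviour that excluded that template from the
original capture-efficiency experiment.

## Numerical and design choices

- Problem sizes in tests: property suites run 25–100 randomized examples;
  simulator recovery uses 200 replicate plates (19 200 Bernoulli draws,
  binomial SE ≈ 0.26 points), chosen so the whole suite completes in a few
  seconds while leaving the 99% exact-binomial acceptance band far wider
  than the Monte-Carlo error.
- Degenerate inputs: coincident reference points, non-positive geometry,
  loss counts outside [0, n] and invalid calibration ranges raise
  `ValueError` naming the offending field; a plate with zero quantifiable
  wells yields NaN statistics flagged `cv_undefined` rather than an
  exception.
- Missing map cells are exported as the literals `BQL`/`LOST`, never zero,
  which would corrupt downstream means. Wells absent from a results file
  are treated as lost.
- Raster maps draw one block per square, row 1 at top (stage convention,
  recorded in the image metadata), with fixed colours for BQL (violet) and
  lost (red) cells; output is deterministic.

## Known limitations

- The placement model covers similarity and rigid motions only; no
  nonlinear stage distortion.
- Only 96-square grids (any `n_rows × n_cols = 96` factorization);
  384-well plates and partial plates are out of scope beyond lost-well
  flagging.
- Calibration-curve regression, peak integration and matrix-effect
  correction are upstream of this package; it consumes extract
  concentrations (or applies a supplied linear slope/intercept to response
  ratios).
- Registration of the concentration map to stained histology images is
  not provided; the map lives in grid coordinates.
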