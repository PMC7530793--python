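# Methods

This note documents the models behind `mplexpheno`, the choices made where
the design was genuinely open, and what the synthetic scenes do and do not
establish about real tissue.

## Acquisition model and spectral unmixing

Acquisition is linear per pixel: `y_c = Σ_f A[c,f]·x_f·t_c + ε_c`, where
`x_f` is fluorophore *f*'s abundance in counts, `t_c` the channel exposure
(ms), `A[c,f]` the trapezoid integral of the fluorophore's emission curve
over channel *c*'s passband, and `ε_c ~ N(0, σ²·t_c)` Gaussian read noise
(no Poisson term in v1 — this keeps every forward-model example
closed-form). Channels are clipped at zero, as a camera would.

Emission curves for the Opal dyes are not published as tables, so the
synthetic library uses Gaussian stand-ins with unit peak at each dye's
nominal emission wavelength (the number in the dye's name; DAPI at 461 nm),
FWHM 40 nm (60 nm for DAPI), on a uniform 2 nm grid over 400–800 nm. Tissue
autofluorescence is a single broad endmember (Gaussian, peak 530 nm, FWHM
260 nm), matching the one-representative-spectrum subtraction approach;
multi-spectrum, thickness-resolved autofluorescence correction is out of
scope. Two filter sets ship: the five standard epifluorescence bands
(DAPI/FITC/Cy3/TexasRed/Cy5) and a seven-band whole-slide set with
spectrally distant passbands.

Unmixing is per-pixel **nonnegative least squares** against the sensing
matrix (abundances are physical concentrations, so negativity is
disallowed). The proprietary commercial unmixer is not documented; linear
NNLS is an explicit modelling assumption. Implementation: the unconstrained
pseudoinverse solution is used wherever it is already nonnegative — the two
coincide there — and only pixels with negative components are re-solved
with NNLS; abundances below 10⁻⁹ of the image maximum are snapped to exact
zero so that noise-free re-acquisitions are bit-comparable. Exposures are
rows of the sensing matrix, so solutions are exposure-normalised counts by
construction; this is what makes batch- vs individual-exposure acquisitions
of the same scene unmix to identical per-cell counts.

A **measured library** can be estimated from singleplex slides: per
fluorophore, the mean channel vector over the brightest 2% of pixels, minus
the mean over the dim background half (pure autofluorescence), normalised
to unit maximum. This is exact when the autofluorescence field is spatially
flat — library-building fixtures therefore disable the AF texture, as real
library slides are chosen for uniform background.

**Crosstalk** between fluorophores is quantified on singleplex scenes as
the total abundance misassigned to another fluorophore, normalised by the
own-fluorophore total. Totals are restricted to the stained-pixel support
(own abundance above 5% of its maximum): background pixels outnumber
stained pixels ~12:1 and their clamped noise floor otherwise dominates the
statistic, which is meant to measure misassignment of *signal*. With the
raw-totals option the same function expresses dropout controls: an
unstained fluorophore's totals sit at noise level.

**QC.** Images whose autofluorescence plane's upper-quartile mean exceeds
6 counts, or whose per-pixel reconstruction-residual upper-quartile mean
exceeds 1 count, are excluded. The quartile statistic and both bounds are
package choices (the underlying exclusion rule is qualitative): at the
τ = 1 baseline the AF plane sits at ~2–3 counts, so the 6-count bound
passes normal sections and excludes τ ≳ 2.5; the residual bound is two
orders of magnitude above the noise-driven residual of a correct library
and fires on library mismatch.

## Synthetic scenes

Each scene is a field of cells with a nuclear disc (radius 4–7 px,
integer-uniform) and a membrane annulus (width 2 px) — the smallest
geometry at which nucleus and membrane means stay distinguishable at desk
scale. Coordinates are 0-based (row, col), pixel-centre convention. One
global seed fans out to labelled substreams (placement, phenotypes,
abundances, texture, read noise), so every artefact is independently
reproducible.

* **Placement.** Dart-throwing with a minimum separation (default 20 px)
  outside hot spots; inside hot spots the separation shrinks by
  √density-multiplier. Cell counts split between contexts in proportion to
  density-weighted area. Infeasible densities raise a generation error
  naming the constraint (random sequential packing saturates near 55% of
  hexagonal density, so configurations are kept below ~60% of that).
* **Phenotypes.** Drawn per tissue context from the profile table. The MP1
  hot-spot mix is germinal-centre-like (65% CD20+ B cells with admixed
  CD3+/CD4+, CD3+/CD8+ and CD4/CD8-null T cells); sparse tissue carries
  epithelium (CK+), scattered lymphocytes and 30% marker-negative cells.
  Positive abundances are lognormal with mean 23 counts (σ = 0.25), inside
  the 20–25-count calibration window; DAPI at 26 counts everywhere.
* **Artefacts.**
  - *Nonspecific co-stain* ν: inside hot-spot discs the CD8 plane receives
    ν × the CD20 plane, reproducing germinal-centre CD20–CD8 co-staining.
    No magnitude is published for this effect; the working value ν = 0.3 is
    a simulator knob chosen so that a B cell's CD8 contamination
    (ν × 23 ≈ 7 counts) sits below the 10-count threshold in isolation but
    crosses it with neighbour spillover — i.e. the artefact is
    context-dependent, not unconditional.
  - *Spillover/masking* κ: when two cells' annuli overlap geometrically,
    each cell's annulus additionally receives κ × the neighbour's membrane
    abundances — whole-annulus contamination, modelling segmentation-level
    signal mixing rather than mere shared boundary pixels, since dense-
    region errors in practice come from misattributed whole compartments.
    At pixels covered by ≥ 2 annuli the weaker co-located membrane markers
    are attenuated by (1 − κ/2), so masking (under-detection) and spillover
    (over-detection) are both producible.
  - *Thickness* τ: the autofluorescence plane is
    τ × (2 counts baseline + low-frequency texture, amplitude 0.8, Gaussian
    correlation length 40 px), hence exactly linear in τ.
* **Magnification.** 20× vs 40× is modelled as a pixel-scale factor applied
  to the same ground truth (geometry, segmentation parameters and ring
  widths scale together); per-class fractions are required to move by less
  than one percentage point between 1× and 2× renders.

What the generator does **not** emulate: photorealistic tissue texture,
chromogenic (DAB) image formation (the reference arm enters as ground
truth), optical PSF blur, z-structure, staining gradients, whole-slide
tiling. Passing tests therefore show that the *computational* pipeline is
correct under the stated artefact models — not that those models exhaust
real-tissue failure modes.

## Segmentation and measurement

Nucleus detection: Gaussian smoothing (σ = 1 px), a global threshold,
removal of objects below 12 px², and distance-transform watershed with
seeds from smoothed-distance maxima at least 5 px apart. The "auto"
threshold seeds a triangle threshold (robust for sparse foreground) and
then cuts at half the mean foreground height: the half-maximum of a blurred
disc lies at the true disc edge, so detected nuclei match the generating
discs instead of the blur skirt. Cells are expanded geodesically by
2 px (nearest nucleus wins contested pixels; the exact expansion geometry
of interactive tools is unpublished, so geodesic dilation is an
implementation choice); the membrane ring is the expansion minus the
nucleus, and per-compartment means are computed on the unmixed planes, so
they are in counts. Watershed under-segments tightly packed hot spots
(~70% recall there vs 100% on sparse scenes) — the known limitation that
motivates star-convex deep-learning detectors as future work.

## Phenotyping

Thresholds are strict (`mean > t`; ties negative — documented, arbitrary).
Three provenances: manual (default 10 counts, midway between ~2-count
background and 20–25-count signal, echoing the 10:1 signal-to-background
rule), quantile-match against a reference positive fraction (the
ground-truth/chromogenic arm; order-statistic midpoint, exact to one cell
on continuous columns), and Otsu.

The default MP1 tree reaches CK+, CD20+, CD3+/CD4+, CD3+/CD8+ and
CD3+ (CD4/CD8-null); its unexpected additions are CD4+/CD8+, CD3−/CD4+ and
CD3−/CD8+. MP2: CK+, CD68+, CD4+, CD4+/FOXP3+, FOXP3+, with CD4+/CD68+
unexpected. Compound-rule matching consults the cell's *current class
only*, mirroring sequential binary relabelling and keeping the tree
finite; compound classes stop at pairwise combinations. Rules are written
for both CD3-before and CD3-after orders so a single tree serves a
detection-order sweep; rules unreachable under a given order are inert
(the audit trail records every firing). Six MP1 orders ship: the naive
CD20-first order and the final order (CK > CD4 > CD3 > CD20 > CD8) are as
established; the four intermediates are labelled reconstructions of a
plausible refinement path. MP2 order effects are negligible by
construction (its co-expressing pair occupies different compartments), so
two orders ship for contrast.

The multilabel classifier computes the per-cell positive-marker set
independently of order (set semantics make order-irrelevance exact); the
learned mode is a random forest (100 trees, seeded) over all compartment
means, with ties resolved by the forest's majority vote.

## Validation statistics

Spearman uses mid-rank ties, exact permutation p for n < 10 and the
t-approximation above (the boundary is an implementation choice; the
original analyses do not state theirs). Mann–Whitney U uses exact
enumeration when the smaller group has ≤ 8 untied observations, otherwise
the tie-corrected normal approximation. Bland–Altman reports bias and
bias ± 1.96 × sample SD; because the bias is by definition the centre of
its own limits, "bias within the 95% limits" is operationalised as
|bias| < 1.96 × SD, with the fraction of per-unit differences inside the
limits reported alongside so either reading can be applied. The
10-percentage-point positivity rule flags units with |ref − test| > 10.
Zero-variance paired differences: zero mean gives (t = 0, p = 1), nonzero
mean gives t = ±∞, p = 0 with a degenerate-certainty flag. α = 0.05
two-tailed throughout; no multiple-testing correction (none is applied in
the source analyses; the report says so).

## Problem sizes

The shipped study scenes are desk-scale by design: 512² px / 300 cells for
the clean sparse reference, 384² px / 300 cells with two 55 px hot spots
(density multiplier 6 — germinal centres pack several-fold denser than
stroma) for the artefact scene, 448² px for MP2, 160² px / 40-cell
singleplexes for crosstalk, and 256² px thickness twins. These sizes keep
every statistic stable across seeds while each pipeline stage runs in
seconds.

## Known limitations

* Linear Gaussian-spectrum unmixing is an assumption, not a reproduction
  of the proprietary unmixer.
* The ν = 0.3 co-stain magnitude and the QC bounds are package defaults,
  not published values.
* Watershed recall degrades in dense regions (by design of the method);
  phenotype-recovery guarantees are stated for sparse scenes only.
* The hierarchical tree stops at pairwise compound classes; triple
  positives fall back to their pairwise branch.
* Real-tissue agreement values (correlations against chromogenic staining
  on patient material) cannot be recomputed here; the validation module is
  exercised against ground truth and closed-form oracles instead.
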