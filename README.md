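# mplexpheno

A desk-scale digital-pathology pipeline for **Opal multiplex
immunofluorescence (mIF)** panels: ground-truthed synthetic tissue scenes,
multispectral unmixing with autofluorescence handling, watershed cell
segmentation with per-compartment measurement, threshold-based **sequential
binary hierarchical phenotyping**, and the method-agreement statistics used
to validate an mIF panel against a chromogenic reference.

## Who this is for

Tyramide-signal-amplification (Opal) panels let six or more markers be
imaged on one FFPE section, but the downstream image analysis has sharp
edges: overlapping dye emission spectra leak signal between channels,
tissue autofluorescence scales with section thickness, and in dense immune
regions (germinal centres) co-expressed membrane markers mask and
contaminate one another, so the *order* in which markers are classified
changes the phenotype counts. `mplexpheno` packages those phenomena — both
the simulator that produces them on demand and the analysis code that must
survive them — so that classification strategies and QC rules can be
studied with known ground truth.

## The model

**Acquisition.** A pixel's raw channel vector is linear in the fluorophore
abundances: `y = A x`, where `A[c, f]` integrates fluorophore *f*'s
emission over filter channel *c*'s passband, scaled by the channel's
exposure time, and one extra column holds a representative tissue
autofluorescence spectrum. Unmixing solves a nonnegative least-squares
problem per pixel and reports abundances in exposure-normalised *counts*
(positives are calibrated to the 20–25-count window, with a < 30-count
signal-balance rule).

**Phenotyping.** Each marker gets one threshold on one compartment mean
(membrane ring for CD3/CD4/CD8/CD20/CD68/CK, nucleus for FOXP3). The
hierarchical classifier walks a *detection order*: unclaimed cells above a
marker's threshold take that step's base class; already-classified cells
are relabelled only through explicit compound rules (e.g.
`CD3-/CD4+ × CD3 → CD3+/CD4+`). Rules tagged *unexpected* (e.g.
`CD3+/CD4+ × CD8 → CD4+/CD8+`) form the difference between "script 1"
(expected classes only) and "script 2" (full tree).

**Validation.** Paired per-core percent-positivity is compared with
Spearman rank correlation, Bland–Altman bias with 95% limits of agreement
(bias ± 1.96 × SD), and a 10-percentage-point cell-positivity rule;
Mann–Whitney U and the paired t-test cover group and pipeline comparisons.

## Worked example

The `hotspot-mp1` fixture is a 384² px scene with two CD20-dominant
germinal-centre-like hot spots, nonspecific CD20→CD8 co-staining
(ν = 0.3) and neighbour spillover/masking (κ = 0.3):

```python
from mplexpheno import fixtures, panels, phenotyping, segmentation, spectral

fx = fixtures.make_fixture("hotspot-mp1")
unmixed = fx.unmixed()
qc = spectral.qc_autofluorescence(unmixed)
print(f"QC: passed={qc.passed} AF upper-quartile mean = {qc.af_upper_quartile_mean:.2f} counts")

cells = segmentation.segment_and_measure(unmixed, panels.MP1)
print(f"detected {len(cells)} cells ({len(fx.truth().cells)} simulated)")

sweep = phenotyping.order_sweep(
    cells, phenotyping.default_thresholds("MP1"),
    phenotyping.mp1_tree(), phenotyping.default_orders("MP1"),
)
print("summed |deviation| from singleplex positivity, per detection order:")
print(sweep.deviations.round(3).to_string())
```

prints

```
QC: passed=True AF upper-quartile mean = 2.51 counts
detected 215 cells (300 simulated)
summed |deviation| from singleplex positivity, per detection order:
order1-cd20-first    0.330
order2               0.330
order3               0.330
order4               0.219
order5-cd20-last     0.219
final                0.219
```

Reading the numbers: the image passes the autofluorescence QC (2.5 counts
is normal-thickness background); watershed detection under-segments the
packed hot spots (215 of 300 cells — the expected failure mode of classical
watershed in crowded regions); and detection orders that classify CD20
before the T-cell markers deviate ~11 percentage points more from the
singleplex reference than the final order (CK > CD4 > CD3 > CD20 > CD8),
because B cells' strong membrane signal claims neighbouring T cells first.

A full run — simulate → mix → unmix (+QC) → segment → measure → phenotype
→ validate, with every intermediate persisted and checksummed in a run
manifest — is one call (or `mplexpheno run` on the command line):

```python
from mplexpheno import pipeline
manifest = pipeline.run_pipeline(pipeline.PipelineConfig(), "out/")
```

QC-excluded images (e.g. a thick section, τ = 5) stop the pipeline after
unmixing: no cell table is produced, the manifest records the exclusion,
and the CLI exits with code 2.

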