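# Methods

## Scope and model

`hidspatial` implements an automated analysis pipeline for multiplex
immunofluorescence ROIs of tumour tissue: quality-gated ROI selection, nuclear
segmentation with cell expansion, single-threshold marker scoring, the
Hypothesised Interaction Distribution (HID) spatial proximity statistic, and
stratified survival analysis. Because cohorts of this kind are generally not
deposited, the package ships a first-class synthetic generator that emulates
the statistical structure such a study assumes, so every stage is testable
end to end.

## The HID statistic

For phenotype sets C_i and C_j with cell centroids x, the raw count is

    H(i, j) = |{ {k, l} : k ∈ C_i, l ∈ C_j, k ≠ l, ‖x_k − x_l‖₂ < d }|

and the normalised frequency is h(i, j) = H(i, j) / N with N the total number
of cells in the sample regardless of phenotype. Conventions, all deliberate
and switchable where noted:

- **Unordered distinct pairs.** A cell belonging to both sets (e.g. a
  co-expressing cell) can participate in pairs but never pairs with itself;
  a zero-distance self pair has no biological meaning. `allow_self_pairs`
  switches this.
- **Strict inequality** at the radius: a pair at exactly d is not counted.
- **No edge correction**; distances are computed in pixel space after an
  exact (unrounded) µm→px conversion, so the boundary is not quantised.
- The k-d-tree implementation is contractually equal to the O(n²) double
  loop; the test suite enforces this on randomised instances including
  coincident centroids and exact-boundary layouts.
- **Patient aggregation**: the default is the median of per-ROI h, parallel
  to the per-patient median convention used for percent-positive densities;
  `mean` and `pooled` (ΣH/ΣN across a patient's ROIs) are available because
  the within-patient aggregation of proximity counts is genuinely a free
  choice.

The default radius d = 30 µm (≈ 60.6 px at 0.495 µm/px) corresponds to a
neighbourhood of 2–3 cell diameters, the conventional scale for hypothesised
receptor–ligand interactions such as PD-1/PD-L1.

## Image preparation

**Spectral unmixing** solves, per pixel, the non-negative least-squares
problem raw ≈ library · abundances. Abundances are physical concentrations,
so negativity is artefactual; pixels whose unconstrained solution is already
non-negative are solved in one vectorised pass, the rest fall back to
per-pixel NNLS. A rank-deficient library is rejected with the collinear
columns named. Building a spectral library from single-stain slides is out of
scope; a synthetic Gaussian-band library is used in tests.

**Quality classification** is an interface `image → QualityMask` with three
labels (background / tissue / artifact) so a learned classifier can be
slotted in. The default rule-based classifier uses:

- background: smoothed total signal < `bg_threshold` (default 0.05 — below
  the diffuse tissue autofluorescence level);
- bright artifact: smoothed AF channel > `af_threshold` (default 1.0 — an
  order of magnitude above tissue AF; bubbles, folds, red blood cells);
- blur artifact: local RMS high-pass energy of the summed channels below
  `blur_threshold` (default 0.6) × the image's median non-background energy.
  Out-of-focus patches lose even the sensor noise floor, which makes the
  noise energy itself the most reliable sharpness cue;
- speckles below `min_region_px` (default 256 px) are absorbed into their
  surroundings.

Thresholds were calibrated once on the synthetic renderer; on rendered ROIs
with 10% planted artifact area the classifier reaches ≈ 98–99% pixel
accuracy. On real Vectra data they would need recalibration — the contract,
not the constants, is the point.

**ROI gate**: an ROI is excluded iff its useful-tissue fraction is strictly
below 0.30; the denominator is all pixels (background included), a choice
flagged in the configuration because the convention is ambiguous. Only cells
whose centroid pixel (nearest pixel, rounded coordinates) is labelled tissue
are analysed.

## Segmentation, measurement, scoring

Nuclear detection is the standard watershed recipe on the DAPI channel:
Gaussian smoothing (σ = 1 px), absolute threshold (0.25 of the nominal
nuclear amplitude), Euclidean distance transform, peak markers
(min distance 2 px), watershed, and an area gate of 30–2500 px. Parameters
were tuned once on synthetic validation ROIs; detection is deterministic.
With the renderer's defaults this yields centroid-matched F1 ≈ 0.95–0.96 at a
3 px radius and a detected count within ~4% of the planted count.

Cytoplasm is simulated by expanding each nucleus by round(2 µm / 0.495 µm/px)
= 4 px, with expansion stopping at the equidistant boundary between
neighbouring cells, so compartments never overlap. Exact-distance ties are
assigned deterministically by the Euclidean feature transform (not by label
id); ties occur on a measure-zero set of pixel configurations and never
change counts materially.

Per cell, channel and compartment the package records mean, min, max and
population standard deviation (divide by n). Intensities are rescaled
per marker onto [0, 1] between the 1st and 99th percentile (linear
interpolation convention) of that marker's pixel intensities pooled over all
included ROIs, so equal intensity means equal brightness in every image. A
cell is positive for a marker iff its rescaled mean intensity in the marker's
primary compartment — cytoplasm by default for the four cytoplasmic/membranous
markers handled here — reaches the marker's single dataset-wide threshold; a
tie at the threshold scores positive (a fixed documented convention where
the field's practice is silent). Phenotype membership is conjunctive and
non-exclusive: a CD8⁺PD-1⁺ cell is a member of CD8⁺, PD-1⁺ and CD8⁺PD-1⁺.

## Cohort statistics

- Percent-positive densities per ROI; the patient value is the median over
  included ROIs.
- Stratification labels a patient high iff the feature exceeds the cut
  statistic (median for densities, mean for HID features, per convention);
  ties go low. By default the cut is computed within the analysis population
  being tested (subgroup analyses use the subgroup's own cut); a cohort-wide
  cut is available since the convention is ambiguous.
- Kaplan–Meier with Greenwood's variance is implemented directly (the
  variance must be exposed for error bars): S(t) = Π(1 − dᵢ/nᵢ),
  Var[S(t)] = S(t)² Σ dᵢ/(nᵢ(nᵢ−dᵢ)); subjects censored at an event time
  remain at risk at that time. Cross-checked against statsmodels to 1e-10.
- The two-group Mantel–Haenszel log-rank test and univariate Cox regression
  (Efron tie handling, Wald CI/p) go through lifelines; the test suite
  cross-checks Cox against an independent direct maximisation of the Efron
  partial likelihood, and the log-rank against a direct hypergeometric
  computation. Monotone likelihood (complete separation) is flagged and the
  CI reported unbounded.
- Distribution comparisons between HPV strata use the one-sided Mann–Whitney
  U test (exact enumeration for combined n ≤ 12 without ties, tie-corrected
  normal approximation otherwise). A Kolmogorov–Smirnov normality p-value is
  reported as a diagnostic only; it never selects the test.
- No multiple-testing correction is applied (the design pre-specifies two
  proximity hypotheses); the report prints the number of tests performed.

## The synthetic generator

The generator's defaults are the study conditions of a 72-patient
oropharyngeal carcinoma cohort: ~57% HPV-positive patients, 10–20 ROIs per
patient of 1392 × 1040 px at 0.495 µm/px, ≈ 1200 cells per ROI split into
exclusive classes (CD8⁺ 61, CD8⁺PD-1⁺ 18, CD68⁺ 24, CD68⁺PD-L1⁺ 13, PD-L1⁺
95, PD-1⁺ 134, negative 855 — marker percentages typical of this tumour type
applied to a realistic cell count per 0.355 mm² field).

**Spatial structure.** With colocalization strength 0, every class is a
homogeneous Poisson process on the tissue region. Planted colocalization is a
parent–offspring (Thomas-like) construction: a fraction s/(1+s) of each
T-cell class (CD8⁺, CD8⁺PD-1⁺, PD-1⁺) is placed uniformly within 20 µm of a
randomly chosen PD-L1-expressing parent. Per-patient strengths follow a
two-point mixture {0, s} in equal proportion by default — a cohort of
low- and high-colocalization subpopulations, the structure a high/low
stratified analysis presumes — with a Uniform(0, s) alternative. Expected
class counts are strength-independent.

**Rendering.** DAPI carries Gaussian nuclear blobs (σ = 3 px); each marker
channel paints a cytoplasmic annulus per cell with amplitude drawn from
overlapping log-normals (positive median 3.0, negative median 0.3, σ = 0.5 on
the log scale — ~4.6 σ separation, i.e. deliberately imperfect, so threshold
scoring is exercised realistically). The AF channel carries a diffuse tissue
level (0.1) plus artifacts: bright AF blobs (bubbles, folds, erythrocytes)
and locally blurred patches (scanning errors), painted to a target area
fraction and recorded in the ground-truth mask, plus optional background
margins. Sensor noise is Gaussian (σ = 0.02).

**Survival.** Times are exponential proportional-hazards draws:
log λ = log(ln2 / 86.8 per month) + β·1[high, in effect stratum] +
β_HPV·1[HPV⁺], with β_HPV = −ln 3.3 by default (HPV-positive disease has
about one third the hazard). The true high/low group is assigned at the mean
of the planted HID feature over the population the hazard applies to.
Censoring is administrative by default — censor times uniform over an
85–204 month follow-up window, matching a retrospective design with a stated
minimum follow-up, under which poor-prognosis strata contribute
proportionally more events (~45–50% censoring overall). An exponential
censoring model calibrated to an exact per-patient censoring probability is
available; censoring rate 0 disables censoring.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: real Opal fluorophore spectra and scanner optics;
stromal versus tumour compartments; nuclear morphology variation beyond
isotropic Gaussian blobs; spatial inhomogeneity of tissue density;
batch/staining variation between slides (the positive/negative intensity
distributions are stationary across the cohort). Recovery rates measured on
synthetic ROIs are therefore upper bounds on real-data performance; the
exactness properties of the HID statistic itself carry over unchanged.

## Numerical choices

- All randomness flows through numpy Generators derived from a single seed
  (per-ROI streams keyed by patient and ROI index), so identical seeds give
  bit-identical cohorts, images and pipeline outputs.
- The strict-< radius is enforced in the k-d tree path by counting at the
  largest float below d.
- CSR calibration tests compare against the exact closed-form two-point
  distance CDF for a rectangle, P(D < d) = (π d² a b − (4/3) d³ (a + b) +
  d⁴/2)/(ab)², so edge effects sit in the expectation and only sampling
  noise in the tolerance.
- Simulation studies in the tests and the acceptance script run at reduced
  problem sizes chosen for precision per unit time: survival studies use
  half-scale ROIs (520 × 696 px, area-scaled densities) and 4–10 ROIs per
  patient, which leave the survival machinery's behaviour unchanged;
  image-level recovery studies use the full 1392 × 1040 px geometry.

## Known limitations

- The rule-based quality classifier is a stand-in honouring the
  image → QualityMask contract; its thresholds are calibrated to the
  renderer, not to any scanner.
- Univariate Cox only (the stratified proximity analysis is univariate by
  design); no multivariate adjustment.
- The watershed splits touching nuclei on distance-transform geometry only;
  heavily overlapping nuclei (> ~60% overlap) merge.
- HID significance is assessed only through downstream survival
  stratification; no permutation test of spatial colocalization per se is
  provided.
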