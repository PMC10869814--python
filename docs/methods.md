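# Methods

## The assay being emulated

An enrichment-free slide-based liquid biopsy: after red-cell lysis the
nucleated fraction of a blood draw is plated at roughly 3×10⁶ cells per
slide, stained with DAPI / cytokeratin (CK) / vimentin (Vim) / CD45+CD31 in
four fluorescence channels, and imaged as 2304 frames per slide.  Each test
uses two slides.  Because the number of nucleated cells plated is known and
the blood's white-cell concentration is measured by a hematology counter,
each slide corresponds to a definite blood volume,

    mL analysed = cells plated / WBC per mL,

which converts event counts into events/mL (about 0.94 mL per two-slide
test at typical counts).  Rare events fall into twelve categories — eight
nucleated phenotypes and four acellular oncosome phenotypes — defined by
the four-channel positivity pattern (see the README table).

## Synthetic data generator

`cytoscout.simulate` produces ground-truthed cohorts in two modes.

**Feature-table mode** draws, per slide: a WBC concentration; per-category
event counts `Poisson(rate × mL analysed)`; per-event geometry and per-event
channel amplitudes; and then synthesises the morphometric feature vector
each event *would* produce under segmentation — channel medians are
background plus amplitude with sampling noise, areas and eccentricities
follow from the planted ellipse.  The full-scale plating count (3×10⁶) is
used for normalisation, so cohort statistics run at realistic blood
volumes.  A configurable sample of common leukocytes represents the
background population for outlier-model fitting and classifier training.

**Render mode** rasterises frames: nucleated cells are rotated ellipses —
nucleus painted in DAPI, a jittered ~1.6× cytoplasm painted in each positive
marker channel; oncosomes are round CK discs (2–8 µm) with no DAPI signal;
mesenchymal CTC clusters are rosettes of k nuclei (k ∈ 1..4, configurable
law) in one shared cytoplasm, counted as one event.  A σ=1 px Gaussian blur
softens edges; per-channel Gaussian background noise (level 100, sd 10 by
default) is added and clipped at zero.  This additive-Gaussian noise model,
rather than a full Poisson-shot model, is deliberate: it gives direct
control of the signal-to-noise ratio that the detection guarantees are
stated at.  Optics (PSF, autofluorescence, spectral bleed-through) are out
of scope.

Key defaults (all configurable on `SimulationConfig`):

| parameter | default | note |
|---|---|---|
| frame geometry | 512×512 px at 0.2 µm/px | 102 µm field |
| frames per slide | 64 (desk) / 2304 (full scale) | |
| WBC law | lognormal, mean 7.49×10⁶/mL, log-sd 0.472 | median ≈ 6.7×10⁶, central 95% ≈ 2.6–17×10⁶; donors use mean 6.3×10⁶ |
| leukocyte nucleus | 8–12 µm diameter | |
| rare-cell nucleus | 15–22 µm diameter | rare cells are larger than leukocytes; this is what makes marker-negative rare phenotypes (D\|CD, DAPI-only) separable at all |
| oncosome diameter | 2–8 µm | round: axis ratio ≥ 0.9 |
| channel amplitude | normal(100, 15), truncated ≥ 50 | ≥ 5 background sd above background |
| proximal fraction | 0.3 | oncosomes planted adjacent to a cell |
| adjacency distance D | 2 µm | shared with the classifier |
| rare rates | 1–20 events/mL per category | illustrative magnitudes, not biology; oncosomes most frequent, classical CTCs least |

Placement geometry: cells may sit close together (≥ 5 px gap), but any pair
involving an oncosome keeps a gap of at least 2.5 D, while planted-proximal
oncosomes are placed with a mask-to-mask gap of 0.1–0.8 D from a host cell
measured along the approach direction of the host ellipse.  Planted
proximity labels are therefore unambiguous under the classifier's rule.
Large rare cells are planted first, the leukocyte background fills in
afterwards (best-effort to the target density; the plated-cell count used
for normalisation is the number of commons actually planted, keeping the
events/mL arithmetic exact at desk scale), and oncosomes attach last.

The full-scale plating density (≈1300 cells per 2304-frame slide field)
cannot physically fit the 102 µm default field; rendered slides therefore
use a configurable `common_cells_per_frame` (default 12) and the
normalisation identity above.  Feature-table mode has no geometric
constraint and keeps the full 3×10⁶ normalisation.

The clinical table mirrors the usual surgical-cohort covariates: age, sex,
race, smoking, alcohol, familial history, grade, tumor volume (lognormal,
clipped to 4.86–184.9 mm²), ordinal pT (pT0<…<pT4) and pN stages, and
therapy.  `tumor_volume_effect` couples a patient's rare rates to
(volume/35 mm²)^effect, planting a monotone association for the correlation
tests.

## Detection

Per frame: the DAPI plane is gated at background + k·sd (k = 5; background
estimated robustly as median + 1.4826·MAD when not supplied), small objects
below 15 µm² are removed, and touching nuclei are split by a
distance-transform watershed (peak separation 3 µm).  The cell foreground
is the union of gated CK/Vim/CD signal and 3-px-dilated nuclei; each
connected component containing k ≥ 1 nuclei is one event with
cluster_size = k.  Acellular CK components qualify as oncosome candidates
when they contain no nucleus pixels, their median DAPI is below the DAPI
gate, and their eccentricity is ≤ 0.8 ("round").

Features per event (~24): per-channel median/mean/sd/max over the cell
mask, cell and nucleus area (µm², via pixel_size²), perimeter, solidity and
best-fit-ellipse eccentricity.  This fixed documented set stands in for the
much larger proprietary morphometry banks used by production rare-cell
pipelines; it is not a reconstruction of any of them.

Rare candidates are selected per slide as outliers from the dominant
leukocyte background (nucleated, CD45/CD31+, CK−, Vim−): a minimum
covariance determinant fit over 8 features (4 channel medians, 2 areas, 2
eccentricities) gives robust Mahalanobis distances, cut at a Hotelling-style
F quantile (default 0.999) — the asymptotic chi-square cutoff under-covers
for small background samples, and an empirical quantile of the gate-selected
background would be contaminated by marker-negative rare cells.  CK- or
Vim-positive events and acellular candidates are always flagged, so the
flagged set is a superset of threshold-positive events.  The false-flag
rate on pure background is calibrated to ~1−quantile for backgrounds of a
few thousand events; much smaller backgrounds run a few-fold above it.

Artifact filtering removes border-touching events (partial masks bias area
and eccentricity), events with more than 20% saturated pixels, events
outside 2–3000 µm², and non-round acellular debris; each removal is logged
with its rule.

## Classification

Positivity is threshold-based (median ≥ background + 5·sd; the at-the-gate
case counts positive) or model-based: one random-forest binary classifier
per non-DAPI channel, trained on the cell-level features augmented with the
frame-level and slide-level mean and sd of every feature (so the models see
staining context).  DAPI positivity is always the threshold gate.  The
positivity vector and nucleation state map onto the twelve categories via a
total truth table; D|CD is reported as rare only for outlier-flagged events,
since that pattern is also the common leukocyte phenotype.  Oncosomes are
proximal when the mask-to-mask distance to the nearest nucleated cell is
≤ D = 2 µm, else distal.

## Enumeration

Counts pool over the slides of a test (counts and mL are summed — not
per-slide rates averaged — matching the per-test blood-volume bookkeeping);
clusters count once with cluster_size retained.  Derived totals are computed
from integer counts and the proximal split as the complement of the distal
one, so the conservation identities (total events = cells + oncosomes;
oncosomes = distal + proximal) hold exactly in floating point.

## Statistics

Unpaired contrasts (cancer vs donor) use the Mann-Whitney U test; paired
contrasts (timepoints or draw sites matched within patient) use the
Wilcoxon signed-rank test on per-patient differences of events/mL;
associations use Spearman's rank correlation, with binary clinical
variables handled by the rank-sum test reporting a signed standardised z
(positive when the second sorted level has larger values).  Significance is
two-sided at α = 0.05, strict; only for significant results are the
one-sided tests run, solely to label the direction.

Exact small-sample nulls are computed by dynamic programming over doubled
midranks (ties supported): the rank-sum distribution over all
subset assignments for Mann-Whitney (used up to n₁+n₂ = 20), and the
positive-rank-sum distribution over all 2ⁿ sign patterns for the signed
rank test (up to n = 20).  Two-sided p doubles the smaller tail, capped
at 1.  Larger samples use the normal approximation with tie and continuity
corrections.  Zero differences are dropped (classical convention; a Pratt
option keeps them in the ranking), and an all-zero sample returns the
degenerate p = 1.  Spearman p uses exact permutation enumeration for n ≤ 7
and the t-approximation otherwise.  No multiple-testing correction is
applied by default (raw p-values are reported); a Benjamini-Hochberg column
is available but never gates the significance flag.

The exact-mode ceiling of 20 rather than a smaller classical cutoff is a
calibration choice: at 10-vs-10 the continuity-corrected normal
approximation rejects noticeably below the achievable exact level (0.043),
while the exact null is cheap to enumerate.

## Embedding

The tSNE operates on 8 standardised columns (channel medians, cell/nucleus
area and eccentricity); standardisation constants are recorded so the
matrix is exactly reproducible.  Perplexity defaults to 30 and is reduced
automatically (with a warning) for small inputs; the seed is fixed.
Density profiles are Gaussian KDEs renormalised to unit area on a shared
grid; categories with fewer than two events or zero variance are flagged
and omitted.  Plots are artifacts; numeric outputs are the test surface.

## What passing tests do and do not show

The generator plants events whose features are drawn from the same laws the
detector assumes: well-separated amplitudes (≥ 5 background sd), elliptical
geometry, Gaussian noise, and rare cells strictly larger than leukocytes.
Passing benchmarks therefore demonstrate that the pipeline's logic —
segmentation bookkeeping, gating, normalisation arithmetic, test
calibration — is correct under controlled conditions.  They do not
demonstrate performance on real slides, where staining variability,
debris, autofluorescence, touching-cell ambiguity and analyst review
dominate, and where marker-negative rare cells need far richer morphometry
to separate from leukocytes.

## Benchmark problem sizes

The benchmark harness (`cytoscout.benchmarks`, driven by
`scripts/acceptance.py` and `tests/test_acceptance.py`) uses: 100 random
small datasets for the exact-test oracle; 20 two-slide samples at 10
events/mL per category for enumeration recovery; 50 rendered 512×512
frames for detection; 500 null replicates (10 cancer vs 10 donor samples,
identical laws including the WBC law) for type-I error; 100 replicates of
16 matched pairs with a 5× planted increase for power; and ~5000 labelled
events for the channel models.  Deterministic reruns are guaranteed by a
single seed hierarchy (`numpy.random.SeedSequence`).
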