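# Methods

This note documents the models behind each module, the parameters that
matter, what the synthetic generators do and do not emulate, and the
design choices made where the design was genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Cardiac-cycle phase analysis

**Model.** One R-R interval of the LV time–volume curve is modelled as a
continuous piecewise-linear function with four segments — isovolumetric
contraction (IVC), ejection, isovolumetric relaxation (IVR), filling —
anchored at the R wave (the first sample is end-diastole, matching a
prospectively gated acquisition). The fit uses the hinge basis
[1, t, (t−τ₁)₊, (t−τ₂)₊, (t−τ₃)₊]; for fixed breakpoints the
least-squares solution comes from 5×5 normal equations assembled from
suffix moment sums, which makes the exhaustive search over all frame-grid
breakpoint triples cheap (all candidates are solved as one batched
linear-algebra call). Physiology enters as hard constraints: ejection
slope < 0, filling slope > 0, each isovolumetric slope smaller in
magnitude than both. Ties in SSE break toward earlier breakpoints, so
the search is deterministic. An optional local refinement
(`refine_levels > 0`) re-searches progressively finer grids around the
optimum; SSE is non-increasing under refinement. The default stays on
the frame grid: the cycle phases are delimited by acquired frames, and
frame-grid breakpoints keep the estimate within one frame of a
ground-truth corner rather than letting noise pull it between frames.

**Degenerate inputs.** A trace with zero amplitude fails immediately.
After fitting, the model-explained amplitude (peak-to-peak of the fitted
curve) must exceed 3× the residual SD; otherwise the curve is reported
as below the noise floor. The model-explained amplitude is used rather
than the raw amplitude because the raw peak-to-peak of a pure-noise
trace is itself ≈ 4–5 noise SDs and would never trip the test.

**EDV/ESV.** Volume is constant during the isovolumetric phases, so EDV
and ESV are estimated as the fitted IVC and IVR plateau levels (the
fitted value at each segment midpoint, i.e. the segment mean). This is
exact on noiseless curves and much less noise-sensitive than the fitted
corner vertices, which inherit the full uncertainty of a breakpoint
placed one frame off.

**Indices.** SV = EDV − ESV, EF = 100·SV/EDV, CO = SV·HR. CI divides CO
by body-surface area from the Meeh allometry BSA = k·m^(2/3) with
k = 9.8 cm²/g^(2/3) by default (overridable); with this k, a CO of
18.3 ml/min at 26.1 g body mass gives CI ≈ 212 µl/min/cm², which is the
self-consistency check the default was chosen by. ER and FR are the
ejection and filling PLR slopes normalised to SV and R-R and reported
×100 (percent of SV per R-R), the scale on which murine values of
~300–500 are conventionally quoted. With biphasic filling, FR uses the
steepest filling sub-slope (a two-segment PLR restricted to the filling
window), which is what a high-frame-rate acquisition resolves as the
early-filling peak. Phase durations are percentages of R-R computed
from the breakpoints, with FT defined as the complement so the four
durations sum to exactly 100.

**E/A.** On a dV/dt series over the filling phase, the two most
prominent local maxima in temporal order are E and A; the ratio is E/A.
If fewer than two peaks exceed a prominence of 10 % of the dV/dt range,
the peaks are reported fused with no ratio — the restrictive-filling
pattern in which E and A merge.

## HARP strain

**Phase extraction.** Per tag direction, the first-harmonic peak nearest
the nominal wavevector (|k| = 1/tag-span) is located in the frame-0
spectrum within a ±20 % search radius and must exceed 5× the median
spectral magnitude. A raised-cosine annular band-pass of radius |k|/2
centred on the peak (standard HARP practice: it excludes DC and the
higher harmonics) is applied to every frame; the phase of the inverse
transform is the harmonic phase. The conjugate −k harmonic is extracted
with the mirrored window.

**Peak combination.** The phase gradients of the +k and −k harmonics
are averaged (with the −k gradient negated). For a noiseless symmetric
spectrum the two carry the same information; combining them cancels the
asymmetry bias a band-pass window can introduce when the spectrum is
not symmetric about the peak.

**Strain reconstruction.** Wrap-aware finite differences (1-pixel
forward/backward differences each re-wrapped into (−π, π], then
averaged) give ∇Φ without global unwrapping; this tolerates phase steps
up to π per pixel, i.e. tag periods down to 2 pixels. With
G = ∇Φ/(2π) = K·F⁻¹, the deformation gradient is taken relative to the
measured reference frame, F = G⁻¹G₀, rather than the nominal K; the
filter's (small, spatially smooth) bias enters G and G₀ identically and
cancels, and frame 0 has exactly zero strain by construction.
Engineering strains along the radial/circumferential unit vectors about
the LV centre are Err = √(1+2eᵣᵀEeᵣ) − 1 (×100 %), with
E = (FᵀF − I)/2. Strains are engineering (stretch − 1), the convention
on which murine radial ≈ +20 % / circumferential ≈ −17 % magnitudes are
reported. Pixels where det F leaves [0.2, 5] over more than 10 % of the
mask trigger an unreliable-deformation warning.

**Segments and indices.** Eight 45° sectors starting at 90° (anterior),
counterclockwise; sector means per frame; the global curve is the
area-weighted sector mean (identical to the mask mean). Per-cycle
indices on a segment-averaged curve: the dominant deformation sign is
the sign of the largest-|·| strain; Es and Epost are dominant-signed
extrema over [0, end-systole] and [end-systole, 1] — the end-systolic
instant belongs to both windows, so a curve peaking exactly at
end-systole has Epost = Ees and PSI = (Epost−Ees)/Emax = 0; Emax is
max|strain| over the cycle; TpeakSI is the cycle fraction of the
|strain| maximum. Strain rates are centred finite differences of strain
vs cycle fraction (%/R-R); SRmax is the dominant-signed rate extremum in
systole, SRe/SRa the opposite-signed extrema in the first/second half of
diastole, SS the largest opposite-signed strain excursion during systole
(the pre-shortening stretch). With no cycle fit supplied, end-systole
defaults to the global strain-extremum time. Fewer than 3 diastolic
samples leave the rate indices undefined (flagged), not extrapolated.

## Ageing transcriptome

**TMM.** The reference sample is the one whose 75th percentile of
library-scaled counts is closest to the mean such percentile. Per
sample, genes positive in both sample and reference contribute
M = log2 ratio and A = mean log abundance; a two-sided 30 % trim on M
and 5 % on A precedes a precision-weighted mean of M (weights from the
binomial delta-method variance); the factor is 2 to that mean, and
factors are rescaled to geometric mean 1. cpm uses factor-adjusted
library sizes. The implementation follows the published algorithm; the
test suite cross-checks it against the edgeR reference implementation
through Rscript on a small matrix.

**Filter.** A gene is kept iff some genotype×age group has cpm > 0.5 in
strictly more than 3 of its samples ("more than 3" is read literally;
both the threshold and count are parameters).

**Differential expression.** Deliberately simple, because the
classification layer — not the DE fit — is the analysis of interest
here: logFC is the difference of group means of log2(cpm+0.5); p-values
are two-sided Welch t with BH adjustment per comparison; DEG means
|logFC| > 1 and adjusted p < 0.05, both strict inequalities. Genes with
vanishing Welch variance get a 1e-12 variance floor and a flag. Any
externally produced table with `logFC`, `adj_p`, `is_deg` columns can be
slotted into the classifier instead. The log offset 0.5 is the common
convention avoiding log 0; its side effect — attenuating fold changes of
weakly expressed genes — is why the generator plants effects only on
expressed genes (below).

**Classification.** With per-age DEG sets of the wild-type
age-vs-youngest comparisons (6, 8, 10, 12, 14 months required),
aged-only = DEG(14) minus the union of younger sets, ageing = DEG(14)
intersected with that union; cardiac-ageing is their union, i.e.
DEG(14) itself. The partition object enforces disjointness on every
construction. The same function applies unchanged to over-represented
process term ids per age group. The contribution fraction of a HF DEG
list is 100·|cardiac-ageing ∩ list|/|list|; an empty list is undefined
(NaN, warned), not zero.

**ORA.** One-sided Fisher exact enrichment = hypergeometric upper tail
P(X ≥ overlap), BH across terms; the over-represented flag uses the
BH-adjusted p < 0.05 by default (`use_adjusted=False` switches to raw p,
since published threshold wordings are sometimes ambiguous between the
two).

**PCA.** Per gene: mid-ranks across samples → inverse normal transform
Φ⁻¹((r−0.5)/n) → standardisation; sample scores from the SVD of the
centred samples×genes matrix. Rank normalisation makes scores invariant
to any monotone per-gene transform of expression. Constant genes carry
no rank information and are dropped with a warning.

## Histomorphometry

Components are 8-connected; axes come from the second central moments
(ellipse-equivalent); the aspect ratio classifies the cutting plane:
transverse < 1.5 ≤ oblique < 3 ≤ longitudinal. These thresholds are an
operational choice — source descriptions of such classes rarely define
them — and are exposed as a parameter. Lumina are enclosed background
holes of a component (or the part of a provided lumen mask inside the
filled component). The nearest-capillary distance is edge-to-edge
between boundary pixels (a KD-tree per component), restricted to
oblique+transverse components, averaged over components; "smallest
distance between capillaries" is read as gap distance, not
centroid-to-centroid (switchable by using the per-component table
directly). Fibrosis is pixel counting: 100·collagen/(collagen+myocardium),
with overlapping masks rejected. All areas scale as pixel-size² and
distances as pixel-size.

## Assays

ACE activity applies its defining formula exactly; Y defaults to 33.33
(plasma) or 10 (tissue) and is overridable for other dilution
protocols. The kinetic slope is plain OLS with standard error;
linear-range trimming exists but is off by default, because the assay
protocol records the simple linear slope. Flow responses are the
subtraction/ratio definitions; a reserve below 1 is flagged, not
rejected.

## Synthetic data

All generators are pure functions of their config; the single seed is
split with `numpy.random.SeedSequence.spawn`, one child stream per
purpose, so e.g. adding noise never changes which genes are planted.
Truth records serialise to JSON and round-trip losslessly.

* **Time–volume curves** — piecewise linear with configurable EDV/ESV,
  phase fractions and frame count; defaults emulate a healthy young FVB
  mouse (EDV 53 µl, ESV 15 µl, R-R 123 ms, fractions 10/30/25/35 % of
  R-R, 60 frames, 1 µl noise). Optional biphasic filling: dV/dt is two
  triangular pulses (E then A), each spanning half the filling window,
  with peak heights rescaled by a common factor so the fill integrates
  exactly to SV — the E/A ratio is preserved exactly and recorded in the
  truth.
* **Tagged stacks** — frame 0 is the product of two 1-D periodic tag
  profiles (raised-cosine-squared lines, 0.6 mm period, 0.2 mm width on
  a 30 mm/192-pixel FOV); later frames advect the pattern by the
  configured deformation (identity, translation, per-axis uniform
  stretch, analytic radial profile) ramped linearly across frames and
  applied to material coordinates about the image centre. The profile
  is synthesised from its Fourier series truncated at the acquisition
  Nyquist (with headroom for compressive deformations): a real scanner's
  k-space coverage imposes exactly this truncation, and it keeps the
  sampled phantom alias-free so its harmonics are spectral deltas.
  Deformations that fold (non-positive Jacobian) are rejected at
  construction. No MR physics beyond that: no relaxation, no tag
  fading, no k-space noise correlations.
* **Count matrices** — negative binomial with variance μ + φμ²
  (gamma–Poisson sampling), per-gene baseline abundances lognormal
  (σ = 3, so roughly the realistic minority of the 54,532-gene reference
  is detectably expressed), lognormal library sizes around 2×10⁷, and
  named planted sets receiving 2^logFC mean shifts in chosen
  genotype×age groups. Defaults emulate the study design: FVB and
  Tgαq*44 at 4–14 months, n = 5 per group (per-group sizes of the
  original 50-sample design are not public; n = 5 is this package's
  choice), with aged-only / ageing / persistent-HF / age-specific-HF
  sets of 50 genes at logFC 2 and dispersion 0.05. Planted genes are
  drawn from genes with baseline cpm ≥ 5: an effect planted on an
  undetectable gene could never be recovered and would not constitute
  meaningful ground truth.
* **Histology masks** — non-overlapping ellipse annuli placed by
  rejection sampling (bounded retries, then an error), aspect ratio
  drawn per orientation class, optional concentric lumina; collagen is a
  Gaussian-smoothed noise field thresholded within the tissue to the
  target fraction, with threshold ties resolved pixel-by-pixel so the
  painted fraction is exact to rounding. Truth records per-component
  class, areas and nearest edge-to-edge distances (computed from the
  painted pixels at generation time).
* **Kinetic traces** — a line plus Gaussian noise.

What passing tests on these phantoms shows — and does not. The phantoms
have exactly the statistical structure each stage assumes (piecewise
linearity, a clean tag spectrum, NB counts, ellipse capillaries), so the
tests demonstrate correctness of the computations, sensitivity to noise
of the prescribed magnitude, and exact unit/invariance behaviour. They
do not demonstrate robustness to model violations of real data:
through-plane motion and tag fading in MRI, batch and library-prep
effects in RNA-seq, segmentation errors and touching capillaries in
histology.

## Problem sizes

Module and acceptance tests run at the study's stated geometry where it
is cheap (192×192 tagged frames, 60-frame cycles, the full 54,532-gene
filter construction) and at reduced scale where only statistical
behaviour matters (4,000-gene chain-recovery runs, 100-seed cycle
batches); the complete suite finishes in well under a minute per module
on one core.

## Known limitations

* The DE engine is a simplified stand-in; no empirical-Bayes moderation,
  no design matrices with batch terms. DEG counts from real data will
  differ from a limma-voom analysis; the classifier consumes either.
* HARP here assumes two nominally orthogonal in-plane tag directions,
  small in-plane motion between adjacent pixels (≤ π phase step), and no
  through-plane motion; there is no displacement tracking and no 3-D
  strain.
* The PLR model fixes four segments; a fused E/A filling wave is still
  fit by one filling segment (its E/A handling lives in the peak
  detector, which reports fusion rather than a ratio).
* Orientation-class thresholds and the edge-to-edge distance convention
  in morphometry are operational definitions; absolute class
  percentages are not comparable across different conventions.
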