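# Methods

This note documents the models implemented in `mirmsi`, the defaults and
why, what the synthetic phantoms do and do not emulate, and the numerical
choices a maintainer would want to know.

## Hyperspectral preprocessing

MIR cubes are rows × cols × bands absorbance (or transmittance) images on a
strictly increasing wavenumber axis, by default 950–1800 cm⁻¹ at 4 cm⁻¹
(213 bands). Pixel centers sit at integer indices; physical position is
index × pixel size (µm), row-major with the origin top-left.

**Baseline.** Asymmetric least squares (Whittaker smoother with asymmetric
weights): minimise Σ wᵢ(yᵢ−zᵢ)² + λ‖Δ²z‖², with wᵢ = p above the current
baseline and 1−p below, iterated a fixed number of times. Defaults
λ = 10⁶, p = 0.01, 10 iterations — the standard setting for tissue
absorbance baselines at this sampling. A fixed iteration count (not a
convergence tolerance) keeps runs bit-reproducible. The linear system is
solved with a sparse second-difference penalty (`scipy.sparse`); a dense
textbook implementation serves as the oracle in the tests. ALS is invariant
under additive constants and reproduces linear ramps to <0.1 % of range.

**Derivatives.** With respect to wavenumber, either central differences on
the uniform grid (one-sided at the ends) or a Savitzky–Golay filter
(window 7, order 3 by default — the usual choice for second derivatives of
tissue spectra). Derivative cubes are treated as unit-less downstream; only
spectral shape matters for segmentation.

**Transmittance.** A = −log₁₀(T). Non-positive transmittance values (noise
in near-opaque pixels) are clamped to 10⁻⁶ with a warning; the choice only
affects pixels that carry no usable signal anyway.

**Band selection.** Requested wavenumbers snap to the nearest grid band
within a tolerance of half the grid spacing (inclusive). This matters
because several canonical features (988, 1548, 1656, 1740 cm⁻¹) fall
exactly between the 4 cm⁻¹ grid points; they snap to the adjacent band,
which carries essentially the same band intensity given 10–18 cm⁻¹ band
widths.

## Segmentation

Tissue/background: a two-component 1-D Gaussian mixture on the mean amide
intensity (1548 + 1656 cm⁻¹); the component with the higher mean is tissue.
A constant image raises a degenerate-mixture error rather than returning an
arbitrary split.

Feature-selective k-means runs on the masked pixels of a reduced cube
(hand-picked wavenumbers per use case), k-means++ initialisation under an
explicit seed, 10 restarts. Labels are canonicalised by descending cluster
size so the partition, not the arbitrary k-means ordering, is the output.
Per-band standardisation over masked pixels is on by default (switchable);
the features in a reduced derivative cube can differ by an order of
magnitude in scale, and unstandardised distances would let one band
dominate. The cluster count is chosen by maximising the Calinski–Harabasz
score over k = 2…10 by default, ties toward smaller k.

Z-score maps use the reference region's mean and population SD; this is the
representation used for box-plot comparisons of lipid accumulation between
imaging modalities.

## Small-object detection

Mean feature images (pixelwise mean over selected bands, min–max rescaled
to 8-bit) are thresholded, restricted by a mask (e.g. a donut following the
tissue outline, computed from the Euclidean distance transform of the
tissue mask), and decomposed into 8-connected components. Components pass
if min ≤ area ≤ max and ellipse-equivalent eccentricity (from central image
moments) ≤ 0.94. Defaults: threshold 45 (the midpoint of the 30–60 8-bit
range typical for glomeruli at 4.66 µm pixels), area 50–1000 px. Components
touching the restriction-mask border are retained. Raising the threshold
can only remove objects (monotonicity is a tested invariant).

Concordance between two object sets (e.g. MIR-detected vs MSI-detected
glomeruli) uses greedy largest-overlap matching with a ≥1-px overlap rule
and reports centroid offsets in µm.

## ROI transfer

Registration: SimpleITK affine registration with Mattes mutual information
(32 bins), linear interpolation, 3-level multiresolution (shrink 4/2/1,
smoothing 2/1/0), regular-step gradient descent (300 iterations, min step
10⁻⁶). Dense metric sampling is the default, which makes the optimisation
deterministic irrespective of the seed; seeded random sampling is available
for large images. A final sanity check requires the optimised metric to
beat the initial (centered) transform, otherwise the registration errors
out with both metric values. On phantom pairs with |shift| ≤ 20 px and
|rotation| ≤ 10°, translation is recovered with sub-pixel error (measured
at the rotation center) in ≥95 % of seeded trials.

Masks are resampled nearest-neighbour (labels stay crisp); intensity images
use linear interpolation; point sets are mapped exactly through the 2×3
matrix.

Refinement order: small-hole removal → erosion (disk radius = the erosion
factor, bound to the 4.66 µm reference grid) or dilation by
⌈n_MALDI × step/pixel⌉ pixels → optional re-opening of interior holes whose
area is at or above the small-hole threshold, so donut-shaped measurement
regions (medulla rings) keep their topology. A zero-parameter config is the
identity; erosion that erases the ROI raises.

Polygons come from marching squares at level 0.5, one polygon per
component. Marching squares truncates right-angle corners by ~0.7 px, so
before Douglas–Peucker simplification short corner-cut edges are replaced
by the intersection of their neighbouring segments, and exactly collinear
vertices are dropped afterwards; an axis-aligned square therefore
simplifies to its 4 true corners with exact area. JSON is the canonical
acquisition export (schema: rois with vertex lists in µm, the teach affine,
the MALDI step); the XML dialect is a documented look-alike with integer
pixel coordinates — the vendor format is proprietary and bit-exactness to
an undocumented format would be untestable.

## Lipid registry

Masses depend only on total composition n:d;Ok — the sphingoid/FA split is
annotation, resolved by on-tissue MS², never an input to MS¹ masses.

Building blocks (residue formulas, water of condensation already removed):
hexose C₆H₁₀O₅, HexNAc C₈H₁₃NO₅, NeuAc C₁₁H₁₇NO₈, sulfation SO₃, phosphate
HPO₃, phosphoethanolamine C₂H₆NO₃P. The ceramide core is
C_n H_{2n+1−2d} N O_{k+1} (d counts C=C only; the amide carbonyl adds one O
and one degree of unsaturation); the lyso (sphingoid-only) core is
C_n H_{2n+3−2d} N O_k. Heads: SM4 = Hex+SO₃; SM3 = 2Hex+SO₃;
SM2a = 2Hex+HexNAc+SO₃; SM1a/SM1b = 3Hex+HexNAc+SO₃ (positional isomers —
identical formulas, distinguished only by annotation); SB1a adds a second
sulfate; GM3 = 2Hex+NeuAc. Glycerophospholipids are assembled from
glycerol + HPO₃ + head alcohol (−H₂O for the phosphodiester) + fatty acids
(−H₂O per ester); plasmalogens (PE-P) replace one ester by a vinyl ether,
i.e. the diacyl formula minus one oxygen, with d counting non-vinyl double
bonds.

Atomic masses and isotope abundances are frozen in `mirmsi.constants` so
every theoretical m/z is bit-stable. Adduct m/z keeps the electron ledger
explicit: a 1− anion is M − m(H) + m(e) = M − m(proton). The internal
standard SM4 35:1;O2 (C₄₁H₇₉NO₁₁S) computes to 792.530107 at [M−H]⁻, which
doubles as a self-check of the whole block table.

Isotope envelopes use the unit-mass (nucleon-shift) approximation:
per-element abundance polynomials convolved by exponentiation-by-squaring,
normalised to the monoisotopic peak. That is sufficient for intensity
thresholds; it does not model fine structure.

The theoretical sulfatide space enumerates chains 32–46 with double bonds
0–3 for the ;O2/;O3 series and 0–1 for ;O4 (150 species) plus six lyso
compositions per subclass (156 each, 936 over six subclasses). The six lyso
identities are a package convention (bases 18:1;O2, 18:0;O2, 18:1;O3,
18:0;O3, 18:0;O4, 20:1;O2), configurable. SB1a defaults to the
[M+Na−2H]⁻ adduct, as bis-sulfated species ionise sodiated; configurable.
Every subclass contains near-isobar pairs closer than 0.05 Da (e.g.
848.556/848.593) — the reason ion mobility is needed at all, and a tested
invariant of the enumeration.

## TIMS peak quality

A target peak is **non-clean** (qTOF rule) if any other peak within
±1.1 Da exceeds the intensity of the target's first isotopologue; the M+1
reference is computed from the formula by default (measured M+1 can be
supplied). In TIMS mode the interferent must also lie within ±0.005 Vs/cm²
of the target mobility. Peaks matching the target's own isotope envelope
within 5 ppm are never counted as interferents — the envelope is part of
the target, not an interference. The implementation is vectorised; the
tests hold it against a plain-loop exhaustive oracle on 1000 random frames.

EIMs are intensity histograms over mobility (default bin 0.001 Vs/cm²) for
an m/z window. Gaussian deconvolution is nonlinear least squares of a
Gaussian sum, initialised from the largest local maxima with FWHM-derived
widths; when fewer maxima exist than requested components, surplus
components share the strongest peak with split amplitude, which makes the
over-parameterised case converge to a recognisably degenerate fit (collapsed
amplitude or coincident means) instead of failing. Fits are deterministic
for a fixed initialisation.

Isolation-window purity uses the analytic Gaussian integral per component;
shares are normalised to the window total and the target/interferent ratio
is target area over the summed area of all other components (both shares
and ratio are returned, since "ratio" is ambiguous in figure legends).
Narrowing all peak widths strictly increases the ratio — the analytic
monotonicity counterpart of the experimental 2–3-fold AUC-ratio gains when
quadrupling the ramp time.

Scheduling is classic interval partitioning with a capacity cap: candidates
sorted by mobility-interval start are assigned to the lowest-indexed batch
with room and no overlap (≤15 per batch). Without a binding cap this is the
optimal interval colouring; with the cap the tests verify it stays within
one batch of the brute-force optimum on small instances. Mobility intervals
default to mean ± 3σ of the fitted component.

**Mobility-resolution model.** Peak sigma follows
σ(ramp) = σ_ref · ramp_ref/ramp (σ_ref = 0.012 Vs/cm² at 120 ms). Only the
qualitative fact that longer ramps resolve what shorter ones cannot is
empirically anchored; the inverse law is this package's modelling choice
and is stated as such.

## Structure–CCS model

The parallel-line model fits CCS(x; g) = a·x² + b·x + c_g by global least
squares with shared a, b and free per-group intercepts (design matrix
[x², x, group dummies], `statsmodels` OLS, covariance from the fit).
ΔCCS(A,B) = c_A − c_B; with replicate ids present the fit runs per
replicate and ΔCCS is reported as mean ± sd across replicates (the
convention of replicate-resolved CCS tables), otherwise the SE propagates
from the parameter covariance (var c_A + var c_B − 2 cov). The shared-slope
linear model and the polymer-style y = b·x^{2/3} + c_g model use the same
machinery for RSS-based model comparison; the linear model is nested in the
quadratic, so its RSS can never be smaller — a tested invariant.

The predictor x is the total chain carbon number. ε̄ is the sign-less mean
of 100·|CCS_exp − CCS_pred|/CCS_exp over pairs matched by shorthand;
unmatched keys are an error, not a silent drop. Cross-platform comparison
is OLS of one platform's CCS on the other over shared species, reporting
slope, intercept, R² and ε̄. Recalibration between gas-flow conditions
divides all off-condition values by the mean off/reference ratio of a
paired reference subset, which zeroes the subset's mean relative deviation
by construction. Mobility→CCS conversion (Mason–Schamp, N₂ drift gas) is
provided as an untested convenience helper; CCS tables are the supported
input path.

## Volcano statistics

Per-feature two-sided t-tests between two groups (Welch by default — equal
variances are not defensible for MSI intensities; pooled variance is a
switch), Benjamini–Hochberg step-up across features, flags for q < α and
fold change ≥ threshold (default 3) in either direction. Fold change is the
ratio of raw-intensity group means with an optional pseudo-count; log₂ is
for plotting. Features with zero variance in both groups get p = 1 with a
warning. Observations should be per-replicate aggregates
(`aggregate_replicates`, median by default); testing pixels directly
pseudo-replicates.

## Synthetic phantoms

Phantom MIR cubes place Gaussian absorption bands (amide I/II at 1656/1548,
CH₂ 1466, ester C=O 1742, sulfogalactosyl 988 cm⁻¹) on labelled geometric
regions: a background tissue disk, concentric ring layers (medulla-like)
and planted elliptical blobs (glomeruli-like; anti-aliased, image-moment
eccentricity convention, placement keeps ≥4 px separation so thresholded
components stay distinct). Additive Gaussian noise, polynomial baseline
drift, explicit seeds; generators are pure functions of their spec. TIMS
phantoms put Gaussian mobility profiles (discretely normalised, so profiles
sum exactly to the species intensity) and formula-derived isotope envelopes
on the 0.80–1.87 Vs/cm² window. CCS phantoms draw from the parallel-line
quadratic with configurable intercept offsets (defaults at the 25–30 Å²
scale of sulfatide head-group differences) and 0.2 Å² noise.

The phantoms emulate spectral contrast, band positions, mobility peak
shapes and homologous-series structure. They do **not** emulate scattering
artefacts (resonant Mie correction is out of scope), matrix
crystallisation, realistic tissue morphology, chimeric MS² spectra or
instrument drift — so passing tests demonstrate correctness of the
algorithms under the stated models, not robustness to every artefact of
real acquisitions.

## Problem sizes used in tests

Phantom cubes are 96–128 px square with the full 213-band axis;
registration phantoms 128×128 over 50 seeded trials; the ΔCCS recovery
study uses 15 chain lengths × 2 subclasses × 4 replicates over 200 seeds;
the clean-rule oracle comparison uses 1000 random 16-peak frames. These
sizes keep the full suite under half a minute on one CPU while leaving
every statistical acceptance margin comfortably wide.

## Known limitations

- The affine registration assumes overlapping content and a roughly
  centered initialisation; it is not a deformable registration and will
  not recover large rotations (>~15°) without a better initial guess.
- The clean-peak rule is deterministic; the manual curation step used in
  practice is replaced by an override input, so borderline verdicts follow
  the rule exactly.
- Isotope envelopes ignore isotopic fine structure and mass defects within
  a nucleon shift.
- The vendor acquisition-file dialect is a look-alike, not byte-compatible
  with any instrument software.
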