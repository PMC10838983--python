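# Methods

This note documents the models, conventions, and numerical choices behind
`perishell`, in the spirit of a statistical package's methods appendix.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Geometry

**Layer construction.** The perilesional band is defined by the Euclidean
distance transform (EDT) of the lesion complement, computed in millimetres
using the voxel size. Layer k (k = 1..10) collects voxels with
(k−1)·2 mm < d ≤ k·2 mm, intersected first with the cortical GM mask and
then cropped to the lesion's hemisphere. The EDT banding is
rotation-invariant, independent of any structuring-element convention,
and exactly reproducible by a per-voxel brute-force distance scan (which
the test suite performs). A compatibility mode (`shell_mode="dilation"`)
instead grows the region by iterated 26-connected binary dilation —
the classical morphological recipe, two 1-voxel iterations per layer on a
1-mm grid — for users who need to match a morphology-based toolchain;
its shells depend on the structuring element and are not oracle-exact,
so EDT is the default. Layers may legitimately be empty (a lesion
abutting a GM boundary) and are returned empty rather than raised.

**Homotopic mirroring.** The contralateral control shells are built
around the lesion mirrored about the midsagittal plane (world x = 0).
Mirroring is implemented as index reversal along the storage axis whose
world direction is dominantly ±x, and requires the grid itself to be
symmetric about x = 0 so every mirrored voxel center lands on a voxel
center; the operation is then an exact involution and preserves voxel
counts. Strongly oblique affines are rejected rather than resampled.
The contralateral shells intersect the *native* contralateral GM (not the
flipped ipsilateral GM): with a symmetric GM mask the two choices
coincide, and with real asymmetric anatomy the native mask is the one the
control regions actually live in.

**Lesion volume.** Normalized lesion volume is
vol_mm³ × 10⁶ / ICV_mm³, log₁₀-transformed for correlation analyses to
tame the right skew typical of lesion volumes.

## Preprocessing

Fixed stage order: discard the first 10 volumes → motion QC (exclude a
subject when any |translation| > 3 mm or |rotation| > 3°, strict
inequalities) → nuisance regression → linear detrend → metric branches.
The nuisance design holds the Friston 24-parameter motion expansion
[R, R_{t−1}, R², R_{t−1}²] (lagged rows zero-padded at t = 0) plus the
white-matter and CSF mask-mean signals — summary signals, not
PCA/aCompCor components. Rank-deficient designs drop collinear columns
with a logged warning; residuals are orthogonal to every retained
regressor. Motion files are 6-column text with rotations **in degrees**;
callers whose realignment tool emits radians must convert.

The temporal filter is an ideal (boxcar) FFT bandpass that keeps bins
with 0.01 ≤ f ≤ 0.1 Hz and zeroes the rest including DC; it is exactly
idempotent. ALFF is computed on the detrended, nuisance-regressed but
**not** bandpassed series — on a bandpassed series the band-amplitude
ratio degenerates to ≈ 1 — while ReHo uses the bandpassed series.

Spatial smoothing is Gaussian with sigma = FWHM/(2√(2 ln 2)) per axis in
mm (6-mm FWHM default, 'nearest' boundary mode, which preserves constant
volumes exactly). The smoothed series feeds the ALFF branch. For ReHo,
pre-smoothing mechanically inflates local rank concordance, so by default
the series enters ReHo unsmoothed (`smooth_before_reho=False` switchable)
and the standardized ReHo map is smoothed afterwards instead, using
mask-normalized smoothing (smooth(values·mask)/smooth(mask)) so
out-of-mask zeros do not bleed into edge voxels.

## Metrics

**ALFF** sums *amplitude* (not power) spectra: numerator over
0.01–0.1 Hz, denominator over 0–0.25 Hz, DC excluded from both (the mean
is already removed by detrending; keeping DC would make the ratio depend
on residual numerical mean). The spectrum is scaled 2/t, though any
per-voxel scale cancels in the ratio. Requires Nyquist ≥ 0.25 Hz
(TR ≤ 2 s). All-zero series yield ALFF 0 with a logged count.

**ReHo** ranks each voxel's series over time with mid-ranks and computes
tie-corrected Kendall's W over the 27-voxel cube. Neighbourhoods are
clipped to the analysis mask (K < 27 at edges) rather than zero-padded,
because padding with constant series manufactures spurious concordance;
K = 1 voxels are undefined and removed from the output mask. Ranking
uses a fast double-argsort path, falling back to explicit mid-ranks (and
accumulating the tie term Σ(g³−g)) only for columns that actually contain
ties — continuous BOLD data essentially never ties, synthetic fixtures
may.

**Standardization** divides by the global in-mask mean; the analysis mask
defaults to the whole-brain mask (GM ∪ WM ∪ CSF ∪ lesion ∪ layers) rather
than GM only. Standardized maps have in-mask mean 1 and are idempotent
under re-standardization. Standardized ALFF and raw ReHo are invariant
to rescaling the input series.

## Statistics

Per layer: two-sided paired t (ipsilateral vs contralateral homotopic
layer mean), Bonferroni threshold family-α/10 = 0.005, strict inequality.
Subjects with an empty layer are dropped pairwise per layer (not
listwise), maximizing n per comparison. Zero-variance differences leave
t undefined and the layer non-significant, with a note. Between-group
comparisons use Student's pooled-variance two-sample t on ipsilateral
means (Welch by flag); only ipsilateral means are compared between
groups, contralateral means remain available in the output tables. The
abnormal extent L is the outermost layer of the contiguous significant
run starting at layer 1 (0 when layer 1 is not significant);
non-contiguous patterns are truncated at the first gap and the full
pattern is reported alongside.

Resection completeness is judged against the group-level extent L applied
to every subject of the group: complete iff every voxel of
lesion ∪ layers 1..L lies inside the subject's resection mask (L = 0
reduces to a lesion-only check). The completeness × seizure-freedom 2×2
table is tested by chi-square without continuity correction, falling back
to Fisher's exact test when any expected cell is below 5; degenerate
margins return an explicit "undefined" result.

The cohort battery is packaged as a model/results pair:
`PerilesionalLayerModel` holds the per-subject layer profiles (and
optional log lesion volumes), `fit()` returns a results object carrying
the per-layer tests, group contrasts, extents, correlations, a
`summary()` table and plotting hooks — the statsmodels idiom, chosen so
downstream code can treat the layer battery like any other fitted model.

## Synthetic cohorts

The generator emulates the structure of a single-site patient study:
2-s TR, 205 volumes (first 10 discarded), masks and series on one 2-mm
isotropic grid, one cortical lesion per cohort. Anatomy is a
midline-symmetric ellipsoidal GM shell (normalized radius 0.8–1.0 of
semi-axes at 45% of the field of view) over a CSF shell (0.65–0.8) and WM
core, hemispheres split at x = 0, and a spherical 8-mm lesion embedded in
right-hemisphere GM at 0.9 of the +x semi-axis — placed so the full 20-mm
band clears the midline (validated, with an explicit error otherwise).

Each brain voxel's series is a low-frequency (0.01–0.1 Hz) signal —
random-phase sinusoids at the in-band DFT frequencies, i.e. spectrally
flat in-band noise — mixed from a component shared within the voxel's
3×3×3 block (weight w, default 0.6) and an independent component
(√(1−w²)), scaled by an amplitude field a_v (default 1), plus unit-SD
white noise, a small linear drift, and a global nuisance signal that
dominates the WM/CSF compartments so mask-mean regression can remove it.
ALFF is controlled by a_v and ReHo by w. Deficits multiply a_v by
(1 − δ_A·profile(d)) and w by (1 − δ_R·profile(d)) within ipsilateral GM
at lesion distance d < D (step profile by default; a linear taper is
available). Because δ_A also lowers the signal-to-noise ratio inside the
deficit zone, a pure amplitude deficit slightly depresses ReHo as well —
real pathology is similarly entangled, and the two are separable in
simulation by setting one fraction to zero.

Two deliberate symmetry constraints make the null exactly fair: the
anatomy is mirror-symmetric, and the x-partition of the shared-signal
blocks counts outward from the midline, so a voxel and its mirror have
identical sharing structure. (With grid-aligned blocks the two sides
differ in how smoothing aggregates shared vs independent signal, which
measurably biases inner-layer ipsi-vs-contra comparisons even with no
deficit.)

Between-subject variability is a smooth lognormal modulation of a_v
(white noise smoothed at 12-mm correlation length, sd 0.12 on the log
scale) — enough that layer means genuinely vary across subjects and
small smoothing-spillover effects at the deficit edge do not reach
significance at n = 15, while a 40% deficit does, with paired effect
sizes well above d = 1.5. Motion traces are small random walks
(QC-passing) unless a spec lists QC-fail subjects, who get a 3.5-mm
spike. Determinism: one seed yields one cohort via
`numpy.random.SeedSequence(seed).spawn`, PCG64 streams split per subject,
so subject k is reproducible independently of cohort size.

The mapping from mixing weight w to expected ReHo has no closed form
under this model; it was calibrated empirically once (three seeds per
weight, default noise settings) and frozen as a package data table
(`perishell/data/reho_weight_calibration.json`), interpolated by
`expected_reho()`.

**What the generator does not emulate:** hemodynamic response shape,
cardiac/respiratory physiological noise, spatial autocorrelation beyond
the block structure, registration error, scanner drift nonlinearity,
multi-site effects, or asymmetric anatomy. Passing recovery tests
therefore show that the pipeline correctly measures the kind of
distance-dependent amplitude/synchrony deficit it targets under clean
alignment — not that it is robust to real-world confounds.

## Monte-Carlo problem sizes

The calibration and recovery checks are sized to run on one CPU in a few
minutes each:

* **Null calibration:** 50 replicates of a 15-subject zero-deficit group
  on a 48×48×32 grid (t = 100), 500 layer-tests total; the paired-test
  rejection rate at α = 0.005 must stay ≤ 1%.
* **Extent recovery:** 25 replicates per condition on a 40×40×28 grid,
  δ_A = 0.4, D = 12 mm (true extent 6 layers) and D = 4 mm (2 layers);
  the recovered extent must be within ±1 layer in ≥ 90% of replicates.
  The ±1 tolerance absorbs the 6-mm kernel's spillover into the first
  layer beyond the deficit edge.
* `scripts/acceptance.py` uses 20 null replicates and 12 recovery
  replicates per condition to stay well inside its runtime budget while
  reporting the same quantities.

## Degenerate inputs and tie-breaks

Empty lesion or analysis mask: error. Empty individual layers: returned
empty, NaN layer means, flagged, dropped pairwise in tests. Band edges
compared with 1e-12 absolute tolerance so bin-aligned frequencies are
included deterministically. Alignment checks use 1e-6 absolute tolerance
on affines and voxel sizes. Distances exactly on a band boundary belong
to the inner layer (d ≤ k·2 mm). Masks are stored as uint8, maps as
float32; heavy linear algebra runs in the series dtype with the
pseudoinverse computed in double.

## Known limitations

Completeness classification uses the group-level extent, not per-subject
voxelwise maps — mirroring how such analyses are reported, but blunt for
heterogeneous groups. The layer approach assumes the lesion mask is
correct; segmentation error propagates directly into layer geometry.
Real data must arrive pre-aligned in a symmetric space (the package
performs no registration), and hemisphere labels must be consistent with
the affine's left-right axis.
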