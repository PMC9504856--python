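# Methods

## Scope and data model

`aquaspec` analyses diffuse-reflectance NIR spectra of polymer–water
mixtures on a shared, uniformly spaced wavenumber grid (default
10,000–4000 cm⁻¹ at 2 cm⁻¹; all reference wavenumbers used by the anchored
subtraction are even, so they fall on grid points). Intensities at a quoted
wavenumber are always read from the nearest grid point, with exact ties
resolved toward the lower wavenumber — matching discrete instrument
sampling rather than interpolating. Standard deviations are sample
(n−1) throughout. Spectra below 4500 cm⁻¹ are generated and carried along
but should be treated as qualitative: in real measurements of these systems
the region suffers complete absorption for several matrices.

## Preprocessing

Reflectance is converted as A = log₁₀(1/R). The "linear offset correction"
is implemented as subtraction of each spectrum's minimum over a
configurable region (default: the full grid). This choice preserves every
band shape and all point-to-point differences, makes spectra directly
comparable, and is idempotent; whether the original vendor pretreatment
instead fits a sloped line through two anchor points is not documented
anywhere we could verify, so the simplest shape-preserving variant was
chosen. SNV standardizes each spectrum to mean 0, sd 1. Reflectance-mode
sets are auto-converted to absorbance (with a log record) on entry to any
analysis.

## Synthetic spectra generator

The generator exists because no measured spectra of this design are
publicly deposited; it emulates the *structure* of such data so that every
downstream stage has a ground truth. A mixture spectrum is

    A(ν; w) = (1 + κ·w) · Σ_b G(ν; c_b, Γ_b, a_b)          (polymer bands)
            + Σ_{band ∈ {ot, cb}} [ (r + a_band·w^γ_band) · G(ν; c_band(w), Γ_band)
                                    + s·a_band·w^γ_band · G(ν; c_band(w) − Δ, Γ_band) ]
            + baseline + ε(ν)

with G a Gaussian of given center, FWHM and peak amplitude (Lorentzian
optional; real NIR bands are asymmetric, but no line-shape information is
available to fit, so symmetric profiles are used). The parts:

* **Polymer bands** sit at published group-frequency positions for each
  matrix (C–H first/second overtones, 2ν+δ combinations, N–H and O–H
  overtones), including a band at each matrix's difference-spectroscopy
  anchor wavenumber. κ is a small relative intensity coupling to water
  content (0.05–0.45, growing with hydrophilicity), reflecting the observed
  sensitivity of polymer bands to moisture.
* **Water bands.** Each of the overtone (ot) and combination (cb) bands has
  its center move *linearly* in w between per-matrix endpoints quoted at
  1 % and 10 % w/w, clipped outside that range; only the endpoint pairs are
  known, so the linear trajectory is the minimal assumption. The
  water-driven amplitude is a·w^γ on top of a residual bound-water
  amplitude r present at nominal dryness (r = 0 for PTFE, rising to
  0.02 AU for cellulose).
* **Bulk-like shoulder.** Self-associated water domains appear as one extra
  band Δ = 380–450 cm⁻¹ red of each main water band with weight s
  (0.55 for PTFE down to 0.05 for cellulose). The shoulder geometry was
  sized analytically so that the summed band's argmax stays within one
  2 cm⁻¹ grid step of the nominal center: to first order the peak shift is
  (s·driven/A)·Δ·exp(−Δ²/2σ²), and all library profiles keep this below
  one grid step at every design concentration. Matrices reported to host
  two distinct bulk-like domains could carry two shoulders; the default
  library uses one.
* **Response exponents γ.** With strictly linear per-band amplitudes every
  channel's concentration trajectory is proportional to every other's and
  the asynchronous 2D-COS map vanishes identically. Real systems show
  lead/lag structure between the two water bands, so each band carries an
  exponent γ (amplitude ∝ w^γ, default 1 = linear): γ_ot < 1 for the weakly
  hydrophilic PS/PVC (overtone responds early, i.e. leads) and γ_ot > 1
  for hydrophilic matrices (overtone lags), γ_cb = 1 everywhere. This is
  the package's own minimal mechanism for the reported sequential-order
  asymmetry, not a fitted quantity.
* **Noise.** A constant baseline offset drawn once per preparation
  (sd 0.01 AU, shared by that preparation's repeated measurements — the
  offset correction removes it exactly, which is why replicate scatter is
  dominated by the additive term) and i.i.d. additive noise per point
  (sd 3·10⁻⁴ AU, typical of accumulated FT-NIR scans). All draws derive
  deterministically from a master seed via per-(profile, concentration,
  preparation) seed sequences.

All amplitudes and widths are implementer-chosen, versioned model
parameters (`src/aquaspec/data/profiles.yaml`), not measurements. The
default design is 6 water fractions {0, 1, 3, 5, 7, 10 % w/w} × 6
preparations × 3 measurements per matrix.

**What the generator does not emulate:** diffuse-reflectance radiative
transfer and particle-size/scattering effects, band asymmetry, water
activity equilibria, instrument line-shape and wavelength error, and the
complete-absorption saturation below 4500 cm⁻¹. Passing tests therefore
demonstrate the correctness and internal consistency of the algorithms on
spectra with the reported *structure*, not instrument-level validity on
real measurements.

## Difference spectroscopy

The water component at each concentration is mixture − f·(pure polymer)
with f the intensity ratio at the polymer's reference wavenumber (PTFE
5944, PP 5796, PS 5952, PVC 5828, POM 5968, PA 5828, lignin 5964, chitin
5800, cellulose 5604 cm⁻¹); the polymer component is mixture − f·(pure
water) anchored at the water combination-band maximum, 5180 cm⁻¹. The same
mixture/reference ratio convention is used in both directions. Anchors are
read from offset-corrected spectra (consistent with the stated
preprocessing order). Negative difference values are preserved — they
carry the signature of hydrogen-bonded species losing intensity. The
difference is exactly zero at the anchor grid point by construction.
A PTFE-with-water-layer sample is handled as a plain averaged set with a
single 10 % level; no layered-sample optics are modelled. Band shifts are
reported as the discrete argmax positions at the lowest and highest
nonzero concentrations, ties toward the lower wavenumber.

## NIPALS PCA and PLS1

Both use the NIPALS iteration (tolerance 10⁻¹⁰ on the score-vector change,
max 500 iterations — double-precision practice) with successive deflation;
PCA loading signs are fixed so the largest-magnitude element is positive.
Non-convergence yields a warning and a partial model rather than an error.
PCA leave-one-out reconstruction PRESS per component count is reported for
inspection only, never used for automatic selection. PLS regression
coefficients are accumulated per cumulative factor count via
b = W(PᵀW)⁻¹q; cumulative explained X-variance per factor is
Σ‖t_a‖²‖p_a‖²/‖X_c‖². Leave-one-out cross-validation refits the entire
model (including centering) on each n−1 subset; by default each measured
spectrum is left out individually, with an option to leave out whole
preparations instead (the replicate structure makes per-spectrum LOO
slightly optimistic; both are exposed). Outliers are flagged at
|CV residual| > 3·RMSECV.

## Median-linkage clustering

Agglomeration under the Lance–Williams recursion for median linkage
(WPGMC) on squared Euclidean distances, d(k, i∪j) = d(ki)/2 + d(kj)/2 −
d(ij)/4, with merge ties broken toward the smallest cluster indices. Merge
heights are therefore squared distances between cluster midpoints (scipy's
`median` linkage reports their square roots; the test suite cross-checks
against both scipy and a brute-force midpoint recomputation). Flat labels
come from cutting the merge sequence at the requested cluster count.

## MCR-ALS

X ≈ C·S is solved by alternating non-negative least squares with k = 2
components (the chemical rank of a binary mixture). The averaged pure
polymer and pure water spectra enter as *initial estimates* of S, not as
equality constraints — resolved curves are expected to deviate from the
pure spectra, which equality constraints would forbid. Non-negativity is
enforced by the solver itself (exact analytic active-set solution for
k = 2, scipy NNLS otherwise), never by post-hoc clipping. Iteration stops
when the relative change of the lack of fit √(Σr²/ΣX²) falls below 10⁻⁸
(max 200 iterations). The bilinear model has intrinsic scale ambiguity,
so resolved spectra are compared after SNV; absolute resolved intensities
are not interpretable.

## 2D correlation spectroscopy

Spectra averaged per concentration and ordered by ascending water fraction
(0–10 % inclusive) are the perturbation series; the mean dynamic spectrum
is the default reference. Φ = X̃ᵀX̃/(m−1) and Ψ = X̃ᵀNX̃/(m−1) with
N_jk = 1/(π(k−j)), zero diagonal. The 1/(m−1) normalization makes Φ's
diagonal the per-channel sample variance; conventions with 1/m differ only
by a constant factor. Ψ is symmetrized to exact antisymmetry and zero
diagonal to remove floating-point residue. Synchronous maps are intended
to be rendered on a shared intensity scale across matrices, asynchronous
maps individually scaled.

## Aquagrams

For one matrix's averaged, SNV-treated concentration spectra, wavenumbers
of interest are selected per water region (overtone 7300–6500, combination
5400–5000 cm⁻¹) as the union of the n = 8 highest across-concentration
variance grid points (n configurable; no count is prescribed anywhere,
8 per region gives readable charts) and the local maxima of the mean
spectrum, deduplicated and sorted descending. The normalized absorbance
An_λ = (A_λ − µ_λ)/σ_λ uses µ/σ computed across that matrix's averaged
spectra, 0–10 % inclusive (averaged rather than replicate-level spectra —
the standardization population is a documented choice). The radar layout
lists overtone-region axes first, then combination-region axes, one closed
trace per concentration in ascending order.

## Pipeline

`run_pipeline` validates its configuration strictly (unknown keys are
errors; simulation requires a master seed), runs the requested stages, and
writes a manifest (config echo + versions) sufficient to reproduce the run
plus a machine-readable summary (shift ranges, R²_cv, explained variances,
MCR recovery cosines, 2D-COS cross-peak signs). Identical configurations
produce byte-identical summaries.

## Problem sizes

The reference designs used by the test suite and the acceptance script are
one matrix × 6 concentrations × 6 preparations × 3 measurements
(108 spectra × 3001 channels) for the regression figures and single-
replicate noise-free series for the deterministic round trips; these are
the study's own design dimensions and complete in seconds on one CPU.

## Known limitations

* The generator's parameter magnitudes are plausible but invented; only
  band positions, shift endpoints and the design layout are anchored to
  reported values.
* Difference spectroscopy assumes additivity in absorbance; the polymer
  direction inherits all the distortions the method is known for when
  water interacts strongly with the matrix.
* MCR-ALS resolves rotational/intensity ambiguity only through
  non-negativity and the reference initialization.
* JCAMP-DX support covers single-spectrum AFFN `XYDATA=(X++(Y..Y))` blocks
  only (no compressed DIF/DUP forms).
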