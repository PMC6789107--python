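# Methods

This note documents the models implemented in `cslim`, the parameter
choices that matter, what the synthetic phantoms do and do not emulate,
and the numerical conventions.

## Interferometric forward model and its inversion

The sample is modeled as a thin, dispersionless phase object: the field
behind it is `U(x, y) = exp(i φ(x, y))` for unit plane-wave illumination.
The incident (unscattered) reference is the illumination itself,
`U_i = 1`, and the scattered component is `U_s = U − 1`. The spatial
light modulator imparts a shift φ_k ∈ {0, π/2, π, 3π/2} between the two,
and the camera records the two-beam interferogram

    I_k = A² + B² + 2AB·cos(Δφ + φ_k),

with `A` the detected incident amplitude, `B = |U_s|`, and
`Δφ = arg U_s`. A bright-field objective does not attenuate the incident
beam the way a phase-contrast ring does, so an equivalent attenuation
factor α (calibrated value 3.4) is carried numerically: the detected
incident amplitude is `A = 1/α`, and the reconstruction divides the
measured modulation ratio by α before recombining,

    Δφ = atan2(I(3π/2) − I(π/2), I(0) − I(π)),
    S = A² + B² = (I0 + Iπ)/2,   P = AB = hypot(...)/4,
    β = B/A  (smaller root of x² − Sx + P² = 0, β ≤ 1 branch),
    φ = arg[1 + (β/α)·e^{iΔφ}].

With these conventions the reconstruction exactly inverts the renderer:
noiseless round trips agree to ~1e-9 rad (float32 storage). Two
consequences are worth stating plainly:

* **Validity region.** The β ≤ 1 branch is the physically sensible one
  when the detected incident beam dominates; with α = 3.4 that requires
  `|φ| ≤ 2·asin(1/(2α)) ≈ 0.295 rad`. Phantom defaults (epithelium
  0.15 rad, fibers 0.10 rad, background noise sd 0.01 rad) sit inside
  this weak-scattering regime. Pixels whose amplitude quadratic has no
  real root in [0, 1] (possible under noise) are clamped to β = 1 and
  counted in a diagnostic, never silently fixed.
* **Reference choice.** Using the illumination plane wave as the
  incident reference (rather than the spatial mean of the transmitted
  field) is what makes the global phase recoverable; a mean-field
  reference would leave an unobservable constant offset between the
  reconstruction and the true phase.

Channels are rendered at a common sample phase (the sample is modeled
dispersionless); they differ only by spectral power and stain
absorbance, both of which multiply all four frames of a channel equally
and therefore cancel in the inversion. Per-channel central wavelengths
matter only in the spectral module, where the equivalent-source algebra
lives. No phase unwrapping is performed — thin (5 µm) sections keep
|φ| < π — out-of-range pixels are counted and reported.

## Spectral model

The equivalent detected spectrum is the illumination times the summed,
weight-scaled channel responses, `S_c(ω) = S_i(ω)[S_R + S_G + S_B]`; its
Fourier transform is the temporal autocorrelation Γ(τ), plotted against
distance d = cτ. Numerics: λ-tabulated inputs are converted to a uniform
angular-frequency grid with the |dω/dλ| Jacobian; the grid spans 4× the
tabulated support with 2¹⁴ samples, which places ≥ 4 samples per optical
carrier period and ~mm of delay range. The central wavelength is the
envelope-weighted mean phase advance of Γ per delay step over the
half-maximum region (robust to coarse sampling below the Nyquist limit
of the carrier); the coherence length is the FWHM of the envelope, taken
as the analytic-signal envelope of Re Γ (the plotted quantity), with
linear interpolation at the half-maximum crossings. Default modeled
spectra are Gaussians (illumination at 589 nm; channels at 610/550/470
nm): the instrument's measured spectra are not distributed, so measured
instrument values of λ_c and l_c are not reproduction targets here.

## Stain model and Z normalization

Staining is modeled inside the tissue mask as the affine map
`φ → a·φ + b` (0 < a ≤ 1) plus Gaussian noise, with per-channel Beer–
Lambert absorbance `exp(−D_c)` applied to the color channels. The
standard-normal transform Z = (φ − μ)/σ, with μ and σ (population sd)
computed over tissue pixels only, removes any affine stain exactly;
tissue/background segmentation is an Otsu threshold on |φ| (two-sided in
contrast) followed by a disk-2 opening and hole filling. Histogram
agreement uses 256 shared bins spanning the pooled range,
density-normalized (cosmetic — Pearson ρ is scale-invariant).

The stain-normalization study runs at full histology phase scale
(epithelium 1.5 rad, as a 5 µm section with Δn ≈ 0.03 at 558 nm gives
2πΔn·t/λ ≈ 1.7 rad) with a measurement-scale noise floor (0.08 rad) and
core-sized images (1024², ~10⁵ tissue pixels), because the comparison is
between *phase maps*, not camera frames; the interferometric studies use
the weak-scattering defaults instead. Two effects otherwise dominate the
histogram correlation and are worth knowing about: per-bin counting
noise (256 bins need ≥ ~400 pixels/bin for ρ > 0.99) and the relative
smoothing mismatch between the unstained map (noise n_b) and the stained
map (noise √(a²n_b² + n_s²)/a after normalization).

## Diagnosis features

* **Curvature**: the EC polygon is resampled at 1 px arc-length spacing,
  smoothed with a periodic Gaussian (sd 5 px), and
  κ = (x′y″ − y′x″)/(x′² + y′²)^{3/2} evaluated with periodic central
  differences; the feature is the median |κ| in 1/µm. The smoothing
  attenuates a circle of radius R by ≈ exp(−(σ/R)²/2) — 0.1 % at
  σ = 5 px, R = 100 px — well inside the 2 % oracle tolerance.
* **Scattering length**: `l_s = t / var_w(φ)` with the variance in a
  15 px sliding window; where the variance vanishes the value is capped
  at 10⁶ µm (documented ceiling, "no scattering"). Median per EC.
* **Textons**: an 18-filter bank (Gaussians and LoG at σ = 1, 2, 4 px;
  first- and second-derivative pairs at 4 orientations, 3:1 elongation,
  σ = 1.5/3 px for first, 1.5 px for second order). Responses are
  rectified (absolute value) so clustering is invariant to contrast
  polarity and to the local phase of oscillatory textures, then
  standardized per filter with training-set statistics that are stored
  in the dictionary. k-means (k = 30 default, 10 restarts, fixed seed)
  on pixels sampled from the training images gives the textons;
  T(x, y) is the texton-label histogram in a 25 px window and ⟨T⟩ its
  elementwise median over the EC. Medians of simplex vectors sum to at
  most 1 and are deliberately left un-renormalized.
* **Classifier**: two-class LDA on the standardized concatenation
  [⟨C⟩, ⟨l_s⟩, ⟨T⟩₁…⟨T⟩_k] (length 2 + k; 32 at k = 30), pooled
  covariance with a relative ridge of 1e-6 (handles exactly collinear
  columns and the n < p folds of small studies, with a warning);
  posterior scores via the logistic of the discriminant. Evaluation is
  stratified 3-fold cross-validation with all held-out scores pooled
  into one ROC (trapezoidal AUC); standardization is learned on training
  folds only.

## Fiber tracing and TACS-3 features

Tracing is a bespoke ridge/skeleton tracer (deliberately not a curvelet
re-implementation — θ, l, ε and skew θ are portable across tracers): EC
pixels (dilated 3 px) are replaced by the stromal median; a multiscale
Sato line filter (σ = 1, 2, 3 px) enhances ridges; hysteresis thresholds
are the larger of 4×/10× the robust (MAD) scale of the stromal response
and 10 %/30 % of its peak (the former suppresses noise, the latter
governs clean images where the MAD collapses; both are relative, so
tracing is invariant to affine intensity scaling); the thresholded mask
is skeletonized and decomposed into simple paths at junctions, split
where the local direction turns > 45°, and filtered at 10 µm minimum
length. Skeleton tips are trimmed (2 px) before end-segment orientation
fits, as thick-ridge tips hook.

Per fiber: the representative orientation for ε is the total-least-
squares line fit (axial, mod 180°); for θ it is the end segment nearest
the boundary, matching the "terminates at the edge" semantics. θ is the
acute angle to the boundary tangent at the nearest edge point (fibers
with no boundary within the eligibility distance — 63 µm for near-EC
analyses, 100 µm for TACS-3 — are excluded, not errors). l is the
minimum vertex-to-boundary distance in µm. ε_i averages, over
neighborhood sizes m ∈ {2, 4, 8, 16} (those with m ≤ n−1), the axial
resultant |mean exp(2iθ)| of the fiber *with* its m nearest neighbors by
centroid distance (self included — a documented choice that matters at
small m; ties broken by fiber id). Core predictors are mean ε, mean l
and the biased moment skewness g₁ = m₃/m₂^{3/2} of θ (0 when m₂ = 0),
over eligible fibers; cores with < 3 eligible fibers are flagged
unclassifiable. The TACS-3 classifier is a linear SVM on the
standardized 3-vector with decision threshold 0.

The phantom regimes behind the prognosis studies: *positive* cores mix a
boundary-terminating near-perpendicular subpopulation (30 % of fibers at
90° to the local tangent) into a wrapped parallel background, all within
1–20 µm of the edge — high ε, low l, θ bulk low with a high tail
(positive skew); *negative* cores have uniformly oriented fibers at
25–60 µm. Pixel size is always an explicit input, never inferred from
image content.

## Survival analysis

Kaplan–Meier is the standard product-limit estimator (censoring marks
retained; with no censoring it reduces exactly to 1 − ECDF at event
times). The log-rank test accumulates observed-minus-expected events
with hypergeometric variance over pooled distinct event times (1 df).
Cox regression maximizes the Breslow-ties partial likelihood by Newton
iterations (tolerance 1e-8, ≤ 50 iterations), implemented with suffix
cumulative sums over time-sorted subjects; Wald CI and p. Tables with no
events or a monotone likelihood (complete separation; detected via a
vanishing information or |β| > 50) are flagged and return no estimate.
Breslow ties were chosen as the simplest standard handling that a
brute-force partial-likelihood search can verify; the test suite also
cross-checks against an independent survival library. Times are in
months; DSS and DFS are carried as an endpoint tag and analyzed
independently.

The survival simulator draws exponential event times with rate ratio
equal to the prescribed hazard ratio and independent exponential
censoring at `censor_rate` (0 disables censoring).

## Synthetic phantoms: what they are and are not

Phantoms have simply connected gland-like ECs (benign: smooth ellipses,
fine speckle texture σ = 1.5 px, lumen at 0.35 of the ring amplitude;
malignant: harmonically perturbed boundaries at 12 % rms radial
irregularity, coarser σ = 4 px and stronger speckle, more solid
interiors at 0.75 — emulating the loss of luminal architecture) and
straight stromal fibers with recorded true orientations, kept ≥ 8 px
apart so centerlines stay unambiguous (crossing-fiber resolution is a
known limitation of ridge tracers and is out of scope). Cell speckle is
a tanh-bounded smoothed Gaussian field — bounded without the density
atoms a hard clip creates. All noise is additive Gaussian.

Consequently, passing studies show that the *measurement chain* is
correct and self-consistent: exact interferometric inversion, exact
affine stain removal, feature oracles at closed-form values, classifiers
that separate generatively different classes and respect permutation
nulls, and survival statistics calibrated against their own simulator.
They do not show that these features separate real benign from malignant
tissue, or that the SVM trained on phantom regimes transfers to real
TMAs — the phantom classes are cleanly separable by construction, real
cores are not, and real AUCs/hazard ratios require the original slides.

## Degenerate inputs and conventions

0-based (row, col) array indexing; polygons and fiber vertices stored as
(x = col, y = row); angles counterclockwise from +x (image y negated),
orientations mod 180°. Unimodal images segment to a full mask with a
warning; constant tissue (σ = 0) is an error for Z maps; empty stroma
yields an empty fiber list, not an error; negative rendered intensities
clip at 0 with a count. Float32 on disk, float64 internally.
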