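# Methods

## Digital image correlation (DIC)

Deformation of the microsphere-seeded collagen gel is measured subset-wise:
a square interrogation window (default 31 px, odd) is centred on each node
of a regular lattice (default pitch 16 px) and matched into the deformed
frame by maximising the **zero-normalized cross-correlation** (ZNCC) over
integer offsets within a search radius (default 10 px). ZNCC — mean
subtraction and variance normalisation of both windows — is insensitive to
the slow illumination drift of long phase-contrast time-lapses. The integer
peak is refined per axis by a 1-D quadratic fit through the peak and its two
neighbours, clamped to ±0.5 px; when the integer-lattice correlation is
exactly 1 (an identical-content match) refinement is skipped, since the
parabola through asymmetric neighbours would otherwise bias a perfect match.
Windows with zero intensity variance are unmatchable and are flagged invalid
rather than silently zeroed; a scene in which more than half the nodes fail
is rejected.

Node clearance from the borders is `subset//2 + search_radius`, so both the
window and its search region always lie inside the frame. Coordinates are
0-based, x = column (rightward), y = row (downward); displacements are in
pixels.

**Green–Lagrange strain.** Displacement gradients are central differences on
the node lattice (one-sided at the edges), with node coordinates in pixels,
so the components

    Sxx = u_x + (u_x² + v_x²)/2
    Syy = v_y + (u_y² + v_y²)/2
    Sxy = (u_y + v_x + u_x u_y + v_x v_y)/2

are dimensionless and exactly invariant to rigid rotation. The
**representative strain** of a field is √(median(Sxx)² + median(Syy)²):
medians over nodes are robust to isolated bad matches, only the normal
components enter, and the Euclidean-norm convention keeps the result in
strain units, as the ordinate of a creep curve must be. The literal
sum-of-squares reading (strain² units) is available via
`representative_strain(..., convention="sum_of_squares")`.

Defaults (subset 31, spacing 16, search 10) are engineering choices sized so
that a 256² frame yields an ~13×13 node lattice; all are configuration
fields. Affine subset shape functions and large-rotation DIC are out of
scope: the gel deformations of interest are a few percent strain.

## Kelvin–Voigt creep model and fitting

A spring E₁ in series with a Voigt element (spring E₂ ∥ dashpot η) under a
constant stress σ₀ creeps as

    γ(t) = σ₀/E₁ + (σ₀/E₂)(1 − e^(−t/τ)),   τ = η/E₂.

Units: stress in Pa, time in minutes, viscosity in Pa·min; conversions only
at I/O boundaries. σ₀ is known from the loading hardware (7.7 × 10² Pa) and
is held fixed, so three parameters are free. Positivity is enforced by
optimising log E₁, log E₂, log η, keeping the Levenberg–Marquardt solver
(scipy `least_squares`, `method="lm"`, gradient tolerance 1e−10, iteration
cap 500) unconstrained. The data-driven start is E₁ = σ₀/γ(first positive
sample), E₂ = σ₀/(γ_last − γ_first) guarded positive, η = E₂·t_last/3.
Non-convergence is reported as `converged=False`, not an exception; a
constant curve is a hard error. The fit index is Pearson's r between
observed and fitted strain over the fitted samples (no hold-out).

**Pre-load sample handling.** A creep curve assembled from imaging contains
the reference point (t=0, γ=0) — the state before the load acts. The model,
whose elastic branch responds instantaneously, predicts γ(0)=σ₀/E₁ > 0, so
that sample is off-model by construction: including it in the residuals
biases the recovered delay time by roughly −40% even on otherwise exact
data. `fit_kv` therefore keeps the pre-load point in the curve (it is a real
measurement) but excludes it from the least-squares residuals and the fit
index (`drop_preload_zero=True`). Curves sampled strictly under load (no
leading zero) are unaffected.

At a strain noise of 5% of the creep plateau the delay time is inherently
hard to pin down from a 31-sample record: the LM estimate coincides with a
brute-force profile-likelihood grid search (it is the global optimum), and
the median relative τ error of that optimum is itself around 10%. Tests
therefore assert optimality against the grid-search oracle plus a moderate
error bound, rather than pretending the fitter can beat the information
content of the data.

`creep_analysis` chains the stages: every frame k > 0 is correlated against
frame 0, reduced to a strain field and then to γ(t_k); `creep_batch`
additionally reports the median τ and median Pearson r over specimens, the
two quantities summarised for repeated gel samples.

## Image metrics

* **Colony progression** — median filter (disk radius 2) then Otsu
  threshold; the largest connected component is kept and hole-filled; its
  pixel count is the occupied area. A polarity flag handles dark-on-bright
  colonies. The progression distance is the equivalent-circle radius change
  l_t = √(a_t/π) − √(a₀/π) (negative if the region shrinks), and the
  progression rate is the OLS slope of l_t against time. The unspecified
  "filtering" of the original protocol is implemented as a median filter
  (edge-preserving, standard for speckle-like noise).
* **Live-cell count** — Laplacian-of-Gaussian blob detection at a scale
  matched to the configured cell diameter (default 12 px), with overlap
  suppression; a functional replacement for template-based ImageJ nucleus
  counters, validated against generator ground truth. Intensities are
  min–max normalised first, so counts are invariant to global affine
  intensity rescaling.
* **Nucleus count** — global threshold (Otsu for PI, image mean for DAPI),
  Euclidean distance transform, watershed seeded at h-maxima of the distance
  map (depth 2 px suppresses over-segmentation of mildly lumpy nuclei),
  minimum-area filter 12 px².
* **F-actin length** — difference-of-Gaussians bandpass (σ 1.0 and 13.3 px,
  passing structures of roughly 3–40 px, mirroring FFT-bandpass
  conventions), Otsu threshold, morphological skeletonisation; Lf is the
  skeleton pixel count (equivalently a grayscale sum divided by the
  foreground value). An optional diagonal-aware estimator weights diagonal
  skeleton steps by √2 but is not the default, which stays faithful to the
  pixel-count readout. LFC = Lf/Nn is a bulk multi-cell metric — single-cell
  segmentation in dense sheets is explicitly out of scope.
* **Viability** — the ratio NL/(NL+ND) is exposed as `dcr_printed`, the
  formula exactly as printed in the source protocol (labelled there a "dead
  cell rate", though it is the live fraction — a suspected typo), with
  `dead_fraction` = ND/(NL+ND) alongside; the two always sum to one. CPR is
  (NL+ND)/(NL+ND)_control.

## Statistics

* **2^−ΔΔCt** — technical replicates are averaged on the Ct (log) scale;
  per biological replicate ΔCt = Ct_target − Ct_reference; ΔΔCt subtracts
  the calibrator group's mean ΔCt; fold = 2^−ΔΔCt. Because the calibrator is
  computed from the same table, a global shift of either gene's Ct across
  all samples leaves the folds unchanged.
* **Dunnett's many-to-one test** — pooled-variance t statistics of each
  group against the control; the two-sided family-wise adjusted p-value is
  P(max_j |T_j| ≥ |t_i|) under the equicorrelated multivariate-t null
  (correlations from group sizes), evaluated by seeded Monte-Carlo
  integration with 10⁵ draws by default. Monte Carlo avoids
  platform-dependent quadrature while staying bit-reproducible: the null
  sample depends only on (k, df, correlation, draws, seed) and is cached
  under that key. An add-one-smoothed tail estimate keeps p in (0, 1]. With
  one comparison the procedure collapses to the pooled two-sample t-test.
  Two-sided alternatives throughout; significance stars at 0.05 and 0.001.

## Synthetic data: what it emulates, what it does not

All generators take a mandatory seed (never wall-clock) and are
bit-reproducible; images are float in [0, 1] with 8-bit export at the I/O
boundary.

* **Speckle scenes** mimic phase-contrast polystyrene microspheres: dark
  Gaussian-profile discs (default 400 spots of radius 3 px on 256²) on a
  bright field, giving every interrogation window texture. Deformation is
  applied by inverse mapping with bicubic interpolation (no holes, texture
  preserved); additive Gaussian intensity noise models CCD read noise
  (default 1% of range in creep sequences).
* **Creep sequences**: frame 0 is the pristine pre-load reference; frame k
  is warped by a uniaxial horizontal stretch whose displacement gradient is
  e_k = √(1 + 2γ(t_k)) − 1, so the scene's true Green–Lagrange normal strain
  equals the model strain γ(t_k) exactly (a linearly scaled displacement
  field would instead impose γ + γ²/2, a small systematic distortion of the
  creep curve). Default acquisition matches the protocol: one frame per
  minute for 30 min.
* **Colonies**: one quasi-circular region per frame, radius r₀ + rate·t with
  a low-order Fourier boundary perturbation; ground-truth area is the
  rasterised mask's pixel count (the analytic πr² differs from the raster by
  under 1%).
* **Live/dead scenes**: non-overlapping Gaussian cells placed by rejection
  sampling; exactly round(n·dead_fraction) render in the red channel.
* **Filament scenes**: smooth random walks emitted Bresenham-style, so each
  chain is a minimal 8-connected digital curve — the same pixel class a
  skeleton retraces; the ground-truth length is the thinned centerline's
  pixel count, making truth and measurement commensurate. Walks terminate at
  the field margin and restart elsewhere. The default direction noise
  (0.02 rad/px) gives the gently curved, nearly straight morphology of
  stress-fiber bundles. Strokes are dilated to the configured thickness,
  blurred and noised.
* **Ct tables**: Ct(target) = Ct(reference) + ΔCt_calibrator − log₂(fold)
  plus per-measurement Gaussian noise; with zero noise the ΔΔCt pipeline
  recovers every fold exactly. Defaults follow the protocol: biological and
  technical triplicates.

Passing recovery tests on these scenes shows the measurement chain is
correct and unbiased under controlled conditions; it does not certify
performance on real micrographs, which add uneven illumination, optical
PSF structure, debris, overlapping cells, filament crossings at high
density, and staining variability that the generators deliberately do not
model (no optics/PSF simulation, no photorealistic rendering).

## Demo study conditions

The `demo` subcommand sizes the synthetic study for a desk-scale run
(~10 s on one CPU): three creep specimens (true τ = 6.5, 7.74, 9.0 min,
192² frames, 11 frames each), three replicates per group for colonies
(growth 2.0 / 1.2 / 2.8 px/h for control / T4 / T8), live/dead scenes
(100 / 100 / 130 cells, 5% dead), filament scenes (centerline budgets
1500 / 900 / 1400 px) and a Ct table with true folds 1 / 0.5 / 4 at 0.15
cycles of noise. The heavier validation battery (six 31-frame creep
sequences, 2000-dataset Dunnett null calibration) lives in the test suite.

## Known limitations

* Subpixel matching uses a quadratic peak fit; pixel-locking bias of a few
  hundredths of a pixel remains and is why strain recovery is specified at
  the 10% level rather than 1%.
* The skeleton pixel count under-measures very wiggly or thick filaments
  (medial-axis corner cutting, end erosion of ~thickness/2 per end); at the
  default geometry the bias stays within 10%.
* Dunnett p-values carry Monte-Carlo noise of order 1/√draws (~0.003 at the
  default 10⁵ draws).
* The DIC engine assumes small rotations and homogeneous-enough deformation
  within a subset; it is not a general-purpose large-deformation DIC.
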