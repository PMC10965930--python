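# Methods

`qsmcohort` simulates and analyses quantitative susceptibility mapping (QSM)
studies of subcortical gray matter in a three-group design (healthy controls,
major depressive disorder, schizophrenia). This note records the models, the
numerical choices, and what the synthetic data do and do not establish.

## Signal model and phantom

Tissue with volume susceptibility χ(r) (ppm) in a main field B₀ ẑ perturbs
the local Larmor frequency by the dipole convolution, evaluated in k-space:

    Δf/f₀ = F⁻¹[ D(k) · F[χ] ],   D(k) = 1/3 − (k·ẑ)²/|k|²,   D(0) := 0

The phantom rasterizes spheres/ellipsoids/boxes with per-structure χ and R2*
into a 3D grid, inside an ellipsoidal "brain" mask containing a CSF-like
ventricle pair at χ = 0 (the zero reference) and ten bilateral "subcortical"
structures in the cohort scene. Air-like external sources (χ = 9 ppm spheres)
sit in the grid corners, outside the mask: far enough that the wrapped phase
they induce stays spatially resolvable (|∇φ| < π/voxel at the last echo, as a
shimmed scan's would be) yet strong enough to dominate the low spatial
frequencies inside the mask — the situation background-field removal exists
for.

The multi-echo gradient-echo signal per echo i is

    s_i = M₀ e^{−TE_i·R2*} e^{jφ_i},  φ_i = 2π·(γB₀)·(field·10⁻⁶)·TE_i

with M₀ = 1 inside the brain, complex Gaussian noise at a configurable SNR
(defined on the first-echo magnitude inside the brain; Rician magnitude
statistics follow), and phase stored wrapped to (−π, π]. Defaults follow a
3 T protocol: TE₁ = 3.6 ms, echo spacing 5.91 ms, 8 echoes, flip angle 15°
(metadata only — the signal model is spoiled steady state up to a constant).
The paper-analogous study reports no SNR for its in-vivo data; SNR = 50 is
the package's stated assumption for noisy demonstrations, and noiseless runs
are used for algorithm validation.

## Reconstruction

1. **Laplacian unwrapping.** φ_u = ∇⁻²[cos φ_w ∇² sin φ_w − sin φ_w ∇² cos φ_w],
   with spectral operators on a mirror-extended grid (Neumann boundary
   conditions — a periodic solver cannot represent non-periodic ramps), then
   a congruence correction φ_u ← φ_u + wrap(φ_w − φ_u). Wherever the spectral
   estimate is within π of the truth the correction recovers the exact phase;
   this removes a discretization bias that otherwise grows with phase
   amplitude, i.e. with echo time.
2. **V-SHARP background removal.** Spherical-mean-value filtering (I − S_r)
   with, per voxel, the largest kernel radius that fits inside the mask
   (default schedule 1–29 mm, the in-vivo-scale setting), followed by
   spectral deconvolution by (I − S_rmax) truncated where |1 − S̃| is below
   `deconv_threshold`; the valid mask is the brain mask eroded by the
   smallest radius. Fields that are harmonic inside the mask (all external
   sources) are annihilated where the kernel fits. On the 64³ phantom, whose
   brain radius (~26 mm) is a third of an adult head's, the boundary shell
   where only small kernels fit would dominate the volume; the phantom-scale
   configuration (`phantom_recon_config`) therefore uses a single 4 mm kernel
   with truncation 0.02 — the scaled-down analogue of the in-vivo schedule,
   fixed by noiseless pilot runs before the validation thresholds were
   frozen.
3. **R2\* and echo combination.** R2* is the negated slope of the log-linear
   fit of magnitude against TE (closed form; floor configurable, default 0;
   all-zero voxels flagged). Per-echo local-field maps are converted to ppm
   (φ / (2π γB₀ TE · 10⁻⁶)) and combined with weights w_i ∝ TE_i e^{−TE_i R2*},
   the SNR-optimal weighting for phase-derived frequency estimates.
4. **Dipole inversion (iLSQR-style).** Stage 1 solves
   argmin_χ ‖M(F⁻¹ D F χ − f)‖₂ by LSQR (tolerance 10⁻⁴, ≤50 iterations),
   with χ constrained to the valid mask: without a support constraint the
   masked problem is underdetermined and the minimum-norm iterate
   systematically underestimates structure means (~30% on the phantom).
   Stage 2 estimates streaking — stage-1 content whose spectrum lies in the
   ill-conditioned cone {|D| < 0.1} — by a short least-squares fit to the
   high-pass (Gaussian σ = 2 voxels) of the stage-1 map over smooth regions
   only (gradient gate at 2× the median, edge set dilated by a 3-voxel guard
   band so inversion ringing at structure boundaries is not mistaken for
   streaks), and subtracts it. All stages are linear up to the
   scale-invariant gates, so scaling the field scales the map.
5. **Zero reference.** The mean over the lateral-ventricle mask is
   subtracted; the offset is recorded. QSM determines χ only up to a
   constant (D(0) = 0), so all reported values are relative to ventricular
   CSF.

Noiseless 64³ validation: both sphere VOI means recover within 2% of truth
(|χ| = 0.10 and 0.015 ppm), forward-field data fidelity ≈ 4% RMS, external
background suppressed to ≈ 1% RMS inside the valid mask. At SNR 50 recovery
stays within ~4%.

## VOI measurements

Susceptibility per structure = mean χ over the VOI after two iterations of
in-plane (per axial slice) 4-connected binary erosion — the partial-volume
guard — computed per hemisphere and then averaged left/right without
weighting. Volume = uneroded voxel count × voxel volume, per hemisphere,
averaged likewise. A structure whose eroded VOI empties in one hemisphere
uses the surviving side and carries a flag; empty in both is an error.
Connectivity (4 vs 8) is configurable; 4-connected is the default reading of
"two pixels eroded inward per slice".

## Cohort generator

`simulate_cohort` draws, per subject and region, volume ~ N(μ_v, σ_v) with
group-specific moments (defaults: the reference study's per-group mean/SD
tables for all 10 regions, n = 50/49/24), and susceptibility

    χ = μ_c + β·(σ̄_c/σ̄_v)·(v − μ_v) + ε

where σ̄ are the pooled (mixture) SDs implied by the group moments and ε is
scaled so the marginal susceptibility SD matches the group spec. β is the
standardized volume→susceptibility slope on the *pooled* scale — exactly the
quantity the group×volume GLM estimates, so generated and recovered slopes
share units (defaults: β = 0.58 for the MDD nucleus accumbens, 0 elsewhere).
Covariates (sex, handedness, IQ with missingness, illness duration, severity,
medication dose) are drawn from the study's demographic table; they are
exchangeable decorations, not causally linked to the brain measures.

What the generator does *not* emulate: spatial correlation between regions
within subject (regions are drawn independently), non-Gaussian tails,
site/scanner effects, and any coupling between covariates and susceptibility.
Passing tests therefore demonstrate correctness of the estimators under the
stated sampling model, not robustness to those real-data features.

## Statistics

- Per-region one-way ANOVA (classic between/within decomposition), BH-FDR
  across the 10 regions within each measure — susceptibility and volume are
  separate families, mirroring two separate report tables.
- `anova_from_summary` recomputes F from printed means/SDs/n
  (SSB = Σnᵢ(mᵢ−m̄)², SSW = Σ(nᵢ−1)sᵢ²) — an exact refactoring of the raw
  decomposition, tested to 10⁻⁹ agreement. Printed (rounded) inputs limit
  reproduction accuracy: with the reference tables, thalamus/caudate/putamen/
  GPe F values reproduce to 2 dp while hippocampus-class cells drift by a few
  hundredths.
- Tukey HSD from the pooled MSW via the studentized-range distribution
  (k groups, N−k df), gated on ANOVA q < 0.05, with an optional (default-on)
  second BH step across the three pairs; the double correction follows the
  reference analysis text, and the switch exists because that text is
  ambiguous.
- GLM: susceptibility and volume z-scored over the pooled sample, OLS on
  treatment-coded group (HC reference), volume, and interactions; BH-FDR over
  the five non-intercept terms within a region. Rank deficiency errors out.
- One-way ANCOVA: partial F for group adjusting for categorical handedness;
  absent levels are dropped and logged.
- Pearson correlation screens with pairwise deletion; zero-variance and
  n < 3 cases flagged, never silently computed.
- Shapiro–Wilk per group and Levene (center = mean) across groups are
  reported only — they never gate the main analyses.

Calibration (10⁴ null replicates at the study's group sizes): ANOVA and GLM
interaction type-I error 5.1% and 4.6% at α = 0.05. Parameter recovery (500
simulated cohorts): mean interaction estimate 0.567 for a true 0.58, 95% CI
coverage 96.8%.

## Numerical and degenerate-input conventions

Arrays are indexed (x, y, z) with axial slices at fixed z and B₀ along +z.
Grids are periodic for FFT work; the mask is zero-padded by 8 voxels in
V-SHARP and inversion. SMV kernels use linear partial-volume weights on the
sphere surface, which makes small-radius kernels far better approximations
of the continuous spherical mean. Zero-signal input to reconstruction raises
rather than propagating NaNs; MSW = 0 in ANOVA yields F = ∞ (p = 0) or F = 0
(p = 1) depending on SSB; echo-combination weight collapse falls back to an
unweighted mean with a warning.

## Scales used for validation

Validation runs use a 64³ phantom (1 mm isotropic) and the demo pipeline a
48³ grid with 3 subjects per group — sizes chosen so every algorithmic stage
is exercised at interactive runtimes; nothing in the pipeline is specific to
these sizes, and the reconstruction defaults target in-vivo-scale masks.

## Known limitations

- The inversion's support constraint attributes all field sources inside the
  valid mask; susceptibility in the eroded boundary shell is not estimated.
- V-SHARP + truncated deconvolution removes some genuinely low-frequency
  tissue field; quantification relies on the kernel being large relative to
  the structures, which the phantom-scale configuration enforces by design.
- The streak-correction stage's gates are heuristic; on data with dense
  fine-scale structure the smooth-region mask may be small and the correction
  correspondingly weak.
- The cohort generator's independence assumptions (see above) make
  multi-region joint inference (e.g. FDR behaviour under cross-region
  correlation) optimistic relative to real cohorts.
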