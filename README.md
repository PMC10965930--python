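# qsmcohort

Phantom-based **quantitative susceptibility mapping (QSM)** with subcortical
VOI morphometry and three-group cohort statistics.

QSM estimates tissue volume magnetic susceptibility χ (ppm) from the phase of
multi-echo gradient-echo (GRE) MRI. Paramagnetic iron raises χ, diamagnetic
myelin lowers it, so subcortical χ is a window on iron load and myelination —
quantities of interest in psychiatric case-control studies comparing healthy
controls (HC) with major depressive disorder (MDD) and schizophrenia (SCZ)
cohorts. This package provides the whole measurement chain as tested,
reusable components:

- **`qsmcohort.phantom`** — digital susceptibility scenes (ellipsoidal
  subcortical structures, a CSF ventricle pair at χ = 0, air-like external
  sources), the forward dipole field `Δf/f₀ = F⁻¹[D(k)·F[χ]]` with
  `D(k) = 1/3 − k_z²/|k|²`, a 3 T 8-echo GRE simulator (TE₁ = 3.6 ms,
  ΔTE = 5.91 ms), and a synthetic-cohort generator with configurable
  per-region group means/SDs and a group-specific standardized
  volume→susceptibility slope.
- **`qsmcohort.recon`** — reconstruction: Laplacian phase unwrapping,
  V-SHARP background-field removal (variable spherical-mean-value kernels),
  log-linear R2\* mapping, R2\*-weighted echo combination, two-stage
  iterative least-squares (iLSQR-style) dipole inversion with streak
  correction, and zero-referencing to the lateral ventricles.
- **`qsmcohort.roi`** — per-structure measurements: mean χ over the VOI
  after a 2-pixel in-plane erosion (partial-volume guard), volume as
  uneroded voxel count × voxel volume, both averaged across hemispheres.
- **`qsmcohort.stats`** — the group analysis: per-region one-way ANOVA with
  Benjamini–Hochberg FDR across 10 regions, Tukey HSD post hocs gated on the
  FDR-corrected ANOVA, a standardized group × volume GLM (treatment coding,
  HC reference), ANCOVA with handedness, Pearson correlation screens, and
  ANOVA reconstruction directly from *printed* summary statistics
  (mean/SD/n), so published tables can be checked without raw data.
- **`qsmcohort.pipeline` / CLI** — an end-to-end demo
  (phantom → GRE → reconstruction → VOI extraction → statistics) with
  seed-controlled determinism and provenance records.

Sign convention: positive phase accumulation ⇔ positive local field ⇔
paramagnetic χ > 0; the simulator and the reconstruction share one constant
(γ = 42.577 MHz/T).

## Worked example 1 — checking published F statistics from a printed table

Given a CSV of printed per-group summaries (`region, measure, group, mean,
sd, n`), the one-way ANOVA is recomputed exactly from
SSB = Σnᵢ(mᵢ−m̄)², SSW = Σ(nᵢ−1)sᵢ²:

```bash
qsmcohort reproduce-anova --summary table_volumes.csv --out f.csv
```

With the subcortical volume summaries of a 50/49/24-subject HC/MDD/SCZ
cohort this prints:

```
                 region    measure        F  df1  df2        p        q
               thalamus volume_mm3 3.380292    2  120 0.037310 0.149239
                caudate volume_mm3 0.810172    2  120 0.447199 0.596266
                putamen volume_mm3 1.098845    2  120 0.336585 0.596266
globus_pallidus_externa volume_mm3 0.389311    2  120 0.678376 0.678376
```

i.e. F = 3.38, 0.81, 1.10, 0.39 — matching the published values to the
printed precision — and the q column shows why a raw p = 0.037 does not
survive FDR across regions.

## Worked example 2 — simulated cohort and the group × volume GLM

```bash
qsmcohort simulate-cohort --out cohort.csv --seed 1
qsmcohort stats --cohort cohort.csv --out results
```

`cohort.csv` holds 1230 rows (123 subjects × 10 regions) drawn at the
default group moments, with a standardized volume→susceptibility slope of
0.58 in the MDD nucleus accumbens and 0 elsewhere. The GLM table
(`results/glm.csv`) for the nucleus accumbens reads:

```
                          B      SE       t   p_raw   q_fdr
group[MDD]           0.6063  0.1902  3.1869  0.0018  0.0092
group[SCZ]           0.3553  0.2418  1.4691  0.1445  0.2408
volume_z            -0.0641  0.1562 -0.4104  0.6823  0.7605
group[MDD]:volume_z  0.5418  0.2121  2.5548  0.0119  0.0298
```

The MDD × volume interaction estimate (0.54 ± 0.21 here) recovers the
generated slope of 0.58 within its standard error: in this cohort, larger
accumbens volume predicts higher susceptibility in the MDD group only.
Averaged over 500 simulated cohorts the mean estimate is 0.567 with 96.8%
CI coverage (see below).

## Worked example 3 — end-to-end imaging demo

```bash
qsmcohort demo --out demo_out --seed 7
```

simulates 3 subjects per group on a 48³ grid (per-subject structure χ drawn
from the group distributions), reconstructs every susceptibility map,
extracts the 10 bilateral VOIs, and writes `cohort.csv`,
`stats_susceptibility.{csv,md}`, `stats_volume.{csv,md}` and
`provenance.json` (~20 s on one CPU). Re-running with the same seed
reproduces every output byte-for-byte.

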