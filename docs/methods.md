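# Methods

`petmtv` re-implements, on synthetic PET phantoms, the measurement and
statistics pipeline used to compare the reproducibility of metabolic tumour
volume (MTV) segmentation methods in lymphoma: two simulated observers place
regions of interest on SUV volumes, eight delineation methods turn each
region into a binary mask, per-patient total MTVs feed inter-observer
agreement statistics, and the resulting volumes drive a prognostic cut-off
and survival analysis.

## Phantom model

A phantom is a 3-D grid of standardised uptake values (SUV, unitless).
Default voxel geometry follows a clinical whole-body acquisition: 5.3 mm
in-plane pixels on a 168 × 168 matrix, 2 mm plane spacing, and a scanner
point-spread function (PSF) of 4.4 mm FWHM modelled as an isotropic
Gaussian.

The noiseless field is built from spherical uptake regions composed over a
uniform background by voxelwise maximum (additive composition would double
the tracer concentration where cluster members overlap), then convolved
with the PSF.  Optional zero-mean Gaussian noise is added post-PSF and the
result clipped at zero.  This is a deliberate desk-scale stand-in: there is
no anatomy, attenuation, scatter, or Poisson/reconstruction noise
correlation.  A green test therefore establishes that the *measurement and
statistics machinery* behaves as described, not that the simulator predicts
clinical image texture.

Two lesion archetypes are generated:

* **isolated lesions** — single spheres (radius 8–22 mm, uptake SUV 4–12 on
  background 1.0);
* **infiltrative clusters** — 2–4 abutting spheres with unequal uptakes
  (centres just under the sum of radii apart), emulating diffusely
  infiltrated regions where it is genuinely ambiguous whether one merged or
  several per-node regions of interest should be drawn.

A spherical "liver" (default mean SUV 2.2, voxel texture SD 0.2) provides
the automatic reference statistics; it is identical for both observers, as
in the emulated workflow where liver SUV measurement is automatic.

## Observer model

Each observer receives the tight ground-truth box of every lesion (sphere
extent dilated by the PSF FWHM, so the suprathreshold blur tail is
contained) and perturbs it:

* **margin jitter** — each box face moves outward by
  `max(0, round(N(0, sd)))` voxels (default SD 1).  Outward-only jitter
  keeps the lesion's suprathreshold support inside the box.
* **split/merge** — each infiltrative cluster is independently delineated
  either as one merged box (the union of member boxes; probability
  `split_merge_probability`, default 0.3) or as per-member boxes clipped at
  the midplane between neighbouring member centres.  The clipping reflects
  how a reader carves an infiltrated region; without it an individual box
  would still contain the neighbour's hot core and the 41%-of-max method
  would be artificially immune to the split/merge choice.  The 0.3 default
  is a free simulation parameter — no published estimate of the split/merge
  frequency exists.

## Delineation methods

All masks are "every voxel in the box with SUV ≥ T" (inclusive, no
connected-component filtering).  The threshold T per method:

| method      | threshold                                                        |
|-------------|------------------------------------------------------------------|
| `suv2.5`    | fixed SUV 2.5                                                    |
| `liver_max` | liver SUVmax                                                     |
| `percist`   | 1.5 × liver SUVmean + 2 × liver SD (sample SD, n−1)              |
| `percent41` | 0.41 × box SUVmax                                                |
| `nestle`    | β (I₇₀ + background), β = 0.15, I₇₀ = mean of voxels ≥ 0.7 × max |
| `black`     | iterative T = 0.307 × SUVmean(mask) + 0.588                      |
| `daisne`    | iterative fraction f = m/SBR + c of box max (phantom-calibrated) |
| `fitting`   | least-squares fit of a blurred-sphere forward model              |

Notes and numerical choices:

* **Iterative methods** start from the 41%-of-max mask and stop at a mask
  fixed point (cap 100 iterations).  On coarse grids the Daisne update can
  enter a discrete 2-cycle; the cycle is detected and resolved by
  thresholding at the midpoint of the two cycling thresholds (flagged
  `cycle_resolved`).  An empty mask ("threshold escaped lesion") or
  exceeding the cap raises with the full iteration trace.
* **Daisne calibration** finds, for each (diameter, contrast) calibration
  sphere, the threshold fraction recovering the voxelised sphere volume by
  bisection on the fraction, and regresses fraction on 1/SBR
  (signal-to-background ratio).  The built-in calibration uses four spheres
  (20–50 mm, contrast 3–12) at the configured PSF.  With no blur the first
  bisection probe (f = 0.5) is already exact for any contrast > 2, so the
  fitted slope is ~0: the method degenerates to fixed-fraction
  thresholding, as it should.
* **Fitting** uses the closed-form radial profile of a uniform ball
  convolved with an isotropic Gaussian (the chi-3 CDF form), which is
  smooth in centre, radius, uptake and background, so a bounded
  least-squares fit is well conditioned.  The model sigma is floored at
  0.35 × the smallest voxel spacing — a stand-in for voxel partial-volume
  averaging that keeps the FWHM = 0 limit optimizable.  The reported MTV is
  the analytic fitted-sphere volume; the voxel mask exists for
  visualisation.  Flat boxes, sub-voxel fitted diameters and optimizer
  failure raise.
* **Ties**: "≥" everywhere.  Volumes are voxel count × voxel volume, full
  precision internally, cm³ in outputs.

Partial-volume arithmetic bounds what threshold methods can achieve: a
threshold T sitting at fraction C of the lesion-background contrast lands at
radius ≈ R + σ·Φ⁻¹(1−C), so near-background thresholds (Nestle at β = 0.15,
SUV 2.5 at high contrast) systematically over-segment small blurred
spheres.  The recovery test therefore uses a 70 mm, 15:1-contrast sphere,
where all eight methods land within 10% of truth; at the small end of the
"d ≥ 4 × FWHM" domain a 25% recovery bound is not attainable for the
background-level thresholds, which is a property of the methods, not a
defect of the implementation.

## Aggregation

Per-patient total MTV is the voxel **union** of all per-box masks (each
voxel counted once), so overlapping boxes — e.g. a merged cluster next to an
enlarged neighbour — never double count; `double_count=True` restores plain
summation for comparison.  The fitting method contributes analytic sphere
volumes per box instead of voxels.  Organ rules: bone marrow is included
only with focal uptake; the spleen with focal uptake or diffuse uptake
strictly above 150% of the liver SUVmean (exactly 150% excluded).

## Agreement statistics

* **ICC**: two-way mixed, single rater, consistency — ICC(3,1) from the
  ANOVA mean squares, `(MSR − MSE)/(MSR + MSE)` for two raters.  Consistency
  (not absolute agreement) was chosen because the emulated analysis reports
  "consistency"; it is invariant to a constant shift between observers.
* **Kendall tau-b** with tie correction (scipy).
* **BCa bootstrap CIs**: patient-level resampling, bias correction z₀ from
  the proportion of replicates below the point estimate, acceleration from
  the jackknife.  Degenerate bootstrap distributions collapse the CI to the
  point estimate with a flag; a statistic undefined on more than 1% of
  replicates is an error.  Default 10,000 replicates (reduced in tests).
* **Between-method comparison**: one joint patient resample per replicate
  drives all methods, preserving the cross-method correlation of the paired
  series; Δ = coef(a) − coef(b) is summarised by percentile CIs and a
  two-sided bootstrap p-value 2·min(P(Δ* ≤ 0), P(Δ* ≥ 0)) with a +1
  continuity correction (no exact zeros).  Hochberg's step-up correction is
  applied across the 28 method pairs, separately per coefficient.
* **Bland–Altman**: bias ± 1.96 SD limits with normal-theory CIs
  (SE(bias) = SD/√n, SE(limit) = SD·√(3/n)).

## Prognosis

Survival outcomes are generated from an exponential proportional-hazards
model: baseline hazard 0.10/year, log-hazard 0.84 on the high-volume group
(hazard ratio 2.31), 0.59 on the adverse-IPI group (prevalence 58.2%), 1.11
on the CHOP-family chemotherapy group (prevalence 72%), with uniform(3, 10)
year administrative censoring — parameters restating the clinical world the
analysis targets.  Analyses censor at 5 years.

The 5-year outcome for ROC construction is "progression/death within 5
years"; patients censored event-free earlier carry no label and are
excluded (count logged).  The optimal cut-off maximises Youden's J over the
observed MTVs of the two observers' mean, ties broken toward the larger
cut-off; per-observer ROCs give the evaluator-specific cut-offs whose
difference and resulting low/high-MTV reclassification are tabulated.
Kaplan–Meier curves carry Greenwood variance; Cox models use Efron tie
handling (Breslow available behind `ties="breslow"` via statsmodels);
median follow-up is reverse Kaplan–Meier (censoring as the event), with the
longest observed time returned as an upper bound when the median is not
reached.

## Determinism and scale

Every stochastic operation takes a seed; cohort simulation spawns
per-patient seeds from the master seed via `numpy.random.SeedSequence`, so
any patient is reproducible in isolation and repeated runs emit
byte-identical JSON.  Cohort experiments use compact 64³ per-patient grids
(paper-scale spacing retained) so a 200-patient, two-observer, four-method
cohort simulates and measures in a few seconds on one CPU.

## Known limitations

* No anatomy, physiologic uptake (beyond the liver sphere), attenuation or
  reconstruction effects; noise is white Gaussian.
* Infiltrative clusters are unions of spheres; real infiltration is not
  spherical, so the absolute ICC values produced here should be read as a
  mechanism demonstration, not a calibration of clinical ICCs.
* The spleen/marrow inclusion rules are implemented and tested at the rule
  level; the default cohort generator does not simulate organ involvement.
* The Daisne and Fitting implementations are deliberate re-parameterisations
  of named commercial algorithms whose exact constants are unpublished.
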