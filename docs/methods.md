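# Methods

## Kinetic model and simulation

Target-region time-activity curves are generated from the simplified
reference tissue model (SRTM):

    C_T(t) = R1·C_ref(t) + (k2 − R1·k2a)·[C_ref ⊗ exp(−k2a·t)](t),
    k2a = k2 / (1 + BP_ND),

which fixes the ground-truth distribution volume ratio of a generated pair
at DVR = 1 + BP_ND (the ratio of total time integrals of target and
reference equals 1 + BP_ND exactly; a test verifies this to 1% by numerical
integration to 400 min). The convolution runs on a 1 s uniform grid and the
continuous curves are then averaged over the acquisition frames with the
trapezoid rule; at 1 s resolution the grid error is negligible against
frame durations of 20–360 s.

The reference (cerebellum) curve is a gamma-variate bolus response,
C_ref(t) = A·t^α·exp(−t/β). No arterial input is modelled: the reference
shape is chosen directly, which is sufficient because every downstream
quantity depends only on the target/reference pair.

### Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| R1 | 0.9 | – | near-unity delivery ratio typical of grey-matter targets |
| k2 | 0.5 | 1/min | reference washout of a fast-kinetics DAT tracer; see below |
| gamma shape α | 0.3 | – | early peak (α·β = 7.5 min) with a slowly decaying tail |
| gamma decay β | 25 | min | terminal reference decay slower than k2a for all simulated BP_ND |
| amplitude A | 70 | arb. | sets peak activity ≈ 100; all measures are scale-invariant |
| frame schedule | 9×20 s, 3×60 s, 5×180 s, 9×360 s | – | the 75-min dynamic protocol |
| voxel size | 1.4626 | mm | makes a 2.5 mL top-k selection exactly 799 voxels |
| PET PSF | 3.2 | mm FWHM | in-plane resolution of the emulated reconstruction |
| SPECT PSF | 12.5 | mm FWHM | isotropic resolution of the emulated reconstruction |

The kinetic defaults were calibrated once, jointly, so that the simulated
tracer reproduces the qualitative behaviour the pipeline presumes:
the target/cerebellum ratio reaches a pseudo-equilibrium plateau by
~50 min (< 5% variation over 50–75 min at the default BP_ND = 3.5), and
reference Logan on noiseless pairs is essentially unbiased (≤ 0.6% for
BP_ND 0.5–5). Both properties require the apparent target efflux
k2a = k2/(1+BP_ND) to dominate the reference terminal decay rate and the
transient exp(−k2a·t) to die out within the scan; slow kinetics
(k2 ≲ 0.1/min) make the 27–75 min window sit far from equilibrium and bias
the no-k2 Logan slope by tens of percent regardless of the reference shape.
A fast washout is therefore intrinsic to this tracer class, not a tuning
convenience. With these defaults the with-k2 and without-k2 Logan variants
agree within 0.4% on noiseless data, consistent with dropping the k2 term
in production.

### Noise model

Voxel and TAC noise is zero-mean Gaussian with variance proportional to
activity divided by frame duration — the standard desk-scale stand-in for
reconstructed-PET noise. It reproduces the relative frame weighting of real
data (short early frames are noisy, long late frames stable) but not the
spatial correlation introduced by reconstruction, nor Poisson skewness at
very low counts.

### Image phantom

Regions are axis-aligned ellipsoids on an isotropic grid, rasterized into an
integer label volume; a large "background" ellipsoid with low non-specific
binding (BP_ND = 0.1) is filled first so PSF smoothing produces realistic
spill-in/spill-out at region borders. Non-background regions must be
pairwise disjoint (validated at rasterization). The default geometry keeps
the substantia nigra search box clear of smoothed putamen spill-over, as
anatomy does. Ground truth (per-region TACs and BP_ND) is returned with
every phantom.

What passing phantom tests do *not* show about real data: no head motion,
no reconstruction artefacts, no anatomical mis-segmentation, ellipsoidal
rather than folded anatomy, and a spatially invariant Gaussian PSF.

### Cohorts

Per-subject regional BP_ND is drawn from group-specific normal
distributions; defaults are calibrated to published healthy-control and
early-PS FE-PE2I ranges (HC caudate 2.93 ± 0.46, putamen 3.78 ± 0.46,
SN 0.72 ± 0.07; PS 2.29 ± 0.80, 1.98 ± 1.07, 0.60 ± 0.10). Draws are
floored at 0.05 (severe disease retains some binding; an exact zero would
be kinetically degenerate). Patients are assigned a clinical side with
frequencies 12:8:2 (right : left : symmetric). Lateralized patients get a
multiplicative asymmetry of 30% (attenuated ×0.25 in the SN, whose clinical
laterality is weak) split symmetrically around the drawn mean — contralateral
hemisphere × (1 − offset/2), ipsilateral × (1 + offset/2) — so the
left/right average preserves the drawn value and the generating group effect
size is unchanged by lateralization.

## Delineation

Striatal VOIs are fixed-volume top-k selections inside the anatomical mask
on a duration-weighted summed image (27–75 min for the kinetic path;
51–75 min, re-delineated, for the static SUVR path). k = round(V / voxel
volume); ties are broken by ascending (z, y, x) index for determinism. An
anatomical mask smaller than k raises a segmentation error — the realistic
upstream-failure mode. The substantia nigra VOI thresholds a 17×13×10 mm
axis-aligned box (half-widths rounded to voxels, clipped at grid edges)
centred on the unweighted mass centre of the seed mask, at
A_th = f·(A_max − A_ref) + A_ref with f = 0.5 and A_ref the cerebellum mean
of the same summed image; the comparison is inclusive (≥), so the VOI always
contains the maximum voxel, and A_max ≤ A_ref is flagged as absent specific
binding rather than silently returning an empty mask.

A half-maximum VOI on a smoothed blob averages the smoothed shell: at
3.2 mm FWHM on a nigra-sized structure the VOI mean retains ~77% of the
true contrast (≥ 90% requires resolution well below the structure size).
This partial-volume loss is intentional — no correction is applied anywhere
in the pipeline — and is visible in the phantom recovery tables.

## Quantification

Reference Logan uses unweighted OLS over frames whose mid-time lies in
[t*, end] = [27, 75] min; running integrals are trapezoidal from injection
with activity anchored at zero at t = 0, evaluated at frame mid-times. Fit
diagnostics (R² of the Logan plot, point count, slope standard error) are
carried with every result. Degenerate inputs — non-positive target activity
in the window, fewer than two frames, zero abscissa spread — raise rather
than return garbage. The framed trapezoid integral is within 1% of adaptive
quadrature beyond the first minutes; over the earliest 20 s frames the
sharply concave bolus rise limits its accuracy, which never affects the
late-window regression.

SUVR divides VOI mean by cerebellum mean on the 51–75 min summed image
(window configurable); SUR = (VOI − background)/background with the
occipital background, so SUR = SUVR − 1 exactly on identical inputs.
Whole-striatum values are (v_c·caudate + v_p·putamen)/(v_c + v_p) with
v_c = 2.0, v_p = 2.5 mL, applied identically to BP_ND, SUVR and SUR; the
SPECT striatal value uses this same combination (a proprietary template
system might define its striatal VOI differently, which reports flag).

## Statistics

- Glass's Δ = (mean_HC − mean_PS)/SD_HC with the sample SD (n−1); chosen
  because disease inflates patient-group variance. Affine-invariant under a
  common rescaling of both groups.
- Consistency ICC: single-rater two-way mixed, ICC(3,1) =
  (MS_subjects − MS_error)/(MS_subjects + MS_error) for k = 2 methods, from
  the two-way ANOVA without subject-by-method interaction. Single-rater is
  the conventional method-agreement choice; additive method offsets do not
  reduce it.
- ROC AUC via the rank (Mann-Whitney) identity with half-credit for ties;
  the `direction="lower"` flag encodes that lower DAT availability indicates
  disease. The 95% CI is a 2000-replicate stratified bootstrap, seeded;
  age adjustment, where wanted, residualizes the measure on age by simple
  linear regression before the ROC (a documented interpretation — the
  original covariate-adjustment procedure is not specified anywhere).
- Exact Mann-Whitney: two-sided p = min(1, 2·min(P(U ≤ u), P(U ≥ u))) over
  the full enumeration of group assignments (tie-adjusted via mid-ranks);
  beyond 2·10⁵ assignments a seeded Monte-Carlo permutation approximation
  (20 000 draws) substitutes, with agreement verified in tests.
- Group tables average left and right hemispheres per subject before group
  summaries; laterality analyses select the hemisphere contralateral to the
  clinically most affected side (lower-binding hemisphere when symmetric)
  and report percent concordance. No multiple-testing correction is applied.

## Problem sizes and determinism

The default image phantom is 64×64×48 voxels × 26 frames (≈ 20 MB float32),
quantified in ~2 s; cohort analyses run at TAC level (28 + 22 subjects,
seconds). The test suite's end-to-end recovery uses a 10 + 10 cohort and
asserts the recovered Glass's Δ within the large-sample sampling CI of the
generating value and AUC ≥ 0.85. All randomness flows through explicit
integer seeds (numpy Generator); identical spec + seed reproduces outputs
bit-for-bit, which the suite asserts for phantoms, cohorts and CLI files.

## Known limitations

- The reference curve is an imposed shape, not a plasma-driven solution;
  absolute activities are arbitrary (all outputs are ratios).
- No partial-volume correction; recovery at PET resolution is deliberately
  biased low, most strongly in the substantia nigra.
- SPECT modelling is a resolution-degraded intensity phantom, not a
  projection/reconstruction simulation; template VOIs are stand-ins for a
  proprietary system.
- The exact Mann-Whitney two-sided rule (doubled smaller tail) is one of
  several conventions; it matches the enumeration oracle and scipy's exact
  method on tie-free data.
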