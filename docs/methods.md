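# Methods

This package replicates, on synthetic data, a two-stage study design for
identifying adolescent mice at behavioural risk of subthreshold depression
and mapping the resting-state brain metabolic correlates of that risk with
voxel-wise ^18F-FDG PET statistics. Both stages are implemented as reusable
library code; the generators that stand in for the animals and the scans
are first-class, tested components.

## Stage 1 — composite behavioural phenotyping

Four behavioural endpoints are measured per animal: time in the open-field
centre (s, anxiety), sucrose preference ratio (anhedonia), water-maze
probe-test platform crossings (spatial memory) and forced-swim immobility
(s, passive stress-coping). Each endpoint is standardised against the mean
and sample SD (ddof = 1) of the animal's *own cohort*, and the four
z-scores are combined into

    z_tot = (z_OF + z_SP + z_WM − z_FST) / 4,

so a low z_tot marks the at-risk profile (little exploration, low sucrose
preference, few crossings, long immobility). Within each cohort the 10%
lowest-z_tot animals form the high-risk group (HDR), the 10% highest the
low-risk group (LDR), and the 10% whose ascending ranks straddle the cohort
median the intermediate group (IDR) — for cohorts of 30 and fraction 0.10
that is ranks 1–3, 28–30 and 14–16. "Intermediate" admits several readings;
the median-centred window is the least arbitrary and is configurable. Ties
in z_tot are broken by animal id so assignment is deterministic. The
selected animals (90 of 300 at the default design) are characterised per
endpoint by fixed-effects one-way ANOVA computed from sums of squares, with
Tukey's HSD post hoc (Tukey–Kramer harmonic-n for unbalanced groups,
p from the studentized-range distribution) when the omnibus F is
significant at 0.05. Degenerate cohorts (zero within-cohort SD) raise an
error naming the cohort rather than propagating NaNs.

### Behavioural generator

One scalar latent propensity per animal (standard normal by default)
drives all four endpoints through signed linear loadings plus independent
Gaussian noise; values are clipped to their physical ranges (0–600 s,
0–1, ≥ 0, 0–360 s) and crossings are rounded to integers. The immobility
loading is negative relative to the others, encoding that higher immobility
accompanies higher risk. Defaults (means 30 s / 0.65 / 2.0 / 50 s, residual
SDs 12 / 0.20 / 1.0 / 45, loadings +9 / +0.15 / +0.8 / −30 per unit latent)
were chosen once so that the *selected* extreme deciles land near the
group summaries the study design anticipates (high-risk ≈ 20 s centre time
and ≈ 90 s immobility; low-risk ≈ 47 s and ≈ 20 s after floor clipping).
Clipping (rather than resampling) keeps generation bit-reproducible under a
seed at the cost of a small mean bias where a bound binds — material only
for immobility, whose floor sits ~1.1 SD below the mean; tests compare
against the clipped-normal closed form, not the unclipped mean. Inter-trait
correlations in the source population are not published; the latent-factor
defaults are an assumption, and `null_mode` severs them entirely for
calibration runs.

## Stage 2 — voxel-wise PET group comparison

Processing follows the standard small-animal pipeline: Gaussian smoothing
at 0.6 mm isotropic FWHM (per-axis sigma = FWHM / (2√(2 ln 2)) / spacing,
i.e. ≈ 0.658 / 0.658 / 0.329 voxels at the 0.3875 × 0.3875 × 0.775 mm PET
grid; nearest-neighbour edge extension avoids rim darkening), optional
six-parameter rigid registration (translations in mm, rotations in degrees
about the volume centre, intrinsic x→y→z order — conventions on which
upstream tools differ, fixed here once), then division of every voxel by
the mean
activity inside the whole-brain mask (the union of all atlas ROIs), which
cancels per-animal global tracer scale exactly.

Registration maximises the mutual information of the 32 × 32 joint
intensity histogram (binned over each volume's 1st–99th percentile range,
MI in nats) with Powell's derivative-free method and trilinear resampling,
in two resolutions: a first pass on copies smoothed by an extra 1.5 mm
FWHM — whose smoother MI landscape steers the search past the
interpolation-induced local optima that trap a single-resolution run —
seeds the pass on the native volumes. A result whose MI falls below the
starting value is replaced by the start point, and non-convergence is
flagged, never silent. Registration is a pipeline flag rather than an
always-on stage because the synthetic volumes can be generated pre-aligned.

Statistics per contrast (HDR vs IDR, LDR vs IDR, HDR vs LDR): pooled-
variance unpaired two-tailed t-test at every in-mask voxel (df = n_A + n_B
− 2; zero-variance voxels get p = 1 and a degeneracy flag), BH step-up
FDR q-values across in-mask voxels, and a signed Z-map defined as the
standard-normal quantile of the t cumulative probability — the mapping is
a convention choice, stated here because published ROI tables report Z
without defining it. The headline significance path thresholds the
*uncorrected* p at 0.05 and keeps only connected components of at least
50 voxels (face/6-connectivity by default, 18/26 selectable; positive and
negative voxels are labelled separately, since signed extraction is what a
signed ROI table implies); this mirrors analyses where BH leaves no
voxel significant at the low df of n ≈ 30/group, while q-values remain
available. Cohen's d is derived from t as d = t·√(1/n_A + 1/n_B) and
classified moderate (< 0.80), large (0.80–1.20, boundaries inclusive) or
very large (> 1.20). Published tables pair Z ≈ 2.6 with d ≈ 0.98 at these
group sizes, a pairing no standard Z↔d mapping reproduces; this package
derives d from t and documents the divergence rather than reverse-
engineering an undocumented relation. Per ROI overlapping a surviving
cluster, the summary row reports mean ± SD of Z and of d over the
significant in-ROI voxels, the median voxel p as the representative p
(another undefined convention fixed here), and the voxel count; ROIs
without overlap are omitted.

### PET generator and atlas

The synthetic atlas is a deterministic arrangement of 13 box ROIs named
after the regions the study's tables discuss (PrL/IL, Mot, Som, Aud, DStr,
VStr, Thal, Amyg, Hipp, PAG, SupCol, RN, Cereb; 144 voxels each, all above
the 50-voxel extent floor) plus one large "Rest" block standing in for the
unlisted majority of brain tissue, on a 40 × 40 × 24 grid at the PET voxel
size. It shares the NIfTI-1 interface of a real digital mouse atlas, which
is therefore a drop-in replacement.

Subject volumes are baseline × group-multiplier × per-animal lognormal
global scale + i.i.d. Gaussian noise, with optional rigid misalignment
drawn per animal. Multiplicative scale matches what ratio normalisation
removes; i.i.d. Gaussian noise keeps the t-test's assumptions exact so
calibration checks are clean. One consequence of ratio normalisation worth
stating: only *relative* regional differences are identifiable, and any
net shift of the whole-brain mean redistributes into compensatory apparent
effects elsewhere. The large Rest region (≈ 89% of brain volume, multiplier
1 in every group) keeps that redistribution below ~0.3% for the default
focal effects, which is why the planted signs survive normalisation. The
default multipliers encode the published direction structure (high-risk
hypermetabolic vs intermediate in PrL/IL, Mot, Aud, VStr, Amyg with a
hypometabolic thalamus; low-risk hypometabolic vs intermediate in DStr and
Thal; high above low additionally in Som, Hipp, PAG, SupCol, RN, Cereb),
at ±2–9% of baseline with noise chosen (SD 12 at baseline 100) so
post-smoothing per-voxel d lands near 1 — the magnitude regime the
published ROI tables report. The milder ±2% effects sit near d ≈ 0.35
against the intermediate group and only occasionally clear the cluster
filter there, emulating regions significant only in the extreme-vs-extreme
comparison.

What the generator does *not* emulate: PET physics (decay, scatter,
partial-volume, reconstruction correlations), anatomical variability,
spatially correlated physiological noise, and real atlas geometry. Passing
tests therefore demonstrate the correctness and calibration of the
*analysis*, not the biology of any real cohort.

## Design power utility

The sample-size computation for the behavioural arm uses the noncentral F
distribution: for k groups of n, power = P(F' > F_crit(α; k−1, N−k)) with
noncentrality λ = N·η²/(1−η²). At the design point (k = 3, η² = 0.1,
α = 0.05, n = 30) the analytic power is 0.801, cross-checked by a
vectorised Monte-Carlo simulation with equally spaced group means scaled to
the same λ.

## Problem sizes and numerical choices

Tests and the reproduction script run entirely on synthetic data at the
study's own scale where that is cheap (300 animals, 30/group imaging, the
default 40 × 40 × 24 grid) and at reduced-but-sufficient scale elsewhere:
null calibration uses 200 simulated experiments on a 16³-voxel cube brain;
effect recovery 20 seeded end-to-end runs; registration recovery 20
perturbation trials on one smoothed brain. Tolerances: oracle equivalence
at 1e-10 (exact for connected components); stochastic checks at 3
Monte-Carlo SE. Seeds propagate from a single integer through
`numpy.random.SeedSequence`, so every artefact is reproducible
bit-for-bit from the run manifest.

## Known limitations

- The intermediate-decile definition, the Z-map convention, the
  representative-p convention and the rotation conventions are this
  package's explicit choices where the source design is silent; all are
  configurable or documented above.
- Selection-on-extremes makes exact calibration of the generator to
  published group summaries ill-posed; calibration is approximate and
  reported by the analysis scripts, not asserted by tests.
- The imaging group size is 30/group by default (matching the selection
  arithmetic); a 33/group variant can be requested via
  `imaging_n_per_group` only if selection provides enough animals, since
  published reports are internally inconsistent on this count.
- MI registration is validated for the perturbation range ±3 voxels / ±5°;
  far larger misalignments may need a coarse pre-search.
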