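# Methods

## Scope and data model

The pipeline quantifies paired pre/post-treatment PSMA PET scans. A scan is
a 3-D SUV grid (body-weight-normalized, dimensionless) with per-axis voxel
spacing in mm; world coordinates are `origin + index * spacing` with
0-based indices. All volumes of one patient are assumed to share a single
grid: same-scanner follow-up without a registration step. How pre and post
scans of a real cohort were spatially aligned is generally not recoverable
from published reports; identity alignment is the explicit assumption here,
and the lesion-matching step depends on it.

Volumes and VOI masks travel as NIfTI-1; lesion tables and cohort tables as
CSV; segmentation and phantom parameters as YAML. One mask file per
compartment (prostate / lymph node / bone), masks of different compartments
disjoint. SUV conversion from activity concentration
(`suv_from_activity`) is provided as a helper; I/O assumes volumes are
already in SUV units.

## Segmentation

Lesions are connected components of voxels whose SUV exceeds a threshold,
restricted to the compartment VOI:

- **Absolute threshold**, default SUV 3.0 for bone. The scan-dependent
  soft-tissue threshold formula used by some groups is not public in a form
  this package could cite, so the default soft-tissue strategy is the same
  absolute 3.0 with a plug-in point (`soft_tissue_threshold` may be a
  callable `f(volume, voi) -> SUV`) rather than an invented formula.
- **Relative (isocontour) threshold** at a fraction (default 45%) of the
  VOI's SUVmax. For high-uptake tumors this underestimates the volume
  relative to the absolute threshold (verified as a set-inclusion property
  in the tests); it is provided for method comparison only and is not used
  by the main pipeline.

"Above the threshold" is implemented strictly (`>`), configurable to `>=`.
Default connectivity is 26 (faces + edges + corners), the common choice for
sparse PET foci; 6 and 18 are available for sensitivity analyses.
`min_lesion_voxels` defaults to 1 — no size filter. Component order is
deterministic (sorted by minimum linear C-order index), which fixes lesion
ids. Spatially adjacent but disconnected uptake within one VOI is split
into separate lesions.

## Indices

Per lesion: SUVmax, SUVmean (arithmetic mean over the supra-threshold voxel
set only), PSMA-TV = voxel count × voxel volume in cm³ (exact), and
PSMA-TL = SUVmean × PSMA-TV (units cm³·SUV). Whole-body indices are the
lesion maximum (SUVmax) and sums (TV, TL); compartment aggregates partition
the whole-body sums. A compartment without lesions is *absent*, never 0:
a zero SUVmax is physically meaningless, and the absent convention keeps
reduction ratios and CR logic well-defined.

## Response classification

The reduction ratio is `1 - post/pre` (requires `pre > 0`; undefined
baselines are excluded from statistics, never coerced). Lesion
correspondence across timepoints uses voxel overlap: each follow-up lesion
is assigned to the baseline lesion sharing the most voxels (ties to the
smaller baseline lesion id); zero-overlap follow-up lesions are *new*,
unmatched baseline lesions *disappeared*. When only index tables are
available, correspondence falls back to shared `(compartment, lesion_id)`
keys.

Categories are assigned in rule order CR → PD → PR → SD:

1. **CR**: zero residual segmented lesions (new lesions included).
2. **PD**: ≥ 2 new lesions, or a ≥ 30% increase of PSMA-TV or SUVmax in any
   matched lesion or in the whole-body aggregates.
3. **PR**: > 30% reduction of both wbSUVmax and wbPSMA-TV.
4. **SD**: the rest.

Two interpretation choices are deliberate and documented: "uptake value" is
operationalized as SUVmax (the only uptake index reported per lesion and
per patient in this literature), and PD is checked per lesion *and* whole
body, before PR — a growing primary with regressing metastases must come
out PD even though the whole-body burden improves. Boundary semantics:
exactly +30% triggers PD (`>=`), exactly −30% does not qualify for PR
(strict `>`). The comparisons are evaluated multiplicatively
(`post >= 1.3*pre`, `post < 0.7*pre`) so boundary behavior does not depend
on rounding of derived ratios.

## Synthetic phantom cohorts

The generator's role is to produce paired scans whose ground truth is known
exactly, with the statistical structure the analysis assumes.

**Rendering.** Uniform background (SUV 1.0, a typical soft-tissue level) +
hard ellipsoidal plateaus of height `peak_suv` per lesion, Gaussian PSF
blur (default FWHM 5 mm, matching the axial slice thickness as a
resolution proxy), then additive Gaussian noise (default SD 0.2 SUV)
truncated at 0. Hard ellipsoids give the analytic volume 4/3·π·abc for
parameter-recovery tests. Default grid 96×96×96 at 2.73×2.73×5 mm — a
cropped torso stand-in at scanner-like in-plane resolution chosen so a full
30-patient paired cohort renders and analyzes in well under a minute.
VOIs are the baseline lesion ellipsoids dilated by 3 voxels; lesion centers
sit on well-separated per-compartment slots so VOIs never touch.
Occasional non-lesion hot regions (urinary pooling in the bladder) are
rendered *outside* every VOI; the tests assert they never leak into the
quantification.

**Post-treatment change.** Each lesion carries two multipliers: uptake
(`post_multiplier_suv`, scaling the plateau height) and volume
(`post_multiplier_volume`, scaling semi-axes by its cube root); 0 encodes
disappearance.

**Cohort calibration.** Baseline SUVmax and reduction ratios are drawn from
per-compartment normal distributions calibrated to a published pre/post-ADT
cohort of 30 advanced-prostate-cancer patients: baseline SUVmax means ± SD
30.1 ± 21.4 / 27.2 ± 20.6 / 28.5 ± 22.4 (prostate / nodes / bone; truncated
to [10, 90]), SUVmax reduction ratios 0.49 ± 0.52 / 0.74 ± 0.37 /
0.63 ± 0.34, volume reduction ratios 0.50 ± 0.94 / 0.89 ± 0.19 /
0.65 ± 0.37. Disease-spread patterns follow the same cohort (30% prostate
only, 20% +nodes, 17% +bone, 33% +both); the default response mix is
2 CR / 24 PR / 2 SD / 2 PD, scaled by largest remainder for other cohort
sizes. PSA is lognormal at baseline (median 42 ng/mL, log-SD 1.2) with a
planted reduction ratio ~N(0.95, 0.06) truncated to [0.75, 1.0]. ISUP grade
group 5 occurs with probability 16/30 (CR patients are forced into the <5
stratum, mirroring the source cohort); 20% of patients are on ADT
monotherapy. No systematic ISUP effect on reduction ratios is planted — the
stratified machinery is exercised structurally, not calibrated.

**Category planting.** Multipliers are sampled inside the region of
multiplier space implied by the intended category, with margins off the
±30% boundaries so PSF blur and noise cannot flip a category: PR reduction
ratios truncated to [0.40, 0.95] (prostate additionally kept visible above
the segmentation threshold so a responder never degenerates into an
accidental CR), SD to [−0.10, 0.20], PD primaries grow ×2.8–4.0 in volume
with uptake multipliers 0.45–0.95 (volume up, uptake down — the pattern of
real threshold-segmented progressors), CR sets all multipliers to 0. Every
patient is then verified by running the actual classifier on the analytic
(unrendered) index values; mismatches are resampled. Consequences worth
knowing: the truncation raises the realized mean prostate SUVmax reduction
ratio (≈0.55–0.60) above the nominal 0.49 calibration mean — recovery tests
therefore compare pipeline estimates against the *planted* means, not the
nominal calibration; and because the rendered plateau is background + peak,
planted and measured ratios differ by a small background offset (≲0.02 at
these uptake levels).

**What the phantom does not emulate.** Reconstruction artifacts, spatially
correlated noise, partial-volume effects beyond Gaussian blur, lesion shape
irregularity, patient motion or misregistration between timepoints, and
genuinely new post-treatment lesions (progression is planted as growth, as
in the documented progressor cases). Passing recovery tests therefore shows
the analysis chain is correct and well-calibrated under its own
assumptions, not that it is robust to every property of clinical images.

## Statistics

Paired pre/post comparisons: Wilcoxon signed-rank, two-sided, zeros dropped
(classic convention; the SPSS convention used by clinical reports is not
always documented — the strict/lenient difference only matters with exact
zeros, which continuous indices essentially never produce). Exact
permutation null for n ≤ 25 when |differences| are untied (scipy's
recursion); with midrank ties the conditional exact distribution is
enumerated directly over all 2ⁿ sign patterns for n ≤ 20 (scipy's "exact"
method ignores ties and disagrees with the conditional enumeration, so the
enumeration is done in-package); tied samples with 20 < n ≤ 25 fall back to
the normal approximation with tie correction, as do all larger samples.

Group contrasts: Mann–Whitney U, exact for min(nₐ, n_b) ≤ 8 (scipy's
recursion when untied; full combination enumeration under ties when
feasible), normal approximation with tie correction otherwise.
Associations: Spearman's rho as midrank Pearson, exact n!-permutation p for
n ≤ 9, Student-t approximation otherwise.

All tests are two-sided at the 5% level; no multiple-testing adjustment is
applied (each index is reported with its unadjusted p, matching standard
practice in this literature). Missing compartments are handled by pairwise
deletion with per-row n; for paired tests and summaries, a compartment
present at baseline but fully regressed at follow-up contributes a
follow-up burden of 0.

## Numerical conventions

- Voxelized ellipsoid volumes are compared to 4/3·π·abc within a
  one-voxel-surface-shell tolerance (surface area × max spacing).
- Lesion ids and component order are deterministic (minimum linear index).
- All randomness flows through `numpy.random.default_rng` seeded from
  explicit integers; identical seeds give bit-identical phantoms and
  cohorts.
- Exact-test p-values use a 1e-9 slack when comparing permutation statistic
  deviations, absorbing floating error in midranks.

## Known limitations

- The classifier's hybrid per-lesion/whole-body PD rule is one defensible
  reading of mPERCIST; criteria sets differ between groups.
- Lesion matching by single-voxel overlap is only meaningful on a shared
  grid; misregistered inputs would need alignment upstream.
- The soft-tissue threshold is a stand-in default (3.0) until a
  scan-context formula is plugged in.
- Cohort statistics treat lesions within a patient as exchangeable within
  compartments; no hierarchical modeling is attempted.
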