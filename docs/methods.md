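# Methods

This note documents the models and procedures implemented in
`fetalmorph`, the assumptions behind them, the numerical choices, and the
limits of what the synthetic data can demonstrate.

## Data model

The pipeline consumes 3D integer label volumes (NIfTI) on an isotropic
0.6 mm grid, with one label per structure: total brain (TB), cortical
plate (CoP), white matter (WM), deep grey matter (DGM), cerebellum (CB),
thalamus (Th), lateral posterior ventricle horns (LV), choroid plexus
(ChP), frontal horns (FH), brainstem (BS), cavum septum (CSP), and five
cortical-lobe parcellations (FL, TL, PL, OL, IL).  The five lobes
partition the cortical-plate shell, so a single integer grid suffices:
the CoP mask is the union of the lobe labels (plus the plain CoP label
where no parcellation exists) and the TB mask is the union of all
foreground labels.  TB and CSP are measured bilaterally; all other
structures only on the distal hemisphere, the one facing away from the
ultrasound probe and therefore free of skull shadowing.

Coordinates are 0-based voxel indices; world position is index × spacing.
No affine rotations are modelled — alignment of real scans is a separate
(learned) step outside this package's scope.

## Preprocessing contracts

- **Resampling** to isotropic voxels (default 0.6 mm): trilinear for
  intensities, nearest-neighbour for labels (label identity must
  survive).  `scipy.ndimage.zoom` is used with `grid_mode=True`, the
  pixel-area convention appropriate for regridding; with the sample-point
  convention a digital ball loses ≈13% of its volume at a 2× downsample,
  versus <1% with the convention used.
- **Intensity normalisation**: affine map of the per-volume min/max onto
  [0, 1]; constant volumes are rejected rather than silently zeroed.
- **Centre crop** to 160³ voxels about the foreground centroid, padding
  with background where the window overruns the grid.
- **Distal restriction**: the mid-sagittal plane is taken through the TB
  centroid orthogonal to the grid axis of greatest extent (phantoms are
  axis-aligned).  Proximal structure labels are replaced by the generic
  TB label, not background: the tissue is still brain, it merely cannot
  be parcellated, and the bilateral TB volume must be unaffected.

## The 28 image-derived phenotypes

Volumes are voxel counts × voxel volume (0.6³ = 0.216 mm³).  The voxel
volume is the cube of the edge length; an isotropic "0.6 mm" grid has
0.216 mm³ voxels, not 0.6 mm³.

**Surface area.**  The CoP mask is meshed with the topology-consistent
Lewiner marching-cubes variant at iso-level 0.5 after zero-padding, and
the triangle areas are summed.  The binary mask is pre-smoothed with a
Gaussian (σ = 1 voxel, configurable) before meshing: meshing the raw
mask carries a persistent staircase bias of about +9% on curved surfaces,
while the smoothed mesh is within 0.5% of the analytic sphere area at a
20-voxel radius and converges with radius.  Note the area of a shell mask
includes both its pial and inner surfaces.

**Cortical depth.**  The exact Euclidean distance transform of the TB
mask (per-axis spacing weights, `scipy.ndimage.distance_transform_edt`)
gives each voxel's distance in mm to the nearest background voxel; the
depth map is this field restricted to the CoP.  On spherical phantoms the
error against the analytic R − ρ is below one voxel diagonal.

**Cortical thickness.**  From each pial-boundary voxel (CoP voxel
6-adjacent to background) a ray marches inward along the trilinearly
interpolated gradient of the depth field in steps of 0.25 voxel until it
enters WM (interpolated indicator ≥ 0.5); the path length, plus half a
voxel for the seed-centre offset from the pial surface, is the local
thickness.  Rays are capped at 10 mm to contain degenerate geometry.  The
step, cap and seed rule are exposed as parameters; on an ideal flat slab
the estimate is exact, and on a one-voxel shell it returns ≈ one voxel.

**Sylvian fissure depth** is the median (not mean) cortical depth over
the insular lobe — robust to the mixture of inner and outer boundary
voxels.  Medians of even counts are the mean of the two central values.

**Relative measures.**  Structure volumes are normalised by TBV, lobe
volumes by CoPV; rILV:rPLV is the ratio of the two relative lobe volumes
and is flagged missing when the parietal lobe is empty.  Missing labels
yield NaN measures rather than failing the scan.

## Growth standards

For each IDP, values y against gestational age (GA, weeks) follow a
Gaussian with a degree-2 fractional-polynomial mean and log-linear SD:

    y | GA ~ N( β₀ + β₁·GA^p₁ + β₂·GA^p₂ ,  exp(γ₀ + γ₁·GA)² )

Powers come from the standard candidate set {−2, −1, −0.5, 0, 0.5, 1, 2,
3} (power 0 = log GA; a repeated power p contributes GA^p and
GA^p·log GA); the pair minimising residual deviance is selected.
Optional skewness/kurtosis terms of the broader GAMLSS family are not
modelled: the published standard is fully described by mean and SD
coefficients, and the Gaussian member reproduces it exactly.

Fitting is staged: OLS mean fit → log-SD fit on the residuals → one
weighted mean refit (weights 1/SD²) → SD refit.  The SD fit uses the
half-normal correction: per integer-GA bin, SD̂ = √(π/2)·mean|residual|
(unbiased under Gaussian residuals), then log SD̂ is regressed linearly
on the bin-mean GA with bin-size weights.  Averaging before taking logs
avoids the −(γ+log 2)/2 bias of E[log|Z|].  When exact SD values are
available (e.g. refitting a published curve) the model is fit to
log SD directly.

Centiles are mean(GA) + Φ⁻¹(p)·SD(GA); z-scores invert this, and the
round trip is exact to numerical precision.  No extrapolation is allowed
outside the fitted GA domain (hard error).  Repeated scans of the same
fetus are pooled cross-sectionally; within-fetus correlation inflates
the nominal precision of the curves but does not bias them, which the
longitudinal simulation test confirms.

With noisy data the selected power pair may differ from the generating
one (e.g. (3,3) instead of (2,3)) while describing a nearly identical
curve over the 9-week domain; coefficient-recovery tests therefore fix
the generating powers, and curve-level tests compare predictions.

**Outlier filter.**  Values more than 4 SD from the GA-specific pooled
mean are removed in a single pass, with mean/SD computed in integer-week
bins over all sites; bins with fewer than 3 rows are skipped with a
warning.  On clean Gaussian data the false-removal probability per scan
is P(|Z| > 4) ≈ 6.3×10⁻⁵.

## Cross-site comparability

**SSD.**  Every scan is converted to a z-score against the pooled growth
standard (this is the gestational-age adjustment; window-local raw means
would confound site with within-window GA skew).  A site's SSD in a
3-week window (18+0–20+6, 21+0–23+6, 24+0–26+6; half-open [18,21) etc.
in weeks) is the mean z of its scans.  |SSD| ≤ 0.5 is the prespecified
poolability bound.  Because the pooled model is fit including every
site, a site carrying a true offset δ and a fraction w of the data shows
an expected SSD of δ(1−w) — the pooled mean absorbs its own share; the
construction-oracle tests account for this.

**Variance components.**  A Gaussian random-intercept model
y = Xβ + b_site + ε with fixed effects sex and GA (entering with the
pooled model's FP powers when available) is estimated by REML profiled
to a one-dimensional search over λ = σ²_site/σ²_resid; each site block
of the marginal covariance is inverted in closed form (Sherman–
Morrison), and the reported quantity is 100·σ²_site/(σ²_site+σ²_resid).
The estimator agrees with `statsmodels` MixedLM to ~0.1% on simulated
data.  A Gaussian random effect replaces the unspecified "nonparametric"
discrete-mass-point variant sometimes used in this literature; the
declared estimand is the Gaussian REML fraction, validated by simulation
recovery (including the low single-percent regime typical of these
data).  Note that with K sites the fraction estimate is conditional on
the realised site offsets; tests compare against the realised, not the
population, fraction.

**Leave-one-site-out.**  The standard is refit without each site and the
maximum absolute shift of the 3rd/50th/97th centiles over the GA domain
is reported in pooled-SD units.

## Maturation index

Features are the 28 IDPs, standardised to zero mean and unit variance.
Confounds — sex and hemisphere as single demeaned indicators, site as K
demeaned indicators (the rank deficiency is absorbed by the
pseudo-inverse) — are removed simultaneously by projection
X̂ = X − VV⁺X.  Gestational age itself is deliberately not deconfounded:
age-dependent covariates cannot be removed from an age-prediction
target.

Per-confound accounting: %VE_j = 100·‖V₁V₁⁺X_j‖²/‖X_j‖² is the variance
a confound would explain acting alone; %UVE_j is the variance explained
by the full confound set minus that explained by the others — the unique
contribution.  Under mutually orthogonal confounds %UVE = %VE, which the
tests verify against a brute-force two-regression oracle.

The regressor is a random forest with 100 trees and
⌈0.15 × n_features⌉ = 5 candidate features per split (scikit-learn's
fractional `max_features` truncates instead of rounding up, so the
integer is passed explicitly).  Cross-validation is 3-fold grouped by
fetus: all scans of a fetus fall on one side of every fold, and
standardisation and deconfounding parameters are estimated on training
folds only and applied to test folds — the paper-level description does
not fix this, and estimating them per training fold is the only
leakage-free choice.  Reported metrics use out-of-fold predictions
exclusively: MAE in days (weeks × 7), Pearson r, and ICC(A,1) — two-way
absolute agreement, single measures, computed from the McGraw–Wong mean
squares and cross-checked against `pingouin`.  The per-scan brain-age
delta is predicted minus chronological age.

Feature importances are reported both as impurity decreases (averaged
over folds, normalised to sum 1) and as permutation importances on the
held-out folds; the latter replaces SHAP, serving the same ranking role
with no extra dependency.

## Synthetic data

The generators define the study conditions; they are not tuning knobs.

**Cohort rosters.**  The default configuration reproduces the published
flow exactly: 4321 enrolled; 681 missing follow-up and 84 severe
morbidity (765, 17.7%, excluded); 2906 of the remaining 3556 with ≥1
scan in [18, 27) weeks; 101 low-developmental-score exclusions; 2805
included.  Site proportions follow the published per-site contributions
(Turin 11.2% … Nagpur 18.8%, renormalised).  Scan schedules follow the
acquisition protocol — first visit GA ~ U[14, 18], subsequent visits at
+5 ± 1 weeks (uniform jitter) truncated at 42.  Under that protocol
every fetus would hit the 9-week window, so the fetuses designated as
lacking an in-window scan receive a realistic "missed-visit" schedule
(one early scan, then a gap to ≥27 weeks).  All randomness flows from a
single integer seed.

**Phantoms** are sphere-based idealisations: a TB ball whose digitised
volume matches the reference TBV growth equation at the requested GA
(within 2%; in practice ≈0.2% at 0.6 mm), a CoP shell of 2.5 mm default
thickness partitioned into five lobes by angular sectors about the
left–right axis (equal fifths by default), WM filling the interior, and
subcortical structures as interior balls at fixed, non-overlapping
positions, sized by configurable fractions of TBV.  The default
fractions (DGM 3.5%, CB 2.5%, Th 1.2%, BS 1.0%, LV 0.7%, ChP 0.5%,
FH 0.5%, CSP 0.2%) are mid-gestation plausible constants chosen once for
geometric feasibility; only TBV is anchored to a published equation.
CSP sits at the centre, straddling the mid-sagittal plane.  There is no
gyrification, no speckle, no shadowing and no motion: the phantom's
purpose is that every downstream measure has a closed-form oracle, so
passing the geometry tests certifies the estimators, not robustness to
real ultrasound artefacts.

**Simulated IDP tables** draw every column from the reference TBV
standard scaled by a per-IDP fraction, value = frac·[mean(GA) +
(offsets + ε)·SD(GA)], with site/sex/hemisphere offsets expressed in
GA-specific SD units and ε ~ N(0, noise_scale²).  Lobe-volume fractions
sum to the CoP fraction so relative-volume identities hold by
construction.  The non-volume columns (areas, depths, thicknesses) reuse
the same growth curve with small scale factors — their units are
nominal; what matters downstream is a smooth GA-dependent signal with
known confound structure.  Zero noise reproduces the mean curve exactly;
at scale, sample moments match the generating curves within sampling
error (verified at 3 standard errors).

## Problem sizes in tests

The statistical tests run at roughly 2 000–6 000 simulated scans and the
geometric tests at ball radii of 5–30 voxels on grids up to 160³ —
sizes at which the sampling error of every estimate is small against the
asserted tolerance while the full suite stays fast.  Stochastic tests
use fixed seeds and 3-standard-error bounds derived from their own
constructions.

## Known limitations

- The phantom geometry cannot exercise hemisphere asymmetry, partial
  labels, topological defects or acquisition artefacts.
- Only the TBV growth equation is anchored to published coefficients;
  the other 27 standards exist here only as simulation targets.
- The variance-components estimand is the Gaussian-REML fraction, not
  the discrete-random-effect variant.
- Within-fetus correlation is acknowledged but not modelled in curve
  fitting; standard errors of fitted curves are therefore optimistic for
  longitudinal data.
- Headline real-data figures (e.g. few-day brain-age MAE at high r/ICC)
  depend on the restricted scans and are not reproduced; the synthetic
  analogues certify the machinery (leakage-free CV, deconfounding,
  recovery of injected effects), not the biological effect sizes.
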