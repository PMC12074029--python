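# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## Connectivity model

Per animal, functional connectivity is the Pearson correlation between
ROI-averaged time series (rows = volumes, one per TR; columns = ROIs).
The model assumes stationary, approximately Gaussian ROI signals over the
scan; no dynamic (sliding-window) connectivity, partial correlation or
precision-matrix estimation is attempted.

All group-level computation happens in Fisher-z space (`z = atanh r`),
which stabilizes the sampling variance of r at roughly `1/(T−3)` for `T`
volumes. Group averages are computed in z and mapped back with `tanh`; a
config switch (`average_domain="r"`) averages raw correlations instead for
users who want the literal arithmetic mean. Correlations with `|r| ≥ 1 −
1e−7` are clipped before `atanh` so z stays finite; the induced bias is
orders of magnitude below sampling noise. The matrix diagonal is masked
(NaN) in z space and restored to 1 in r space.

## The multi-parameter screen

Two selection arms run on the per-edge z values with the animal as the
unit:

* Significance: two-sample t-test per unordered edge. The pooled-variance
  (Student) variant is the default — an unqualified "two-sample t-test"
  conventionally means pooled, and the intended group sizes are
  near-equal — with Welch available by config. p-values are two-sided.
  Multiplicity correction is Benjamini–Hochberg FDR at α = 0.01 by
  default; Bonferroni (FWE) is available because both conventions are in
  circulation for this design. Edges where the pooled variance is exactly
  zero but the means differ get p = 1 with a warning: there is no
  within-group variability to test against.
* Effect size: Cohen's `D = (z̄_A − z̄_B)/s_pooled`, threshold `|D| > 0.8`
  ("large"). Positive D means stronger connectivity in the treated group
  (group A). Zero-pooled-SD edges are masked from this arm but remain
  eligible for the significance arm.

The screen reports both arms, their intersection, and the enhanced/reduced
split. A note on power at desk scale: with 9 vs 8 animals and 465 edges,
the FDR arm at α = 0.01 requires |t| ≈ 5, i.e. much larger standardized
effects than d = 1.5; the effect-size arm is the one with usable power at
that effect size (analytically ≈ 0.89 per edge), and it is the arm the
recall measurements in the tests and the acceptance script quantify. The
|D| > 0.8 arm equally admits substantial sampling noise at n = 17 (the
null sampling SD of D is ≈ 0.5), which is exactly why the method crosses
it with the significance arm rather than using it alone.

## Node Modulation Index

For ROI i with n−1 connections, rank by |D| descending (ties broken toward
the smaller partner index, making the contributing set deterministic), take
`k = ceil(fraction · (n−1))` (ceil so k ≥ 1 for any atlas size; fraction
defaults to 0.10, so k = 3 at 31 ROIs) and average the signed D. Whether
the original index averaged signed or absolute effects is ambiguous; signed
is the default and `absolute=True` is provided. ROIs are ranked by |NMI|
descending with an alphabetical tie-break. `fraction=1` reduces the NMI to
the plain row mean, a closed-form check used in the tests.

## Seed maps

The seed time course is the unweighted mean over seed voxels (matching the
ROI-averaging convention; no PCA eigenvariate). Each in-mask voxel is
correlated with it, z-transformed, and groups are compared with a
voxel-wise pooled t-test. Voxels with zero between-animal variance (e.g.
the seed's own voxels, whose clipped z is constant) are excluded from the
test. No cluster-extent correction is applied; a voxel-level BH-FDR mask is
available and off by default — thresholds are treated as display-layer
choices.

## Behavior coupling

Screened-edge z values are correlated with behavioral metrics across
animals, both groups pooled by default so the correlation spans the
treatment-induced spread; a per-group option exists. Correlation magnitude
labels follow the Evans scale (0.2/0.4/0.6/0.8 band edges) — a documented
convention of this package, not a claim about any particular study's
cutoffs. Multiple-testing correction across edges × metrics is off by
default (the correlations are descriptive).

## EMG analysis

Recordings are wake-gated by the label track (sleep staging itself is out
of scope); extraction preserves segment boundaries so that RMS windows and
Welch segments never straddle a gap. "Filtered at 50 Hz" is implemented as
an IIR notch at mains frequency (Q = 30), detachable by config — a low-pass
interpretation would contradict analysing a 50–150 Hz band. Welch uses 4 s
Hann windows with 50 % overlap (0.25 Hz resolution at 1 kHz sampling;
these parameters are this package's choice), constant detrend, and
segment-weighted averaging. Band power integrates the density with a
cumulative trapezoid interpolated at the band edges, so disjoint bands
partition the total power exactly; the integrated density matches the
signal variance (Parseval) within a few percent. Reported bands are
20–150, 20–50 and 50–150 Hz. Group comparison aggregates one band power
per animal (no pseudo-replication across windows) and runs a two-sample t
on log power, since band powers are right-skewed and gain effects are
multiplicative. The CWT uses a complex Morlet wavelet (`cmor1.5-1.0`).

## g-ratio morphometry

`g = d_inner / d_outer` with circular-equivalent diameters `d = 2√(A/π)`
when areas are supplied (never mixed per row); the identity
`g = √(A_in/A_out)` is used as an algebraic cross-check in the tests.
"Axon diameter" for the 400 nm stratification means the inner (axonal)
diameter. Rows violating `inner < outer` are rejected with a reported
count. Per stratum, groups are compared with a two-sample t on g; strata
with fewer than 2 axons per group are skipped with a warning. The
g-vs-diameter relationship is summarized by per-group OLS.

## Fiber skeleton metrics

Grayscale images are Otsu-thresholded; binary images pass through.
Skeletons come from topology-preserving thinning (scikit-image). Length
follows the chain-code convention — 1 per orthogonal step, √2 per diagonal
step, times pixel size — with corner-shortcut diagonals (two skeleton
pixels sharing an orthogonal common neighbor) pruned to avoid
double-counting at corners. Branch points are 8-connected clusters of
skeleton pixels with ≥ 3 corrected neighbors, merged to one junction per
cluster to absorb thinning artifacts. Degree is defined on the
junction/endpoint graph (isolated cycles get one degree-2 node); the
node-degree density is the normalized histogram over graph nodes.

## The synthetic generator

The generator defines the conditions under which the pipeline is verified.

* FC cohorts: 31 ROIs, 300 volumes, 9 treated / 8 control animals by
  default. Effects are planted in z space: a target Cohen's D on an edge
  becomes group means separated by `d · σ_z`, with `σ_z = 0.15` the
  between-animal z spread (a free parameter of the generator — no
  animal-level variance estimates exist to calibrate it against). Each
  animal draws its edge z around its group mean, then a multivariate
  normal time series matching its correlation matrix (two-level noise:
  between-animal and within-scan). Non-positive-definite correlation
  matrices are rejected with the offending edges named. Empirical D
  converges to the target as animals and volumes grow; at 300 volumes the
  within-scan estimation noise (`SD ≈ 1/√297`) attenuates it by ≈ 7 %
  (measured mean ≈ 1.45 at target 1.5), an expected finite-T property,
  not a bug. Baseline correlation defaults to 0.1, a modest positive
  resting-state background.
* Voxel volumes: seed voxels carry a latent unit-variance signal; planted
  region voxels mix it at the target correlation; everything else is
  independent noise. No hemodynamics, spatial smoothness or physiological
  nuisance structure is emulated.
* EMG: per-band bandpassed unit-variance Gaussian noise scaled by linear
  gains (band power ∝ gain²) plus a mains sinusoid; a contiguous wake
  block covers the wake fraction and sleep samples are attenuated ×0.2
  (atonia). Between-animal variability is a lognormal gain jitter
  (log-SD 0.2). Real EMG's bursty, non-stationary firing structure is not
  modeled — passing tests show spectral bookkeeping and group inference
  are correct, not that the generator is a muscle.
* Axons: log-normal inner diameters (median 450 nm, log-SD 0.45, spanning
  the 400 nm threshold), baseline g = 0.8, Gaussian noise SD 0.05, planted
  shift −0.05 applied only below threshold in the treated group, g clipped
  to (0.05, 0.98) so `inner < outer` holds by construction.
* Fiber images: unit-step random walks with Gaussian heading drift
  (SD 0.15 rad), reflected at borders; `L` pixels means `L−1` unit steps,
  so a straight 100-pixel segment has analytic length 99. Rasterized chain
  length differs from arc length by the usual chain-code quantization
  (few %, within the 10 % verification band).

One integer seed drives everything through deterministically spawned child
sequences; identical spec + seed reproduces outputs bit for bit.

## Problem sizes used in verification

The replicate counts follow the verification plan (500 null cohorts, 200
planted cohorts, 200 axon replicates); seed-map recovery uses a 20³ grid
and EMG group runs use 30 s recordings — representative-trace scale rather
than the full 24 h recordings such studies acquire, chosen because band
power estimates at 0.25 Hz resolution are already stable at that length and
the comparison operates on one number per animal either way.

## Known limitations

* The screen models no covariates (age, motion) and no spatial dependence
  between edges; BH-FDR assumes positive dependence at worst.
* The effect-size arm's |D| threshold is not a significance statement; at
  n ≈ 17 its null sampling spread admits |D| > 0.8 by chance at a rate the
  calibration tests quantify only for the significance arm.
* ROI names beyond the published abbreviations in the shipped atlas are
  documented placeholders; analyses treat ROI labels as opaque strings.
* Degenerate cohorts (one animal per group) can be generated but every
  inferential entry point refuses them.
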