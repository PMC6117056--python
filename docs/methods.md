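# Methods

## The indices

**LAV% and SD-LAV (CT).** Lung voxels are first calibrated so that the mean
HU inside the trachea mask equals −1000 (pure air); the calibration is a
constant additive shift, the minimal model that preserves threshold
semantics, and the shift is recorded. A voxel is low attenuation volume
(LAV) when its calibrated HU is **strictly below −960** — a voxel at exactly
−960.0 is not LAV. Whole-lung LAV% is the LAV fraction of the entire lung
mask. For the heterogeneity index, lung voxels are ordered cranial→caudal
(and row-major within a slice) and cut into 12 equal-count runs; because
boundary slices straddle two partitions, voxels of such a slice fill the
earlier partition's quota before spilling over, giving bit-reproducible
assignments with counts differing by at most one. The most cranial and most
caudal partitions are excluded (partial-volume effects at the lung apices
and bases), and **SD-LAV** is the sample SD (n−1) of the LAV% of the 10 kept
partitions. Whole-lung LAV% deliberately uses all 12 partitions' voxels;
only the SD uses the kept 10.

With uniform slice spacing, equal voxel count equals equal physical volume,
so voxel-count partitioning is used and noted; the two coincide for every
volume this package generates.

**RER, MRER, SD-RER (OEMRI).** The acquisition is three coronal sections,
each a signal-intensity time series over three phases: room air, 100%
oxygen, room air (5 min each by default). SI_baseline and SI_enhanced are
means over the **last 50%** of the first room-air phase and of the oxygen
phase respectively — the steady-state tails, avoiding the wash-in transient;
the fraction is configurable because the original frame-selection rule is
not documented anywhere. Per pixel,

    RER = 100 · |SI_enhanced − SI_baseline| / |SI_baseline|

(the absolute value makes signal drops positive, so RER measures change
magnitude). Pixels whose baseline magnitude falls below a floor — 5% of the
ROI median baseline per section — are excluded from the ROI and counted,
preventing division blow-ups. **MRER** is the unweighted mean over the
pooled ROI pixels of all sections (pixel-weighted, so larger sections
contribute proportionally; per-section averaging first is a configurable
alternative). **SD-RER** pools all sections' ROI pixels, orders them by
physical cranial-caudal coordinate, cuts them into **10 equal-count
partitions with no end exclusion** (unlike the CT scheme; a flag mimics the
12-minus-2 scheme for sensitivity analysis), and takes the sample SD of the
10 partition means. Pooling across sections rather than partitioning each
section separately is the default; the per-section alternative is retained
behind the same flag set.

## The statistics layer

Two-group comparisons run Shapiro-Wilk per group at α = 0.05 (the gate's α
is a choice; only the gate itself is standard practice): if either group
fails, Mann-Whitney U; otherwise a t-test, Welch-corrected by default with a
classic equal-variance flag. Group summaries report median (25th, 75th
percentile) plus mean ± SD. Constant variables are reported as degenerate
rather than tested. Correlations are Pearson, switching to Spearman when
either variable fails the same gate. Stepwise regression is bidirectional
and p-value-gated (enter 0.05, remove 0.10 — classic defaults, exposed as
flags): forward-add the candidate with the smallest partial p below the
entry threshold, backward-drop any term above the removal threshold,
iterate to a fixed point with an iteration cap. All variables including the
outcome are z-scored, so coefficients are standardized β and a
single-predictor β equals the Pearson r exactly. Candidates that would make
the design ill-conditioned (condition number > 1e8) are skipped with a
warning. No multiple-testing correction is applied by default; a
Benjamini-Hochberg helper exists for users who want it.

## The synthetic generators

**CT phantom.** The lung is a pair of ellipsoids in a (36, 28, 28) grid at
2 mm isotropic spacing by default, with a cylindrical trachea (HU fixed at
−1000 plus 2-HU Gaussian jitter, so calibration has something to estimate)
separated from the lung by a one-voxel moat. Emphysema is placed as
spherical clusters (radius 4 mm default) whose centres are drawn from a
slice density ∝ lung cross-section × max(0, 1 + g·ramp(z)), where
g ∈ [−1, 1] is the cranial-caudal gradient parameter (0 homogeneous,
positive caudal-dominant). Sampling is inverse-CDF on the slice axis, so
sweeps over g under a fixed seed share their random draws and change the
layout smoothly. Clusters overlap freely (the union counts once); placement
stops when the labelled lung fraction reaches the target, with the final
cluster trimmed nearest-voxels-first so the realized fraction lands on the
target exactly (well within the ±0.5 percentage-point contract). Parenchyma
HU is N(−870, 25), emphysema N(−985, 8): with the SDs set to zero the
−960 threshold separates the two populations exactly, which is what makes
closed-form recovery tests possible. A global HU offset emulates scanner
miscalibration and is exactly undone by the tracheal calibration.

**OEMRI phantom.** Per-pixel signal is S(t) = baseline · (1 + a·w(t)) +
N(0, σ), where w(t) is 0 on room air, 1 − exp(−j/τ) during oxygen frame j,
and decays as w_end·exp(−k/τ) afterwards (τ = 3 frames of 20 per phase by
default). The amplitude field a combines the mean level (0.22, the healthy
plateau, giving MRER ≈ 22 at full wash-in), a linear cranial-caudal tilt,
and a reduction inside emphysema-dense regions taken from the CT ground
truth's per-partition fractions (reduction factor 1 − coupling·local
fraction, coupling 1.0). That coupling is a modeling choice — no
quantitative model of how emphysema depresses local oxygen enhancement is
available — and it is the only channel tying the two modalities together.
Noise is additive Gaussian, not Rician: a documented simplification,
adequate at the simulated SNRs (baseline 100, σ ≤ a few units). Negative
noisy samples are clipped at zero with a logged count.

**Cohort.** 40 COPD and 9 control subjects by default. True LAV fraction f
is truncated-normal (COPD 0.25 ± 0.10, controls 0.02 ± 0.01), the true
gradient g uniform (COPD 0–0.7, controls 0–0.1). The enhancement amplitude
follows a = 0.228 − 0.40·f plus group-specific noise, calibrated so the
analytic MRER distribution reproduces the observed group separation
(COPD ≈ 12.9 ± 4.6%, controls ≈ 22.0 ± 3.4% on the plateau scale).
Covariates follow linear links with Gaussian noise: FEV₁ = 3.9 − 8.0·f
(noise 0.5 L), DL_CO = 31 − 70·f (noise 6 mL/min/mmHg), and PaO₂ = 88 −
90·(f·g) (noise 4 Torr). PaO₂ is driven by f·g — the absolute cranial-caudal
slope of the emphysema profile, i.e. the heterogeneous destruction burden to
which ventilation-perfusion mismatch is attributed — rather than by
whole-lung severity f; this is what makes the heterogeneity index, not the
severity index, the structurally correct predictor of oxygenation in the
stepwise recovery experiments. Link noise for DL_CO and FEV₁ is set so the
imaging–function correlations sit in the moderate range characteristic of
clinical cohorts (r ≈ −0.6 to −0.8) rather than being near-deterministic.

The cohort table carries *analytic* imaging indices implied by each
subject's true parameters: a 10-partition linear LAV profile f·(1 + g·ramp)
with per-partition noise 0.10·√f — matched to the cluster-granularity
scatter the CT phantom generator itself produces at the default cluster
size — and MRER on the plateau scale 100·a. The pipeline overwrites these
columns with values measured from actually generated images, which differ
systematically (finite wash-in, emphysema coupling) but track the truth
closely; recovery tests cover both routes. Per-subject image configs carry
seeds derived from the cohort seed via seed sequences, so one global seed
reproduces the entire bundle bit for bit.

**What the generators do not emulate.** Airway trees, lobar fissures,
vasculature, scanner physics (beam hardening, reconstruction kernels),
respiratory motion, Rician noise, and gravity-dependent perfusion gradients
across the three coronal sections. Passing tests therefore demonstrate that
the measurement chain is correct and that the statistical conclusions follow
from the stated effect structure at these sample sizes — not that those
effects have clinical magnitude in real patients.

## Numerical choices and degenerate inputs

Partition quota remainders go to the most cranial partitions (counts differ
by ≤ 1); in-slice order is row-major; SD-RER ordering ties are broken by
pooling order (section, then row-major), which is deterministic. Sample SDs
use the n−1 denominator throughout (configurable `ddof`); the original
denominator convention is undocumented. Volumes with fewer than 12
lung-containing slices are rejected at generation, and partitioning refuses
n < 3 with end exclusion (nothing would remain). Empty trachea masks,
empty phase windows, all-ROI-below-floor sections and constant regression
outcomes raise before any computation proceeds. NIfTI affines are used only
for spacing and axis orientation; a negative diagonal entry triggers a flip
into the canonical index-0-cranial convention, which is logged.

## Problem sizes

Default phantoms are 36×28×28 voxels at 2 mm (≈ 8 000 lung voxels), OEMRI
frames 32×26 over 60 frames × 3 sections; the gradient-sweep experiments
use 48×32×32 grids with 2.5 mm clusters, where cluster-granularity noise
(≈ 3–4 percentage points of SD-LAV) is small enough for the gradient signal
to dominate. The demo pipeline runs 8 + 3 subjects on 24³-scale volumes.
Replicated statistical experiments use 100 cohorts at the full 40/9 design.
These sizes keep a full test run around ten seconds while leaving every
effect comfortably resolvable.
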