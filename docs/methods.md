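# Methods

This note documents the models, numerical choices and limitations behind
`cflung`, in the order data flows through the package.

## FLD quantification (`cflung.fld`)

**Model.** A fast gradient-echo sequence alternates between two echo
times in one breath-hold while the magnitude signal of each voxel decays
mono-exponentially, `S(TE) = S0 · exp(−TE/T2*)`. With exactly two
distinct echo times the TE = 0 back-extrapolation has the closed form
`S0 = S1 · (S1/S2)^(TE1/(TE2−TE1))`; a two-point fit is exact for a
mono-exponential, so no iterative fitting is used (repeat acquisitions
at the same TE should be averaged before the fit). Dividing `S0` by the
reference signal of a 100%-water phantom in the field of view gives the
fractional water density FLD.

**Calibration.** Two phantom-referencing modes exist:

* `te0` (default): the phantom voxels are themselves extrapolated to
  TE = 0, so the reference is the phantom's `S0` and the correction
  factor is exactly 1. This removes any dependence on an empirically
  tuned constant.
* `mean_signal`: the reference is the raw mean phantom signal at the
  first echo times a user-supplied correction factor — the scheme used
  with a long-T2* phantom whose decay over the first echo is treated as
  negligible. The factor is a required user input in this mode; for a
  phantom with decay constant `T2p` and negligible other effects it is
  `exp(TE1/T2p)`.

T1/flip-angle saturation differences between lung and phantom are
absorbed into the calibration; no separate T1 correction is applied.

**Validity flagging.** Per voxel, the fit is invalid when the signal
rises between echoes (no physical decay constant) or when the second
echo is zero with a nonzero first echo. `S1 = S2 = 0` is a valid
zero-signal voxel (FLD 0). FLD values above a configurable cap
(default 1.2) are flagged invalid rather than clipped, so noise
outliers remain visible for QC. Medians are taken over valid voxels
only.

**Acquisition defaults.** TE 1.0/1.8 ms, TR 10 ms, flip 10°, slice
15 mm, FOV 40 cm, matrix 64×64. Voxel dimensions are always an explicit
input and never derived from FOV/matrix, because derived and nominal
voxel sizes can disagree; all volume computations use the explicit
dimensions.

## Region geometry (`cflung.regions`)

Per sagittal slice and per lung, the central region is a rectangle of
half the width and half the height of the lung mask's bounding box;
the peripheral region is every lung pixel outside it. Placement within
the bounding box is an explicit `anchor` option (default `centered`,
with the spare margin of odd dimensions going to the high-index side;
directional anchors abut an edge instead, since "interior boundary"
placements differ between sites). Coordinates are 0-based half-open.
Central and peripheral masks are disjoint and partition the lung by
construction. Multi-slice analyses process slices independently and
pool voxels before taking medians. Volumes are voxel counts times voxel
volume (the "pulmonary thoracic space" when applied to the lung mask).

## Washout analysis (`cflung.mbw`)

**Breath segmentation.** Breaths are delimited on the cumulative-volume
curve (trapezoidal integral of flow, expiration positive) using a
turning-point detector with a volume hysteresis (default 0.05 L), which
is robust to flow noise around zero. A breath is an inspiration segment
immediately followed by an expiration segment.

**Per-breath quantities.** Expired volume and volume-weighted mean
expired N₂ come from trapezoidal integration over the expiration; the
end-tidal concentration is the mean over the final 5% of expired
volume. The phase-III slope S3 is the least-squares slope of N₂
fraction against expired volume over a fractional-volume window
(default 50–95%, configurable; at least 5 samples required), and
Sₙ = S3 / (window-mean N₂). Breaths smaller than half the median
expired volume are flagged and excluded from the slope series.

**Indices.** FRC = (net expired N₂ volume) / (C_start − C_end) with
inspired N₂ taken as zero (pure O₂) and C_end the last end-tidal value.
LCI is the turnover (cumulative expired volume / FRC) of the first
breath whose end-tidal N₂ is below C_start/40 with the following breath
(if any) also below — the two-breath confirmation guards against noise;
an interpolated crossing is available behind a flag. Scond* is the
ordinary-least-squares slope of Sₙ vs turnover over breaths with
turnover in [1.5, 3.0]; the fit's R² gates replicate acceptance
(R² > 0.5). A constant Sₙ series is treated as a perfect degenerate
fit (slope 0, R² = 1), so homogeneous lungs are accepted with
Scond* = 0 rather than rejected on an undefined correlation.
Sacin* = Sₙ(first breath) − Scond*·TO(first breath). Replicate
averaging (triplicates in practice) takes FRC and LCI over all
replicates and Scond*/Sacin* over accepted replicates only.

**Known limitations.** No tissue-nitrogen excretion correction is
applied; re-inspired dead-space gas is not modelled on the analysis
side; SF₆ and other tracers are out of scope.

## Washout simulator (`cflung.synthetic`)

The lung is a set of parallel alveolar compartments. Compartment *i*
holds `frc_fraction[i]` of the total FRC and receives
`ventilation_fraction[i]` of each breath's alveolar tidal volume
`VT − VD`. Breathing pure O₂, its N₂ fraction follows the exact
discrete dilution `C[i,n] = C[i,n−1] · FRC_i / (FRC_i + v_i (VT−VD))`.
Expired gas is dead-space gas (the previous inspirate, N₂-free) over
the first `VD` litres, then a ventilation-weighted alveolar mixture
whose composition drifts linearly across the expiration according to
per-compartment slope coefficients. The coefficients are centred
(`Σ vᵢsᵢ = 0`) so the flow-composition weights sum to one at every
point of the expiration; this keeps the model exactly mass-conserving,
forces single-compartment plateaus flat, and means only slope
*contrasts* between compartments matter. Re-inspired dead-space N₂ is
not returned to the alveoli, which keeps the dilution update closed
form. With unequal specific ventilation and the positive slope
coefficient on the slow compartment, the slow unit dominates late
expiration increasingly as washout proceeds, so Sₙ rises with turnover
— the mechanism Scond* quantifies. This is a deliberately minimal
stand-in for convective ventilation heterogeneity; it contains no
airway tree, no diffusion front, and therefore produces only small
first-breath Sₙ (Sacin* near zero) unless slope contrast is configured.

Flow is a square wave (equal inspiration/expiration) with explicit
zero-flow samples at phase boundaries and amplitude chosen so the
trapezoidal integral of the sampled flow reproduces the tidal volume
exactly; sampling is 100 Hz by default. Noise is additive Gaussian on
the N₂ fraction and, optionally, on flow; seeds are explicit fields and
no global random state is touched. The simulation stops when the mean
expired N₂ falls below 2% *and* the end-tidal 1/40 criterion has held
for two consecutive breaths (operators likewise wash out beyond the
nominal stopping point); this guarantees the analyzer's noise-guarded
LCI crossing lies inside every simulated trace.

Default conditions: FRC 3 L, VT 1 L, VD 0.15 L, 12 breaths/min,
C₀ = 0.78. The two-compartment preset splits FRC 50/50 with a 70/30
ventilation split and slope contrast 1.4 on the slow unit.

## MR simulator

Per voxel, `S(TE) = fld · gain · exp(−TE/T2*)` with the phantom's own
(long, default 50 ms) decay constant on phantom voxels and additive
Gaussian noise clipped at zero (magnitude images are non-negative; a
Rician model is deliberately not the default at the SNRs exercised).
Default lung T2* is 2 ms, typical of lung parenchyma at 1.5 T. Noiseless
stacks invert exactly through the quantifier (round trip to machine
precision). Note that TE0 extrapolation amplifies voxel noise by a
factor of ~2.5 at these echo times, so FLD error targets must be read
against the lung-signal SNR, not the (much brighter) phantom signal:
at lung first-echo SNR 100 the median absolute FLD error is ≈0.004.

## Cohort generator

One row per subject with group label, demographics, spirometry, MBW
indices and regional mFLD metrics. Metrics are drawn per group from
configured normal distributions; defaults are calibrated to the group
means/SDs of a small adult CF-vs-control study (e.g. LCI 6.0 ± 0.3 vs
9.9 ± 3.9; central mFLD_TLC 0.11 ± 0.01 vs 0.18 ± 0.04). Cross-metric
couplings are listed as (target, predictor, ρ) within-group
correlations, applied in order while preserving each target's group
mean and SD; defaults couple Scond* to central mFLD_TLC (ρ = 0.6),
Sacin* to peripheral mFLD_TLC, LCI to Scond*, and FEV₁ negatively to
LCI. mFLD ratios and BMI are computed per subject, not drawn.
Physical lower bounds are enforced by flooring, which slightly lifts
means when the bound is within ~1 SD (relevant for CF Sacin*); tests
compare against the floored-normal closed form. The generator emulates
the between-subject distributions only — it contains no images or
traces, no measurement error model, and no non-Gaussian tails, so
passing cohort-level tests demonstrates that the statistical surface
recovers configured effects, not that real data behave this way.

## Statistics (`cflung.stats`)

* **Group comparisons**: two-sided Student's t with pooled variance
  (Welch behind a flag).
* **Mixed-design ANOVA**: two 2-level within factors (lung volume,
  region) and one between factor (group), via the standard univariate
  decomposition computed on per-subject contrast scores; each within
  effect is tested against its own subject-by-factor error term. With
  two levels per factor, sphericity holds trivially, so no correction
  is needed. The implementation is verified against R's
  `aov(... Error(subject/(volume*region)))` on a fixed dataset.
  Subjects with incomplete cells are dropped with a warning.
* **Hierarchical regression**: cumulative OLS per block;
  `F_change = (ΔR²/q) / ((1−R²)/(n−k−1))`; β from the scale
  transformation `b · sd(x)/sd(y)`; sr² as the R² drop when the
  predictor alone is removed from the step's model; VIF per predictor
  with a configurable flag threshold (default 5). Singular designs
  raise rather than fit silently. Missing data are removed listwise.
* No multiple-testing correction is applied; p-values are reported
  unadjusted.

## Problem sizes and determinism

Tests and the acceptance script use 64×64 single-slice images
(~1,500 lung voxels), washouts of ~15–35 breaths sampled at 100 Hz,
cohorts of 12+12 (3,000+3,000 for mean-recovery checks), and
500–1,000 Monte-Carlo replicates for calibration checks. Every source
of randomness takes an explicit integer seed; identical seeds give
byte-identical outputs.
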