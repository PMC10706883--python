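# Methods

This note records the models the package implements, the numerical choices
behind the fitting routines, the study conditions encoded in the synthetic
data generators, and what the tests do and do not demonstrate about real
data.

## Digital kidney phantom

The phantom is two axis-aligned ellipsoids ("kidneys") on a 48×48×16 grid
of 3×3×5 mm voxels, each with a concentric medullary ellipsoid (semi-axes
scaled by 0.55) inside a cortical shell.  Default semi-axes 20×38×20 mm
give a two-kidney volume of ~127 mL; an isotropic `size_scale` prescribes
per-subject TKV, and construction fails loudly if a scaled kidney would be
clipped by the grid (which would silently corrupt TKV).  Anatomic realism
is deliberately absent — no renal pelvis, vasculature, partial-volume
mixing, B0/B1 fields or respiratory motion.  What the phantom preserves is
the one property the analysis depends on: cortex and medulla are
histogram-separable in T1, as they are in vivo at 3 T.

Ground-truth per-tissue parameters (cortex / medulla defaults): T1
1500/1900 ms, M0 100 a.u., ADC 2.2/1.9 ×10⁻³ mm²/s, T2\* 55/40 ms,
perfusion 250/80 mL/100 g/min, arterial transit 400/600 ms, bolus duration
800 ms.  Voxel values are drawn per tissue with an intra-tissue SD (T1
50 ms, ADC 0.08×10⁻³, T2\* 2.5 ms, perfusion 12), truncated at 5% of the
mean to stay physical.  Acquisition noise is Gaussian on the magnitude
signal by default; at the simulated SNRs (≥50) the Rician floor is
negligible and Gaussian noise keeps the analytic oracles exact.  A Rician
option (`noise_model="rician"`) exists for studying low-SNR bias.  All
randomness flows from a single integer seed; identical specs produce
bit-identical outputs.

Simulated protocols follow the acquisition design throughout: 13 inversion
times 200–1500 ms; 11 b-values 0–500 s/mm² in three orthogonal directions;
12 echoes from TE 5 ms in 3 ms steps; FAIR ASL pairs at post-label delays
300/500/700/900 ms (4 pairs each) and 1800 ms (25 pairs) plus a base M0
volume.

## Fitting

**T1 (inversion recovery).** Magnitude data lose the sign of the
recovering magnetisation, so the fit restores polarity by trying every
candidate null-crossing position (sign-flipping the samples before it).
For fixed polarity and trial T1 the amplitude enters the model linearly
and is solved in closed form (variable projection); T1 itself is found by
a 128-point log-spaced grid scan over [50, 5000] ms followed by
golden-section refinement (60 iterations, driving the bracket far below
the 10⁻⁸ cost tolerance).  Because polarity candidates adjacent to the
null point can be nearly tied on the coarse grid, the three best
candidates are refined and the lowest-SSE solution wins.  The inversion
efficiency ε is fixed at 1 by default; `fit_efficiency=True` fits it as a
third, linearised parameter.  Voxels with numerically constant signal
(including all-zero) carry no inversion information and are flagged failed
rather than assigned a confident T1.  Noiseless recovery on the 13-TI
protocol grid is better than 10⁻³ relative for T1 ∈ [500, 3000] ms
(sweep-tested), and the fitted null point satisfies TI\* = T1 ln 2.

**T2\* and ADC.** Both use ordinary least squares of log-signal on TE or b
("log of the exponential decay"), unweighted, with non-positive samples
dropped voxel-wise and a minimum of three usable points.  Negative decay
rates (signal rising with TE; ADC < 0) are flagged, not returned.
Direction combination for DWI is the geometric mean per b-value — the
arithmetic mean in the log domain — chosen so that combination and the
log-linear fit commute exactly; for an anisotropic voxel the fitted ADC is
then precisely the mean of the per-direction ADCs.  The mono-exponential
fit over *all* b-values means low-b perfusion contamination biases ADC
upward; the generator can inject per-direction or pseudo-diffusion
structure to study that, but no IVIM separation is performed.

**ASL.** The perfusion-weighted signal is the pairwise S − NS difference
averaged within each PLD.  Quantification uses the single-compartment
general kinetic model for pulsed ASL with plug-flow delivery
(α e^(−t/T1b) during the bolus), T1 relaxation of label in tissue and
outflow at rate f/λ:

    ΔM(t) = 0,                                          t < Δt
    ΔM(t) = 2 α (M0/λ) f′ e^(−t/T1′) · (e^(−kΔt) − e^(−ku))/k,  t ≥ Δt

with u = Δt + min(t − Δt, τ), 1/T1′ = 1/T1 + f′/λ, k = 1/T1b − 1/T1′, and
f′ = f/6×10⁶ converting mL/100 g/min to mL/g/ms.  The (e^a − e^b)/k factor
is evaluated through a series-protected (1 − e^(−u))/u so the model is
smooth through k → 0 and exactly continuous at both piece boundaries.
Constants default to 3 T community values — T1b = 1650 ms, α = 0.95,
λ = 0.9 mL/g, τ = 800 ms — all exposed in `ASLConstants`; tissue T1 comes
from the relaxometry stage.  A worked unit audit is frozen in the module
docstring and asserted in a test: f = 250 mL/100 g/min, Δt = 500 ms,
M0 = 100, T1 = 1500 ms ⇒ ΔM(1800 ms) = 2.1476 a.u.

Inflow estimation fits (f, Δt) per voxel with τ fixed: a grid over Δt
(100–1500 ms, 25 ms step, then a 2 ms local refinement) with f solved at
each node by iterating the linearised closed form (the model is linear in
f up to the weak outflow term).  Long-PLD inversion for f given Δt uses a
damped fixed-point iteration to machine precision.

*Identifiability limit.* The protocol constrains Δt only up to the last
short PLD (900 ms).  If the true transit time is ≥ 900 ms, every inflow
difference is exactly zero and the single long-PLD value cannot determine
f and Δt jointly — the SSE has an exact ridge, and no estimator can
resolve it.  Such voxels are returned with a low-confidence status flag.
Noiseless recovery is verified to <1% in f and <25 ms in Δt over a 20×20
grid spanning f ∈ [50, 400] mL/100 g/min and Δt ∈ [200, 875] ms — the
identifiable inflow window of this PLD set.  Kidney transit times at the
simulated conditions (400–600 ms) sit comfortably inside it.

## Segmentation and tissue summaries

The cortex/medulla threshold is computed from the in-kidney T1 histogram
by a two-component Gaussian mixture (EM, k-means initialisation, fixed
seed, 3 restarts) with the threshold at the intersection of the weighted
component densities between the means — robust to histogram binning,
unlike a raw valley search.  Cortex is the lower-T1 component, the
physiological ordering at 3 T.  The fit is rejected as effectively
unimodal when a component holds <2% of the weight or the means are closer
than 2 pooled SDs; the factor 2 is the Ashman-D bimodality condition
(fitting two components to a single Gaussian typically yields a spurious
separation near 1.5 pooled SDs, which a gate at 1.0 would accept).

Tissue summaries fit A e^(−(x−μ)²/2σ²) to the histogram bin counts
(Freedman–Diaconis bin rule, floor of 10 bins) and report mode = μ and
FWHM = 2√(2 ln 2) σ ≈ 2.3548 σ.  Summaries require ≥30 in-mask voxels and
reject constant data.  Both kidneys are pooled into one histogram (the
bilateral mean convention); per-kidney summaries remain available by
masking, and the pooled mode provably lies between the per-kidney modes.
TKV is voxel count × voxel volume in mL over both kidneys, with optional
DuBois BSA normalisation (0.007184 · W^0.425 · H^0.725).

## Clinical layer

eGFR uses the 2009 CKD-EPI creatinine equation (κ = 0.7/0.9, a =
−0.329/−0.411 for F/M, 1.018 female and 1.159 black factors); creatinine
is accepted in µmol/L (÷88.4) or mg/dL.  The per-subject eGFR slope is the
OLS slope over time in years (365.25 days), translation-invariant, using
all available values; two points yield a slope flagged low-confidence.
A decline of ≥5 mL/min/1.73 m²/yr (slope ≤ −5.0, boundary inclusive)
labels a progressor.  PCR is log10-transformed; the base is a convention —
rank statistics are unaffected.  The closed-form piecewise inverse of
CKD-EPI (`creatinine_for_egfr`) lets the cohort generator back-compute
creatinine series from prescribed eGFR trajectories.

## Statistics

α = 0.05 two-sided throughout, with no multiple-testing correction by
default (an optional Benjamini–Hochberg helper is provided); this mirrors
small pilot-study practice and is a documented limitation.  Group
comparisons gate on Shapiro-Wilk per group: both normal → Welch
(unequal-variance) t-test, else Mann-Whitney U with mid-rank ties and the
asymptotic p-value; constant samples are treated as non-normal, and fully
tied data return p = 1.  ROC AUC is U/(n₁n₂) (the probability a random
positive out-scores a random negative, ties ½), its 95% CI a stratified
bootstrap percentile interval (2000 resamples, seeded; the point estimate
is clamped into the interval), and its p-value the normal approximation of
U.  An orientation flag records whether higher or lower values predict
progression; `oriented_auc` reports the ≥0.5 direction.

The monitoring report takes complete cases only (subjects observed at
baseline, Year 1 and Year 2).  A (group × measure × timepoint) cell is
*significant* when the per-subject percentage changes differ from zero by
a one-sample t-test **and** the mean |change| exceeds the measure's
reference between-session CV — a two-criterion operationalisation of
"significantly different from the baseline CV", both criteria exposed in
config.  Significant cells are mapped to decline/improve through the
polarity table {TKV↓, ADC↓, T2\*↓, perfusion↓, T1↑} = decline; perfusion's
polarity (reduction = decline) is included on physiological grounds.  The
category assignment is invariant to unit rescaling.  Between-group and
Year-1-vs-Year-2 paired comparisons accompany the table.

Default reference CVs (%): TKV 3, T1 3, ADC 4, T2\* 6, perfusion 12 —
representative published short-term between-session values, with perfusion
deliberately the largest (ASL has the poorest repeatability of these
measures).

## Synthetic cohort: the study conditions

The generator emulates a two-group pilot cohort: 9 progressors and 13
stable subjects (22 at baseline), all completing three annual MRI visits;
withdrawal/dropout is not modelled.  Clinical series: eGFR intercept
N(40, 10²) in both groups, slopes N(−8, 1²) vs N(−1, 1²) mL/min/1.73
m²/yr, creatinine back-computed per visit (nine visits, 91-day spacing
over two years) with 5% multiplicative measurement CV, log10 PCR N(2.1,
0.35²) vs N(1.5, 0.45²), age N(58, 15²), 70% male, 10% black.  Both the
*intended* group and the *realized* label (re-derived from the noisy
creatinine series by the slope rule) are stored; all analyses use realized
labels.  With these settings ~4% of progressors realize above the −5
boundary, a deliberate imperfect-labelling feature.

Baseline tissue distributions encode the qualitative prediction structure:
progressors have higher cortex T1 (1570 vs 1450 ms, SD 40), higher medulla
T1 (2000 vs 1850 ms, SD 55) and lower cortex perfusion (140 vs 230, SD 30);
TKV, ADC, T2\* and medullary perfusion are identical across groups.
Longitudinal drifts per year: progressors TKV −5%, cortex T1 +4%, ADC −5%,
cortex perfusion −6%; stable TKV −2%; T2\* drifts nowhere.  Between-session
measurement CVs of the generator (TKV 1.5%, T1 2%, ADC 2.5%, T2\* 3%,
perfusion 8%) sit at or below the reference CV table, as published
reference CVs include repositioning and physiological effects beyond pure
measurement noise.

The effect magnitudes are free parameters of the generator — no published
values exist for them — chosen once by power analysis so that a pilot-sized
cohort (n = 9/13) detects the three intended baseline effects with ~99%
joint power (standardised differences ≈ 2.4–2.7) and the Year-2 monitoring
cells for TKV/cortex-T1/ADC are decisively classified.  They are
*illustrative study conditions*, stronger than typical clinical effect
sizes; passing the pattern tests demonstrates that the pipeline detects
structure it is fed at these magnitudes, not that real CKD cohorts carry
effects this large.

## Monte-Carlo design and what the tests show

The pattern-replication study runs 200 cohort replicates through the full
clinical + statistical pipeline using the generator's summary-level
measurement model (tissue summaries = drifted truth × session noise).  A
full voxel-wise replicate — phantom rendering, four simulated acquisitions,
all fits, GMM segmentation, histogram summaries — takes ~3 s per
subject-visit (~3 min per 66-visit cohort), so the 200-replicate loop at
the voxel level is computationally out of reach; instead the voxel chain is
validated separately: closed-loop recovery sweeps (above) plus an
end-to-end voxel replicate whose nine summary measures match the
generator's truth within 2% (typically <0.5%).  Since the voxel chain's
measurement error is *smaller* than the summary model's session CV, the
summary-level Monte-Carlo is conservative for power.

Expected outcomes at the default conditions: the three intended baseline
effects significant, the perfusion AUC CI excluding 0.5, and the Year-2
heat-map pattern (TKV/T1/ADC red in progressors, T2\* grey everywhere)
jointly in ≥95% of replicates; the six null measures reject at their
nominal 5% rate — individual replicates are *expected* to show occasional
false positives, which is why "only the intended effects are significant"
is checked as a rate, not per replicate.

## Numerical choices

- T1 search bounds [50, 5000] ms; grid 128 log-spaced points; golden-section
  refinement, 60 iterations; top-3 polarity candidates refined.
- ASL Δt grid 100–1500 ms step 25 ms, refined at 2 ms; inner f solve 6
  linearised iterations; long-PLD inversion fixed-point to 10⁻¹² relative.
- GMM: 2 components, 3 initialisations, seeded; density intersection found
  on a 4001-point grid between the means with linear zero-crossing
  interpolation; analytic fallback to the SD-weighted midpoint if one
  density dominates throughout.
- Histogram fits: scipy `curve_fit`, initialised at (max count, sample
  mean, sample SD), ≤5000 evaluations.
- Degenerate inputs are flagged (status volumes with OK / failed /
  low-confidence codes) rather than silently zeroed; pipeline stages wrap
  failures in stage-tagged errors.

## Limitations

- No image registration: ASL S/NS pairs are assumed aligned (true for the
  phantom by construction); a future registration hook belongs upstream of
  `compute_delta_m`.
- Mono-exponential ADC over all b-values, by design; IVIM and tensor models
  are out of scope.
- No MOLLI/Look-Locker or B1 correction in T1 mapping; no slice-timing
  model.
- Transit times beyond the last short PLD are unidentifiable (flagged, see
  above) — a property of the acquisition, not the estimator.
- The cohort generator draws each measure independently per subject;
  cross-measure correlations (e.g. T1–perfusion coupling) are not induced
  at baseline beyond what group membership creates.
- TKV in the pipeline comes from the phantom's kidney mask (the phantom
  stands in for manual tracing); mask-generation error is not modelled.
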