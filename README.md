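# renal-mpmri

Multiparametric renal MRI quantification and CKD-progression analysis on
digital kidney phantoms and synthetic clinical cohorts.

## The problem

Multiparametric renal MRI measures kidney structure and function without
contrast agents: longitudinal relaxation time T1 (rises with inflammation
and fibrosis), apparent diffusion coefficient ADC (falls with fibrosis),
effective transverse relaxation T2\* (a tissue-oxygenation surrogate),
arterial-spin-labelling (ASL) perfusion, and total kidney volume (TKV).
In chronic kidney disease (CKD) the open questions are whether baseline MRI
measures *predict* subsequent decline of the estimated glomerular
filtration rate (eGFR), and which measures *change* fast enough against
their between-session variability to monitor progression.

This package implements that entire measurement-and-analysis chain as a
tested library for methodologists and imaging scientists: every stage can
be exercised on a digital kidney phantom and a synthetic cohort with known
ground truth, so estimator accuracy, segmentation fidelity and the power of
the downstream statistics can be studied without patient data.

## What it computes

**Voxel-wise mapping** (`relaxometry`, `diffusion`, `asl`)

- T1, M0 from magnitude inversion recovery (13 TIs, 200–1500 ms):
  per-voxel least squares of |M0 (1 − 2ε e^(−TI/T1))| with polarity
  restoration, solved by variable projection over T1;
- ADC from 11 b-values (0–500 s/mm²) × 3 orthogonal directions:
  geometric-mean direction combination, then OLS of log S on b;
- T2\* from 12 echoes (TE 5 ms, ΔTE 3 ms): OLS of log S on TE;
- perfusion f (mL/100 g/min) and arterial transit time Δt from FAIR ASL
  selective/non-selective pairs at post-label delays 300/500/700/900 ms
  (inflow) and 1800 ms (25 pairs), via the single-compartment general
  kinetic model for pulsed ASL:

  ΔM(t) = 2 α (M0/λ) f′ e^(−t/T1′) (e^(−kΔt) − e^(−k·min(t, Δt+τ)))/k
  for t ≥ Δt, else 0, with 1/T1′ = 1/T1 + f′/λ and k = 1/T1b − 1/T1′.

**Segmentation and summaries** (`segmentation`) — a two-component Gaussian
mixture on the in-kidney T1 histogram places the cortex/medulla threshold
at the component-density intersection; each measure is summarised per
tissue by the mode and FWHM (= 2√(2 ln 2) σ) of a Gaussian fitted to its
histogram; TKV = voxel count × voxel volume, optionally BSA-normalised
(DuBois).

**Clinical layer** (`clinical`) — eGFR from serum creatinine via the 2009
CKD-EPI equation; per-subject eGFR slope by OLS over all available values;
decline ≥ 5 mL/min/1.73 m²/yr classifies a *progressor*; proteinuria
analysed as log10(PCR).

**Statistics** (`stats`) — Shapiro-Wilk-gated Welch-t / Mann-Whitney
baseline group comparisons; ROC AUC (rank formulation, mid-rank ties) with
stratified-bootstrap CI; Spearman/Pearson correlation matrices; and the
longitudinal monitoring rule: per-subject % change from baseline is called
significant when it differs from zero (one-sample t) *and* its mean
magnitude exceeds the measure's published between-session coefficient of
variation, then mapped to decline/improve through the measure's polarity
(TKV↓, ADC↓, T2\*↓, perfusion↓, T1↑ = decline).

**Synthetic data** (`phantom`) — a two-ellipsoid kidney phantom (cortex
shell + medullary core, 3×3×5 mm voxels) with per-tissue ground truth, the
four acquisition simulators, and a two-group cohort generator whose
creatinine series are back-computed through the inverse CKD-EPI equation.

## Worked example

```python
from renal_mpmri import PipelineConfig, run_pipeline

res = run_pipeline(PipelineConfig(seed=1))
print(res.baseline[["measure", "p_value", "test", "significant"]].to_string(index=False))
r = res.roc["perfusion_cortex"]
print(f"perfusion ROCAUC {r.oriented_auc:.2f} "
      f"(95% CI {r.oriented_ci[0]:.2f}, {r.oriented_ci[1]:.2f}; p = {r.p_value:.3f})")
```

prints

```
          measure  p_value         test  significant
              tkv 0.458578       t-test        False
        t1_cortex 0.001494       t-test         True
       t1_medulla 0.001679       t-test         True
       adc_cortex 0.504274 mann-whitney        False
      adc_medulla 0.702772       t-test        False
    t2star_cortex 0.580293       t-test        False
   t2star_medulla 0.265114       t-test        False
 perfusion_cortex 0.000030       t-test         True
perfusion_medulla 0.088195       t-test        False
perfusion ROCAUC 1.00 (95% CI 1.00, 1.00; p = 0.000)
```

On this synthetic 22-subject cohort (9 progressors, 13 stable), baseline
cortex and medulla T1 are higher and cortex perfusion lower in subjects who
go on to progress — the three effects the generator encodes — while TKV,
ADC, T2\* and medullary perfusion show no baseline difference.  Perfusion
separates the groups perfectly here (oriented AUC 1.0; lower perfusion
predicts progression).  The Year-2 monitoring report from the same run
classifies TKV (−11.1%), cortex T1 (+8.2%) and cortex ADC (−9.4%) as
significant decline in progressors, with T2\* unchanged in both groups:

```python
print(res.change_report.table.query("visit=='year2' and group=='progressor'")
      [["measure", "mean_pct_change", "category"]].to_string(index=False))
```

A command-line interface mirrors the library
(`renal-mpmri simulate | fit | segment | summarize | progress | run`), e.g.

```bash
renal-mpmri simulate --out-dir phantom --seed 1
renal-mpmri fit t1 --series phantom/ir_series.nii.gz \
    --mask phantom/masks/kidney_mask.nii.gz --out-dir fits
renal-mpmri segment --t1-map fits/t1.nii.gz \
    --kidney-mask phantom/masks/kidney_mask.nii.gz --out-dir seg
```

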