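# dcekinetics

Tracer-kinetic analysis of dynamic contrast-enhanced MRI (DCE-MRI) for
glioma molecular phenotyping, with a fully synthetic study generator.

## The problem

DCE-MRI follows a gadolinium bolus through tissue with serial T1-weighted
imaging. Fitting a pharmacokinetic model to each voxel's concentration
curve yields perfusion and permeability parameters that track the
blood-brain-barrier disruption and angiogenesis of diffuse glioma — and,
noninvasively, its molecular subtype: IDH mutation status, 1p/19q
codeletion (the marker of oligodendroglioma) and the Ki-67 proliferation
index. The package implements the two standard models side by side:

* **extended Tofts**:
  `C_tiss(t) = v_p c_p(t) + K^trans ∫ c_p(s) e^{-k_ep (t-s)} ds`,
  with transfer constant `K^trans` (min⁻¹), interstitial fraction `v_e`,
  plasma fraction `v_p` and efflux rate `k_ep = K^trans/v_e`;
* **distributed parameter (DP, Sangren–Sheppard)**:
  `C_tiss = F · (c_p ⊗ R)`, where the residue `R(t)` is a plateau of 1 over
  the capillary transit time `T_c = v_p/F`, drops to the first-pass
  extraction `E = 1 − e^{−PS/F}` at `T_c`, and then decays through the
  Bessel-function back-flux term of the two-region capillary–interstitium
  exchange. The DP model separates blood flow `F` from the
  permeability–surface-area product `PS`, which the Tofts family conflates
  into `K^trans`.

Around the models sits the full study pipeline: variable-flip-angle
(DESPOT1) T1 mapping, SPGR signal ↔ concentration conversion, voxelwise
multi-start bounded least-squares fitting, ROI-median aggregation, and a
cohort statistics battery (Mann–Whitney U with Benjamini–Hochberg
correction, ROC with DeLong variance and Youden cut-offs, paired DeLong
model comparison, Spearman correlation with Ki-67). Because no real
patient imaging ships with the package, a calibrated synthetic cohort —
48 patients in three molecular subtypes whose parameter distributions
match published group medians/IQRs — exercises every stage end to end.

## Worked example

Classify three reference cases with the package's two-threshold decision
rule (interstitial fraction for IDH genotype, then blood flow for 1p/19q
status within IDH-mutant tumors):

```python
>>> from dcekinetics.cohort_stats import classify_glioma_subtype
>>> classify_glioma_subtype(extofts_ve=16.08, dp_f=9.21)
'IDH wild-type'
>>> classify_glioma_subtype(extofts_ve=0.08, dp_f=7.00)
'IDH mutation, 1p/19q intact'
>>> classify_glioma_subtype(extofts_ve=1.34, dp_f=8.82)
'IDH mutation, 1p/19q codeleted'
```

All three match the pathology-proven subtypes: the first tumor's large
interstitial fraction (V_e = 16.08 mL/100 mL ≥ 1.670) marks a wild-type
glioblastoma; among the IDH-mutant tumors, high blood flow
(F = 8.82 ≥ 7.154 mL/min/100 mL) identifies the codeleted
oligodendroglioma.

A full synthetic study from the shell:

```bash
dcekinetics simulate --out run/ --seed 1          # render a 48-patient cohort
dcekinetics fit --run-dir run/ --out run/cohort.csv
dcekinetics stats --cohort run/cohort.csv --out run/stats/
# or, skipping the imaging stage:
dcekinetics report --out desk/ --seed 1
```

`stats/` then contains `group_comparisons.csv` (18 rows: 9 parameters ×
IDH and 1p/19q comparisons, with U, raw and BH-adjusted p),
`roc_analysis.csv` (AUC with DeLong 95% CI and the Youden operating
point per parameter), `model_comparison.csv` (paired DeLong test of the
best parameter of each model) and `ki67_correlations.csv` (Spearman ρ per
parameter). On a default synthetic cohort the interstitial fraction
dominates the IDH comparison (DP V_e AUC ≈ 0.9 on a typical seed,
adjusted p < 0.05) and blood flow is the parameter separating codeletion
status — the structure the generator is calibrated to.

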