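# lunghetero

Quantifying the **cranial-caudal heterogeneity** of emphysema in COPD from
two imaging modalities, with the cohort statistics that relate those indices
to lung function:

* **CT densitometry** — the low attenuation volume percentage (LAV%, lung
  voxels below −960 HU after tracheal-air calibration) measures whole-lung
  emphysema severity; **SD-LAV**, the standard deviation of LAV% across 10
  equal-volume cranial-caudal lung partitions (12 partitions with the top
  and bottom excluded for partial-volume effects), measures how unevenly
  that destruction is distributed along the lung's long axis.
* **Oxygen-enhanced MRI (OEMRI)** — breathing 100% oxygen raises the
  T1-weighted lung signal in proportion to regional oxygen uptake. The
  relative enhancement ratio per pixel is
  `RER = 100 · |SI_enhanced − SI_baseline| / |SI_baseline|`; **MRER** is its
  mean over lung-parenchyma ROIs pooled across three coronal sections, and
  **SD-RER** is the SD of the mean RER in 10 equal-count cranial-caudal
  partitions of the pooled pixels — a functional heterogeneity index that
  needs no ionising radiation.
* **Cohort statistics** — Shapiro-Wilk-gated two-group comparisons
  (t vs Mann-Whitney), normality-gated Pearson/Spearman correlations, and
  p-value-gated bidirectional stepwise OLS with standardized coefficients
  and cumulative R², the machinery used to ask which imaging index
  (severity or heterogeneity) carries independent information about FEV₁,
  DL_CO and PaO₂.

Because the underlying patient images are not public, the package ships a
**synthetic phantom and cohort generator** with known ground truth: an
ellipsoid-pair lung with a trachea and spherical low-attenuation clusters
whose cranial-caudal placement density is controlled by a single gradient
parameter; an exponential oxygen wash-in signal model with regional
amplitude modulation; and a 40-COPD / 9-control cohort whose covariates are
linked to the imaging truth by stated linear models. Every downstream stage
is therefore testable against a recount, a closed form or a constructed
effect direction.

Intended users: researchers in quantitative lung imaging who want a tested,
reproducible reference implementation of these heterogeneity indices, and a
simulation bench for their statistical behaviour at realistic cohort sizes.

## Worked example

```python
import lunghetero as lh

# a caudal-dominant emphysema phantom at 25% whole-lung burden
vol, gt = lh.generate_ct_phantom(
    lh.CTPhantomConfig(lav_fraction_target=0.25, gradient_strength=0.5, seed=42))
res = lh.analyze_volume(vol)
print(f"whole-lung LAV% = {res.lav_percent_whole:.2f}")
print(f"SD-LAV = {res.sd_lav:.2f}  calibration shift = {res.calibration_shift:+.2f} HU")

# a COPD-like OEMRI series (depressed, cranially-shifted oxygen uptake)
series = lh.generate_oemri_phantom(
    lh.OEMRIPhantomConfig(enhancement_amplitude_mean=0.126,
                          enhancement_gradient=-0.3, noise_sd=1.0, seed=42), gt)
rer = lh.analyze_series(series)
print(f"MRER = {rer.mrer:.2f}  SD-RER = {rer.sd_rer:.2f}")

# a full synthetic cohort and the statistics layer
table, _, _ = lh.generate_cohort(lh.CohortConfig(seed=42))
gc = lh.compare_groups(table, "mrer")
print(f"MRER COPD vs control: {gc.summaries['COPD']['mean']:.1f} vs "
      f"{gc.summaries['control']['mean']:.1f} ({gc.test_used}-test, p={gc.pvalue:.2g})")
rep = lh.stepwise_regression(table[table.group == "COPD"], "pao2",
                             ["age", "bmi", "lav_pct", "sd_lav"])
print(rep.summary())
```

prints

```
whole-lung LAV% = 25.00
SD-LAV = 7.13  calibration shift = +0.06 HU
MRER = 9.35  SD-RER = 2.07
MRER COPD vs control: 12.8 vs 21.2 (t-test, p=0.00097)
Stepwise regression: pao2 ~ {age, bmi, lav_pct, sd_lav}  (n=40, p_enter=0.05, p_remove=0.1)
variable        std beta     p-value
age                    -      0.9206
bmi                    -       0.461
lav_pct                -      0.7475
sd_lav            -0.709   2.972e-07
cumulative R^2 = 0.503
```

The phantom's measured LAV% recovers the 25% target exactly; the COPD-like
series shows depressed oxygen uptake (MRER ≈ 9, versus ≈ 22 for a healthy
amplitude of 0.22); and on the synthetic COPD cohort the stepwise model
attributes arterial oxygenation to the heterogeneity index SD-LAV
(standardized β = −0.71) while whole-lung severity, age and BMI are left
out — the qualitative pattern the indices are designed to expose.

A command-line interface wraps the same chain:

```
lunghetero all --out run1 --seed 7          # generate → ct-quant → oemri-quant → stats
lunghetero ct-quant --volume run1/subjects/copd000/ct.nii --out lav.json
lunghetero stats --table run1/cohort_measured.csv --outcome dlco \
    --candidates age,bmi,lav_pct,sd_lav --group COPD
```

Re-running `lunghetero all` with the same config and seed reproduces the
whole output bundle byte for byte.

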