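# prrt-hemtox

Tools for the imaging and haematology side of **peptide receptor radionuclide
therapy (PRRT)** of neuroendocrine tumours: somatostatin-receptor PET
tumour-volume segmentation, longitudinal CTCAE v5 haematotoxicity grading,
treatment-course classification, and the cohort statistics that link baseline
blood values to nadir toxicity. Because clinical PRRT records are not freely
shareable, the package ships first-class synthetic-data generators — a PET
phantom and a longitudinal haematology cohort — so that every stage of the
analysis can be exercised, tested and calibrated without any patient data.

Intended users: nuclear-medicine physicists and clinical data analysts who
want a reproducible, scriptable implementation of these standard manual
workflows.

## What it computes

**Lesion segmentation (bone / soft tissue).** For a lesion region the package
finds SUV<sub>peak</sub>, the highest mean standardized uptake value over
placements of a 1 mL sphere (radius r with (4/3)πr³ = 1000 mm³, r ≈ 6.2 mm)
centered on voxel centers inside the region. The lesion is the 26-connected
component of voxels with SUV ≥ 0.40 × SUV<sub>peak</sub> containing the peak
center; its volume is voxel count × voxel volume.

**Liver tumour volume (three-Gaussian histogram method).** All liver-mask
SUVs are binned (0.1 SUV fixed width) and the model

&nbsp;&nbsp;&nbsp;&nbsp;f(x) = Σᵢ Aᵢ exp(−(x − μᵢ)² / 2σᵢ²),&nbsp;&nbsp;i ∈ {blood pool, normal parenchyma, tumour}

is fitted to the bin counts by weighted least squares (Poisson weights,
deterministic quantile initialization). Every liver voxel with
SUV > μ_normal + σ_normal is counted as tumour. An EM fit on the raw voxel
values is available as an independent cross-check route.

**CTCAE v5 grading.** Haemoglobin, leucocyte, neutrophil and platelet series
are graded value-wise (haemoglobin converted at 1.6113 g/dL per mmol/L); a
patient's overall toxicity is the highest grade of any parameter at any time
after the first administration, partitioned into the groups 0–1 / 2 / 3–4.
Per-cycle windows, nadir extraction, the PRRT eligibility screen (strict
thresholds: Hgb > 5.5 mmol/L, WBC > 3.0, ANC > 1.0, PLT > 75 ×10⁹/L,
GFR > 50 mL/min/1.7 m², albumin > 30 g/L) and postponement / dose-reduction
classification of treatment courses are included.

**Cohort statistics.** Automatic identity-vs-log scale choice (|skewness| ≤ 1
rule), chi-square / one-way ANOVA / Kruskal–Wallis omnibus comparisons across
grade groups with Bonferroni-adjusted post hoc tests (pairwise Welch t, Dunn),
and Pearson correlation plus OLS regression of nadir on baseline with 95% CI
for the slope.

## Worked example

```python
from prrt_hemtox import (PhantomSpec, generate_phantom, build_liver_histogram,
    fit_three_gaussians, identify_normal_component, liver_tumour_volume,
    segment_lesion_40pct, CohortSpec, generate_cohort, grade_profile)

vol, truth = generate_phantom(PhantomSpec(seed=7))
fit = fit_three_gaussians(build_liver_histogram(vol, "liver", bin_width=0.1))
idx = identify_normal_component(fit)
w, mu, sd = fit.components[idx]
ml, _ = liver_tumour_volume(vol, "liver", fit)
print(f"normal parenchyma: mu = {mu:.2f} SUV, sigma = {sd:.2f} SUV (weight {w:.2f})")
print(f"liver tumour volume (mu+sigma rule): {ml:.1f} mL "
      f"(analytic expectation {truth['expected_threshold_volume_ml']:.1f} mL)")
seg = segment_lesion_40pct(vol, "lesion_0")
print(f"bone lesion: SUVpeak = {seg.suvpeak:.2f}, threshold = {seg.threshold:.2f}, "
      f"volume = {seg.volume_ml:.2f} mL")

cohort = generate_cohort(CohortSpec(n_patients=100, seed=7))
profiles = [grade_profile(s, c) for s, c in zip(cohort.labs, cohort.courses)]
from collections import Counter
print("grade groups:", dict(sorted(Counter(p.grade_group for p in profiles).items())))
```

prints

```
normal parenchyma: mu = 5.00 SUV, sigma = 1.00 SUV (weight 0.70)
liver tumour volume (mu+sigma rule): 124.0 mL (analytic expectation 124.2 mL)
bone lesion: SUVpeak = 12.00, threshold = 4.80, volume = 2.10 mL
grade groups: {'0-1': 56, '2': 42, '3-4': 2}
```

The phantom's liver voxels are drawn from the mixture 0.1·N(1.5, 0.4) +
0.7·N(5, 1) + 0.2·N(15, 4) SUV; the fit recovers the normal-parenchyma
component essentially exactly, and the μ+σ thresholded volume matches the
numerically integrated mixture mass above the threshold. The synthetic
100-patient cohort lands mostly in grade group 0–1 with a substantial
moderate-toxicity group — the typical shape of a screened PRRT population.

The same steps are available from the shell:

```sh
prrt-hemtox simulate phantom --seed 7 --out phantom/
prrt-hemtox segment liver --volume phantom/phantom.nii --mask phantom/mask_liver.nii --out seg/
prrt-hemtox simulate cohort --seed 7 --out cohort/
prrt-hemtox grade --labs cohort/labs.csv --course cohort/course.csv --out profiles.csv
prrt-hemtox run --config run.yaml     # full pipeline with a manifest
```

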