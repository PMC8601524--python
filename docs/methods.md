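# Methods

This note records the models, numerical choices and known limitations of
`prrt_hemtox`, in the spirit of a methods appendix.

## PET phantom

The phantom emulates the substrate of the liver-histogram segmentation
method: a 64³ grid at 2 mm isotropic spacing (voxel 8 mm³) containing an
ellipsoidal liver (default semi-axes 50 × 48 × 40 mm, ≈ 402 mL ≈ 50,000
voxels — a realistic liver volume at a resolution fine enough for histogram
work). Liver voxels are drawn from a three-component Gaussian mixture

w_b·N(μ_b, σ_b) + w_n·N(μ_n, σ_n) + w_t·N(μ_t, σ_t),
defaults w = (0.1, 0.7, 0.2), μ = (1.5, 5, 15) SUV, σ = (0.4, 1, 4) SUV,

representing blood pool, normal parenchyma and tumour. Draws are clipped at
zero (negligible mass for the defaults). The tumour component is realised as
spatially disjoint spheres rather than salt-and-pepper voxels so that volume
accounting is meaningful; when blob radii are not given they are auto-scaled
(relative sizes 1 : 0.85 : 0.85² …) so the total analytic blob volume equals
w_t × liver volume, which makes empirical component proportions converge to
the nominal weights as resolution grows. Blob placement is rejection
sampling with an exact support-function containment test
(p·u + r ≤ √(Σ sᵢ²uᵢ²) over a dense direction set) and whole-placement
restarts; a blob whose radius cannot fit raises an error naming it.
Extra-hepatic bone and soft-tissue lesions are ellipsoidal SUV plateaus
(defaults 12 and 9 SUV) on a noisy low background (0.5 ± 0.05 SUV).

Deliberately **not** modelled: point-spread function, partial-volume effect,
attenuation, reconstruction noise correlation. Voxel values are independent
given tissue class, so segmentation accuracy measured on phantoms is an
upper bound on real-data performance; what the passing tests establish is
the correctness of the algorithms, not clinical accuracy.

The analytic liver tumour volume under the μ+σ rule is computed by numeric
integration of the generating mixture above the threshold, times the
voxelized liver volume; this is the reference for the recovery checks.

## Segmentation

**SUV<sub>peak</sub>.** Candidate sphere centers are the voxel centers of
the lesion region; a voxel belongs to the 1 mL sphere iff its center lies
within r = (3·1000/4π)^{1/3} ≈ 6.2035 mm of the candidate center. Voxels
outside the grid are excluded from the mean. Ties break toward the
lexicographically smallest center (row-major order). Regions smaller than
one sphere are evaluated anyway — the sphere then extends beyond the
region — and flagged in the result. The production path (chunked offset
gathering) is checked against an exhaustive distance-based enumeration.

**40% threshold.** Lesion membership is SUV ≥ 0.40 × SUV<sub>peak</sub>
(the ≥/> choice is immaterial at float resolution but fixed as ≥);
connectivity is 26-neighbour, configurable to 6. Volume is exactly voxel
count × voxel volume, in mL = mm³/1000.

**Liver histogram fit.** Default bin width 0.1 SUV from 0 to one bin past
the maximum. The sum of three scaled Gaussians is fitted to bin counts by
least squares with 1/√max(count, 1) residual weights (Poisson). Quantile
initialization — means at the 10th/50th/90th weighted percentile, equal
widths (q90−q10)/6, amplitudes read off the counts — is fully
deterministic: identical histograms give identical fits. Component weights
are the relative areas Aᵢσᵢ√(2π)/Σ, so they sum to one by construction.
Non-convergence returns the best iterate flagged. An EM alternative on raw
voxel values (scikit-learn mixture, deterministic quantile/uniform/unit
initialization) serves as an independent cross-check in tests, never as the
primary route.

**Normal-component identification.** The automatic rule picks the middle
mean, following the ordering assumption blood pool < parenchyma < tumour;
equal means tie-break toward the larger weight. This assumes three genuine
populations: on degenerate (single-population) data the fitted components
overlap and the automatic choice is not meaningful — the manual override
(mirroring the visual selection step of the clinical workflow) is the
supported path there. The tumour rule is *strictly* above μ_normal +
σ_normal; blood-pool voxels are not excluded beforehand (the threshold
keeps them out in practice).

## Haematology cohort

Schedule: up to four cycles of 7.4 GBq every 10 weeks, sampling at 3, 6 and
8.5 weeks after each cycle plus one baseline panel at day −7. Baseline
distributions follow the descriptives of a screened clinical PRRT
population: haemoglobin normal 8.0 ± 0.9 mmol/L; leucocytes, neutrophils
and platelets log-normal matched to median/IQR 6.8 [5.6–8.0], 4.2 [3.3–5.2]
and 244 [190–329] ×10⁹/L (a two-parameter log-normal reproduces the median
and the IQR *ratio*; the printed quartiles are not exactly log-symmetric).

Trajectory model (the simplest one producing configurable per-cycle
nadirs): after cycle c the parameter declines linearly to baseline × f_c at
the nadir offset (6 weeks, a sampling time), then the dip decays
exponentially at a recovery fraction of 0.35 per week. f_c is a clipped
normal, f_c = clip(m_p + s_patient + ε_c, 0.05, 1], with per-parameter
decline means m_p = 0.93 (Hgb), 0.62 (WBC), 0.65 (ANC), 0.65 (PLT) and SDs
0.04/0.07/0.09/0.08 — chosen once so that the expected minimum over four
cycles reproduces the baseline→nadir median ratios of the reference
population (e.g. platelets 244 → ≈ 144). Patient susceptibility SD 0.05
shifts all of a patient's decline means jointly; measurement error is
multiplicative with CV 3%; values are floored at 0.1 unit to avoid
non-physical zeros. Cycles are otherwise independent (no cumulative marrow
damage), and missing visits are not simulated.

In the noise-free configuration (CV = 0, susceptibility 0) the observed
nadir is exactly baseline × min(f₁…f₄), so the grade-group probabilities
integrate in closed form over the baseline law:
P(nadir < t) = E_B[1 − (1 − F_f(t/B))⁴]. This is the analytic reference for
the grade-frequency calibration check; with noise on, no closed form is
attempted. Grade-group boundaries (grade ≥ 2) do not involve the LLN, so
these probabilities are sex-free.

## CTCAE v5 grading

Numeric bins, in canonical units (haemoglobin g/dL, counts ×10⁹/L):

| parameter | grade 1 | grade 2 | grade 3 | grade 4 |
|---|---|---|---|---|
| haemoglobin | < LLN–10.0 | < 10.0–8.0 | < 8.0 | — (clinical) |
| leucocytes | < LLN–3.0 | < 3.0–2.0 | < 2.0–1.0 | < 1.0 |
| neutrophils | < LLN–1.5 | < 1.5–1.0 | < 1.0–0.5 | < 0.5 |
| platelets | < LLN–75 | < 75–50 | < 50–25 | < 25 |

Anaemia grade 4 is a clinical ("life-threatening") criterion, so value-based
grading caps it at 3. Haemoglobin mmol/L is converted at 1.6113 g/dL per
mmol/L (the monomeric-Fe convention of Dutch laboratories — this is what
makes mmol/L values like 6.0 land in grade 2). LLN defaults: haemoglobin
8.5 (male) / 7.5 (female) mmol/L, WBC 4.0, ANC 1.5, PLT 150 ×10⁹/L; all
bins and LLNs ship as an editable JSON rules file. Only the grade-0/1
boundary depends on the LLN (and on sex), so the 0–1 / 2 / 3–4 grouping is
insensitive to both. When sex is unknown the female LLN is used.

Nadir search excludes baseline records (day ≤ 0); ties resolve to the
earliest day. Cycle windows are half-open (cycle day, next cycle day], the
last extending 10 weeks past the final administration. Course
classification is descriptive: postponed = any interval > 70 + 7 days,
reduced = any activity < 7.4 − 0.2 GBq; the clinical decision rule behind a
postponement is not modelled.

## Statistics

Scale rule: |sample skewness| ≤ 1 keeps the identity scale, otherwise log
(requires positive values); this replaces visual histogram assessment for
reproducibility and can be overridden. Identity-scaled variables are
compared with one-way ANOVA, log-scaled ones with Kruskal–Wallis,
categorical ones with chi-square (no continuity correction, which keeps the
type-I error nominal away from 2×2 small-sample corners; expected cell
counts below 1 raise a recorded warning). Post hoc tests run only when the
omnibus p < 0.05: pairwise Welch t (ANOVA), Dunn's rank test with tie
correction (Kruskal–Wallis; hand-implemented, validated against the
two-group identity z² = H), pairwise chi-square (categorical), all
Bonferroni-adjusted. Association analysis is Pearson correlation (Spearman
optional) and OLS of nadir on baseline with the textbook 95% CI.

## Pipeline

`run_pipeline` executes simulate → segment → grade → stats, writing every
intermediate artifact and a manifest of options, seeds and SHA-256
checksums. The manifest contains no timestamps, so identical configs and
seeds give byte-identical manifests; stage timings go to the log. All
randomness flows from integer seeds through named `numpy` generators — no
global RNG state anywhere.

## Problem sizes used in the checks

The automated checks use 20 phantoms of ~50,000 liver voxels for mixture
recovery, 50 random volumes up to 25³ for the SUV<sub>peak</sub> oracle,
100 random lesion phantoms for threshold monotonicity, 1000 null
simulations at group sizes 54 + 38 for test calibration, 500 replicates for
CI coverage, and a 400-patient noise-free cohort for the grade-frequency
calibration — sizes at which the Monte-Carlo error of each quantity is
comfortably below its acceptance band.

## Known limitations

- No PET physics: phantom results bound, not estimate, real-data accuracy.
- The trajectory model is phenomenological; it makes no claim about marrow
  biology, and cycles are independent apart from shared susceptibility.
- Value-based grading only: clinical criteria (transfusion indicated,
  life-threatening) are not evaluated.
- Automatic normal-component selection requires three separated
  populations; degenerate livers need the manual override.
- The course classifier describes administered schedules; it cannot
  recover the physician's reasoning.
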