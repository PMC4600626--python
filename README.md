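# epiaging

Does an epigenetically "old" methylome predict future disease beyond
chronological age and smoking history? `epiaging` implements the full
analysis pipeline for testing whether **intrinsic epigenetic age
acceleration (IEAA)** — DNA-methylation age residualized on chronological
age and blood cell composition — predicts incident disease (the motivating
application is lung cancer in a prospective cohort of postmenopausal women),
and validates every stage on synthetic methylation cohorts with planted
ground truth.

It is written for epidemiologists and methylation analysts who want a
tested, reproducible implementation of each stage, and for methodologists
who want to measure how well the pipeline recovers known effects.

## The method

1. **Beta values.** Illumina-style methylation fractions per CpG,
   β = max(M,0) / [max(M,0) + max(U,0) + 100], with M/U the methylated and
   unmethylated signal intensities.
2. **DNAm age.** An epigenetic clock predicts age from a sparse weighted
   sum of CpG betas on a calibrated scale: F(age) = log(age+1) −
   log(adult_age+1) below the knot (adult_age = 20) and
   (age − adult_age)/(adult_age+1) above it; DNAm age = F⁻¹(intercept +
   Σⱼ cⱼ βⱼ). Clocks can be loaded from the standard two-column
   coefficient CSV or trained by elastic net on synthetic cohorts.
3. **Cell deconvolution.** Per-sample abundances of seven leukocyte types
   (naive CD8 T, exhausted CD8 T, plasmablasts, CD4 T, NK, monocytes,
   granulocytes) by constrained least squares: min‖β − Rw‖² s.t. w ≥ 0,
   Σw = 1, with R a reference signature matrix.
4. **IEAA.** Residual of DNAm age regressed (OLS) on chronological age and
   the seven cell fractions, standardized to mean 0 / SD 1 over the cohort.
   Positive IEAA = methylome older than expected; by construction it is
   orthogonal to age and to cell composition.
5. **Survival analysis.** Cox proportional-hazards models of incident
   disease on standardized IEAA adjusted for age, race/ethnicity, CHD,
   smoking status and pack-years; stratified fits by 10-year age group and
   smoking status; Breslow baseline cumulative hazard with
   covariate-profile incidence curves 1 − exp(−H₀(t)·exp(xᵀβ));
   Kruskal–Wallis and biweight-midcorrelation screens; landmark-exclusion
   and logistic-regression sensitivity analyses.

Because the motivating cohort data are access-controlled, the package
ships a first-class **synthetic cohort generator**: beta matrices composed
of cell-type mixtures plus a clock signal plus logit-scale noise, and
exponential event times under a proportional-hazards model in which the
planted age-acceleration effect is known exactly.

## Worked example

```bash
cat > pipe.yaml <<'YAML'
seed: 17
out_dir: demo
simulate: {enabled: true, n_subjects: 2000, clock_mode: linear}
survive:  {enabled: true, strata: [age, smoking], landmark_years: [1], logistic: true}
YAML
epiaging pipeline run --config pipe.yaml
```

prints `completed 5 stages; 16 artifacts in demo`, and
`demo/survival_summary.json` contains:

```json
{"n": 2000, "events": 35, "person_years": 39624.9423,
 "r_squared": 0.0337, "hr_ieaa": 1.8325, "p_ieaa": 0.00057}
```

i.e. in this simulated cohort (planted hazard ratio 1.5 per SD of
acceleration; a single draw scatters around that) each SD of IEAA
multiplies the lung-cancer hazard by 1.83. The age-stratified table
(`demo/cox_strata_age.csv`) shows the effect concentrating in the oldest
group — HR 1.07 (ages 50–59), 1.59 (60–69), 2.77 (70+) — and
`demo/incidence_curves.csv` holds predicted 20-year incidence for a
75-year-old white current smoker with 30 pack-years: 8.7% at IEAA = −1,
15.4% at IEAA = 0, 26.3% at IEAA = +1.

Every stage is also a standalone subcommand (`epiaging simulate`,
`epiaging clock train/apply`, `epiaging deconvolve`, `epiaging ieaa`,
`epiaging survive`) operating on plain TSV/CSV files, and a plain Python
API (`epiaging.methylation_core`, `cell_deconvolution`,
`age_acceleration`, `survival_analysis`, `synthetic_cohort`).

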