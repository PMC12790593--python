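# stnpower

Spectral frameworks for subthalamic local field potentials (STN-LFPs) in
Parkinson's disease: cohort simulation, spectral estimation and
parameterization, and the across-patient / within-patient statistics used to
evaluate beta power and aperiodic broadband power as motor-symptom
biomarkers.

## Who this is for

Researchers analysing DBS-electrode LFP recordings against clinical scores
(UPDRS-III), and methodologists studying how analysis choices — spectral
normalization, frequency-band definitions, periodic/aperiodic separation —
change biomarker conclusions. Everything runs end to end on simulated
cohorts with known ground truth, so each pipeline stage can be validated
before touching patient data.

## The models at the core

**Signal model.** A one-sided Fourier power spectrum is constructed as

    S(f) = offset · f^(−m) + Σ_k A_k · exp(−(f − f_k)² / (2σ_k²))   [µV²/Hz]

with uniformly random phases, Hermitian symmetry, and an inverse FFT
producing a real time series (default 180 s at 2400 Hz). `offset·f^(−m)` is
the aperiodic (1/f) component; the Gaussians are oscillatory peaks
(theta/beta/gamma).

**Spectral frameworks.** Welch spectra (1-s Hamming windows, 50% overlap,
1 Hz grid) are analysed three ways:

- *relative total power*: spectrum normalized so the 5–95 Hz bins sum to
  100%;
- *absolute total power*: the raw density in µV²/Hz;
- *parameterized power*: log₁₀ P(f) = a − m·log₁₀ f + Gaussian peaks fitted
  over 2–60 Hz (≤4 peaks, widths 2–12 Hz, minimum height 0.1, fits kept when
  R² > 0.85), separating periodic from aperiodic activity.

**Aperiodic broadband power**, the proposed spiking-related marker, is the
sum of the fitted aperiodic log-power over the integer bins 2–60 Hz:

    P_bb = Σ_{f=2}^{60} (a − m·log₁₀ f) = 59·a − m·Σ log₁₀ f.

**Statistics.** Spearman correlations with 10,000-iteration bootstrap CIs
and Fisher-z sample-size estimates; Cohen's d with Bonferroni-adjusted
bootstrap CIs; Maris–Oostenveld cluster-based permutation tests on spectra
(mean-difference statistic, exhaustive sign-flip enumeration when feasible);
an 18-path multiverse (3 medication states × 2 sampling units × 3 beta
ranges); OLS symptom models compared by Davidson–MacKinnon J-tests and
AIC/AICc/BIC; and repeated-measures (rank) correlation treating the two
hemispheres as within-patient observations.

## Worked example

Simulate two 40-patient datasets with a planted across-patient correlation
of ρ = 0.4 between relative low-beta power and the UPDRS-III total, then run
the 18-path multiverse over both:

```python
from stnpower import (CohortSpec, simulate_cohort, cohort_feature_table,
                      run_multiverse, summarize)

spec = CohortSpec(n_patients=40, n_datasets=2, duration_s=30.0,
                  sample_rate=500.0, effect_map={"low_beta": 0.4}, seed=7)
cohorts = simulate_cohort(spec)
frames = {}
for cohort in cohorts:
    df, _ = cohort_feature_table(cohort)
    frames[df["dataset_id"].iloc[0]] = df.rename(columns={
        "relative_alpha_beta": "alpha_beta", "relative_beta": "beta",
    }).assign(low_beta=df["relative_low_beta"])
result = run_multiverse(frames, n_boot=1000, seed=7)
print(summarize(result)["counts"])
row = result.pooled.query("state == 'off' and unit == 'patient' and band == 'low_beta'")
print(row[["rho", "ci_low", "ci_high", "p", "required_n"]].to_string(index=False))
```

Output (seed 7, ~30 s):

```
{'significant_positive': 12, 'significant_negative': 0, 'nonsignificant': 24, 'unavailable': 0}
     rho   ci_low  ci_high        p  required_n
0.200007 -0.01579  0.41381 0.075275         194
```

This run illustrates the core phenomenon the package exists to study: a
genuine ρ = 0.4 effect, observed through 30-s recordings in 80 pooled
patients, comes out as ρ̂ = 0.20 with p = 0.075 in the off-state low-beta
path — not significant — and the Fisher-z estimate says ~194 patients would
be needed to replicate the *observed* coefficient at 80% power. The twelve
significant cells concentrate in the Levodopa-response (off-minus-on) paths,
where the planted link between low-beta modulation and symptom improvement
is strongest. Beta–symptom correlations need large cohorts; single small
datasets disagree by sampling noise alone.

A command-line pipeline wraps the same stages:

```bash
stnpower report --seed 3 --out out/    # simulate → spectra → all analyses
stnpower simulate --seed 3 --out raw/  # write recordings + scores to disk
```

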