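# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of `stnpower`, in the spirit of a model-documentation page
for a simulation/statistics package.

## Signal simulation

A recording is built in the frequency domain. On the rFFT grid of an
`n = duration × fs` sample record, the target one-sided density is

    S(f) = offset · f^(−m) + Σ_k A_k exp(−(f − f_k)² / (2σ_k²))   [µV²/Hz]

Coefficient magnitudes are set deterministically, |X_j|² = S(f_j)·fs·n/2,
and only the phases are uniformly random. The DC bin is zeroed (so the
output is zero-mean) and, for even n, the Nyquist bin is zeroed rather than
given a random sign, since a random real coefficient there would break the
"phase-only randomness" design for a negligible sliver of power. The inverse
real FFT is therefore exactly real without any post-hoc `real` cast.

Consequences worth knowing:

- A *single* realization already follows S(f) closely; across-seed averaging
  removes only phase-interaction noise in the Welch estimate, not amplitude
  scatter (there is none). Parseval fixes the variance of the trace at
  ∫S df exactly.
- Peak amplitudes `A` are *additive in linear power*. The fitting module
  works in log10 space, where the same peak has height
  `log10(1 + A / (offset · f_c^(−m)))` at its centre. The package exposes
  the amplitude scale as a free parameter of each peak rather than fixing a
  normalization to the background.

Defaults: 180 s at 2400 Hz. The sampling-rate precondition
`fs > 2(f_c + 3σ)` is enforced per peak with an error naming the offender.

## Welch expectation and window bias

`welch_psd` uses 1-s Hamming windows with 50% overlap (1 Hz grid), averaging
plain periodograms of windows that contain no masked sample. The estimator's
expectation is the true density convolved with the squared window transform.
For steep 1/f^1.5 spectra this main-lobe smoothing biases the 2 Hz bin by
roughly 8–13%, and it flattens peaks narrower than σ ≈ 1.5 Hz by a few
percent — properties of the estimator, not of the simulator. The fidelity
tests therefore check the mean Welch spectrum against the window-convolved
analytic expectation (2% over 2–200 Hz) and against the raw analytic target
only where the target is smooth on the kernel scale (5% over 3–200 Hz).

## Preprocessing

Zero-phase 4th-order Butterworth high-pass at 1 Hz; resampling to 2000 Hz by
a polyphase FIR whose Kaiser-windowed low-pass is the anti-alias filter. The
good-segment mask is carried to the new rate by index mapping. Line noise is
interpolated in the *spectrum*: bins within ±2 Hz (configurable; the width
is not standardized in the field) of 50 Hz and optionally its harmonics are
replaced by the linear interpolant between the nearest clean bins.

## Band conventions

Canonical bands delta 2–4, theta 4–9, alpha 9–13, low beta 13–20, high beta
20–30, low gamma 30–45, mid gamma 45–60 Hz. Printed band edges in the
clinical literature overlap at shared frequencies; on an integer grid this
package uses half-open bins [f_lo, f_hi) so adjacent bands never share a
bin. Relative power normalizes the *inclusive* integer bins 5..95 (91 bins)
to a 100% sum — the most literal reading of "from 5 to 95 Hz" — making a
flat spectrum contribute 100/91 % per bin. The mid-gamma proxy locates the
largest bin in [45, 60] and averages the bins within ±2.5 Hz of it, clamped
to the range; on the integer grid that is a symmetric 5-bin window except at
the edges.

## Spectral parameterization

The fit over 2–60 Hz (fixed mode, no knee) proceeds in four steps:

1. *Robust aperiodic fit*: a least-squares line in log10–log10 space, then a
   refit restricted to the bins at or below the first fit (the lower
   envelope), which shields the slope from oscillatory peaks.
2. *Peak extraction*: iteratively take the largest residual maximum; accept
   it if its height clears both the absolute floor (0.1 log10 units) and
   2 × SD of the current flattened spectrum; estimate σ from the half-height
   width (bounded to bandwidths 2–12 Hz, i.e. σ ∈ [1, 6]); subtract; stop at
   four peaks.
3. *Joint refit* of all Gaussians on the flattened spectrum
   (`scipy.optimize.curve_fit`, bounded); peaks falling below the height
   floor after the joint fit are dropped; remaining peaks are ordered by
   descending height with frequency as the tie-break.
4. *Final aperiodic refit* on the peak-subtracted spectrum, and R² of the
   full model in log10 space. Fits with R² ≤ 0.85 are flagged rejected and
   excluded from periodic/aperiodic feature extraction downstream.

Degenerate inputs: non-positive power inside the fit range is an error (the
log is undefined); a non-convergent joint Gaussian fit falls back to the
iterative estimates with a warning.

**Aperiodic broadband power** is implemented as the literal summation
Σ_{f=2}^{60} (a − m log10 f) — 59 terms. A closed form sometimes printed
with a factor (f_high − f_low) = 58 differs by one `a`; the summation is
what the quantity means, and the range is exposed as parameters.

**Two readings of periodic band power.** The default reading averages the
fitted Gaussian model (log10 height above the aperiodic fit) over a band's
bins; a `residual` mode averages the flattened spectrum instead. For the
didactic offset scenario there is also `periodic_linear_band_power`, the
mean of 10^(aperiodic+periodic) − 10^aperiodic: when an oscillation of fixed
*linear* amplitude rides on a rising aperiodic floor, the linear reading is
invariant while the log-height reading necessarily shrinks. The scenario
tests use the linear reading for exactly that reason.

## Synthetic cohorts

The cohort generator is the package's test bed; its defaults are the study
conditions, not tuning knobs.

- **Scores.** UPDRS-III totals are built from parts: per-hemibody
  bradykinesia-rigidity (≈55% of the total, split with a planted asymmetry
  of 1 + Poisson(2) points), small integer tremor subscores, and an axial
  remainder — so subscore sums can never exceed the total and all values are
  integers in range (totals clipped to [5, 108], hemibody scores to
  [0, 40]). Off-state totals target 34.9 ± 12.9, on-state 19.0 ± 9.2, with
  a 0.85 latent correlation between states. 10% of patients are symmetric
  and 5% flip asymmetry sign between conditions, so inclusion filters have
  something to reject.
- **Spectra.** Per patient: exponent ~ N(1.5, 0.15), aperiodic offset
  log10 ~ N(−0.3, 0.15); peak presence probabilities theta 0.7, low beta
  0.5, high beta 0.7, low gamma 0.3 (low-beta peaks absent in about half of
  STNs off medication is the empirically reported pattern). Peak amplitudes
  are log-normal around a band-specific multiple of the local aperiodic
  background.
- **Planted across-patient effects.** A Gaussian copula links each targeted
  band's amplitude latent to the severity latent with
  r = 2 sin(π ρ_s / 6), so the *Spearman* correlation hits the requested
  target. The planted correlation is realized on **relative** band power;
  absolute band power attenuates it because across-patient broadband scale
  variation multiplies every band — a real phenomenon, not an artifact.
  Bands named in the effect map always express their peak.
- **Within-patient asymmetry.** The STN contralateral to the worse hemibody
  receives +asymmetry/2 log10 aperiodic offset, the other −asymmetry/2
  (default total 0.3 log10 units).
- **Levodopa.** On-state peak amplitudes are multiplied per band (defaults:
  theta ×1.3, low beta ×0.75) and the aperiodic parameters shift slightly
  (+0.05 exponent, +0.02 log10 offset), mirroring the direction of reported
  modulations at modest magnitude.
- **Montage.** Each hemisphere mixes the bipolar source into four monopolar
  levels with fixed gains plus a shared pink-noise common mode; the bipolar
  pair bracketing the planted stimulation level recovers the source with
  unit gain and cancels the common mode exactly. MNI coordinates place the
  stimulation level at the sweet spot, so the proximity rule and the
  high-beta fallback agree. 30% of leads carry directional sub-contacts
  whose deviations average to zero.
- **Reproducibility.** One global seed fans out through `SeedSequence`
  spawns per dataset → patient → recording, so enlarging a cohort leaves
  existing patients bit-identical.

What the generator does *not* emulate: volume conduction, neural-mass
dynamics, tremor time courses, non-stationarity within a recording,
recording artifacts (masks must be supplied), and DBS stimulation artifacts.
Passing tests on these cohorts therefore validate the *statistical
machinery*, not robustness to real-world contamination.

## Statistics: conventions and edge cases

- Bootstrap CIs are percentile, 10,000 resamples by default; bootstrap and
  permutation routines take explicit seeds.
- Permutation p-values use (b+1)/(B+1) for sampled permutations; exhaustive
  enumerations (paired: all 2^n sign flips whenever 2^n ≤ n_perm) include
  the identity and use the exact count/B.
- Cluster tests form clusters from bins whose two-sided permutation p falls
  below the same α used for cluster significance; the cluster statistic is
  the summed bin mean-difference, compared against the permutation
  distribution of the maximum |cluster mass|.
- Cohen's d: paired d = mean(Δ)/SD(Δ), sign convention off-minus-on. For six
  bands the Bonferroni-adjusted confidence level is 1 − 0.05/6 ≈ 0.9917
  (printed as 0.992 at three decimals).
- Required sample size uses the Fisher-z formula
  n = ((z_{1−α/2} + z_{power}) / atanh ρ)² + 3, rounded up; for ρ = 0.26 it
  gives 114. Published figures near 116 are consistent with an unrounded
  input coefficient or an exact-power variant; the formula used is reported
  alongside the estimate.
- Kruskal–Wallis comparisons switch to an exhaustive rank-permutation
  p-value when the pooled sample has ≤ 10 observations; Dunn's post-hoc z
  uses pooled mean ranks with tie correction.
- OLS information criteria use the concentrated Gaussian likelihood,
  AIC = n ln(RSS/n) + 2k with k = intercept + slopes. This differs from
  full-likelihood conventions by an additive constant, so *differences and
  ranks* are the supported comparison, never absolute values. AICc adds
  (2k² + 2k)/(n − k − 1) and is reported as undefined when n ≤ k + 1.
- The J-test is computed in both directions and is asymmetric by nature. It
  over-rejects in finite samples when the competitor is pure noise (~8% at
  n = 200, matching the reference implementation); with competitors that
  share information with the truth — the realistic situation for competing
  spectral frameworks — it is close to nominal. A pure-noise response is a
  degenerate design for the J-test (the true intercept-only model is nested
  in both competitors) and is not used for calibration.
- Repeated-measures correlation: per-subject centring of x and y, residual
  correlation, df = N_obs − N_subjects − 1. The ranked variant ranks
  globally across all observations *before* centring; it is exactly
  rank-invariant but only approximately invariant to per-subject shifts
  (the plain variant is exactly shift-invariant). Within-patient analyses
  carry an `exploratory` flag and receive no multiplicity correction by
  design.
- Multiverse: the off-minus-on path correlates the power decrease (off−on)
  with the UPDRS improvement (off−on); a percentage-change pairing is
  available by preprocessing the feature columns. Pooling concatenates
  patients across datasets (no meta-analytic weighting). Correlations use
  the UPDRS-III total for both sampling units; lateralized subscores are
  available as columns for sensitivity analyses.

## Contact selection

Directional contacts are ring-averaged per level (1 or 3 sub-contacts; other
counts are errors). The stimulation contact is level 2 or 3, chosen by
Euclidean proximity to the sweet-spot coordinate when MNI positions exist
(the metric is an assumption; the convention in the literature is not
explicit), otherwise by larger high-beta (20–30 Hz) power. Exact ties go to
the more ventral level 2. The analysed bipolar channel brackets the
stimulation contact (2 → 1−3, 3 → 2−4), lower index minus higher; polarity
does not affect power. The default sweet-spot coordinate
(±12.5, −12.7, −5.4) mm MNI is an approximate published STN value and is a
configuration entry, not a constant.

## Problem sizes in the shipped tests

The test suite and acceptance script run at desk scale as the package's own
choice of problem size: 180-s single recordings where the full duration
matters (parameter recovery, scenarios), 10–30 s at 500 Hz for cohort-level
Monte-Carlo (30–50 cohorts), 1000-permutation cluster nulls, and
200-replicate calibration loops. Sizes are stated in each test.

## Known limitations

- Knee-mode aperiodic fits are not implemented; spectra with a bend inside
  2–60 Hz will fit poorly and be rejected by the R² filter.
- The peak-σ initial guess from half-height widths is crude for strongly
  overlapping peaks; the joint refit usually repairs it, but two peaks
  closer than ~2 Hz may merge.
- EDF files can be read (via the optional `mne` dependency) but not
  written; the native on-disk format is raw float64 + JSON sidecar.
- The spatial (electrode-localization) analyses that sometimes accompany
  this kind of study are out of scope; only the sweet-spot distance rule for
  contact selection is implemented.
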