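# Methods

This note documents the models, estimators and design choices behind the
package, in the spirit of a statistical methods appendix.

## The closed-loop beat-to-beat model

No public beat-by-beat recordings exist for the populations of interest, so
the pipeline is developed and validated against a synthetic cohort. The
generator is a discrete beat-to-beat update in the tradition of the DeBoer
cardiovascular model — the simplest structure that exhibits the four
phenomena the analysis measures: respiratory sinus arrhythmia (RSA),
~0.1 Hz Mayer-wave pressure oscillations, very-low-frequency drift, and a
recoverable baroreflex gain.

Beat *n* at time *t‌ₙ*:

```
SBP_n = S0 + A_resp·sin(θ_n) + A_mayer·sin(2π f_m t_n + φ) + w_n + ε_S
RR_n  = R0 + G·(SBP_{n−k} − S0) + A_rsa·sin(θ_n + ψ) + v_n + ε_R
DBP_n = D0 + 0.5·(SBP_n − S0) + ε_D
t_{n+1} = t_n + RR_n / 1000
```

where θ is the respiratory phase, f_m = 0.1 Hz, G is the baroreflex gain
(ms/mmHg) acting at lag k ∈ {1, 2} beats, and φ, ψ, θ₀ are random phases.
Parameters (units, defaults): R0 = 850 ms (HC) / 800 ms (patients),
S0 = 120 mmHg, D0 = 70 mmHg; A_rsa in ms and A_mayer in mmHg set by
calibration; A_resp = 1.5 mmHg; measurement noise 2 ms / 1 mmHg /
0.8 mmHg. A non-positive RR aborts the simulation with the offending beat
named.

**Breathing.** Paced protocols fix the respiratory rate at 0.2 Hz
(12 breaths/min) or 0.1 Hz (6 breaths/min) for 2-minute recordings;
spontaneous breathing runs 5 minutes at 0.25 Hz (15 breaths/min) with a
slow multiplicative AR(1) frequency jitter (5% sd, clipped to 0.16–0.4 Hz)
so RSA stays inside the HF band. The 0.25 Hz rate is an assumption — no
spontaneous-rate statistics were available for the populations modelled —
chosen from the middle of the normal adult range.

**VLF drift.** The drift terms *w*, *v* are mean-reverting AR(1)
(discrete Ornstein–Uhlenbeck) walks with a 12-beat relaxation time:
bounded-variance random walks whose Lorentzian spectrum puts ≈ 77% of its
power below 0.04 Hz at typical heart rates (≈ 17% leaks into LF, which the
calibration accounts for). A reflecting random walk was rejected because
its mixing time at the required variance exceeds a 5-minute recording, so
it cannot reach its stationary VLF power within one recording.

**Paced-breathing response.** Paced breathing deepens tidal volume, so the
RSA amplitude is multiplied by 1.4 at 12 breaths/min; at 6 breaths/min the
respiratory rhythm synchronises with the baroreflex loop and the
multiplier is 2.8 (cardiorespiratory resonance — this is what moves RSA
power from HF into LF and inflates TP at slow breathing). The Mayer-wave
amplitude is damped to 0.6 at 12/min, reflecting reduced non-respiratory
LF drive during attentive paced breathing; this produces the
characteristic LF decrease at 12/min. The post-COVID preset additionally
scales its paced RSA multipliers by √(HF_HC/HF_PCC) so its paced HF
normalises toward the healthy-control level, while the ME/CFS preset does
not — patients' autonomic responses to paced breathing differ in exactly
this way, and the degree of normalisation is matched qualitatively only.

## Calibration of group presets

`make_group_presets` accepts target medians of spontaneous-breathing TP,
LF, HF (ms²) and sequence-method BRS (ms/mmHg) per group; defaults are the
reference cohort medians (HC 2709/759/704/8.45, ME/CFS 852/367/153/4.60,
PCC 1358/429/335/5.99). Calibration proceeds in two stages, both
deterministic (fixed internal seed):

1. **Analytic start + dispersion-free pilot.** A sinusoid of amplitude *a*
   carries *a*²/2 of band power, which gives starting values for A_rsa,
   A_mayer (through G) and the drift variance. Six pilot recordings per
   group (no between-subject dispersion) then refine the parameters
   multiplicatively. This step is needed because the sequence-method BRS
   estimate is not the generating gain: the ≥ 4 ms/beat response threshold
   selects ramps where RSA and noise happen to align with the pressure
   ramp, biasing the estimate in a way that depends on the RSA/noise mix.
   The gain is therefore calibrated against the *measured* BRS, not set to
   the target.
2. **Dispersed-cohort correction.** Between-subject dispersion enters as
   log-normal multipliers (CV 0.5, unit median) on RSA amplitude,
   baroreflex gain, Mayer amplitude and drift variance. Although each
   multiplier has unit median, the median of a *sum* of skewed band powers
   (TP) sits above the sum of medians, and BRS responds nonlinearly to the
   draws, so dispersed-cohort medians drift from dispersion-free ones.
   Three rounds over a 64-subject-per-group pilot cohort measure and
   remove that drift. To keep the pilot estimate sharp, the median is
   estimated as the intercept of a regression of log(index) on the known
   log-multipliers (plus the median residual) rather than as a raw sample
   median — the multipliers are simulator ground truth, so this is
   legitimate variance reduction inside the generator.

Simulated cohort medians (n ≥ 30 per group) land within ±25% of the
targets; the residual scatter is dominated by the sampling error of a
median under CV-0.5 dispersion, not by calibration bias. Targets with
LF + HF > TP are rejected as unattainable.

## Questionnaire covariates

Scores are drawn through a Gaussian copula: a common fatigue factor loads
(λ = 0.85) on the five MFI-20 domains; group-specific means/spreads come
from the reference cohort's medians and IQRs (sd ≈ IQR/1.35); scores are
rounded and clipped to instrument ranges (MFI 4–20, HADS 0–21); IPAQ
totals are log-normal. Couplings:

- **HC:** HADS correlates with fatigue (target r = 0.5, sampled Spearman
  ≈ 0.37–0.62 at n = 200) — in healthy people fatigue tracks mood.
- **Patients:** fatigue is *uncoupled* from HADS but correlates negatively
  (target −0.55) with the subject's RSA-amplitude and baroreflex-gain
  draws — fatigue tracks dysautonomia, not mood.
- **PCC only:** IPAQ couples negatively (−0.45) to fatigue.

Diagnostic-criteria flags are Bernoulli draws: ME/CFS patients meet all
criteria sets (they are recruited as established cases); post-COVID
patients meet ME/CFS criteria at rates 14/29 (CCC) and 16/29 (IOM/NAM).
What the generator does **not** emulate: respiratory-volume signals (the
published models' TP_RV predictor must be supplied externally), realistic
hemodynamics (no Windkessel or stroke-volume model), non-stationarity
beyond VLF drift, age/sex effects on physiology, and missing data. Tests
passing on this cohort therefore validate the estimators and the
statistical pipeline, not any clinical claim about real patients.

## Spectral estimation

The device originally used for such recordings does not document its
estimator, so the conventional choice is made: cubic-spline resampling of
the beat series at 4 Hz (no extrapolation beyond the first/last beat),
linear detrending (keeps drift out of VLF at 2-minute lengths), Welch PSD
with 120-s Hann segments and 50% overlap for 5-minute recordings, a single
Hann periodogram for 2-minute recordings. Band power sums PSD bins over
[lo, hi) — half-open edges so the bands partition [0, 0.4) exactly and
TP = VLF + LF + HF holds to rounding. VLF is flagged invalid for
recordings under 240 s, where one band-width cannot be resolved; the LF/HF
ratio is reported as NaN when HF power is numerically zero. Recordings
under 60 s or sampled below 0.8 Hz are refused.

## Sequence method

Thresholds of 1 mmHg/beat (SBP) and 4 ms/beat (RR) follow common practice;
both are parameters. "Within two heart beats" is read as lags {0, 1, 2},
first qualifying lag wins (deterministic tie-break). Ramps never share
beats: at a pressure turning point the shared beat belongs to the earlier
ramp and the later run is trimmed, surviving only if ≥ 3 beats remain.
Per-sequence slope is least-squares (equal to the endpoint ratio on
collinear data; an endpoint mode is provided); BRS per direction averages
per-sequence slopes, and the overall BRS averages the directions that
exist. An optional minimum-correlation filter (r ≥ 0.85) is off by
default, since the analysis being reproduced mentions none. Implementation
is verified against an exhaustive brute-force enumerator on ~10⁴ small
series.

## Statistics layer

Kruskal–Wallis uses tie-corrected ranks; Dunn z-tests use pooled mean
ranks with the standard tie term, and pairwise significance is judged by
comparing the unadjusted Dunn p to the Bonferroni-corrected α
(0.05/3 = 0.01667 for three groups) — the corrected-α convention rather
than p-value multiplication, preserving the printed α. Spearman
correlations are tie-corrected (Pearson on average ranks); the screen
retains pairs at p < 0.01 per group. Chi-square tests are Pearson without
continuity correction. Descriptives are median (P25–P75).

## Diagnostic models

Forward selection uses Rao score tests (entry p < 0.05), backward uses
Wald tests (removal p > 0.10); the thresholds are conventional defaults
and exposed. Complete separation is flagged on the model object.
Hosmer–Lemeshow groups deciles of predicted risk, χ² over 2g cells with
df = g − 2 (the convention for model-fitted risks; g ≤ 2 is refused, empty
cells merge with a neighbour). AUC is the Mann–Whitney statistic with a
DeLong 95% CI (the CI method for the published AUCs is unknown; DeLong is
the standard analytic choice). Cutoffs are midpoints between consecutive
distinct scores; Youden ties resolve toward higher sensitivity (screening
context), and a Se = Sp cutoff is reported alongside. Score orientation is
auto-detected so AUC ≥ 0.5, with the direction recorded. The two published
models ship as fixed coefficient sets; their coefficients are printed at
three decimals, so probabilities computed from them are approximate.

## Artifact screening

The original recordings were edited manually; the package substitutes an
explicit two-rule surrogate so the pipeline is reproducible: a beat is
flagged when RR leaves [300, 2000] ms or deviates from the median of a
centered 11-beat window by more than 20% of that median. Flagged beats are
replaced by linear interpolation between clean neighbours and beat times
rebuilt cumulatively; recordings with ≥ 20% flagged beats are rejected as
unusable (a repository policy, not an empirical claim). Screening is
idempotent after interpolation.

## Problem sizes

Default problem sizes used by the test suite and the acceptance script:
20 seeds for gain recovery, 12–96 subjects per group for cohort-level
checks, 100–200 replicates for the null-cohort Type-I check. These sizes
give Monte-Carlo error comfortably inside the stated tolerances while
keeping a full run fast on a laptop.
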