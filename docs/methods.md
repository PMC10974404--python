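# Methods

## Optical forward model

The generator treats the finger as a static absorber plus a pulsing arterial
compartment.  Transmitted intensity per channel is

    I(t) = DC_λ · (1 − r_λ · p(t)) + DC_λ · (disturbances),
    DC_λ = I₀ · exp(−A_base(λ)),
    r_λ  = (ε_HbO2(λ)·c₁ + ε_Hb(λ)·c₂ + μ_bg(λ)) · Δ⟨L⟩,

where p(t) is a periodic unit-range cardiac waveform (raised-cosine systolic
lobe plus a smaller, disjoint dicrotic bump — only the peak-to-trough
amplitude enters the features, so the morphology is a free choice) and r_λ is
the fractional AC/DC modulation.  Defaults: Δ⟨L⟩ = 0.008 cm (≈ 80 µm path
pulsation), extinction coefficients from the standard oxy/deoxy-hemoglobin
compilations converted to (g/dL)⁻¹cm⁻¹, and μ_bg the water absorption
spectrum scaled by the ≈ 0.85 plasma volume fraction of whole blood.  These
are configuration defaults, not fitted values; they produce perfusions
(AC/DC ≈ 0.6–2.3%) in the physiological range.

The μ_bg term is load-bearing.  In the pure two-chromophore model the ratio
R_ij = ΔA_i/ΔA_j is algebraically independent of total hemoglobin
(c cancels between numerator and denominator), so no regressor could recover
Hb from ratio features.  Whole blood, however, is hemoglobin *diluted in
plasma*: the non-hemoglobin absorption, strongest near 940 nm, does not scale
with c, so the hemoglobin:water proportion — the concentration itself —
shifts the ratios by several percent across the clinical range.  Setting
`ext_background` to zeros recovers the idealised model (used by the tests of
the pure-model identities).

## Synthetic cohort

Per subject: Hb from a mixture 0.8·N(14, 1²) + 0.2·U(7, 19) truncated to
(4, 22) g/dL — mass concentrated in the normal 12–16 g/dL band with sparse
abnormal tails; age ~ N(41.7, 24.3²) truncated to [18, 90] years; P(male) =
100/249; SpO₂ ~ N(0.97, 0.02²) truncated to [0.88, 1]; heart rate ~
U(55, 95) bpm; respiration ~ U(0.15, 0.35) Hz.  Records are 2 min at 100 Hz.
Disturbances (relative to DC): white noise SD 0.2%, respiratory baseline
wander 2%, 50 Hz mains tone 0.5%, and motion transients (Gaussian bumps,
τ = 0.3 s, amplitude 5%) with probability 0.05 per 5 s segment; drift, mains
and motion are common-mode across channels, white noise independent.
Per-subject seeds are `seed + index`.

What the generator does **not** emulate: photon scattering and melanin,
reflective-mode probes, beat-to-beat heart-rate and pulse-shape variability,
venous pulsation, and probe-coupling drift.  Passing tests therefore show the
chain is correct and noise-robust under a Beer–Lambert world; they do not
certify clinical accuracy, where the AC/DC–Hb map is confounded by exactly
the omitted effects.

## Preprocessing

* **Low-pass**: 101-tap Hamming-windowed linear-phase FIR, 10 Hz cutoff,
  applied forward–backward (zero net phase, so landmark timing survives).
  Passband ripple < 1% below ~8 Hz; > 40 dB stopband beyond ~15 Hz.
* **Baseline removal**: 7-level `coif5` decomposition (symmetric extension),
  deepest approximation band zeroed (< fs/2⁸ ≈ 0.39 Hz at 100 Hz),
  reconstruction cropped to input length.  Linear; approximately idempotent.
* **Cardiac period**: dominant FFT magnitude peak in 0.7–3.0 Hz, refined by
  parabolic interpolation; a peak must exceed 4× the in-band median magnitude
  or a no-pulse error is raised.  Estimated once per record on the
  perfusion-normalized channel sum (best SNR; channels share timing).
* **Comb filter**: feed-forward average of M = 4 cycle-delayed copies with
  fractional-delay (linear-interpolation) taps, so exactly periodic signals —
  including heart rates incommensurate with the sample grid — pass unchanged,
  while aperiodic transients attenuate ≈ 4× and wide-band noise SD halves.

DC is defined as the mean of the low-pass output (the baseline-removed signal
has none); AC comes from the fully preprocessed signal.  Because the DC
window still contains the pulse, DC is underestimated by r·mean(p) ≈ 0.5%,
a common-mode bias that cancels in the ratios.

## AC read-out

The documented single-channel read-out (`extract_ac_dc`) is the differential
method: beat landmarks at derivative sign changes, prominence-filtered at half
the window range, AC = mean peak-to-trough amplitude over complete cycles.

The cohort pipeline uses a multi-channel refinement
(`extract_ac_dc_channels`), for a measured reason: reading extrema of a noisy
trace is biased upward by the expected maximum of the residual noise — on the
low-perfusion channels (660/690 nm, AC/DC ≈ 0.6%) by up to +13% with ~1–2%
cross-subject scatter, which swamps the few-percent hemoglobin signal in the
ratios.  Instead, per 5 s window:

1. build a leave-one-out reference for each channel — the perfusion-normalized
   sum of the *other* seven channels (high SNR, statistically independent of
   the channel's own noise);
2. validate the window by landmarking the reference (derivative sign changes,
   ≥ 1 complete peak/trough cycle);
3. read the reference's beat amplitude from its cardiac-period-folded average
   beat (fractional-period folding by linear interpolation);
4. set the channel's AC to the least-squares projection of its window onto the
   mean-removed reference, scaled by that amplitude — a linear functional of
   the samples, hence zero-mean noise and no selection bias; landmark jitter
   affects all channels' identically shaped beats equally and cancels in the
   ratios.

Windows are aggregated by the mean of per-channel perfusions after
whole-window artifact rejection (a window is dropped when any channel deviates
from the across-window median by > 5× MAD — motion transients are common-mode,
so rejection is all-or-nothing).  The mean was preferred to a plain median
because the read-out is unbiased and the median costs ~25% statistical
efficiency; robustness is supplied by the rejection step.  On noiseless
records the extracted ratios match the closed-form values to < 0.5%; under
the full noise model per-channel AC/DC is within ~3% of ground truth.

## Feature selection

SVR-RFE with a linear-kernel ε-SVR (C = 1, ε = 0.1): train on the surviving
features, score each by its squared weight, drop the single weakest, record
5-fold CV RMSE (fold assignment fixed by the config seed) for every subset
size down to one.  The retained size is the CV argmin, ties toward fewer
features.  All 58 features, demographics included, compete uniformly.  On
noisy synthetic cohorts the CV curve is shallow and its argmin unstable
(sometimes k = 2); the experiment config therefore allows pinning the subset
size (the full-protocol runs use 29, the deployed configuration of the
method), with the CV choice as the default rule.

## Ensemble ELM

One ELM: W, b i.i.d. U(−1, 1) (pairs with z-scored inputs), hidden layer
H = g(XWᵀ + b) with sigmoid g (bias inside the activation, the standard
single-hidden-layer form), β = pinv(H)·Y via SVD with the conventional
relative singular-value cutoff, no ridge term.  The ensemble trains P = 200
members differing only in their hidden-layer randomness (member seeds derived
from the base seed via `SeedSequence(base, (i,))` — platform-stable) and
averages predictions, shrinking initialisation variance roughly as 1/P;
measured re-training SD falls monotonically over P ∈ {1, 10, 50, 200}
(≈ 0.46 → 0.03 g/dL on the synthetic recovery task).

## Evaluation

Repeated random 8:2 splits (floor(0.8·n) training rows; 249 → 199/50), 200
repeats by default; per repeat the standardizer is fit on the training rows
only, the RFE mask is computed on the first repeat's training split and
reused (per-repeat re-ranking available by flag), and metrics are averaged
over repeats.  Metrics: RMSE; Pearson r with two-sided p (t transform, n−2
df); Bland–Altman mean difference, SD (n−1), limits mean ± 1.96 SD and the
fraction of points inside them; error-grid percentages with closed boundaries
on the safe side (|e| = 1 → A, |e| = 2 → B).  Repeats with a degenerate test
target are skipped and counted.  Baseline regressors (linear, default-kernel
SVR, random forest, single ELM) are comparison hooks at library defaults, not
tuned replicas.

## Problem sizes and numerical choices

Recovery experiments use 250 subjects (200 train / 50 test) of 2-minute
records — the protocol's sample sizes; the full-protocol run uses a
249-subject cohort and 200 repeats.  The acceptance script and the test suite
regenerate all cohorts from their seeds at run time.  Degenerate inputs fail
loudly: constant channels → unusable record; constant regression target →
degenerate target; no spectral peak → no pulse; zero-AC channel → degenerate
channel.  Ratio order is fixed (R_12 … R_18, R_21 … R_87) so selected-feature
indices are reproducible; gender is encoded 0 = female, 1 = male.

## Known limitations

* The Hb information in the ratios rides on a few percent of signal
  (940 nm-paired ratios); under the default noise model the recovery PCC on
  50 held-out subjects is ≈ 0.76–0.85 across cohort seeds — close to the
  information floor of the features (stronger regressors plateau at the same
  level), so individual seeds can land on either side of 0.8.
* Sparse Hb tails (by design) make tail predictions less accurate, mirroring
  the usual clinical-cohort imbalance.
* The comb filter assumes a fixed period per record (resting protocol);
  heart-rate drift within a record would degrade it.
* LED channels are treated as simultaneously sampled; hardware
  time-multiplexing skew is not modelled.
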