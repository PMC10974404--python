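# hemoppg

Non-invasive hemoglobin (Hb) estimation from eight-wavelength
photoplethysmography (PPG), for researchers in optical physiological sensing
who want a complete, testable reference implementation of the
ratio-of-ratios + ensemble-ELM estimation chain — including a physics-based
synthetic cohort generator, so every stage can be validated against ground
truth without clinical data.

## The method

Transmissive PPG at wavelength λ modulates with arterial pulsation.  Under the
Beer–Lambert law the pulsatile absorbance change is

    ΔA(λ) = (ε_HbO2(λ)·c₁ + ε_Hb(λ)·c₂ + μ_bg(λ)) · Δ⟨L⟩

with c₁ = s·c, c₂ = (1−s)·c the oxy/deoxy hemoglobin concentrations (g/dL),
s the oxygen saturation, Δ⟨L⟩ the beat-synchronous optical path change, and
μ_bg the absorption of the non-hemoglobin (plasma/water) fraction of pulsing
blood.  In practice ΔA(λ) ≈ AC_λ/DC_λ, the pulsatile over static signal
amplitude.  Ratios of two channels,

    R_ij = (AC_i/DC_i) / (AC_j/DC_j),

cancel Δ⟨L⟩ and the source intensity; for 8 wavelengths
(610/630/660/690/750/805/850/940 nm) there are 56 ordered ratios, which with
age and gender give a 58-feature vector per subject.  The water term is what
makes the ratios sensitive to total Hb — without it c cancels entirely and
only s survives.

The chain: FIR low-pass at 10 Hz → 7-level `coif5` wavelet baseline removal →
cardiac-period comb filtering → 5 s windows → AC/DC read-out → 56 ratios →
z-scoring → SVR-RFE feature ranking → ensemble of P = 200 extreme learning
machines (K = 20 sigmoid hidden units each, output weights by Moore–Penrose
pseudoinverse, predictions averaged).  Evaluation follows the clinical
protocol: repeated random 8:2 splits (200 repeats), RMSE, Pearson correlation,
Bland–Altman limits of agreement, and a Clarke-style error grid adapted to Hb
(region A ≤ 1 g/dL, B ≤ 2 g/dL, C > 2 g/dL).

## Worked example

```python
from hemoppg import (NoiseConfig, Standardizer, feature_table, generate_cohort,
                     pcc, predict_eelm, rmse, train_eelm)

records = generate_cohort(250, noise=NoiseConfig(), seed=1)   # 2 min @ 100 Hz each
table = feature_table(records)                                 # 250 x 58 + hb_ref
X = table.drop(columns="hb_ref").to_numpy()
y = table["hb_ref"].to_numpy()

std = Standardizer().fit(X[:200])
model = train_eelm(std.transform(X[:200]), y[:200], K=20, P=200, seed=1)
pred = predict_eelm(model, std.transform(X[200:]))
print(f"RMSE {rmse(y[200:], pred):.3f} g/dL, PCC {pcc(y[200:], pred)[0]:.3f}")
```

prints

```
RMSE 1.363 g/dL, PCC 0.829
```

i.e. on 50 held-out synthetic subjects under the full noise model (wide-band
noise, baseline wander, mains tone, motion transients) the ensemble recovers
the generator's ground-truth hemoglobin to 1.36 g/dL with correlation 0.83;
on noiseless data the same pipeline reaches RMSE ≈ 0.47 g/dL and PCC ≈ 0.99.
The `examples/` directory walks through each capability (forward model,
preprocessing, feature selection, ensemble training, full experiment), and the
`hemoppg` CLI (`synth`, `preprocess`, `featurize`, `select`, `train`,
`predict`, `evaluate`, `run`) exposes the same steps from the shell.

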