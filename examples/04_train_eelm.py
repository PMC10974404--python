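"""Train the ensemble ELM and measure hemoglobin recovery and stability.

Trains on 100 synthetic subjects, tests on 30, and contrasts a single ELM's
re-training scatter with the 200-member ensemble's.
"""

import numpy as np

from hemoppg import (
    Standardizer,
    feature_table,
    generate_cohort,
    pcc,
    predict_eelm,
    predict_elm,
    rmse,
    train_eelm,
    train_elm,
)

records = generate_cohort(130, seed=5, duration=60.0)
table = feature_table(records)
X = table.drop(columns="hb_ref").to_numpy()
y = table["hb_ref"].to_numpy()
std = Standardizer().fit(X[:100])
X_tr, X_te = std.transform(X[:100]), std.transform(X[100:])

model = train_eelm(X_tr, y[:100], K=20, P=200, seed=0)
pred = predict_eelm(model, X_te)
r, p = pcc(y[100:], pred)
print(f"EELM (K=20, P=200): test RMSE {rmse(y[100:], pred):.3f} g/dL, "
      f"PCC {r:.3f} (p={p:.2e})")

single = [predict_elm(train_elm(X_tr, y[:100], K=20, seed=s), X_te[:5])
          for s in range(30)]
ensemble = [predict_eelm(train_eelm(X_tr, y[:100], K=20, P=50, seed=s), X_te[:5])
            for s in range(30)]
print(f"re-training SD per prediction: single ELM {np.std(single, 0).mean():.3f}, "
      f"EELM(P=50) {np.std(ensemble, 0).mean():.3f} g/dL")
print("\nAveraging independently initialised ELMs removes most of the "
      "initialisation scatter without touching the bias.")
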