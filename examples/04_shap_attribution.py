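"""Explain a seizure prediction with exact (enumeration) Shapley values.

Trains XGBoost to flag ictal windows, then attributes one prediction over
all 2^4 feature coalitions: base value + attributions reconstruct the
predicted probability exactly (local accuracy), and mean |phi| over many
windows ranks the features globally.
"""

import numpy as np

import eegmark as em
from eegmark.dynamic import BASE_FEATURES

dataset = em.generate_dataset(n_per_state=10, duration_s=23.6, master_seed=3)
features = em.extract_features(dataset.recordings, warn_uncalibrated=False)

X = features[BASE_FEATURES]
y = (features["label"] == "ictal").astype(int).to_numpy()
clf = em.make_classifier("xgb", seed=0).fit(X.to_numpy(), y)

model = em.probability_output(clf, target_class=1)
ictal_rows = X[y == 1]
explanations = em.explain_table(model, ictal_rows.head(10), X,
                                feature_names=BASE_FEATURES,
                                max_background=128, seed=0)

e = explanations[0]
print(f"explained window {e.instance_id}: P(ictal) = {e.model_output:.4f}")
print(f"base value (background mean prediction) = {e.base_value:.4f}")
for name, phi in zip(e.feature_names, e.phi):
    print(f"  phi[{name:12s}] = {phi:+.4f}")
recon = e.base_value + e.phi.sum()
print(f"base + sum(phi) = {recon:.4f}  "
      f"(local accuracy error {e.local_accuracy_error:.2e})")

ranking = em.global_importance(explanations)
print("\nglobal ranking by mean |phi| over 10 ictal windows:")
print(ranking.round(4).to_string(index=False))
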