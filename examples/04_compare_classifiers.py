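"""Compare two classifiers on the same hold-out with McNemar's test.

Trains the stacking and voting ensembles on one split, then tests whether
their error patterns differ more than chance would allow: the statistic is
chi2 = (b - c)^2 / (b + c) over the discordant counts b (stacking right,
voting wrong) and c (the reverse).
"""

import numpy as np

from bcgkit import (
    SyntheticConfig,
    build_feature_table,
    compare_models,
    generate_dataset,
    holdout_split,
    preprocess_pipeline,
    segment_recording,
)
from bcgkit.features import feature_matrix, standardize_features
from bcgkit.models import make_model

cfg = SyntheticConfig(duration_s=120.0, seed=3)
recordings = generate_dataset(cfg, n_per_class=10)
segments = [seg for rec in recordings
            for seg in segment_recording(preprocess_pipeline(rec))]
X, y, groups = feature_matrix(build_feature_table(segments))

train, test = holdout_split(y, groups, test_fraction=0.25, seed=0)
(X_train, X_test), _ = standardize_features(X[train], X[test])

preds = {}
for name in ("stacking", "voting"):
    model = make_model(name, seed=0).fit(X_train, y[train])
    preds[name] = np.argmax(model.predict_proba(X_test), axis=1)
    acc = (preds[name] == y[test]).mean()
    print(f"{name:8s} hold-out accuracy: {acc:.3f}")

result = compare_models(y[test], preds["stacking"], preds["voting"])
print(f"\nMcNemar: b={result['b']} c={result['c']} "
      f"chi2={result['chi2']:.3f} p={result['p']:.3f}")
# A large p-value means the two ensembles' disagreements are symmetric --
# no evidence that one classifier is systematically better on this split.
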