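"""Stratified split, the tuned SVM and random forest, and a small grid search."""

import numpy as np

from etongue import (
    RFConfig,
    SVMConfig,
    build_feature_table,
    default_config,
    fit_normalization,
    grid_search,
    simulate_dataset,
    split_dataset,
    train_rf,
    train_svm,
)

ds = simulate_dataset(default_config(delta=0.2, n_per_class=30, noise_seed=3))
sp = split_dataset(ds.y, fraction=0.8, seed=3)
stats = fit_normalization(ds.X_concat[sp.train_rows])
area = build_feature_table(ds, "AREA", stats)
Xtr, ytr = area.matrix[sp.train_rows], ds.y[sp.train_rows]
Xte, yte = area.matrix[sp.test_rows], ds.y[sp.test_rows]
print(f"split: {len(ytr)} train / {len(yte)} test (stratified)")

svm = train_svm(Xtr, ytr, SVMConfig(), seed=3)     # linear kernel, C = 6
rf = train_rf(Xtr, ytr, RFConfig(), seed=3)        # 64 trees, depth 8
for clf in (svm, rf):
    acc = np.mean(clf.predict(Xte) == yte)
    print(f"{clf.model_kind:3s} test accuracy: {acc:.3f}")

# Grid search by stratified 5-fold CV accuracy; ties go to the first listed.
res = grid_search(Xtr, ytr, [SVMConfig(C=c) for c in (1, 6, 10)], folds=5, seed=3)
print(f"best SVM C = {res.best_config.C} (CV accuracy {res.best_score:.3f})")
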