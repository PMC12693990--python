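"""Scoreboards, model comparison, and the LDA class map with 95% ellipses."""

import numpy as np

from etongue import (
    build_feature_table,
    compare_models,
    default_config,
    fit_normalization,
    lda_fit_project,
    score_predictions,
    simulate_dataset,
    split_dataset,
    train_rf,
    train_svm,
)
from etongue.evaluate import plot_lda

ds = simulate_dataset(default_config(delta=0.1, n_per_class=30, noise_seed=7))
sp = split_dataset(ds.y, 0.8, seed=7)
stats = fit_normalization(ds.X_concat[sp.train_rows])
area = build_feature_table(ds, "AREA", stats)
order = sorted(set(ds.y.tolist()))

reports = []
for trainer, name in ((train_svm, "SVM"), (train_rf, "RF")):
    clf = trainer(area.matrix[sp.train_rows], ds.y[sp.train_rows], seed=7)
    pred = clf.predict(area.matrix[sp.test_rows])
    reports.append(score_predictions(ds.y[sp.test_rows], pred, order, name, "AREA"))
    print(f"{name}: accuracy {reports[-1].accuracy:.3f}, "
          f"misclassified {reports[-1].misclassified}")
    print(reports[-1].confusion)

print(compare_models(reports).to_string(index=False))

# LDA on the AREA features: 2-D scores, exact class centroids, 95% ellipses.
proj = lda_fit_project(area.matrix, ds.y)
print("class centroids (LD1, LD2):")
for c, cen in zip(proj.class_order, np.round(proj.centroids, 2)):
    print(f"  {c}: {cen}")
plot_lda(proj, "lda_map.png")
print("wrote lda_map.png")
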