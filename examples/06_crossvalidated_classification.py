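"""Stratified 5-fold evaluation of the softmax head on fused images.

A compact head (flatten -> dense(64, ReLU) -> dropout(0.1) -> dense(2) ->
softmax) is trained with RMSprop at learning rate 1e-4 and scored with
accuracy, recall, F1 and AUC per fold.
"""

import numpy as np

from eegfusion import (
    ClassifierConfig, CohortSpec, PipelineConfig, default_montage,
    generate_cohort, kfold_evaluate, subject_images,
)

recordings, _, labels = generate_cohort(CohortSpec(n_per_class=15, seed=2))
montage = default_montage()
X = np.stack([
    subject_images(rec, montage, PipelineConfig())[1].pixels for rec in recordings
])

report = kfold_evaluate(X, labels, ClassifierConfig(seed=2))
print(f"per-fold accuracy: {[round(a, 3) for a in report.fold_accuracy]}")
print(f"mean accuracy {report.mean_accuracy:.3f}  recall {report.mean_recall:.3f}  "
      f"F1 {report.mean_f1:.3f}  AUC {report.mean_auc:.3f}")
print(f"mean validation loss {report.mean_val_loss:.3f}")
curve = np.mean(report.val_accuracy_curves, axis=0)
print(f"validation accuracy epoch 10: {curve[9]:.3f} -> epoch 400: {curve[-1]:.3f}")
print("Accuracy well above 0.5 means the fused images retain the class-specific")
print("spatial pattern injected by the simulated frontal-theta effect.")
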