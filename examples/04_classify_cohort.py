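"""Leave-one-subject-out classification of a small simulated cohort.

Simulates 4 subjects x 5 emotion classes x 2 trials, extracts features,
runs class-weighted one-vs-one LOOCV with test-fold undersampling, and
prints the headline metrics.  Takes a few minutes on one CPU.
"""

import numpy as np

from tstms import evaluate, featurize_cohort, make_cohort, run_loocv

cohort = make_cohort(
    n_subjects=4, classes="ADFSN", trials_per_class=2, seed=0,
    native_resolutions={c: (200, 140) for c in ["R", "G", "B", "NIR", "LWIR"]},
)
ds, table = featurize_cohort(cohort)
print(f"featurized {len(ds.y)} trials from {len(set(ds.subjects))} subjects")

folds = run_loocv(ds, seed=0)
report = evaluate(folds)
print(f"macro one-vs-rest ROC AUC: {report.macro_roc_auc:.3f}  (chance 0.5)")
print(f"subset accuracy:           {report.subset_accuracy:.3f}  (chance 0.2)")
print("per-class AUC:", {k: round(v, 3) for k, v in report.roc_auc.items()})
print("median row-normalized confusion matrix (%):")
print(np.round(report.confusion_percent, 1))
# Classes differ by where on the face the simulator placed extra pulsatile
# modulation, so a well-functioning pipeline separates them far above chance.
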