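"""Published benchmark confusion matrices for the 38-patient clinical cohort.

These row-percentage 6×6 confusion matrices are the reported classification
outcomes on the original clinical study group (38 hemodialysis patients,
classes A–F) for the three classifiers compared: distance-weighted Manhattan
k-NN (k = 7), an RBF SVM, and a random forest.  They serve as fixed inputs
for verifying the quality-indicator conventions: feeding them through
:func:`phonoavf.classification.quality_indicators` must reproduce the
reported per-class precision/recall/F-score and macro accuracies
0.81 / 0.78 / 0.74 after two-decimal rounding.
"""

import numpy as np

from .io import CLASS_LABELS

KNN_CONFUSION = np.array(
    [
        [91.0, 9.0, 0.0, 0.0, 0.0, 0.0],
        [9.0, 69.0, 22.0, 0.0, 0.0, 0.0],
        [0.0, 23.0, 67.0, 10.0, 0.0, 0.0],
        [0.0, 0.0, 4.0, 81.0, 15.0, 0.0],
        [0.0, 0.0, 0.0, 9.0, 83.0, 8.0],
        [0.0, 0.0, 0.0, 0.0, 8.0, 92.0],
    ]
)

SVM_CONFUSION = np.array(
    [
        [88.0, 12.0, 0.0, 0.0, 0.0, 0.0],
        [10.0, 65.0, 25.0, 0.0, 0.0, 0.0],
        [0.0, 26.0, 64.0, 10.0, 0.0, 0.0],
        [0.0, 0.0, 5.0, 79.0, 16.0, 0.0],
        [0.0, 0.0, 0.0, 10.0, 81.0, 9.0],
        [0.0, 0.0, 0.0, 0.0, 10.0, 90.0],
    ]
)

RF_CONFUSION = np.array(
    [
        [86.0, 14.0, 0.0, 0.0, 0.0, 0.0],
        [13.0, 61.0, 26.0, 0.0, 0.0, 0.0],
        [0.0, 27.0, 60.0, 13.0, 0.0, 0.0],
        [0.0, 0.0, 7.0, 75.0, 18.0, 0.0],
        [0.0, 0.0, 0.0, 13.0, 76.0, 11.0],
        [0.0, 0.0, 0.0, 0.0, 12.0, 88.0],
    ]
)

#: Reported two-decimal quality indicators for each classifier, as published.
REPORTED_INDICATORS = {
    "knn": {
        "precision": [0.91, 0.68, 0.72, 0.81, 0.78, 0.92],
        "recall": [0.91, 0.69, 0.67, 0.81, 0.83, 0.92],
        "f_score": [0.91, 0.69, 0.69, 0.81, 0.81, 0.92],
        "acc": 0.81,
    },
    "svm": {
        "precision": [0.90, 0.63, 0.68, 0.80, 0.76, 0.91],
        "recall": [0.88, 0.65, 0.64, 0.79, 0.81, 0.90],
        "f_score": [0.89, 0.64, 0.66, 0.79, 0.78, 0.90],
        "acc": 0.78,
    },
    "rf": {
        "precision": [0.87, 0.60, 0.65, 0.74, 0.72, 0.89],
        "recall": [0.86, 0.61, 0.60, 0.75, 0.76, 0.88],
        "f_score": [0.86, 0.60, 0.62, 0.75, 0.74, 0.88],
        "acc": 0.74,
    },
}

CONFUSION_MATRICES = {"knn": KNN_CONFUSION, "svm": SVM_CONFUSION, "rf": RF_CONFUSION}

LABELS = CLASS_LABELS
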