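"""Reference benchmark: the published summed confusion matrix.

The four-cell-line SERS lysate identification benchmark reports, for a
leave-three-batches-out validation over 20 batch permutations, the summed
confusion matrix below together with per-class sensitivity, specificity
and accuracy percentages. The counts are the package's headline fixture:
:func:`sersid.validation.compute_metrics` applied to them must reproduce
every published percentage after one-decimal rounding, which ties the
metric definitions used here to the benchmark's.
"""

from __future__ import annotations

import numpy as np

from .spectral_io import ConfusionMatrix

__all__ = [
    "REFERENCE_LABELS",
    "reference_confusion_matrix",
    "REFERENCE_SENSITIVITY",
    "REFERENCE_SPECIFICITY",
    "REFERENCE_ACCURACY",
]

REFERENCE_LABELS = ("Capan-1", "HepG2", "MCF-7", "SK-Hep1")

_REFERENCE_COUNTS = (
    (906, 6, 3, 24),
    (74, 898, 33, 0),
    (0, 0, 932, 0),
    (22, 0, 0, 980),
)

# Published per-class percentages (one decimal), in REFERENCE_LABELS order.
REFERENCE_SENSITIVITY = (96.5, 89.4, 100.0, 97.8)
REFERENCE_SPECIFICITY = (96.7, 99.8, 98.8, 99.2)
REFERENCE_ACCURACY = (96.7, 97.1, 99.1, 98.8)


def reference_confusion_matrix() -> ConfusionMatrix:
    """The benchmark's summed confusion matrix (rows = true class)."""
    return ConfusionMatrix(REFERENCE_LABELS, np.array(_REFERENCE_COUNTS))
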