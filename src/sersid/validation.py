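"""Leave-three-batches-out validation and confusion-matrix metrics.

Whole batches — independently cultured, lysed and measured preparations —
are the unit of replication, so cross-validation holds out entire batches:
with six batches per class and training sets of three, all C(6,3) = 20
train/test partitions are evaluated. For each split a PCA model and a
linear SVM are fitted on the training batches only; the held-out batches
are projected onto the training loadings and classified; the resulting
per-split confusion matrices are summed entry-wise.

Per-class metrics are one-vs-rest on the summed matrix: for class k with
TP = cm[k, k], FN = row_k - TP, FP = col_k - TP, TN = total - TP - FN - FP,

* sensitivity = 100 * TP / (TP + FN)
* specificity = 100 * TN / (TN + FP)
* accuracy    = 100 * (TP + TN) / total

Sensitivity and specificity are additionally reported as the mean +/- SD
of the per-split values (sample SD); splits with an empty denominator are
excluded from those means (and counted), never silently treated as zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .chemometrics import pca_fit, pca_project, svm_predict, svm_train
from .errors import ValidationError
from .spectral_io import ConfusionMatrix, SpectrumSet

__all__ = [
    "SplitPlan",
    "MetricsReport",
    "enumerate_splits",
    "run_split",
    "cross_validate",
    "compute_metrics",
]


@dataclass(frozen=True)
class SplitPlan:
    """All train/test batch partitions, in lexicographic training order."""

    n_batches: int
    train_size: int
    splits: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]

    def __len__(self) -> int:
        return len(self.splits)


@dataclass(frozen=True)
class MetricsReport:
    """Per-class classification metrics, pooled and per-split.

    Pooled values are recomputable from the summed confusion matrix
    alone; per-split means/SDs summarize the distribution over
    cross-validation splits. All values are percentages; undefined
    entries (empty denominators) are NaN.
    """

    labels: tuple[str, ...]
    pooled_sensitivity: np.ndarray
    pooled_specificity: np.ndarray
    pooled_accuracy: np.ndarray
    mean_sensitivity: np.ndarray
    sd_sensitivity: np.ndarray
    mean_specificity: np.ndarray
    sd_specificity: np.ndarray
    n_splits: int = 0
    n_excluded: dict = field(default_factory=dict)


def enumerate_splits(n_batches: int, train_size: int) -> SplitPlan:
    """All unordered choices of ``train_size`` training batches.

    The complement of each training set is the test set, so every pair
    partitions {1..n_batches}; there are C(n_batches, train_size) splits,
    enumerated in lexicographic order of the training set.
    """
    if n_batches < 2 or not (1 <= train_size < n_batches):
        raise ValidationError(
            f"invalid split sizes: need 1 <= train_size < n_batches, got "
            f"train_size={train_size}, n_batches={n_batches}"
        )
    all_batches = set(range(1, n_batches + 1))
    splits = []
    for train in combinations(sorted(all_batches), train_size):
        test = tuple(sorted(all_batches - set(train)))
        splits.append((train, test))
    return SplitPlan(n_batches=n_batches, train_size=train_size, splits=tuple(splits))


def run_split(
    train: SpectrumSet,
    test: SpectrumSet,
    n_pcs: int = 4,
    cost_C: float = 1.0,
) -> ConfusionMatrix:
    """Fit PCA + SVM on the training batches and score the held-out ones.

    The test spectra are projected onto the loadings fitted on the
    training batches (training mean subtracted) and classified with the
    SVM trained on the training scores.
    """
    train_labels = set(train.class_labels)
    test_labels = set(test.class_labels)
    if any(s.cell_line is None for s in train) or any(
        s.cell_line is None for s in test
    ):
        raise ValidationError("all spectra must carry a cell_line label")
    missing = test_labels - train_labels
    if missing:
        raise ValidationError(
            f"classes {sorted(missing)} appear in the test set but not in "
            "training: the model cannot emit those labels"
        )
    labels = sorted(train_labels)
    pca = pca_fit(train.to_matrix(), n_pcs)
    train_scores = pca_project(pca, train.to_matrix())
    test_scores = pca_project(pca, test.to_matrix())
    clf = svm_train(train_scores, train.labels(), cost_C)
    predicted = svm_predict(clf, test_scores)
    return ConfusionMatrix.from_pairs(test.labels(), predicted, labels)


def cross_validate(
    sset: SpectrumSet,
    plan: SplitPlan,
    n_pcs: int = 4,
    cost_C: float = 1.0,
) -> tuple[ConfusionMatrix, list[ConfusionMatrix]]:
    """Run every split of the plan and sum the confusion matrices.

    Returns the entry-wise sum plus the list of per-split matrices; every
    test spectrum of every split is counted exactly once in the sum.
    """
    present = set(sset.batches)
    needed = set(range(1, plan.n_batches + 1))
    if not needed <= present:
        raise ValidationError(
            f"plan expects batches {sorted(needed)} but the dataset only has "
            f"{sorted(present)}"
        )
    per_split: list[ConfusionMatrix] = []
    summed: ConfusionMatrix | None = None
    for train_batches, test_batches in plan.splits:
        cm = run_split(
            sset.subset_batches(train_batches),
            sset.subset_batches(test_batches),
            n_pcs=n_pcs,
            cost_C=cost_C,
        )
        per_split.append(cm)
        summed = cm if summed is None else summed + cm
    assert summed is not None
    return summed, per_split


def _one_vs_rest(counts: np.ndarray, k: int) -> tuple[int, int, int, int]:
    total = int(counts.sum())
    tp = int(counts[k, k])
    fn = int(counts[k, :].sum()) - tp
    fp = int(counts[:, k].sum()) - tp
    tn = total - tp - fn - fp
    return tp, fn, fp, tn


def _safe_pct(num: float, den: float) -> float:
    return 100.0 * num / den if den > 0 else float("nan")


def compute_metrics(
    cm: ConfusionMatrix, per_split: list[ConfusionMatrix] | None = None
) -> MetricsReport:
    """One-vs-rest metrics from the summed matrix, plus per-split spread.

    Pooled sensitivity/specificity/accuracy come from the summed matrix;
    when per-split matrices are supplied, per-split sensitivities and
    specificities are averaged (sample SD), skipping and counting splits
    where a denominator is empty. An empty class row makes the pooled
    sensitivity undefined: it is reported as NaN with a warning, never as
    a silent zero.
    """
    per_split = per_split or []
    for split_cm in per_split:
        if split_cm.labels != cm.labels:
            raise ValidationError(
                "per-split confusion matrix labels differ from the summed matrix"
            )
    k = len(cm.labels)
    pooled_sens = np.empty(k)
    pooled_spec = np.empty(k)
    pooled_acc = np.empty(k)
    for i, lab in enumerate(cm.labels):
        tp, fn, fp, tn = _one_vs_rest(cm.counts, i)
        pooled_sens[i] = _safe_pct(tp, tp + fn)
        pooled_spec[i] = _safe_pct(tn, tn + fp)
        pooled_acc[i] = _safe_pct(tp + tn, cm.total)
        if tp + fn == 0:
            warnings.warn(
                f"class {lab!r}: pooled sensitivity undefined (no true samples)",
                stacklevel=2,
            )
        if tn + fp == 0:
            warnings.warn(
                f"class {lab!r}: pooled specificity undefined (no negatives)",
                stacklevel=2,
            )

    mean_sens = np.full(k, np.nan)
    sd_sens = np.full(k, np.nan)
    mean_spec = np.full(k, np.nan)
    sd_spec = np.full(k, np.nan)
    n_excluded: dict[str, dict[str, int]] = {}
    if per_split:
        for i, lab in enumerate(cm.labels):
            sens_vals, spec_vals = [], []
            skipped = {"sensitivity": 0, "specificity": 0}
            for split_cm in per_split:
                tp, fn, fp, tn = _one_vs_rest(split_cm.counts, i)
                if tp + fn > 0:
                    sens_vals.append(100.0 * tp / (tp + fn))
                else:
                    skipped["sensitivity"] += 1
                if tn + fp > 0:
                    spec_vals.append(100.0 * tn / (tn + fp))
                else:
                    skipped["specificity"] += 1
            if sens_vals:
                mean_sens[i] = float(np.mean(sens_vals))
                sd_sens[i] = float(np.std(sens_vals, ddof=1)) if len(sens_vals) > 1 else 0.0
            if spec_vals:
                mean_spec[i] = float(np.mean(spec_vals))
                sd_spec[i] = float(np.std(spec_vals, ddof=1)) if len(spec_vals) > 1 else 0.0
            if skipped["sensitivity"] or skipped["specificity"]:
                n_excluded[lab] = skipped
    return MetricsReport(
        labels=cm.labels,
        pooled_sensitivity=pooled_sens,
        pooled_specificity=pooled_spec,
        pooled_accuracy=pooled_acc,
        mean_sensitivity=mean_sens,
        sd_sensitivity=sd_sens,
        mean_specificity=mean_spec,
        sd_specificity=sd_spec,
        n_splits=len(per_split),
        n_excluded=n_excluded,
    )
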