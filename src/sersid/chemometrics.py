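"""PCA dimensionality reduction and linear maximum-margin classification.

PCA is fitted on the training spectra only (SVD of the column-centered
matrix); held-out spectra are projected onto the training loadings after
subtracting the *training* mean, so no information leaks from the test
batches into the model. Loading signs are fixed (largest-magnitude
element positive) so fitted models are reproducible across runs.

Classification is a soft-margin linear SVM in the one-vs-one multiclass
scheme with pairwise voting, the convention of the libSVM family of
solvers. Training delegates to scikit-learn's libSVM binding; the fitted
pairwise hyperplanes are extracted into a plain
:class:`LinearClassifierModel` whose prediction rule (voting, ties broken
toward the earliest label in ``class_labels`` order) is implemented here
and is what the validation pipeline uses.

Models persist as plain text key/value + matrix blocks so they diff
cleanly under version control.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.svm import SVC

from .errors import ValidationError

__all__ = [
    "PCAModel",
    "LinearClassifierModel",
    "pca_fit",
    "pca_project",
    "svm_train",
    "svm_predict",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class PCAModel:
    """Training-set mean, orthonormal loadings, explained-variance ratios."""

    mean: np.ndarray                      # (n_channels,)
    loadings: np.ndarray                  # (n_components, n_channels), orthonormal rows
    explained_variance_ratio: np.ndarray  # (n_components,)

    @property
    def n_components(self) -> int:
        return int(self.loadings.shape[0])

    @property
    def n_channels(self) -> int:
        return int(self.loadings.shape[1])


@dataclass(frozen=True)
class LinearClassifierModel:
    """One-vs-one linear classifier: pairwise hyperplanes plus a vote rule.

    ``pair_weights[p]`` / ``pair_biases[p]`` define the decision value
    ``f = w . x + b`` for the p-th class pair ``pairs[p] = (i, j)`` (pairs
    enumerated as (0,1), (0,2), ..., (1,2), ... over ``class_labels``
    indices); ``f > 0`` votes for class ``i``, otherwise for ``j``.
    """

    class_labels: tuple[str, ...]
    pair_weights: np.ndarray  # (n_pairs, n_features)
    pair_biases: np.ndarray   # (n_pairs,)
    cost_C: float

    @property
    def pairs(self) -> list[tuple[int, int]]:
        k = len(self.class_labels)
        return [(i, j) for i in range(k) for j in range(i + 1, k)]

    @property
    def n_features(self) -> int:
        return int(self.pair_weights.shape[1])


def pca_fit(X: np.ndarray, n_components: int) -> PCAModel:
    """Fit PCA by SVD of the column-centered data matrix.

    Loadings are the top right-singular vectors; explained-variance
    ratios come from the squared singular values. Each loading's sign is
    fixed so its largest-magnitude element is positive, making the fit
    deterministic.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("X must be a 2-D (n_samples, n_channels) matrix")
    n_samples, n_channels = X.shape
    if n_components < 1:
        raise ValidationError("n_components must be >= 1")
    if n_components > min(n_samples, n_channels):
        raise ValidationError(
            f"n_components={n_components} exceeds min(n_samples, n_channels)="
            f"{min(n_samples, n_channels)}"
        )
    mean = X.mean(axis=0)
    _, s, Vt = np.linalg.svd(X - mean, full_matrices=False)
    power = s**2
    total = power.sum()
    ratio = power / total if total > 0 else np.zeros_like(power)
    loadings = Vt[:n_components].copy()
    for row in loadings:
        imax = int(np.argmax(np.abs(row)))
        if row[imax] < 0:
            row *= -1.0
    return PCAModel(
        mean=mean,
        loadings=loadings,
        explained_variance_ratio=ratio[:n_components].copy(),
    )


def pca_project(model: PCAModel, X: np.ndarray) -> np.ndarray:
    """Project spectra onto the model's loadings: ``(X - mean) @ loadings.T``.

    The *model's* training mean is subtracted, never the projected set's
    own mean — held-out batches are scored in the training frame.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_channels:
        raise ValidationError(
            f"channel mismatch: model has {model.n_channels}, data has {X.shape[1]}"
        )
    return (X - model.mean) @ model.loadings.T


def svm_train(
    scores: np.ndarray, labels, cost_C: float = 1.0
) -> LinearClassifierModel:
    """Train a one-vs-one soft-margin linear SVM on PC scores.

    ``class_labels`` is the sorted set of distinct labels; for fixed input
    this is deterministic. The pairwise hyperplanes are extracted from the
    fitted solver so prediction needs only this object.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.array([str(v) for v in labels], dtype=object)
    if scores.ndim != 2 or scores.shape[0] != y.size:
        raise ValidationError("scores must be (n_samples, n_features) matching labels")
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValidationError(
            f"need at least two classes to train a classifier, got {classes}"
        )
    if not cost_C > 0:
        raise ValidationError("cost_C must be > 0")
    # tight stopping tolerance: fitted hyperplanes are part of persisted
    # models and must be reproducible to well below the margin scale
    clf = SVC(kernel="linear", C=cost_C, decision_function_shape="ovo", tol=1e-6)
    clf.fit(scores, y)
    # For a linear one-vs-one SVC, coef_/intercept_ hold one hyperplane per
    # class pair in (0,1), (0,2), ..., (1,2), ... order over clf.classes_.
    # With >= 3 classes a positive decision value votes for the first class
    # of the pair; the two-class special case uses the opposite sign, so
    # flip it to keep one convention in LinearClassifierModel.
    weights = np.asarray(clf.coef_, dtype=float)
    biases = np.asarray(clf.intercept_, dtype=float)
    if len(classes) == 2:
        weights, biases = -weights, -biases
    return LinearClassifierModel(
        class_labels=tuple(str(c) for c in clf.classes_),
        pair_weights=weights,
        pair_biases=biases,
        cost_C=float(cost_C),
    )


def svm_predict(model: LinearClassifierModel, scores: np.ndarray) -> np.ndarray:
    """Predict one label per row by pairwise voting.

    For each class pair (i, j), a positive decision value votes for i,
    otherwise for j. The class with most votes wins; exact vote ties go to
    the earliest label in ``class_labels`` order (``argmax`` of the vote
    vector).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[None, :]
    if scores.shape[1] != model.n_features:
        raise ValidationError(
            f"feature mismatch: model expects {model.n_features}, "
            f"got {scores.shape[1]}"
        )
    n = scores.shape[0]
    k = len(model.class_labels)
    votes = np.zeros((n, k), dtype=np.int64)
    decisions = scores @ model.pair_weights.T + model.pair_biases
    for p, (i, j) in enumerate(model.pairs):
        positive = decisions[:, p] > 0
        votes[positive, i] += 1
        votes[~positive, j] += 1
    winners = np.argmax(votes, axis=1)  # first max = earliest label on ties
    labels = np.array(model.class_labels, dtype=object)
    return labels[winners]


# ---------------------------------------------------------------------------
# plain-text model persistence
# ---------------------------------------------------------------------------

def _write_block(lines: list[str], name: str, M: np.ndarray) -> None:
    M = np.atleast_2d(np.asarray(M, dtype=float))
    lines.append(f"@{name} {M.shape[0]} {M.shape[1]}")
    for row in M:
        lines.append(" ".join("%.12g" % v for v in row))


def save_model(model: PCAModel | LinearClassifierModel, path: str | Path) -> None:
    """Persist a model as plain text (key=value lines + @matrix blocks)."""
    lines: list[str] = []
    if isinstance(model, PCAModel):
        lines.append("kind=pca")
        _write_block(lines, "mean", model.mean)
        _write_block(lines, "loadings", model.loadings)
        _write_block(lines, "explained_variance_ratio", model.explained_variance_ratio)
    elif isinstance(model, LinearClassifierModel):
        lines.append("kind=linear_ovo_svm")
        lines.append("class_labels=" + "\t".join(model.class_labels))
        lines.append(f"cost_C={model.cost_C!r}")
        _write_block(lines, "pair_weights", model.pair_weights)
        _write_block(lines, "pair_biases", model.pair_biases)
    else:
        raise ValidationError(f"cannot persist object of type {type(model).__name__}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_model(path: str | Path) -> PCAModel | LinearClassifierModel:
    """Load a model previously written by :func:`save_model`."""
    text = Path(path).read_text(encoding="utf-8").splitlines()
    fields: dict[str, str] = {}
    blocks: dict[str, np.ndarray] = {}
    i = 0
    while i < len(text):
        line = text[i].strip()
        if line.startswith("@"):
            name, r, c = line[1:].split()
            r, c = int(r), int(c)
            rows = [
                [float(tok) for tok in text[i + 1 + k].split()] for k in range(r)
            ]
            blocks[name] = np.array(rows).reshape(r, c)
            i += 1 + r
        else:
            if "=" in line:
                key, _, value = line.partition("=")
                fields[key] = value
            i += 1
    kind = fields.get("kind")
    if kind == "pca":
        return PCAModel(
            mean=blocks["mean"].ravel(),
            loadings=blocks["loadings"],
            explained_variance_ratio=blocks["explained_variance_ratio"].ravel(),
        )
    if kind == "linear_ovo_svm":
        return LinearClassifierModel(
            class_labels=tuple(fields["class_labels"].split("\t")),
            pair_weights=blocks["pair_weights"],
            pair_biases=blocks["pair_biases"].ravel(),
            cost_C=float(fields["cost_C"]),
        )
    raise ValidationError(f"unrecognized model kind {kind!r} in {path}")
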