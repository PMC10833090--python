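"""Sentiment classifiers and evaluation: multinomial naive Bayes, sparse
logistic regression, and multiclass confusion-matrix metrics.

The logistic model is the binary sigmoid form P(y=1|x) = 1/(1 + e^{-(w.x+b)})
with an optional augmented parameterization (w^(1)..w^(m), b); it is trained
by minimizing the L2-regularized negative log-likelihood with a deterministic
quasi-Newton method starting from zero, operating directly on sparse feature
matrices.  The naive Bayes classifier is the standard multinomial model with
additive smoothing; its posterior is the retrained sentiment score s-hat in
[0, 1] (closer to 1 means positive).  Metrics follow the usual definitions:
precision TP/(TP+FP), recall TP/(TP+FN), F1 their harmonic mean, accuracy,
and macro / support-weighted averages; zero-denominator metrics are reported
as 0 and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import minimize

from .features import DocTermMatrix, Vocabulary

__all__ = [
    "NaiveBayesModel",
    "LogisticModel",
    "ConfusionMatrix",
    "MetricsReport",
    "train_nb",
    "predict_nb",
    "train_lr",
    "predict_lr",
    "train_lr_multiclass",
    "predict_lr_multiclass",
    "evaluate",
    "train_test_split_stratified",
]


@dataclass
class NaiveBayesModel:
    classes: list
    log_priors: np.ndarray  # (C,)
    log_likelihoods: np.ndarray  # (C, M) log word probabilities per class
    vocabulary: Vocabulary
    smoothing: float

    def __post_init__(self) -> None:
        if abs(np.exp(self.log_priors).sum() - 1.0) > 1e-9:
            raise ValueError("priors do not sum to 1")


def _as_matrix(matrix: DocTermMatrix | sp.spmatrix) -> sp.csr_matrix:
    if isinstance(matrix, DocTermMatrix):
        return matrix.matrix
    return sp.csr_matrix(matrix)


def train_nb(
    matrix: DocTermMatrix,
    labels: Sequence,
    smoothing: float = 1.0,
) -> NaiveBayesModel:
    """Multinomial naive Bayes with additive smoothing on feature counts."""
    X = _as_matrix(matrix)
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise ValueError("label count does not match matrix rows")
    classes = sorted(set(y.tolist()))
    if any((y == c).sum() == 0 for c in classes):
        raise ValueError("every class must appear in the training data")
    M = X.shape[1]
    log_priors = np.empty(len(classes))
    log_lik = np.empty((len(classes), M))
    for ci, c in enumerate(classes):
        mask = y == c
        log_priors[ci] = np.log(mask.sum() / len(y))
        counts = np.asarray(X[mask].sum(axis=0)).ravel()
        probs = (counts + smoothing) / (counts.sum() + smoothing * M)
        log_lik[ci] = np.log(probs)
    vocab = matrix.vocabulary if isinstance(matrix, DocTermMatrix) else None
    return NaiveBayesModel(
        classes=classes,
        log_priors=log_priors,
        log_likelihoods=log_lik,
        vocabulary=vocab,
        smoothing=smoothing,
    )


def predict_nb_posterior(
    model: NaiveBayesModel, tokens_or_row: Sequence[str] | np.ndarray | sp.spmatrix
) -> np.ndarray:
    """Posterior over classes for one document (tokens or a feature row)."""
    if isinstance(tokens_or_row, (np.ndarray, sp.spmatrix)):
        counts = np.asarray(
            tokens_or_row.todense() if sp.issparse(tokens_or_row) else tokens_or_row
        ).ravel()
    else:
        counts = np.zeros(len(model.vocabulary))
        idx = model.vocabulary.index
        for t in tokens_or_row:
            j = idx.get(t)
            if j is not None:  # out-of-vocabulary tokens ignored
                counts[j] += 1
    logp = model.log_priors + model.log_likelihoods @ counts
    logp -= logp.max()
    p = np.exp(logp)
    return p / p.sum()


def predict_nb(
    model: NaiveBayesModel, tokens: Sequence[str], positive_class=1
) -> float:
    """s-hat: posterior probability of the positive class, in [0, 1]."""
    post = predict_nb_posterior(model, tokens)
    if positive_class not in model.classes:
        # single-class model: probability 1 if that class is the positive one
        return 0.0
    return float(post[model.classes.index(positive_class)])


@dataclass
class LogisticModel:
    weights: np.ndarray  # (M,)
    bias: float
    n_iter: int
    final_objective: float
    converged: bool

    @property
    def augmented(self) -> np.ndarray:
        """(w^(1), ..., w^(m), b)^T."""
        return np.concatenate([self.weights, [self.bias]])


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def train_lr(
    matrix: DocTermMatrix | sp.spmatrix,
    labels: Sequence[int],
    l2: float = 1e-4,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> LogisticModel:
    """Sparse logistic regression by deterministic L-BFGS from zero init.

    Minimizes mean negative log-likelihood + (l2/2)||w||^2 (bias
    unpenalized).  The feature matrix stays sparse throughout; only the
    parameter vector is dense.
    """
    X = _as_matrix(matrix)
    y = np.asarray(labels, dtype=np.float64)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    n, m = X.shape

    def objective(params: np.ndarray):
        w, b = params[:m], params[m]
        z = X @ w + b
        # log(1+exp(z)) - y z, numerically stable
        nll = np.mean(np.logaddexp(0.0, z) - y * z)
        obj = nll + 0.5 * l2 * w @ w
        p = _sigmoid(z)
        resid = (p - y) / n
        grad_w = X.T @ resid + l2 * w
        grad_b = resid.sum()
        return obj, np.concatenate([grad_w, [grad_b]])

    x0 = np.zeros(m + 1)
    res = minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": tol, "ftol": 1e-14},
    )
    grad_norm = float(np.max(np.abs(res.jac)))
    if not res.success and grad_norm > tol * 10:
        warnings.warn(
            f"logistic regression did not converge: gradient norm {grad_norm:.2e}",
            stacklevel=2,
        )
    return LogisticModel(
        weights=res.x[:m],
        bias=float(res.x[m]),
        n_iter=int(res.nit),
        final_objective=float(res.fun),
        converged=bool(res.success),
    )


def predict_lr(model: LogisticModel, matrix: DocTermMatrix | sp.spmatrix) -> np.ndarray:
    """Sigmoid of the augmented inner product, elementwise over rows."""
    X = _as_matrix(matrix)
    if X.shape[1] != model.weights.shape[0]:
        raise ValueError(
            f"feature count {X.shape[1]} does not match model ({model.weights.shape[0]})"
        )
    return _sigmoid(np.asarray(X @ model.weights).ravel() + model.bias)


def train_lr_multiclass(
    matrix: DocTermMatrix | sp.spmatrix, labels: Sequence, **lr_kwargs
) -> dict:
    """One-vs-rest logistic regression over an arbitrary label set."""
    y = np.asarray(labels)
    classes = sorted(set(y.tolist()))
    models = {}
    for c in classes:
        models[c] = train_lr(matrix, (y == c).astype(int), **lr_kwargs)
    return models


def predict_lr_multiclass(models: dict, matrix: DocTermMatrix | sp.spmatrix) -> np.ndarray:
    classes = sorted(models)
    probs = np.column_stack([predict_lr(models[c], matrix) for c in classes])
    winners = np.argmax(probs, axis=1)
    return np.asarray([classes[i] for i in winners])


@dataclass
class ConfusionMatrix:
    """Square count matrix, rows = true label, columns = predicted."""

    counts: np.ndarray
    labels: list

    def __post_init__(self) -> None:
        if self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("negative counts")


@dataclass
class MetricsReport:
    labels: list
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    zero_division_flags: list = field(default_factory=list)


def evaluate(
    truth: Sequence, predicted: Sequence, label_order: Sequence | None = None
) -> tuple[ConfusionMatrix, MetricsReport]:
    """Confusion matrix plus per-class and averaged metrics.

    Zero-denominator precision/recall are reported as 0 and the affected
    (label, metric) pairs listed in ``zero_division_flags``.
    """
    t = list(truth)
    p = list(predicted)
    if len(t) != len(p):
        raise ValueError("truth and predicted must have equal length")
    labels = list(label_order) if label_order is not None else sorted(set(t) | set(p))
    index = {l: i for i, l in enumerate(labels)}
    for v in t + p:
        if v not in index:
            raise ValueError(f"label {v!r} not in label_order")

    C = len(labels)
    counts = np.zeros((C, C), dtype=np.int64)
    for ti, pi in zip(t, p):
        counts[index[ti], index[pi]] += 1

    tp = np.diag(counts).astype(float)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    support = counts.sum(axis=1)

    flags = []
    precision = np.zeros(C)
    recall = np.zeros(C)
    f1 = np.zeros(C)
    for i, lab in enumerate(labels):
        if tp[i] + fp[i] > 0:
            precision[i] = tp[i] / (tp[i] + fp[i])
        else:
            flags.append((lab, "precision"))
        if tp[i] + fn[i] > 0:
            recall[i] = tp[i] / (tp[i] + fn[i])
        else:
            flags.append((lab, "recall"))
        if precision[i] + recall[i] > 0:
            f1[i] = 2 * precision[i] * recall[i] / (precision[i] + recall[i])
        else:
            flags.append((lab, "f1"))

    total = counts.sum()
    accuracy = float(tp.sum() / total) if total else 0.0
    wts = support / total if total else np.zeros(C)
    report = MetricsReport(
        labels=labels,
        precision=precision,
        recall=recall,
        f1=f1,
        support=support,
        accuracy=accuracy,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        weighted_precision=float(precision @ wts),
        weighted_recall=float(recall @ wts),
        weighted_f1=float(f1 @ wts),
        zero_division_flags=flags,
    )
    return ConfusionMatrix(counts=counts, labels=labels), report


def train_test_split_stratified(
    n: int, labels: Sequence, test_fraction: float = 0.3, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified index split with a recorded seed; returns (train, test)."""
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for c in sorted(set(y.tolist())):
        idx = np.flatnonzero(y == c)
        idx = idx[rng.permutation(len(idx))]
        k = int(round(test_fraction * len(idx)))
        test_idx.extend(idx[:k].tolist())
    test = np.asarray(sorted(test_idx), dtype=int)
    train = np.asarray(sorted(set(range(n)) - set(test_idx)), dtype=int)
    return train, test
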