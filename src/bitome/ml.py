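"""Gene-level classification workflow.

Pipeline: collapse each gene's bitome sub-matrix into a feature vector
(sum of bits per row, or mean for per-bp rates), min/max-normalize,
hold out a stratified lockbox test set, balance the training classes by
downsampling the majority class (or class-weighted losses), run repeated
stratified cross-validation with a shuffled-label negative control and a
sequence-only baseline, then train a final L1-regularized linear SVM and
read feature importances off its coefficients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import LinearSVC

from .types import RowKey


@dataclass
class GeneFeatureMatrix:
    """Genes x row-keys matrix of collapsed bits with binary labels."""

    gene_ids: list[str]
    feature_keys: list[RowKey]
    values: np.ndarray
    labels: np.ndarray | None = None
    collapse: str = "sum"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.feature_keys)):
            raise ValueError("matrix dimensions disagree with ids/keys")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if set(np.unique(self.labels)) - {0, 1}:
                raise ValueError("labels must be binary")

    def subset_genes(self, indices):
        return GeneFeatureMatrix(
            gene_ids=[self.gene_ids[i] for i in indices],
            feature_keys=self.feature_keys,
            values=self.values[indices],
            labels=None if self.labels is None else self.labels[indices],
            collapse=self.collapse,
        )

    def subset_features(self, predicate):
        idx = [i for i, k in enumerate(self.feature_keys) if predicate(k)]
        return GeneFeatureMatrix(
            gene_ids=self.gene_ids,
            feature_keys=[self.feature_keys[i] for i in idx],
            values=self.values[:, idx],
            labels=self.labels,
            collapse=self.collapse,
        )


@dataclass
class EvaluationReport:
    accuracies: list[float]
    mean_accuracy: float
    sd_accuracy: float
    confusion: np.ndarray  # rows = true class, normalized to row sums
    auc: float | None
    seeds: list[int]

    def to_dict(self):
        return {
            "accuracies": self.accuracies,
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "confusion": self.confusion.tolist(),
            "auc": self.auc,
            "seeds": self.seeds,
        }


@dataclass
class ModelSpec:
    """Declarative model choice resolved to a sklearn estimator.

    The mandatory members are the L1 linear SVM (the final model: hinge
    loss in the primal, ``penalty='l1'``, ``dual=False``, ``C=0.1``) and
    logistic regression; other sklearn-compatible classifiers can be
    plugged in via ``builder``.
    """

    name: str = "linear_svm"
    params: dict = field(default_factory=dict)
    builder: object = None

    def build(self, seed=None, class_weight=None):
        params = dict(self.params)
        if class_weight is not None:
            params.setdefault("class_weight", class_weight)
        if self.builder is not None:
            return self.builder(random_state=seed, **params)
        if self.name == "linear_svm":
            params.setdefault("penalty", "l1")
            params.setdefault("dual", False)
            params.setdefault("C", 0.1)
            params.setdefault("max_iter", 5000)
            return LinearSVC(random_state=seed, **params)
        if self.name == "logistic":
            params.setdefault("max_iter", 2000)
            return LogisticRegression(random_state=seed, **params)
        raise ValueError(f"unknown model spec {self.name!r}")


def gene_feature_vectors(bitome, genes, collapse="sum", labels=None):
    """Collapse each gene's bitome region into a feature vector.

    ``collapse='sum'`` totals bits per row over the gene span;
    ``'mean'`` divides by gene length, giving per-bp rates.
    """
    if collapse not in ("sum", "mean"):
        raise ValueError("collapse must be 'sum' or 'mean'")
    mat = bitome.matrix.tocsc()
    rows = []
    for gene in genes:
        if gene.end <= gene.start:
            raise ValueError(f"zero-length gene {gene.id}")
        sub = mat[:, gene.start : gene.end]
        vec = np.asarray(sub.sum(axis=1)).ravel().astype(float)
        if collapse == "mean":
            vec = vec / (gene.end - gene.start)
        rows.append(vec)
    return GeneFeatureMatrix(
        gene_ids=[g.id for g in genes],
        feature_keys=list(bitome.row_keys),
        values=np.vstack(rows) if rows else np.empty((0, len(bitome.row_keys))),
        labels=labels,
        collapse=collapse,
    )


def label_from_snps(genes, snps):
    """1 for genes whose span contains at least one SNP, else 0."""
    positions = np.array(sorted({s.position for s in snps}), dtype=np.int64)
    labels = np.zeros(len(genes), dtype=int)
    for i, gene in enumerate(genes):
        lo = np.searchsorted(positions, gene.start, side="left")
        hi = np.searchsorted(positions, gene.end, side="left")
        labels[i] = 1 if hi > lo else 0
    return labels


def minmax_normalize(values):
    """Per-column (x - min) / (max - min); constant columns map to 0."""
    values = np.asarray(values, dtype=float)
    mins = values.min(axis=0)
    span = values.max(axis=0) - mins
    out = values - mins
    nonconst = span > 0
    out[:, nonconst] /= span[nonconst]
    out[:, ~nonconst] = 0.0
    return out


def lockbox_split(matrix: GeneFeatureMatrix, fraction=0.20, seed=0):
    """Stratified holdout of ``fraction`` of the genes as a lockbox set."""
    if matrix.labels is None:
        raise ValueError("labels required for a stratified split")
    counts = np.bincount(matrix.labels, minlength=2)
    if (counts < 2).any():
        raise ValueError("each class needs at least 2 members to stratify")
    idx = np.arange(len(matrix.gene_ids))
    train_idx, lock_idx = train_test_split(
        idx, test_size=fraction, stratify=matrix.labels, random_state=seed
    )
    return matrix.subset_genes(np.sort(train_idx)), matrix.subset_genes(np.sort(lock_idx))


def downsample_majority(matrix: GeneFeatureMatrix, seed=0):
    """Subsample the majority class (without replacement) to minority size."""
    rng = np.random.default_rng(seed)
    labels = matrix.labels
    counts = np.bincount(labels, minlength=2)
    minority = int(np.argmin(counts))
    majority = 1 - minority
    if counts[0] == counts[1]:
        return matrix
    keep_minor = np.flatnonzero(labels == minority)
    major_idx = np.flatnonzero(labels == majority)
    keep_major = rng.choice(major_idx, size=counts[minority], replace=False)
    keep = np.sort(np.concatenate([keep_minor, keep_major]))
    return matrix.subset_genes(keep)


def _expand_seeds(seed, n):
    return [int(s) for s in
            np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)]


def cv_evaluate(model_spec: ModelSpec, train: GeneFeatureMatrix, k=5,
                n_downsamples=5, seed=0, normalize=True,
                downsample=True, class_weight=None) -> EvaluationReport:
    """k-fold cross-validation over ``n_downsamples`` rebalanced training
    sets; reports accuracy mean +- sd over all folds x resamples and the
    pooled row-normalized confusion matrix."""
    seeds = _expand_seeds(seed, n_downsamples)
    accuracies = []
    conf = np.zeros((2, 2), dtype=float)
    for ds_seed in seeds:
        data = downsample_majority(train, seed=ds_seed) if downsample else train
        X = minmax_normalize(data.values) if normalize else data.values
        y = data.labels
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=ds_seed % (2**31))
        for fold_train, fold_test in skf.split(X, y):
            model = model_spec.build(seed=ds_seed % (2**31))
            if class_weight is not None:
                model.set_params(class_weight=class_weight)
            model.fit(X[fold_train], y[fold_train])
            pred = model.predict(X[fold_test])
            accuracies.append(float((pred == y[fold_test]).mean()))
            conf += confusion_matrix(y[fold_test], pred, labels=[0, 1])
    row_sums = conf.sum(axis=1, keepdims=True)
    row_sums[row_sums == 0] = 1
    return EvaluationReport(
        accuracies=accuracies,
        mean_accuracy=float(np.mean(accuracies)),
        sd_accuracy=float(np.std(accuracies)),
        confusion=conf / row_sums,
        auc=None,
        seeds=seeds,
    )


def shuffled_label_control(model_spec, train, k=5, n_downsamples=5, seed=0,
                           **kwargs) -> EvaluationReport:
    """Negative control: permute labels, then run the same CV. On balanced
    data the expected accuracy is 0.5 (guessing)."""
    rng = np.random.default_rng(seed)
    shuffled = GeneFeatureMatrix(
        gene_ids=train.gene_ids,
        feature_keys=train.feature_keys,
        values=train.values,
        labels=rng.permutation(train.labels),
        collapse=train.collapse,
    )
    return cv_evaluate(model_spec, shuffled, k=k, n_downsamples=n_downsamples,
                       seed=seed, **kwargs)


def sequence_only_baseline(model_spec, train, **kwargs) -> EvaluationReport:
    """CV restricted to the nucleobase rows only (raw-sequence baseline)."""
    seq_only = train.subset_features(lambda k: k.category == "nucleobase")
    return cv_evaluate(model_spec, seq_only, **kwargs)


def train_final_model(train: GeneFeatureMatrix, model_spec=None, seed=0,
                      normalize=True, class_weight=None):
    """Fit the final linear model on the (balanced or weighted) training
    set; returns the fitted estimator. Convergence problems surface as
    sklearn warnings and via ``model.n_iter_``."""
    model_spec = model_spec or ModelSpec()
    X = minmax_normalize(train.values) if normalize else train.values
    model = model_spec.build(seed=seed, class_weight=class_weight)
    model.fit(X, train.labels)
    return model


def evaluate_lockbox(model, lockbox: GeneFeatureMatrix, normalize=True) -> EvaluationReport:
    """Accuracy, row-normalized confusion matrix and (where the model
    exposes decision values) AUC on the held-out lockbox set."""
    X = minmax_normalize(lockbox.values) if normalize else lockbox.values
    y = lockbox.labels
    pred = model.predict(X)
    conf = confusion_matrix(y, pred, labels=[0, 1]).astype(float)
    row_sums = conf.sum(axis=1, keepdims=True)
    row_sums[row_sums == 0] = 1
    auc = None
    if len(np.unique(y)) == 2:
        if hasattr(model, "decision_function"):
            auc = float(roc_auc_score(y, model.decision_function(X)))
        elif hasattr(model, "predict_proba"):
            auc = float(roc_auc_score(y, model.predict_proba(X)[:, 1]))
    acc = float((pred == y).mean())
    return EvaluationReport(
        accuracies=[acc], mean_accuracy=acc, sd_accuracy=0.0,
        confusion=conf / row_sums, auc=auc, seeds=[],
    )


def feature_importance(model, feature_keys):
    """Nonzero coefficients ranked by magnitude, sign retained (positive
    predicts class 1)."""
    coef = np.asarray(model.coef_).ravel()
    order = np.argsort(-np.abs(coef))
    return [(feature_keys[i], float(coef[i])) for i in order if coef[i] != 0]


def save_model(model, feature_keys, path):
    """Persist a linear model as JSON (coefficients + intercept + keys)."""
    payload = {
        "coef": np.asarray(model.coef_).ravel().tolist(),
        "intercept": float(np.asarray(model.intercept_).ravel()[0]),
        "feature_keys": [str(k) for k in feature_keys],
        "model": type(model).__name__,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path):
    with open(path) as fh:
        payload = json.load(fh)
    return payload


def random_search(model_specs, train, n_iter=10, k=5, seed=0, **kwargs):
    """Thin randomized search: sample specs from a list of candidate
    ModelSpecs (each already carrying a parameter draw) and rank by mean
    CV accuracy. Returns (best_spec, results)."""
    rng = np.random.default_rng(seed)
    results = []
    specs = list(model_specs)
    picks = rng.integers(0, len(specs), size=min(n_iter, len(specs) * 3))
    seen = set()
    for p in picks:
        if p in seen:
            continue
        seen.add(p)
        spec = specs[p]
        report = cv_evaluate(spec, train, k=k, seed=int(rng.integers(2**31)), **kwargs)
        results.append((spec, report.mean_accuracy))
    results.sort(key=lambda t: -t[1])
    return results[0][0], results
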