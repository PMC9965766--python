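"""Pairwise Random-Forest classification with balanced resampling.

The evaluation scheme mirrors a standard unbalanced-cohort protocol: for
each of k resamplings, 85% of each group is drawn (stratified, without
replacement) as the training set and the held-out 15% is scored; metric
means and percentile 95% CIs are taken across the k resamplings; model
significance comes from a label-permutation test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from .data_io import AbundanceMatrix, GroupPair
from .univariate import benjamini_hochberg

__all__ = [
    "ResamplingScheme",
    "MetricSummary",
    "ClassificationResult",
    "PermutationTestResult",
    "rf_classify",
    "permutation_test",
    "importance_significance",
]

METRICS = ("accuracy", "sensitivity", "specificity", "auroc")


@dataclass(frozen=True)
class ResamplingScheme:
    """k resamplings retaining ``train_fraction`` of each group for training."""

    k: int = 100
    train_fraction: float = 0.85
    seed: int = 0
    n_trees: int = 500

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class MetricSummary:
    mean: float
    ci95: tuple[float, float]
    per_resampling: np.ndarray

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        assert lo <= self.mean <= hi


@dataclass
class ClassificationResult:
    pair: GroupPair
    accuracy: MetricSummary  # percentages
    sensitivity: MetricSummary
    specificity: MetricSummary
    auroc: MetricSummary  # fraction in [0, 1]
    variable_importance: "np.ndarray"
    metabolite_names: list[str]
    scheme: ResamplingScheme

    def metric(self, name: str) -> MetricSummary:
        return getattr(self, name)


@dataclass
class PermutationTestResult:
    p_values: dict[str, float]
    observed: dict[str, float]
    n_perm: int

    @property
    def p_value(self) -> float:
        """Headline p-value (mean accuracy statistic)."""
        return self.p_values["accuracy"]


def _confusion_metrics(y_true: np.ndarray, y_pred: np.ndarray, scores: np.ndarray) -> dict:
    """Case group coded as 1.  Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP)."""
    tp = np.sum((y_true == 1) & (y_pred == 1))
    tn = np.sum((y_true == 0) & (y_pred == 0))
    fp = np.sum((y_true == 0) & (y_pred == 1))
    fn = np.sum((y_true == 1) & (y_pred == 0))
    return {
        "accuracy": (tp + tn) / y_true.size,
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "auroc": roc_auc_score(y_true, scores),
    }


def _pair_arrays(data: AbundanceMatrix, pair: GroupPair) -> tuple[np.ndarray, np.ndarray]:
    pair.validate_in(data)
    a = data.group_values(pair.group_a)
    b = data.group_values(pair.group_b)
    x = np.vstack([a, b])
    y = np.concatenate([np.ones(a.shape[0], dtype=int), np.zeros(b.shape[0], dtype=int)])
    return x, y


def _resampled_metrics(
    x: np.ndarray,
    y: np.ndarray,
    k: int,
    train_fraction: float,
    n_trees: int,
    seed_seq: np.random.SeedSequence,
    collect_importance: bool = False,
):
    """Run k stratified holdout resamplings; return per-resampling metrics."""
    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == 0)
    per = {m: np.empty(k) for m in METRICS}
    importance = np.zeros(x.shape[1]) if collect_importance else None
    children = seed_seq.spawn(k)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        for attempt in range(10):
            tr_pos = rng.choice(idx_pos, int(np.floor(train_fraction * idx_pos.size)),
                                replace=False)
            tr_neg = rng.choice(idx_neg, int(np.floor(train_fraction * idx_neg.size)),
                                replace=False)
            train = np.concatenate([tr_pos, tr_neg])
            test = np.setdiff1d(np.arange(y.size), train)
            if len(np.unique(y[test])) == 2 and len(np.unique(y[train])) == 2:
                break
            warnings.warn(f"degenerate test fold at resampling {i}; redrawing")
        rf_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        clf = RandomForestClassifier(
            n_estimators=n_trees,
            max_features="sqrt",
            random_state=rf_seed,
            n_jobs=1,
        )
        clf.fit(x[train], y[train])
        scores = clf.predict_proba(x[test])[:, list(clf.classes_).index(1)]
        pred = clf.predict(x[test])
        m = _confusion_metrics(y[test], pred, scores)
        for name in METRICS:
            per[name][i] = m[name]
        if collect_importance:
            importance += clf.feature_importances_
    if collect_importance:
        importance /= k
    return per, importance


def _summarize(values: np.ndarray, as_percent: bool) -> MetricSummary:
    v = values * 100.0 if as_percent else values
    lo, hi = np.percentile(v, [2.5, 97.5])
    return MetricSummary(mean=float(v.mean()), ci95=(float(lo), float(hi)), per_resampling=v)


def rf_classify(
    data: AbundanceMatrix, pair: GroupPair, scheme: ResamplingScheme = ResamplingScheme()
) -> ClassificationResult:
    """Resampled Random-Forest classification of one group pair.

    The first group of the pair is the positive (case) class.  Accuracy,
    sensitivity and specificity are reported as percentages, AUROC as a
    fraction; each with the 2.5/97.5 percentile interval over the k
    resamplings.  Deterministic given ``scheme.seed``.
    """
    x, y = _pair_arrays(data, pair)
    if np.sum(y == 1) < 10 or np.sum(y == 0) < 10:
        raise ValueError("each group needs at least 10 samples for classification")
    per, importance = _resampled_metrics(
        x, y, scheme.k, scheme.train_fraction, scheme.n_trees,
        np.random.SeedSequence(scheme.seed), collect_importance=True,
    )
    return ClassificationResult(
        pair=pair,
        accuracy=_summarize(per["accuracy"], True),
        sensitivity=_summarize(per["sensitivity"], True),
        specificity=_summarize(per["specificity"], True),
        auroc=_summarize(per["auroc"], False),
        variable_importance=importance,
        metabolite_names=data.metabolite_names,
        scheme=scheme,
    )


def permutation_test(
    data: AbundanceMatrix,
    pair: GroupPair,
    scheme: ResamplingScheme = ResamplingScheme(),
    n_perm: int = 1000,
    *,
    perm_k: int = 2,
    perm_trees: int = 100,
) -> PermutationTestResult:
    """Label-permutation significance of the classification model.

    For tractability each permutation (and the observed statistic, so the
    two are exchangeable under the null) uses a reduced scheme of
    ``perm_k`` resamplings and ``perm_trees`` trees.  One permutation
    null is accumulated per metric; p = (1 + #{perm >= obs}) / (1 + n_perm).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    x, y = _pair_arrays(data, pair)
    root = np.random.SeedSequence(scheme.seed)
    obs_ss, perm_label_ss, *perm_ss = root.spawn(2 + n_perm)
    per, _ = _resampled_metrics(x, y, perm_k, scheme.train_fraction, perm_trees, obs_ss)
    observed = {m: float(per[m].mean()) for m in METRICS}
    exceed = {m: 0 for m in METRICS}
    label_rng = np.random.default_rng(perm_label_ss)
    for t in range(n_perm):
        y_perm = label_rng.permutation(y)
        per_t, _ = _resampled_metrics(
            x, y_perm, perm_k, scheme.train_fraction, perm_trees, perm_ss[t]
        )
        for m in METRICS:
            if per_t[m].mean() >= observed[m]:
                exceed[m] += 1
    p_values = {m: (1 + exceed[m]) / (1 + n_perm) for m in METRICS}
    return PermutationTestResult(p_values=p_values, observed=observed, n_perm=n_perm)


def importance_significance(
    data: AbundanceMatrix,
    pair: GroupPair,
    scheme: ResamplingScheme = ResamplingScheme(),
    n_perm: int = 100,
    *,
    perm_trees: int = 100,
) -> np.ndarray:
    """BH-adjusted permutation p-values for per-metabolite RF importance.

    The null importance of each metabolite is its Gini importance in
    forests fit to label-permuted data; p_j compares the observed mean
    importance against that null.
    """
    x, y = _pair_arrays(data, pair)
    root = np.random.SeedSequence(scheme.seed + 1)
    obs_ss, label_ss, *perm_ss = root.spawn(2 + n_perm)
    obs_seed = int(obs_ss.generate_state(1)[0] % (2**31 - 1))
    clf = RandomForestClassifier(n_estimators=scheme.n_trees, max_features="sqrt",
                                 random_state=obs_seed, n_jobs=1)
    clf.fit(x, y)
    obs_imp = clf.feature_importances_
    label_rng = np.random.default_rng(label_ss)
    exceed = np.zeros(x.shape[1])
    for t in range(n_perm):
        seed = int(perm_ss[t].generate_state(1)[0] % (2**31 - 1))
        clf = RandomForestClassifier(n_estimators=perm_trees, max_features="sqrt",
                                     random_state=seed, n_jobs=1)
        clf.fit(x, label_rng.permutation(y))
        exceed += clf.feature_importances_ >= obs_imp
    p = (1 + exceed) / (1 + n_perm)
    return benjamini_hochberg(p)
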