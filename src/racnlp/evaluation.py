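"""Metrics, cross-validated evaluation and baseline feature extractors.

Classification quality is summarised by precision, recall, F1,
specificity, AUPRC and AUROC per fold of a stratified 5-fold
cross-validation, averaged arithmetically with two-sided 95%
t-intervals across folds. Models are compared on their per-fold metric
values with a two-sided Mann–Whitney U test at α = 0.05.

AUROC is computed rank-based with midranks for ties — identically the
Mann–Whitney U statistic of the positive-class scores divided by
n₊·n₋ — and AUPRC uses the step-wise average-precision formulation,
which avoids the optimistic linear interpolation of trapezoidal PR
areas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.model_selection import StratifiedKFold

METRICS = ("precision", "recall", "f1", "specificity", "auprc", "auroc")


@dataclass
class FoldReport:
    fold_index: int
    precision: float
    recall: float
    f1: float
    specificity: float
    auprc: float
    auroc: float
    confusion: tuple[int, int, int, int]  # TP, FP, TN, FN
    undefined: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {m: getattr(self, m) for m in METRICS} | {
            "fold_index": self.fold_index, "confusion": list(self.confusion)}


@dataclass
class CVReport:
    k: int
    per_fold: list[FoldReport]
    mean: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    alpha: float = 0.05

    def as_dict(self) -> dict:
        return {"k": self.k, "per_fold": [f.as_dict() for f in self.per_fold],
                "mean": self.mean,
                "ci95": {m: list(ci) for m, ci in self.ci95.items()},
                "alpha": self.alpha}


def confusion_and_rates(labels, predictions) -> dict:
    """Confusion counts and threshold metrics with positive class = 1.

    Ratios with a zero denominator are reported as 0.0 and flagged in
    the ``undefined`` list rather than raising.
    """
    y = np.asarray(labels).astype(int)
    p = np.asarray(predictions).astype(int)
    if y.shape != p.shape:
        raise ValueError("labels and predictions differ in length")
    if y.size == 0:
        raise ValueError("need at least one sample")
    tp = int(np.sum((y == 1) & (p == 1)))
    fp = int(np.sum((y == 0) & (p == 1)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fn = int(np.sum((y == 1) & (p == 0)))
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    specificity = ratio(tn, tn + fp, "specificity")
    f1 = ratio(2 * precision * recall, precision + recall, "f1")
    return {"tp": tp, "fp": fp, "tn": tn, "fn": fn, "precision": precision,
            "recall": recall, "f1": f1, "specificity": specificity,
            "undefined": undefined}


def auroc(scores, labels) -> float:
    """Rank-based AUROC with midranks; equals U / (n₊·n₋)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC requires both classes")
    ranks = stats.rankdata(s)  # midranks for ties
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auprc(scores, labels) -> float:
    """Average precision: step-wise sum of precision at each recall
    increment, grouping tied scores at a single threshold."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("AUPRC requires at least one positive")
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    ap = 0.0
    tp = fp = 0
    i = 0
    n = y.size
    while i < n:
        j = i
        while j < n and s[j] == s[i]:
            j += 1
        tp_new = tp + int(y[i:j].sum())
        fp_new = fp + (j - i) - int(y[i:j].sum())
        if tp_new > tp:
            precision = tp_new / (tp_new + fp_new)
            ap += precision * (tp_new - tp) / n_pos
        tp, fp = tp_new, fp_new
        i = j
    return float(ap)


def fold_report(fold_index: int, labels, scores, threshold: float = 0.5) -> FoldReport:
    preds = (np.asarray(scores, dtype=float) >= threshold).astype(int)
    rates = confusion_and_rates(labels, preds)
    return FoldReport(
        fold_index=fold_index,
        precision=rates["precision"], recall=rates["recall"], f1=rates["f1"],
        specificity=rates["specificity"],
        auprc=auprc(scores, labels), auroc=auroc(scores, labels),
        confusion=(rates["tp"], rates["fp"], rates["tn"], rates["fn"]),
        undefined=rates["undefined"])


def kfold_cv(items, labels, trainer, k: int = 5, seed: int = 0,
             threshold: float = 0.5) -> CVReport:
    """Stratified k-fold evaluation of a training procedure.

    ``trainer(train_items, train_labels, fold_seed)`` must return a
    callable mapping a list of items to scores in [0, 1]. Each fold's
    held-out metrics go into a FoldReport; means and two-sided 95%
    t-intervals (df = k−1) summarise the folds.
    """
    items = list(items)
    y = np.asarray(labels).astype(int)
    if len(items) < k:
        raise ValueError("dataset smaller than k")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports: list[FoldReport] = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(items)), y), start=1):
        if len(np.unique(y[test_idx])) < 2 or len(np.unique(y[train_idx])) < 2:
            raise ValueError(f"class missing from fold {fold}; stratification failed")
        scorer = trainer([items[i] for i in train_idx], y[train_idx], seed + fold)
        scores = np.asarray(scorer([items[i] for i in test_idx]), dtype=float)
        reports.append(fold_report(fold, y[test_idx], scores, threshold))
    mean = {m: float(np.mean([getattr(r, m) for r in reports])) for m in METRICS}
    ci95 = {}
    tcrit = stats.t.ppf(0.975, df=k - 1)
    for m in METRICS:
        vals = np.array([getattr(r, m) for r in reports])
        half = tcrit * vals.std(ddof=1) / np.sqrt(k) if k > 1 else 0.0
        ci95[m] = (float(mean[m] - half), float(mean[m] + half))
    return CVReport(k=k, per_fold=reports, mean=mean, ci95=ci95)


def compare_models(metric_a, metric_b, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Two-sided Mann–Whitney U comparison of per-fold metric values.

    Exact null distribution for small tie-free samples (n ≤ 8 per
    group), normal approximation with tie correction otherwise.
    Significant iff p < alpha (strict).
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 values per sample")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue), bool(res.pvalue < alpha)


# -- baseline feature extractors ---------------------------------------

def bow_features(texts, vocabulary: dict | None = None):
    """Token-count matrix; the vocabulary is fitted on the training
    corpus only, so unseen test tokens are ignored."""
    texts = list(texts)
    if not texts:
        raise ValueError("empty corpus")
    vec = CountVectorizer(token_pattern=r"[^ ]+", lowercase=True, vocabulary=vocabulary)
    if vocabulary is None:
        mat = vec.fit_transform(texts)
    else:
        mat = vec.transform(texts)
    return mat.toarray(), vec.vocabulary_


def static_embedding_features(texts, vector_table: dict[str, np.ndarray]) -> np.ndarray:
    """Mean of in-vocabulary word vectors per text; all-OOV texts map to
    the zero vector (with a warning)."""
    if not vector_table:
        raise ValueError("empty vector table")
    dim = len(next(iter(vector_table.values())))
    texts = list(texts)
    out = np.zeros((len(texts), dim))
    n_oov = 0
    for i, text in enumerate(texts):
        vecs = [vector_table[w] for w in text.lower().split() if w in vector_table]
        if vecs:
            out[i] = np.mean(vecs, axis=0)
        else:
            n_oov += 1
    if n_oov:
        warnings.warn(f"{n_oov} text(s) contained no in-vocabulary words; mapped to zero vectors")
    return out


def random_vector_table(words, dim: int = 50, seed: int = 0) -> dict[str, np.ndarray]:
    """Random static word vectors (the default stand-in for a trained
    vector table in the static-embedding baseline)."""
    rng = np.random.default_rng(seed)
    return {w: rng.normal(0.0, 1.0, dim) for w in words}
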