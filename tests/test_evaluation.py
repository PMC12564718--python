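"""Metric oracles, cross-validation mechanics and baseline features."""

import numpy as np
import pytest
from scipy import stats

from racnlp import (auprc, auroc, bow_features, compare_models, confusion_and_rates,
                    kfold_cv, static_embedding_features)
from racnlp.evaluation import fold_report, random_vector_table


def test_confusion_hand_example():
    # TP=2, FP=1, FN=1, TN=6
    y = [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
    p = [1, 1, 0, 1, 0, 0, 0, 0, 0, 0]
    r = confusion_and_rates(y, p)
    assert (r["tp"], r["fp"], r["tn"], r["fn"]) == (2, 1, 6, 1)
    assert r["precision"] == pytest.approx(0.667, abs=5e-4)
    assert r["recall"] == pytest.approx(0.667, abs=5e-4)
    assert r["f1"] == pytest.approx(0.667, abs=5e-4)
    assert r["specificity"] == pytest.approx(0.857, abs=5e-4)


def test_perfect_and_degenerate_predictions():
    r = confusion_and_rates([1, 0, 1], [1, 0, 1])
    assert all(r[m] == 1.0 for m in ("precision", "recall", "f1", "specificity"))
    allneg = confusion_and_rates([1, 0, 1], [0, 0, 0])
    assert allneg["recall"] == 0.0
    assert allneg["precision"] == 0.0 and "precision" in allneg["undefined"]
    with pytest.raises(ValueError):
        confusion_and_rates([1, 0], [1])


def test_auroc_examples_and_mwu_identity(rng):
    assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
    assert auroc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == 0.75
    assert auroc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5
    # identity with the Mann–Whitney U statistic, with ties present
    scores = np.round(rng.uniform(0, 1, 60), 1)
    labels = rng.integers(0, 2, 60)
    labels[:3] = 1
    labels[-3:] = 0
    n_pos, n_neg = labels.sum(), (1 - labels).sum()
    u = stats.mannwhitneyu(scores[labels == 1], scores[labels == 0],
                           alternative="two-sided").statistic
    assert auroc(scores, labels) == pytest.approx(u / (n_pos * n_neg), abs=1e-12)


def test_auroc_agrees_with_sklearn(rng):
    from sklearn.metrics import roc_auc_score
    scores = rng.normal(size=80)
    labels = rng.integers(0, 2, 80)
    labels[0], labels[1] = 0, 1
    assert auroc(scores, labels) == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)
    with pytest.raises(ValueError):
        auroc([0.1, 0.2], [1, 1])


def test_auprc_examples_and_sklearn_agreement(rng):
    assert auprc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
    single = [1] + [0] * 9
    scores = np.linspace(1, 0.1, 10)
    assert auprc(scores, single) == 1.0
    from sklearn.metrics import average_precision_score
    s = rng.normal(size=100)
    y = rng.integers(0, 2, 100)
    y[0] = 1
    assert auprc(s, y) == pytest.approx(average_precision_score(y, s), abs=1e-12)
    with pytest.raises(ValueError):
        auprc([0.5, 0.6], [0, 0])


@pytest.mark.parametrize("seed", range(5))
def test_auprc_of_random_scores_approaches_prevalence(seed):
    rng = np.random.default_rng(seed)
    n, prev = 4000, 0.3
    y = (rng.uniform(size=n) < prev).astype(int)
    s = rng.uniform(size=n)
    assert auprc(s, y) == pytest.approx(y.mean(), abs=0.05)


def test_kfold_partitions_and_constant_trainer():
    items = list(range(100))
    labels = [i % 2 for i in items]
    seen = []

    def trainer(train_items, train_labels, fold_seed):
        seen.append(set(train_items))
        return lambda test_items: [0.9 if i % 2 else 0.1 for i in test_items]

    report = kfold_cv(items, labels, trainer, k=5, seed=0)
    assert report.k == 5
    test_sets = [set(items) - s for s in seen]
    assert set().union(*test_sets) == set(items)
    assert sum(len(t) for t in test_sets) == 100
    # constant perfect scorer: zero-width intervals, mean equals folds
    assert report.mean["f1"] == 1.0
    for m, (lo, hi) in report.ci95.items():
        assert lo == pytest.approx(hi, abs=1e-12)
    # fold averaging is the arithmetic mean
    f1s = [f.f1 for f in report.per_fold]
    assert report.mean["f1"] == pytest.approx(np.mean(f1s), abs=1e-12)


def test_kfold_validates_size():
    with pytest.raises(ValueError):
        kfold_cv([1, 2, 3], [0, 1, 0], lambda *a: None, k=5)


def test_compare_models_exact_small_sample():
    u, p, sig = compare_models([1, 2, 3], [4, 5, 6])
    assert u == 0.0
    assert p == pytest.approx(0.1, abs=1e-12)
    assert sig is False
    # identical samples: p = 1, not significant
    _, p2, sig2 = compare_models([0.5] * 5, [0.5] * 5)
    assert p2 == 1.0 and sig2 is False
    # two-sided symmetry
    _, pa, _ = compare_models([1, 2, 3, 7], [4, 5, 6, 8])
    _, pb, _ = compare_models([4, 5, 6, 8], [1, 2, 3, 7])
    assert pa == pytest.approx(pb, abs=1e-12)
    with pytest.raises(ValueError):
        compare_models([1, 2], [3, 4, 5])


def test_significance_threshold_is_strict():
    assert compare_models([1, 2, 3], [4, 5, 6], alpha=0.11)[2] is True
    assert compare_models([1, 2, 3], [4, 5, 6], alpha=0.1)[2] is False


def test_bow_counts_and_vocabulary_leakage():
    mat, vocab = bow_features(["a b a"])
    assert mat[0, vocab["a"]] == 2 and mat[0, vocab["b"]] == 1
    train_mat, train_vocab = bow_features(["alpha beta", "beta gamma"])
    test_mat, _ = bow_features(["delta epsilon"], vocabulary=train_vocab)
    assert test_mat.sum() == 0  # unseen tokens ignored
    assert "delta" not in train_vocab
    with pytest.raises(ValueError):
        bow_features([])


def test_static_embedding_mean_and_oov():
    table = {"a": np.array([1.0, 3.0]), "b": np.array([3.0, 5.0])}
    feats = static_embedding_features(["a", "a b"], table)
    assert np.allclose(feats[0], [1, 3])
    assert np.allclose(feats[1], [2, 4])
    with pytest.warns(UserWarning):
        feats = static_embedding_features(["zzz"], table)
    assert np.allclose(feats[0], 0)
    with pytest.raises(ValueError):
        static_embedding_features(["a"], {})


def test_random_vectors_destroy_keyword_signal(synth_cfg):
    """BOW keeps the injected keyword signal; random static vectors
    scramble it, so the linear model on BOW scores higher F1."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import train_test_split
    from racnlp import clean_text, generate_clients
    from racnlp.synthetic import all_notes

    notes = all_notes(generate_clients(synth_cfg))
    pos = [n for n in notes if n.label == 1][:80]
    neg = [n for n in notes if n.label == 0][:120]
    texts = [clean_text(n.text) for n in pos + neg]
    y = np.array([1] * len(pos) + [0] * len(neg))

    wins = {"bow": 0, "static": 0}
    for seed in range(5):
        tr, te = train_test_split(np.arange(len(y)), test_size=0.3,
                                  stratify=y, random_state=seed)
        bow_tr, vocab = bow_features([texts[i] for i in tr])
        bow_te, _ = bow_features([texts[i] for i in te], vocabulary=vocab)
        table = random_vector_table(vocab.keys(), dim=50, seed=seed)
        st_tr = static_embedding_features([texts[i] for i in tr], table)
        st_te = static_embedding_features([texts[i] for i in te], table)
        f1 = {}
        for name, (xtr, xte) in {"bow": (bow_tr, bow_te), "static": (st_tr, st_te)}.items():
            clf = LogisticRegression(max_iter=2000).fit(xtr, y[tr])
            f1[name] = fold_report(0, y[te], clf.predict_proba(xte)[:, 1]).f1
        wins["bow" if f1["bow"] >= f1["static"] else "static"] += 1
    assert wins["bow"] >= 4


def test_fold_report_f1_identity(rng):
    scores = rng.uniform(size=40)
    labels = rng.integers(0, 2, 40)
    labels[0], labels[1] = 1, 0
    rep = fold_report(1, labels, scores)
    if rep.precision + rep.recall > 0:
        expect = 2 * rep.precision * rep.recall / (rep.precision + rep.recall)
        assert rep.f1 == pytest.approx(expect, abs=1e-12)
    tp, fp, tn, fn = rep.confusion
    assert rep.specificity == pytest.approx(tn / (tn + fp), abs=1e-12)
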