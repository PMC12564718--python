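"""Malnutrition-note classifier (downstream task 1).

A binary head — dropout then a linear layer on the masked mean-pooled
last hidden state, followed by a sigmoid — fine-tuned on labelled
notes with class-weighted binary cross-entropy. 15% of the data is
held out for testing; the remainder is split 80/20 into training and
validation, and the epoch with the lowest validation loss is kept.

The training core here is shared with the malnutrition predictor,
which adds a structured risk-factor block to the head input.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from sklearn.model_selection import train_test_split

from . import autodiff as ad
from .autodiff import AdamW, Tensor, bce_with_logits
from .encoder import TransformerEncoder
from .long_encoder import SegmentedSequence, pooled_batch, segment
from .preprocess import clean_text
from .tokenizer import WordTokenizer

logger = logging.getLogger(__name__)

PROB_CLAMP = 1e-7


@dataclass
class ClassifierConfig:
    learning_rate: float = 3e-5
    batch_size: int = 16
    weight_decay: float = 0.01
    dropout: float = 0.5
    epochs: int = 4
    pos_weight: float | str = "auto"
    threshold: float = 0.5
    test_fraction: float = 0.15
    val_fraction: float = 0.2  # of the non-test portion
    freeze_encoder: bool = False
    part_len: int = 512
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        if isinstance(self.pos_weight, str):
            if self.pos_weight != "auto":
                raise ValueError("pos_weight must be numeric or 'auto'")
        elif self.pos_weight <= 0:
            raise ValueError("pos_weight must be positive")


def compute_pos_weight(labels) -> float:
    """N_negative / N_positive, the weight on the positive BCE term."""
    y = np.asarray(labels).astype(int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("pos_weight needs both classes present")
    return n_neg / n_pos


def weighted_bce(probabilities, labels, pos_weight: float) -> float:
    """Mean of −[w⁺·y·log p + (1−y)·log(1−p)].

    Probabilities exactly 0 or 1 are clamped to [1e-7, 1−1e-7] and the
    clamping is logged; with pos_weight = 1 this is plain binary
    cross-entropy.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        logger.warning("probabilities at {0,1} clamped to %.0e for the BCE computation", PROB_CLAMP)
        p = np.clip(p, PROB_CLAMP, 1.0 - PROB_CLAMP)
    return float(-(pos_weight * y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).mean())


class BinaryHead:
    """dropout → linear → sigmoid on (pooled text ‖ optional extras)."""

    def __init__(self, in_dim: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.w = Tensor(rng.normal(0.0, 0.02, (in_dim, 1)), requires_grad=True)
        self.b = Tensor(np.zeros(1), requires_grad=True)

    @property
    def params(self):
        return {"head.w": self.w, "head.b": self.b}

    def logits(self, x: Tensor) -> Tensor:
        return ad.reshape(ad.add(ad.matmul(x, self.w), self.b), (-1,))


def _snapshot(params: dict[str, Tensor]) -> dict[str, np.ndarray]:
    return {k: v.data.copy() for k, v in params.items()}


def _restore(params: dict[str, Tensor], state: dict[str, np.ndarray]) -> None:
    for k, v in params.items():
        v.data = state[k].copy()


def fit_fused_classifier(encoder: TransformerEncoder, segs: list[SegmentedSequence],
                         extras: np.ndarray | None, labels: np.ndarray,
                         val_segs, val_extras, val_labels,
                         cfg: ClassifierConfig, head: BinaryHead | None = None
                         ) -> tuple[BinaryHead, list[float]]:
    """Train the binary head (and, unless frozen, the encoder) with
    weighted BCE; returns the head and per-epoch validation losses,
    with parameters restored to the best-validation-loss epoch."""
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training split contains a single class")
    pw = compute_pos_weight(y) if cfg.pos_weight == "auto" else float(cfg.pos_weight)
    d = encoder.hidden_size
    extra_dim = 0 if extras is None else extras.shape[1]
    if head is None:
        head = BinaryHead(d + extra_dim, seed=cfg.seed + 17)
    params = dict(head.params)
    if not cfg.freeze_encoder:
        params.update(encoder.params)
    opt = AdamW(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed + 31)

    frozen_feats = None
    frozen_val = None
    if cfg.freeze_encoder:
        frozen_feats = _pooled_matrix(encoder, segs)
        frozen_val = _pooled_matrix(encoder, val_segs)

    def batch_logits(idx, train: bool):
        if cfg.freeze_encoder:
            pooled = Tensor(frozen_feats[idx])
            pooled = ad.dropout(pooled, cfg.dropout, rng, train)
        else:
            pooled = pooled_batch(encoder, [segs[i] for i in idx], train=train,
                                  dropout_p=cfg.dropout, rng=rng)
        x = pooled if extras is None else ad.concat([pooled, Tensor(extras[idx])], axis=1)
        return head.logits(x)

    def val_loss() -> float:
        probs = predict_scores(encoder, head, val_segs, val_extras, cfg,
                               precomputed=frozen_val)
        return weighted_bce(np.clip(probs, PROB_CLAMP, 1 - PROB_CLAMP), val_labels, pw)

    best_state = _snapshot(params)
    best_loss = val_loss()
    history = [best_loss]
    n = len(segs)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            loss = bce_with_logits(batch_logits(idx, train=True), y[idx], pos_weight=pw)
            opt.zero_grad()
            loss.backward()
            opt.step()
        vl = val_loss()
        history.append(vl)
        if vl < best_loss:
            best_loss = vl
            best_state = _snapshot(params)
    _restore(params, best_state)
    return head, history


def _pooled_matrix(encoder, segs, batch: int = 16) -> np.ndarray:
    rows = []
    for start in range(0, len(segs), batch):
        rows.append(pooled_batch(encoder, segs[start:start + batch]).data)
    return np.concatenate(rows)


def predict_scores(encoder, head, segs, extras, cfg, precomputed: np.ndarray | None = None
                   ) -> np.ndarray:
    pooled = _pooled_matrix(encoder, segs) if precomputed is None else precomputed
    x = pooled if extras is None else np.concatenate([pooled, extras], axis=1)
    z = x @ head.w.data[:, 0] + head.b.data[0]
    return 1.0 / (1.0 + np.exp(-z))


def _segment_texts(texts, tokenizer, part_len) -> list[SegmentedSequence]:
    segs = []
    for i, t in enumerate(texts):
        cleaned = clean_text(t)
        if not cleaned:
            raise ValueError(f"text {i} is empty after cleaning")
        ids, _ = tokenizer.encode(cleaned)
        segs.append(segment(ids, tokenizer, part_len=part_len, note_id=str(i)))
    return segs


class NoteClassifier:
    """Fitted malnutrition-note classifier."""

    def __init__(self, encoder: TransformerEncoder, tokenizer: WordTokenizer,
                 head: BinaryHead, cfg: ClassifierConfig):
        self.encoder = encoder
        self.tokenizer = tokenizer
        self.head = head
        self.cfg = cfg

    def predict_proba(self, texts) -> np.ndarray:
        segs = _segment_texts(texts, self.tokenizer, self.cfg.part_len)
        return predict_scores(self.encoder, self.head, segs, None, self.cfg)

    def predict_note(self, text: str) -> tuple[float, int]:
        """Probability and hard label (1 iff p ≥ threshold)."""
        prob = float(self.predict_proba([text])[0])
        return prob, int(prob >= self.cfg.threshold)

    # -- persistence ----------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.encoder.save(directory / "encoder")
        self.tokenizer.save(directory / "tokenizer.json")
        np.savez(directory / "head.npz", w=self.head.w.data, b=self.head.b.data)
        (directory / "classifier_config.json").write_text(json.dumps(asdict(self.cfg)))

    @classmethod
    def load(cls, directory: str | Path) -> "NoteClassifier":
        directory = Path(directory)
        encoder = TransformerEncoder.load(directory / "encoder")
        tokenizer = WordTokenizer.load(directory / "tokenizer.json")
        cfg = ClassifierConfig(**json.loads((directory / "classifier_config.json").read_text()))
        with np.load(directory / "head.npz") as z:
            head = BinaryHead(z["w"].shape[0])
            head.w.data = z["w"].copy()
            head.b.data = z["b"].copy()
        return cls(encoder, tokenizer, head, cfg)


def train_note_classifier(notes, encoder: TransformerEncoder, tokenizer: WordTokenizer,
                          cfg: ClassifierConfig) -> tuple[NoteClassifier, dict]:
    """Fine-tune the note classifier and report holdout metrics.

    ``notes`` may be Note records or (text, label) pairs. The encoder
    object is fine-tuned in place unless ``cfg.freeze_encoder``.
    """
    from .evaluation import fold_report  # local import avoids a cycle

    texts, labels = [], []
    for n in notes:
        if hasattr(n, "text"):
            texts.append(n.text)
            labels.append(int(n.label))
        else:
            texts.append(n[0])
            labels.append(int(n[1]))
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes to train")
    idx = np.arange(len(texts))
    trainval_idx, test_idx = train_test_split(
        idx, test_size=cfg.test_fraction, stratify=y, random_state=cfg.seed)
    train_idx, val_idx = train_test_split(
        trainval_idx, test_size=cfg.val_fraction, stratify=y[trainval_idx],
        random_state=cfg.seed + 1)

    segs = _segment_texts(texts, tokenizer, cfg.part_len)
    head, history = fit_fused_classifier(
        encoder,
        [segs[i] for i in train_idx], None, y[train_idx],
        [segs[i] for i in val_idx], None, y[val_idx], cfg)
    model = NoteClassifier(encoder, tokenizer, head, cfg)
    test_scores = predict_scores(encoder, head, [segs[i] for i in test_idx], None, cfg)
    report = fold_report(0, y[test_idx], test_scores, threshold=cfg.threshold).as_dict()
    report["test_scores"] = test_scores.tolist()
    report["test_labels"] = y[test_idx].tolist()
    report["val_loss_history"] = history
    report["pos_weight"] = compute_pos_weight(y[train_idx]) if cfg.pos_weight == "auto" \
        else float(cfg.pos_weight)
    return model, report
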