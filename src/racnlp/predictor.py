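"""Malnutrition prediction from 30-day pre-onset note windows
(downstream task 2).

For each client the notes recorded in the 30 days before the index
date (malnutrition onset for cases) are ordered chronologically and
concatenated; the aggregated text — typically longer than 512 tokens —
is embedded through the chunk-and-aggregate encoder. In parallel a
46-entry risk-factor catalogue is matched against the text with a
dictionary matcher plus negation detection ("no sign of cancer" does
not set the cancer bit), producing a one-hot vector that is
concatenated with the pooled embedding before a fully connected layer
and sigmoid.

The negation rule is deliberately simple and pluggable: a cue within
the five tokens preceding the matched phrase, inside the same
sentence, negates the mention.
"""

from __future__ import annotations

import csv
import datetime as dt
import json
import re
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
from sklearn.model_selection import train_test_split

from .classifier import (BinaryHead, ClassifierConfig, _segment_texts, compute_pos_weight,
                         fit_fused_classifier, predict_scores)
from .encoder import TransformerEncoder
from .long_encoder import PooledEmbedding
from .preprocess import clean_text
from .records import ClientRecord, Note
from .tokenizer import WordTokenizer

DEFAULT_NEGATION_CUES = ["no", "not", "nil", "without", "denies",
                         "no sign of", "no evidence of"]
NEGATION_SCOPE = 5  # tokens preceding the mention, within the sentence
_SENTENCE_SPLIT = re.compile(r"[.!?;]+")
_PUNCT_EDGE = re.compile(r"^[^\w%]+|[^\w%]+$")


@dataclass
class RiskFactor:
    factor_id: str
    name: str
    synonyms: list[str] = field(default_factory=list)

    @property
    def phrases(self) -> list[str]:
        return [self.name] + [s for s in self.synonyms if s]


@dataclass
class RiskFactorCatalogue:
    """Ordered risk-factor dictionary; the ordering is part of the
    model contract and is serialised with fitted predictors."""

    factors: list[RiskFactor]
    negation_cues: list[str] = field(default_factory=lambda: list(DEFAULT_NEGATION_CUES))

    def __post_init__(self):
        ids = [f.factor_id for f in self.factors]
        if len(set(ids)) != len(ids):
            raise ValueError("factor ids must be unique")

    def __len__(self) -> int:
        return len(self.factors)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RiskFactorCatalogue":
        factors = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                syns = [s.strip() for s in (row.get("synonyms") or "").split("|") if s.strip()]
                factors.append(RiskFactor(row["factor_id"].strip(), row["name"].strip(), syns))
        return cls(factors)

    @classmethod
    def default(cls) -> "RiskFactorCatalogue":
        """The bundled 46-entry catalogue of aged-care malnutrition risk
        factors (an editable fixture, not a clinical standard)."""
        ref = resources.files("racnlp") / "data" / "risk_factors.csv"
        with resources.as_file(ref) as path:
            return cls.from_csv(path)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["factor_id", "name", "synonyms"])
            for f in self.factors:
                writer.writerow([f.factor_id, f.name, "|".join(f.synonyms)])


@dataclass
class RiskFactorVector:
    bits: np.ndarray  # {0,1}, length = catalogue size

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=np.int64)


def _sentence_tokens(text: str) -> list[list[str]]:
    sentences = []
    for raw in _SENTENCE_SPLIT.split(text.lower()):
        toks = [_PUNCT_EDGE.sub("", t) for t in raw.split()]
        toks = [t for t in toks if t]
        if toks:
            sentences.append(toks)
    return sentences


def _phrase_positions(tokens: list[str], phrase_words: list[str]) -> list[int]:
    k = len(phrase_words)
    return [i for i in range(len(tokens) - k + 1) if tokens[i:i + k] == phrase_words]


def extract_risk_factors(text: str, catalogue: RiskFactorCatalogue) -> RiskFactorVector:
    """One-hot risk-factor presence with negation detection.

    A bit is 1 iff any synonym of the factor occurs at least once not
    governed by a negation cue in the preceding five tokens of the same
    sentence. Presence, not count: repeats do not change the bit.
    """
    sentences = _sentence_tokens(clean_text(text))
    cue_words = [c.split() for c in catalogue.negation_cues]
    bits = np.zeros(len(catalogue), dtype=np.int64)
    for fi, factor in enumerate(catalogue.factors):
        confirmed = False
        for phrase in factor.phrases:
            pw = phrase.lower().split()
            for toks in sentences:
                for pos in _phrase_positions(toks, pw):
                    window = toks[max(0, pos - NEGATION_SCOPE):pos]
                    negated = any(
                        window[j:j + len(cw)] == cw
                        for cw in cue_words
                        for j in range(len(window) - len(cw) + 1))
                    if not negated:
                        confirmed = True
                        break
                if confirmed:
                    break
            if confirmed:
                break
        bits[fi] = int(confirmed)
    return RiskFactorVector(bits)


@dataclass
class ClientWindow:
    client_id: str
    index_date: dt.date
    notes: list[Note]
    aggregated_text: str
    label: int
    risk_vector: RiskFactorVector | None = None


class EmptyWindowError(ValueError):
    """No notes fall inside the requested window; the client is excluded."""


def assemble_window(notes: list[Note], index_date: dt.date, window_days: int = 30,
                    label: int = 0, client_id: str | None = None,
                    catalogue: RiskFactorCatalogue | None = None) -> ClientWindow:
    """Notes in the half-open interval [index − window_days, index),
    sorted ascending, concatenated earliest-first.

    A note timestamped exactly ``index_date − window_days`` is included;
    one at ``index_date`` is excluded — "before the onset" excludes the
    onset day itself.
    """
    lo = index_date - dt.timedelta(days=window_days)
    inside = [n for n in notes if lo <= n.timestamp < index_date]
    if not inside:
        raise EmptyWindowError(
            f"client {client_id or '?'} has no notes in [{lo}, {index_date})")
    inside.sort(key=lambda n: (n.timestamp, n.order))
    text = " ".join(clean_text(n.text) for n in inside)
    risk = extract_risk_factors(text, catalogue) if catalogue is not None else None
    return ClientWindow(client_id=client_id or inside[0].client_id,
                        index_date=index_date, notes=inside,
                        aggregated_text=text, label=label, risk_vector=risk)


def build_windows(clients: list[ClientRecord], catalogue: RiskFactorCatalogue | None = None,
                  window_days: int = 30) -> list[ClientWindow]:
    """Assemble one window per client (index = onset for cases, latest
    note date for controls); clients with empty windows are skipped."""
    windows = []
    for rec in clients:
        try:
            windows.append(assemble_window(rec.sorted_notes(), rec.onset_date,
                                           window_days=window_days, label=rec.label,
                                           client_id=rec.client_id, catalogue=catalogue))
        except EmptyWindowError:
            continue
    return windows


def fuse_and_classify(pooled: PooledEmbedding, risk: RiskFactorVector,
                      head: BinaryHead) -> float:
    """sigmoid(linear(concat(pooled, risk bits))) — the fusion output."""
    x = np.concatenate([pooled.vector, risk.bits.astype(float)])
    if x.shape[0] != head.w.data.shape[0]:
        raise ValueError(f"fusion head expects width {head.w.data.shape[0]}, got {x.shape[0]}")
    z = float(x @ head.w.data[:, 0] + head.b.data[0])
    return 1.0 / (1.0 + np.exp(-z))


class MalnutritionPredictor:
    """Fitted fusion model: pooled window embedding ‖ risk bits → sigmoid."""

    def __init__(self, encoder: TransformerEncoder, tokenizer: WordTokenizer,
                 head: BinaryHead, cfg: ClassifierConfig,
                 catalogue: RiskFactorCatalogue, use_risk_factors: bool = True):
        self.encoder = encoder
        self.tokenizer = tokenizer
        self.head = head
        self.cfg = cfg
        self.catalogue = catalogue
        self.use_risk_factors = use_risk_factors

    def _features(self, windows: list[ClientWindow]):
        segs = _segment_texts([w.aggregated_text for w in windows],
                              self.tokenizer, self.cfg.part_len)
        extras = None
        if self.use_risk_factors:
            extras = np.stack([
                (w.risk_vector or extract_risk_factors(w.aggregated_text, self.catalogue)).bits
                for w in windows]).astype(float)
        return segs, extras

    def predict_proba(self, windows: list[ClientWindow]) -> np.ndarray:
        segs, extras = self._features(windows)
        return predict_scores(self.encoder, self.head, segs, extras, self.cfg)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.encoder.save(directory / "encoder")
        self.tokenizer.save(directory / "tokenizer.json")
        np.savez(directory / "head.npz", w=self.head.w.data, b=self.head.b.data)
        self.catalogue.to_csv(directory / "risk_factors.csv")
        (directory / "predictor_config.json").write_text(json.dumps(
            {"classifier": asdict(self.cfg), "use_risk_factors": self.use_risk_factors}))

    @classmethod
    def load(cls, directory: str | Path) -> "MalnutritionPredictor":
        directory = Path(directory)
        meta = json.loads((directory / "predictor_config.json").read_text())
        with np.load(directory / "head.npz") as z:
            head = BinaryHead(z["w"].shape[0])
            head.w.data = z["w"].copy()
            head.b.data = z["b"].copy()
        return cls(TransformerEncoder.load(directory / "encoder"),
                   WordTokenizer.load(directory / "tokenizer.json"),
                   head, ClassifierConfig(**meta["classifier"]),
                   RiskFactorCatalogue.from_csv(directory / "risk_factors.csv"),
                   meta["use_risk_factors"])


def train_predictor(windows: list[ClientWindow], encoder: TransformerEncoder,
                    tokenizer: WordTokenizer, cfg: ClassifierConfig,
                    use_risk_factors: bool = True,
                    catalogue: RiskFactorCatalogue | None = None
                    ) -> tuple[MalnutritionPredictor, dict]:
    """Train the fusion model on assembled windows; with
    ``use_risk_factors`` off the head sees the pooled text embedding
    only (the text-only ablation)."""
    from .evaluation import fold_report

    catalogue = catalogue or RiskFactorCatalogue.default()
    y = np.asarray([w.label for w in windows], dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes to train")
    segs = _segment_texts([w.aggregated_text for w in windows], tokenizer, cfg.part_len)
    extras = None
    if use_risk_factors:
        extras = np.stack([
            (w.risk_vector or extract_risk_factors(w.aggregated_text, catalogue)).bits
            for w in windows]).astype(float)

    idx = np.arange(len(windows))
    trainval_idx, test_idx = train_test_split(
        idx, test_size=cfg.test_fraction, stratify=y, random_state=cfg.seed)
    train_idx, val_idx = train_test_split(
        trainval_idx, test_size=cfg.val_fraction, stratify=y[trainval_idx],
        random_state=cfg.seed + 1)

    def take(arr, ii):
        return None if arr is None else arr[ii]

    head, history = fit_fused_classifier(
        encoder,
        [segs[i] for i in train_idx], take(extras, train_idx), y[train_idx],
        [segs[i] for i in val_idx], take(extras, val_idx), y[val_idx], cfg)
    model = MalnutritionPredictor(encoder, tokenizer, head, cfg, catalogue, use_risk_factors)
    scores = predict_scores(encoder, head, [segs[i] for i in test_idx],
                            take(extras, test_idx), cfg)
    report = fold_report(0, y[test_idx], scores, threshold=cfg.threshold).as_dict()
    report["test_scores"] = scores.tolist()
    report["test_labels"] = y[test_idx].tolist()
    report["val_loss_history"] = history
    report["pos_weight"] = compute_pos_weight(y[train_idx]) if cfg.pos_weight == "auto" \
        else float(cfg.pos_weight)
    return model, report
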