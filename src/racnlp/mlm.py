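"""Domain-adaptive masked-language-model pretraining.

Masking operates on whole words: 15% of the words in each row are
selected, and every subword token of a selected word is corrupted
together — 80% replaced by [MASK], 10% by a random token, 10% left in
place, decided once per word. Mask patterns are redrawn every time a
chunk is served to a batch, so no fixed corruption is memorised across
epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import AdamW, softmax_cross_entropy
from .encoder import EncoderConfig, MLMHead, TransformerEncoder, tiny_config
from .preprocess import CorpusChunk
from .tokenizer import WordTokenizer

IGNORE = -100


@dataclass
class MaskingConfig:
    mask_prob: float = 0.15
    whole_word: bool = True
    replace_mask_fraction: float = 0.8
    replace_random_fraction: float = 0.1
    keep_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.mask_prob <= 1.0:
            raise ValueError("mask_prob must be in [0, 1]")
        total = self.replace_mask_fraction + self.replace_random_fraction + self.keep_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError("corruption fractions must sum to 1")


@dataclass
class PretrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 32
    weight_decay: float = 0.01
    max_steps: int = 200
    eval_every: int = 20
    patience: int = 5
    early_stop_tol: float = 0.005  # relative improvement over the patience window
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size <= 0:
            raise ValueError("learning rate and batch size must be positive")


def whole_word_mask(token_ids: np.ndarray, word_ids: np.ndarray, config: MaskingConfig,
                    rng: np.random.Generator, tokenizer: WordTokenizer
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Corrupt a batch of token rows at the word level.

    ``word_ids`` parallels ``token_ids``; -1 marks padding/special
    positions that are never masked. Returns the corrupted batch and a
    label array holding original ids at corrupted positions, IGNORE
    elsewhere.
    """
    token_ids = np.asarray(token_ids, dtype=np.int64)
    word_ids = np.asarray(word_ids, dtype=np.int64)
    if token_ids.shape != word_ids.shape:
        raise ValueError("word-boundary map inconsistent with batch shape")
    masked = token_ids.copy()
    labels = np.full_like(token_ids, IGNORE)
    if config.mask_prob == 0.0:
        return masked, labels
    n_specials = 5  # random replacements never draw a special token
    vocab_size = tokenizer.vocab_size
    for r in range(token_ids.shape[0]):
        row_words = word_ids[r]
        uniq = np.unique(row_words[row_words >= 0])
        if uniq.size == 0:
            continue
        selected = uniq[rng.random(uniq.size) < config.mask_prob]
        for w in selected:
            pos = np.nonzero(row_words == w)[0]
            if not config.whole_word:
                pos = pos[rng.random(pos.size) < 1.0]  # token-level fallback: all tokens anyway
            labels[r, pos] = token_ids[r, pos]
            u = rng.random()
            if u < config.replace_mask_fraction:
                masked[r, pos] = tokenizer.mask_id
            elif u < config.replace_mask_fraction + config.replace_random_fraction:
                masked[r, pos] = rng.integers(n_specials, vocab_size, size=pos.size)
            # else: keep original tokens, but they still contribute to the loss
    return masked, labels


def word_mask_rate(labels: np.ndarray, word_ids: np.ndarray) -> float:
    """Fraction of words (not tokens) selected for corruption in a batch."""
    total_words = 0
    masked_words = 0
    for r in range(labels.shape[0]):
        row_words = word_ids[r]
        uniq = np.unique(row_words[row_words >= 0])
        total_words += uniq.size
        corrupted = np.unique(row_words[(labels[r] != IGNORE) & (row_words >= 0)])
        masked_words += corrupted.size
    return masked_words / total_words if total_words else 0.0


def make_epoch_batches(chunks: list[CorpusChunk], batch_size: int, mask_cfg: MaskingConfig,
                       rng: np.random.Generator, tokenizer: WordTokenizer):
    """Yield freshly masked batches for one pass over ``chunks``.

    The corruption pattern is drawn anew on every call and for every
    serve of a chunk, implementing per-batch mask re-randomisation.
    """
    if not chunks:
        raise ValueError("empty train set")
    order = rng.permutation(len(chunks))
    for start in range(0, len(order), batch_size):
        idx = order[start:start + batch_size]
        toks = np.stack([chunks[i].token_ids for i in idx])
        wids = np.stack([chunks[i].word_ids for i in idx])
        masked, labels = whole_word_mask(toks, wids, mask_cfg, rng, tokenizer)
        attn = (toks != tokenizer.pad_id).astype(np.float64)
        yield masked, labels, attn


@dataclass
class PretrainResult:
    encoder: TransformerEncoder
    head: MLMHead
    train_losses: list[float]
    val_losses: list[tuple[int, float]]  # (step, loss)
    manifest: dict = field(default_factory=dict)


def _mlm_loss(encoder: TransformerEncoder, head: MLMHead, masked, labels, attn):
    hidden = encoder.forward(masked, attn)
    B, T = labels.shape
    flat_labels = labels.reshape(-1)
    positions = np.nonzero(flat_labels != IGNORE)[0]
    if positions.size == 0:
        return None
    logits = head.logits_at(hidden, positions)
    return softmax_cross_entropy(logits, flat_labels[positions])


def evaluate_mlm(encoder, head, chunks, mask_cfg, tokenizer, seed: int, batch_size: int = 32) -> float:
    """Validation cross-entropy under a deterministic mask drawing."""
    rng = np.random.default_rng(seed)
    losses, weights = [], []
    for start in range(0, len(chunks), batch_size):
        batch = chunks[start:start + batch_size]
        toks = np.stack([c.token_ids for c in batch])
        wids = np.stack([c.word_ids for c in batch])
        masked, labels = whole_word_mask(toks, wids, mask_cfg, rng, tokenizer)
        attn = (toks != tokenizer.pad_id).astype(np.float64)
        loss = _mlm_loss(encoder, head, masked, labels, attn)
        if loss is not None:
            losses.append(float(loss.data))
            weights.append(len(batch))
    return float(np.average(losses, weights=weights)) if losses else float("nan")


def pretrain(corpus_train: list[CorpusChunk], corpus_val: list[CorpusChunk],
             pretrain_cfg: PretrainConfig, mask_cfg: MaskingConfig,
             tokenizer: WordTokenizer, encoder_config: EncoderConfig | None = None
             ) -> PretrainResult:
    """Run masked-language-model pretraining and return the adapted encoder.

    Training stops at ``max_steps`` or earlier when validation loss
    improvement over the patience window drops below the configured
    relative tolerance. Raises on a non-finite loss, reporting the step.
    """
    if not corpus_train:
        raise ValueError("empty training corpus")
    cfg = encoder_config or tiny_config(tokenizer.vocab_size)
    encoder = TransformerEncoder(cfg, seed=pretrain_cfg.seed)
    head = MLMHead(cfg, seed=pretrain_cfg.seed + 1)
    params = dict(encoder.params)
    params.update(head.params)
    opt = AdamW(params, lr=pretrain_cfg.learning_rate, weight_decay=pretrain_cfg.weight_decay)
    rng = np.random.default_rng(mask_cfg.seed)

    val_seed = pretrain_cfg.seed + 104729  # fixed stream for comparable evals
    train_losses: list[float] = []
    val_losses: list[tuple[int, float]] = []
    if corpus_val:
        val_losses.append((0, evaluate_mlm(encoder, head, corpus_val, mask_cfg, tokenizer, val_seed)))

    step = 0
    stop = False
    while not stop:
        step_at_epoch_start = step
        for masked, labels, attn in make_epoch_batches(
                corpus_train, pretrain_cfg.batch_size, mask_cfg, rng, tokenizer):
            loss = _mlm_loss(encoder, head, masked, labels, attn)
            if loss is None:
                continue
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"divergent pretraining loss at step {step}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            train_losses.append(float(loss.data))
            step += 1
            if corpus_val and step % pretrain_cfg.eval_every == 0:
                val_losses.append((step, evaluate_mlm(encoder, head, corpus_val, mask_cfg,
                                                      tokenizer, val_seed)))
                recent = [v for _, v in val_losses[-(pretrain_cfg.patience + 1):]]
                if len(recent) > pretrain_cfg.patience:
                    rel = (recent[0] - min(recent[1:])) / max(abs(recent[0]), 1e-12)
                    if rel < pretrain_cfg.early_stop_tol:
                        stop = True
                        break
            if step >= pretrain_cfg.max_steps:
                stop = True
                break
        if step == step_at_epoch_start:  # e.g. mask_prob=0 yields no loss
            break
    manifest = {"pretrain": asdict(pretrain_cfg), "masking": asdict(mask_cfg),
                "encoder": asdict(cfg), "steps_run": step}
    return PretrainResult(encoder, head, train_losses, val_losses, manifest)
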