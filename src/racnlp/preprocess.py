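"""Note cleaning and fixed-length corpus chunking for pretraining.

Raw nursing notes arrive with irregular whitespace, control characters
and assorted symbols; :func:`clean_text` reduces them to a whitelisted
character set. For masked-language-model pretraining the cleaned notes
are concatenated into a single token stream and cut into consecutive
512-token rows (:func:`chunk_corpus`), the final partial row being
padded by default.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .tokenizer import WordTokenizer

# Letters, digits and basic clinical punctuation survive cleaning.
_WHITELIST = re.compile(r"[^A-Za-z0-9 .,;:?!'\"()/%+-]")
_WS = re.compile(r"\s+")


def clean_text(raw: str) -> str:
    """Normalise a raw note: strip non-whitelisted characters and
    collapse whitespace. Total and idempotent."""
    text = _WHITELIST.sub(" ", raw)
    return _WS.sub(" ", text).strip()


@dataclass
class CorpusChunk:
    """One fixed-length row of the pretraining corpus.

    ``word_ids`` aligns each token with its source word (-1 on padding)
    so the masking collator can act at the word level; ``n_real`` counts
    unpadded tokens.
    """

    token_ids: np.ndarray
    word_ids: np.ndarray
    source_span: tuple[int, int]
    n_real: int = field(default=0)

    def __post_init__(self):
        self.token_ids = np.asarray(self.token_ids, dtype=np.int64)
        self.word_ids = np.asarray(self.word_ids, dtype=np.int64)
        if self.token_ids.shape != self.word_ids.shape:
            raise ValueError("token_ids and word_ids must be parallel")


def chunk_corpus(texts, tokenizer: WordTokenizer, chunk_len: int = 512,
                 drop_remainder: bool = False) -> list[CorpusChunk]:
    """Tokenise ``texts``, concatenate into one stream and split into
    ``chunk_len``-sized rows.

    The final partial chunk is padded to full length unless
    ``drop_remainder`` is set. Word ids are globally unique across the
    stream so a word split by a chunk boundary is never half-masked
    together with an unrelated word.
    """
    if chunk_len < 2:
        raise ValueError("chunk_len must be >= 2")
    texts = list(texts)
    if not texts or all(not t.strip() for t in texts):
        raise ValueError("empty corpus")
    stream_ids: list[int] = []
    stream_words: list[int] = []
    word_offset = 0
    for text in texts:
        ids, wids = tokenizer.encode(text)
        stream_ids.extend(ids)
        stream_words.extend(w + word_offset for w in wids)
        if wids:
            word_offset += max(wids) + 1
    total = len(stream_ids)
    if total == 0:
        raise ValueError("corpus tokenised to an empty stream")
    ids_arr = np.asarray(stream_ids, dtype=np.int64)
    words_arr = np.asarray(stream_words, dtype=np.int64)
    chunks: list[CorpusChunk] = []
    for start in range(0, total, chunk_len):
        end = min(start + chunk_len, total)
        if end - start < chunk_len and drop_remainder:
            break
        tok = np.full(chunk_len, tokenizer.pad_id, dtype=np.int64)
        wid = np.full(chunk_len, -1, dtype=np.int64)
        tok[: end - start] = ids_arr[start:end]
        wid[: end - start] = words_arr[start:end]
        chunks.append(CorpusChunk(tok, wid, (start, end), n_real=end - start))
    return chunks


def split_train_val(chunks: list[CorpusChunk], train_fraction: float = 0.8,
                    seed: int = 0) -> tuple[list[CorpusChunk], list[CorpusChunk]]:
    """Random disjoint train/validation partition, reproducible by seed."""
    if len(chunks) < 2:
        raise ValueError("need at least 2 chunks to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(chunks))
    n_train = int(round(train_fraction * len(chunks)))
    n_train = min(max(n_train, 1), len(chunks) - 1)
    train_idx = set(order[:n_train].tolist())
    train = [c for i, c in enumerate(chunks) if i in train_idx]
    val = [c for i, c in enumerate(chunks) if i not in train_idx]
    return train, val
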