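"""Chunk-and-aggregate encoding of notes longer than the 512-token limit.

A transformer encoder accepts at most ``part_len`` (512) positions, but
aggregated four-week note windows routinely exceed that. The mechanism
here splits the content tokens of a note into equal 512-position parts
— each part carrying its own start and end token, padded to full
length with an explicit attention mask — encodes every part
independently, and pools a single note embedding as

    v = (1 / n) * sum_i  m_i ⊙ e_i

where ``e_i`` are last-hidden-state token embeddings across all parts,
``m_i`` is the pooling mask (1 on content tokens, 0 on specials and
padding) and ``n`` is the tracked total number of content tokens. A
single-part note therefore reduces exactly to plain masked mean
pooling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .encoder import TransformerEncoder
from .preprocess import clean_text
from .tokenizer import WordTokenizer


@dataclass
class SegmentedSequence:
    """A tokenised note split into fixed-length parts.

    ``parts``, ``attention_masks`` and ``pooling_masks`` are parallel
    [n_parts, part_len] arrays; ``content_token_count`` is the number of
    pooling-mask-1 positions across all parts.
    """

    parts: np.ndarray
    attention_masks: np.ndarray
    pooling_masks: np.ndarray
    content_token_count: int
    note_id: str | None = None

    @property
    def n_parts(self) -> int:
        return self.parts.shape[0]


@dataclass
class PooledEmbedding:
    vector: np.ndarray
    source_note_id: str | None = None


def segment(token_ids, tokenizer: WordTokenizer, part_len: int = 512,
            note_id: str | None = None) -> SegmentedSequence:
    """Split a content-token sequence into equal ``part_len``-position parts.

    Each part reserves two positions for the start and end tokens, so
    content capacity per part is ``part_len - 2`` and the number of
    parts is ``ceil(C / (part_len - 2))`` for C content tokens. The last
    part is padded to full length; padding gets attention mask 0, and
    the pooling mask flags content tokens only.
    """
    ids = np.asarray(token_ids, dtype=np.int64).ravel()
    if ids.size == 0:
        raise ValueError("cannot segment an empty token sequence")
    if part_len < 3:
        raise ValueError("part_len must leave room for start/end tokens")
    capacity = part_len - 2
    n_parts = -(-ids.size // capacity)  # ceil division
    parts = np.full((n_parts, part_len), tokenizer.pad_id, dtype=np.int64)
    attn = np.zeros((n_parts, part_len), dtype=np.float64)
    pool = np.zeros((n_parts, part_len), dtype=np.float64)
    for p in range(n_parts):
        content = ids[p * capacity:(p + 1) * capacity]
        k = content.size
        parts[p, 0] = tokenizer.start_id
        parts[p, 1:1 + k] = content
        parts[p, 1 + k] = tokenizer.end_id
        attn[p, :k + 2] = 1.0
        pool[p, 1:1 + k] = 1.0
    return SegmentedSequence(parts, attn, pool, int(ids.size), note_id=note_id)


def _trim_len(seg_list: list[SegmentedSequence]) -> int:
    """Longest attended prefix across parts (padding-only tails can be
    dropped without changing any pooled value)."""
    longest = 1
    for seg in seg_list:
        real = int(seg.attention_masks.sum(axis=1).max())
        longest = max(longest, real)
    return longest


def pooled_embedding(encoder: TransformerEncoder, seg: SegmentedSequence) -> PooledEmbedding:
    """Encode each part independently and pool one vector for the note."""
    vec = pooled_batch(encoder, [seg]).data[0]
    return PooledEmbedding(vector=vec, source_note_id=seg.note_id)


def pooled_batch(encoder: TransformerEncoder, segs: list[SegmentedSequence],
                 train: bool = False, dropout_p: float = 0.0,
                 rng: np.random.Generator | None = None) -> Tensor:
    """Pooled embeddings for a batch of segmented notes as a graph tensor.

    All parts of all notes are stacked into one forward pass; a 0/1
    aggregation matrix then sums part-level masked sums per note before
    dividing by each note's content-token count.
    """
    if not segs:
        raise ValueError("empty batch")
    part_len = segs[0].parts.shape[1]
    if any(s.parts.shape[1] != part_len for s in segs):
        raise ValueError("all segments in a batch must share part_len")
    tlen = _trim_len(segs)
    parts = np.concatenate([s.parts[:, :tlen] for s in segs])
    attn = np.concatenate([s.attention_masks[:, :tlen] for s in segs])
    pool = np.concatenate([s.pooling_masks[:, :tlen] for s in segs])
    hidden = encoder.forward(parts, attn)  # [P, tlen, d]
    hidden = ad.dropout(hidden, dropout_p, rng, train)
    masked = ad.mul(hidden, Tensor(pool[:, :, None]))
    part_sums = ad.tsum(masked, axis=1)  # [P, d]
    agg = np.zeros((len(segs), parts.shape[0]))
    row = 0
    for i, s in enumerate(segs):
        agg[i, row:row + s.n_parts] = 1.0
        row += s.n_parts
    note_sums = ad.matmul(Tensor(agg), part_sums)  # [N, d]
    counts = np.array([[1.0 / s.content_token_count] for s in segs])
    return ad.mul(note_sums, Tensor(counts))


def encode_note(encoder: TransformerEncoder, tokenizer: WordTokenizer, text: str,
                part_len: int = 512, note_id: str | None = None) -> PooledEmbedding:
    """clean → tokenise → segment → pool, for one note."""
    cleaned = clean_text(text)
    if not cleaned:
        raise ValueError("note text is empty after cleaning")
    ids, _ = tokenizer.encode(cleaned)
    if not ids:
        raise ValueError("note tokenised to an empty sequence")
    seg = segment(ids, tokenizer, part_len=part_len, note_id=note_id)
    if encoder.config.d_model != encoder.hidden_size:  # pragma: no cover - defensive
        raise ValueError("encoder width mismatch")
    return pooled_embedding(encoder, seg)
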