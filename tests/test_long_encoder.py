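"""Segmentation law and pooled-embedding oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from racnlp import encode_note, pooled_embedding, segment
from racnlp.autodiff import Tensor
from racnlp.long_encoder import SegmentedSequence, pooled_batch


class StubEncoder:
    """Deterministic fake encoder: hidden state at a position is a
    function of the token id there, so pooled values have a closed form."""

    def __init__(self, d=8, constant=None):
        self.d = d
        self.constant = constant
        self._w = np.linspace(0.5, 2.0, d)

    @property
    def hidden_size(self):
        return self.d

    def forward(self, ids, attention_mask):
        if self.constant is not None:
            data = np.broadcast_to(self.constant, ids.shape + (self.d,)).copy()
        else:
            data = ids[..., None] * self._w
        return Tensor(np.asarray(data, dtype=float))


def test_1530_token_note_splits_into_three_parts(tokenizer):
    """1530 content tokens at part_len 512 split into exactly 3 parts."""
    seg = segment(np.arange(5, 5 + 1530), tokenizer, part_len=512)
    assert seg.n_parts == 3
    assert seg.parts.shape == (3, 512)
    assert seg.content_token_count == 1530


@pytest.mark.parametrize("c,expected", [(509, 1), (510, 1), (511, 2), (1020, 2), (1021, 3)])
def test_part_count_boundaries(tokenizer, c, expected):
    assert segment(np.full(c, 7), tokenizer, part_len=512).n_parts == expected


def test_part_count_law_full_sweep(tokenizer):
    """parts == ceil(C / (part_len - 2)) for every C in 1..2000."""
    for c in range(1, 2001):
        seg = segment(np.full(c, 7), tokenizer, part_len=512)
        assert seg.n_parts == -(-c // 510)


@settings(max_examples=60, derandomize=True)
@given(st.integers(min_value=1, max_value=3000), st.integers(min_value=8, max_value=64))
def test_segmentation_conserves_content_tokens(c, part_len):
    from racnlp.tokenizer import WordTokenizer, SPECIALS
    tok = WordTokenizer({s: i for i, s in enumerate(SPECIALS)})
    ids = np.arange(10, 10 + c) % 1000 + 5
    seg = segment(ids, tok, part_len=part_len)
    recovered = seg.parts[seg.pooling_masks.astype(bool)]
    assert np.array_equal(recovered, ids)
    # structural invariants
    assert np.all(seg.parts[:, 0] == tok.start_id)
    for p in range(seg.n_parts):
        real = int(seg.attention_masks[p].sum())
        assert seg.parts[p, real - 1] == tok.end_id
        assert np.all(seg.attention_masks[p, real:] == 0)
    assert seg.content_token_count == int(seg.pooling_masks.sum()) == c


def test_segment_rejects_empty_and_tiny_parts(tokenizer):
    with pytest.raises(ValueError):
        segment(np.array([], dtype=int), tokenizer)
    with pytest.raises(ValueError):
        segment(np.array([5]), tokenizer, part_len=2)


def test_constant_encoder_pools_to_the_constant(tokenizer):
    const = np.arange(8.0)
    enc = StubEncoder(d=8, constant=const)
    for c in (1, 10, 510, 1200):
        seg = segment(np.full(c, 9), tokenizer, part_len=512)
        emb = pooled_embedding(enc, seg)
        assert np.allclose(emb.vector, const, atol=1e-12)


def test_single_part_pooling_equals_direct_masked_mean_stub(tokenizer):
    """For every C up to capacity, segmented pooling equals the
    single-pass masked mean of the same hidden states."""
    enc = StubEncoder(d=8)
    for c in range(1, 511):
        ids = (np.arange(c) % 700) + 5
        seg = segment(ids, tokenizer, part_len=512)
        pooled = pooled_embedding(enc, seg).vector
        hidden = enc.forward(seg.parts, seg.attention_masks).data
        mask = seg.pooling_masks[..., None]
        direct = (hidden * mask).sum(axis=(0, 1)) / c
        assert np.allclose(pooled, direct, atol=1e-5)


def test_single_part_pooling_equals_direct_masked_mean_trained(tokenizer, trained_encoder):
    for c in (1, 7, 63, 200, 510):
        ids = (np.arange(c) % (tokenizer.vocab_size - 5)) + 5
        seg = segment(ids, tokenizer, part_len=512)
        pooled = pooled_embedding(trained_encoder, seg).vector
        hidden = trained_encoder.encode(seg.parts, seg.attention_masks)
        direct = (hidden * seg.pooling_masks[..., None]).sum(axis=(0, 1)) / c
        assert np.allclose(pooled, direct, atol=1e-5)


def test_padding_positions_do_not_affect_pooling(tokenizer):
    enc = StubEncoder(d=8)
    seg = segment(np.full(20, 9), tokenizer, part_len=512)
    base = pooled_embedding(enc, seg).vector
    # graft 100 extra padding columns onto the same part
    wide = SegmentedSequence(
        parts=np.pad(seg.parts, ((0, 0), (0, 100))),
        attention_masks=np.pad(seg.attention_masks, ((0, 0), (0, 100))),
        pooling_masks=np.pad(seg.pooling_masks, ((0, 0), (0, 100))),
        content_token_count=seg.content_token_count)
    assert np.allclose(pooled_embedding(enc, wide).vector, base, atol=1e-6)


def test_pooling_invariant_to_part_order(tokenizer):
    enc = StubEncoder(d=8)
    seg = segment((np.arange(1200) % 300) + 5, tokenizer, part_len=512)
    flipped = SegmentedSequence(parts=seg.parts[::-1].copy(),
                                attention_masks=seg.attention_masks[::-1].copy(),
                                pooling_masks=seg.pooling_masks[::-1].copy(),
                                content_token_count=seg.content_token_count)
    a = pooled_embedding(enc, seg).vector
    b = pooled_embedding(enc, flipped).vector
    assert np.allclose(a, b, atol=1e-6)


def test_encode_note_pathways_and_determinism(tokenizer, trained_encoder):
    short = "resident ate lunch well today " * 10  # ~60 tokens, 1 part
    long = "resident ate lunch well today " * 130  # ~650 tokens, 2 parts
    ids_long, _ = tokenizer.encode(long)
    assert segment(ids_long, tokenizer).n_parts == 2
    e1 = encode_note(trained_encoder, tokenizer, short)
    e2 = encode_note(trained_encoder, tokenizer, short)
    assert np.array_equal(e1.vector, e2.vector)
    assert e1.vector.shape == (trained_encoder.hidden_size,)
    with pytest.raises(ValueError):
        encode_note(trained_encoder, tokenizer, "###")  # cleans to empty


def test_pooled_batch_matches_individual_pooling(tokenizer):
    enc = StubEncoder(d=8)
    segs = [segment((np.arange(c) % 90) + 5, tokenizer, part_len=64) for c in (3, 70, 200)]
    batch = pooled_batch(enc, segs).data
    for i, seg in enumerate(segs):
        assert np.allclose(batch[i], pooled_embedding(enc, seg).vector, atol=1e-12)
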