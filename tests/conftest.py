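"""Shared fixtures: a small synthetic corpus, a trained tokenizer and a
briefly pretrained tiny encoder, built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from racnlp import (MaskingConfig, PretrainConfig, SyntheticConfig, WordTokenizer,
                    chunk_corpus, clean_text, generate_pretrain_corpus, pretrain,
                    split_train_val)
from racnlp.encoder import EncoderConfig, TransformerEncoder, tiny_config


@pytest.fixture(scope="session")
def synth_cfg() -> SyntheticConfig:
    return SyntheticConfig(n_clients=60, seed=0, signal_strength=1.0)


@pytest.fixture(scope="session")
def corpus_texts(synth_cfg) -> list[str]:
    return [clean_text(t) for t in generate_pretrain_corpus(synth_cfg, 400)]


@pytest.fixture(scope="session")
def tokenizer(corpus_texts) -> WordTokenizer:
    return WordTokenizer.train(corpus_texts, vocab_size=2000)


@pytest.fixture(scope="session")
def random_encoder(tokenizer) -> TransformerEncoder:
    return TransformerEncoder(tiny_config(tokenizer.vocab_size), seed=0)


@pytest.fixture(scope="session")
def trained_encoder(corpus_texts, tokenizer) -> TransformerEncoder:
    """Tiny encoder after a short burst of domain pretraining."""
    chunks = chunk_corpus(corpus_texts, tokenizer, chunk_len=64)
    train, val = split_train_val(chunks, 0.8, seed=0)
    result = pretrain(train, val,
                      PretrainConfig(max_steps=15, batch_size=8, seed=0),
                      MaskingConfig(seed=0), tokenizer)
    return result.encoder


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
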