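"""Subword tokenizer trained on the nursing-note corpus.

A WordPiece-style scheme: frequent whole words become single tokens,
everything else decomposes greedily into pieces (continuations carry a
``##`` prefix, single characters guarantee total coverage). The
encoder works at the subword level while masking works at the word
level, so :meth:`WordTokenizer.encode` also returns a word-id per
token — all subwords of one whitespace-delimited word share an id.
"""

from __future__ import annotations

import json
from collections import Counter
from pathlib import Path

PAD, UNK, START, END, MASK = "[PAD]", "[UNK]", "[START]", "[END]", "[MASK]"
SPECIALS = [PAD, UNK, START, END, MASK]


class WordTokenizer:
    def __init__(self, vocab: dict[str, int]):
        for i, tok in enumerate(SPECIALS):
            if vocab.get(tok) != i:
                raise ValueError("vocab must start with the special tokens in canonical order")
        self.vocab = vocab
        self.inverse = {i: t for t, i in vocab.items()}

    # canonical special-token ids
    pad_id = 0
    unk_id = 1
    start_id = 2
    end_id = 3
    mask_id = 4

    @property
    def vocab_size(self) -> int:
        return len(self.vocab)

    @classmethod
    def train(cls, texts, vocab_size: int = 2000, min_freq: int = 2) -> "WordTokenizer":
        """Build a vocabulary from an iterable of (cleaned) texts.

        Keeps the ``vocab_size`` most frequent words, then adds every
        observed character both as a word-initial piece and as a ``##``
        continuation so any string can be encoded without [UNK] except
        for characters never seen in training.
        """
        counts: Counter[str] = Counter()
        chars: set[str] = set()
        for text in texts:
            for w in text.lower().split():
                counts[w] += 1
                chars.update(w)
        vocab: dict[str, int] = {t: i for i, t in enumerate(SPECIALS)}
        for ch in sorted(chars):
            vocab.setdefault(ch, len(vocab))
            vocab.setdefault("##" + ch, len(vocab))
        for w, c in counts.most_common():
            if len(vocab) >= vocab_size + len(SPECIALS):
                break
            if c < min_freq or len(w) == 1:
                continue
            vocab.setdefault(w, len(vocab))
        return cls(vocab)

    def _encode_word(self, word: str) -> list[int]:
        if word in self.vocab:
            return [self.vocab[word]]
        ids: list[int] = []
        pos = 0
        while pos < len(word):
            end = len(word)
            piece_id = None
            while end > pos:
                piece = word[pos:end]
                key = piece if pos == 0 else "##" + piece
                if key in self.vocab:
                    piece_id = self.vocab[key]
                    break
                end -= 1
            if piece_id is None:  # unseen character
                piece_id = self.unk_id
                end = pos + 1
            ids.append(piece_id)
            pos = end
        return ids

    def encode(self, text: str) -> tuple[list[int], list[int]]:
        """Tokenise ``text``; returns (token_ids, word_ids).

        ``word_ids[i]`` is the index of the whitespace word that token
        ``i`` came from, the alignment whole-word masking relies on.
        """
        token_ids: list[int] = []
        word_ids: list[int] = []
        for wi, word in enumerate(text.lower().split()):
            ids = self._encode_word(word)
            token_ids.extend(ids)
            word_ids.extend([wi] * len(ids))
        return token_ids, word_ids

    def decode(self, ids) -> str:
        pieces = []
        for i in ids:
            tok = self.inverse.get(int(i), UNK)
            if tok in (PAD, START, END):
                continue
            if tok.startswith("##") and pieces:
                pieces[-1] += tok[2:]
            else:
                pieces.append(tok)
        return " ".join(pieces)

    # -- persistence ----------------------------------------------------
    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.vocab))

    @classmethod
    def load(cls, path: str | Path) -> "WordTokenizer":
        return cls(json.loads(Path(path).read_text()))
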