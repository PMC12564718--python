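"""Window assembly, negation-aware factor extraction and fusion."""

import datetime as dt

import numpy as np
import pytest

from racnlp import (ClassifierConfig, RiskFactorCatalogue, assemble_window,
                    build_windows, extract_risk_factors, fuse_and_classify,
                    train_predictor)
from racnlp.classifier import BinaryHead
from racnlp.encoder import TransformerEncoder, tiny_config
from racnlp.long_encoder import PooledEmbedding
from racnlp.predictor import EmptyWindowError, MalnutritionPredictor, RiskFactorVector
from racnlp.records import Note


@pytest.fixture(scope="module")
def catalogue():
    return RiskFactorCatalogue.default()


def _bit(catalogue, factor_id):
    return [f.factor_id for f in catalogue.factors].index(factor_id)


def test_default_catalogue_has_46_unique_factors(catalogue):
    assert len(catalogue) == 46
    ids = [f.factor_id for f in catalogue.factors]
    assert len(set(ids)) == 46


def test_negation_worked_example(catalogue):
    bits = extract_risk_factors("no sign of cancer", catalogue).bits
    assert bits[_bit(catalogue, "cancer")] == 0


def test_confirmed_mention_sets_bit(catalogue):
    bits = extract_risk_factors("resident has poor appetite today", catalogue).bits
    assert bits[_bit(catalogue, "poor_appetite")] == 1


def test_negation_scope_is_sentence_bounded(catalogue):
    bits = extract_risk_factors("no weight loss. poor appetite noted", catalogue).bits
    assert bits[_bit(catalogue, "weight_loss")] == 0
    assert bits[_bit(catalogue, "poor_appetite")] == 1


def test_confirmed_mention_overrides_negated_one(catalogue):
    text = "denies nausea today. nausea after dinner"
    assert extract_risk_factors(text, catalogue).bits[_bit(catalogue, "nausea")] == 1


def test_cue_beyond_five_tokens_does_not_negate(catalogue):
    text = "no change in mood and resident still reports chronic pain"
    # "no" sits more than five tokens before the phrase
    assert extract_risk_factors(text, catalogue).bits[_bit(catalogue, "chronic_pain")] == 1


def test_synonyms_match(catalogue):
    bits = extract_risk_factors("wt loss recorded this week", catalogue).bits
    assert bits[_bit(catalogue, "weight_loss")] == 1


def _notes(days, base=dt.date(2024, 3, 1)):
    return [Note("c1", base + dt.timedelta(days=d), f"note day {d}", order=i)
            for i, d in enumerate(days)]


def test_window_filter_and_ordering():
    index = dt.date(2024, 3, 1)
    notes = _notes([-35, -20, -5], base=index)
    win = assemble_window(notes, index)
    assert [n.timestamp for n in win.notes] == [index + dt.timedelta(days=-20),
                                                index + dt.timedelta(days=-5)]
    assert win.aggregated_text.startswith("note day -20")


def test_window_boundaries_are_half_open():
    index = dt.date(2024, 3, 31)
    notes = _notes([-30, 0], base=index)
    win = assemble_window(notes, index)
    assert len(win.notes) == 1  # -30 included, 0 (index day) excluded
    assert win.notes[0].timestamp == index - dt.timedelta(days=30)


def test_empty_window_raises():
    index = dt.date(2024, 3, 1)
    with pytest.raises(EmptyWindowError):
        assemble_window(_notes([-40, -35], base=index), index)


def test_window_invariant_to_input_order():
    index = dt.date(2024, 3, 1)
    notes = _notes([-25, -15, -5], base=index)
    a = assemble_window(notes, index)
    b = assemble_window(list(reversed(notes)), index)
    assert a.aggregated_text == b.aggregated_text
    assert [n.timestamp for n in a.notes] == [n.timestamp for n in b.notes]


def test_fusion_head_contract(catalogue):
    d = 64
    head = BinaryHead(d + len(catalogue))
    head.w.data[:] = 0.0
    head.b.data[:] = 0.0
    pooled = PooledEmbedding(vector=np.random.default_rng(0).normal(size=d))
    risk = RiskFactorVector(np.zeros(46, dtype=int))
    assert fuse_and_classify(pooled, risk, head) == pytest.approx(0.5, abs=1e-12)
    # flipping a bit with positive weight strictly raises the probability
    head.w.data[d + 3, 0] = 1.5
    lo = fuse_and_classify(pooled, risk, head)
    risk2 = RiskFactorVector(np.eye(46, dtype=int)[3])
    hi = fuse_and_classify(pooled, risk2, head)
    assert hi > lo
    with pytest.raises(ValueError):
        fuse_and_classify(PooledEmbedding(vector=np.zeros(10)), risk, head)


def test_build_windows_skips_clients_without_window_notes(catalogue):
    from racnlp.records import ClientRecord
    base = dt.date(2024, 3, 1)
    good = ClientRecord("a", "female", 88, 1, base, notes=_notes([-10], base))
    bad = ClientRecord("b", "male", 90, 0, base, notes=_notes([-50], base))
    wins = build_windows([good, bad], catalogue=catalogue)
    assert [w.client_id for w in wins] == ["a"]
    assert wins[0].risk_vector is not None


def test_structured_signal_flows_only_through_fusion(tokenizer, catalogue):
    """Neutral text plus label-correlated risk bits: the text-only model
    is at chance while the fused model separates the classes."""
    rng = np.random.default_rng(0)
    from racnlp.predictor import ClientWindow
    windows = []
    for i in range(120):
        label = int(i % 3 == 0)
        bits = np.zeros(46, dtype=int)
        on = rng.choice(46, size=8, replace=False)
        if label:
            bits[on] = 1  # informative bits for cases
        else:
            bits[rng.choice(46, size=2, replace=False)] = 1
        text = "resident ate lunch well today obs stable settled " * 6
        windows.append(ClientWindow(client_id=f"c{i}", index_date=dt.date(2024, 3, 1),
                                    notes=[], aggregated_text=text, label=label,
                                    risk_vector=RiskFactorVector(bits)))
    enc = TransformerEncoder(tiny_config(tokenizer.vocab_size), seed=0)
    cfg = ClassifierConfig(learning_rate=1e-2, epochs=30, freeze_encoder=True, seed=0)
    import copy
    from racnlp.evaluation import auroc
    _, rep_text = train_predictor(windows, copy.deepcopy(enc), tokenizer, cfg,
                                  use_risk_factors=False, catalogue=catalogue)
    _, rep_fused = train_predictor(windows, copy.deepcopy(enc), tokenizer, cfg,
                                   use_risk_factors=True, catalogue=catalogue)
    assert 0.25 <= rep_text["auroc"] <= 0.75  # identical text carries no signal
    assert rep_fused["auroc"] > 0.9


def test_predictor_save_load_preserves_factor_order_and_scores(tokenizer, catalogue, tmp_path):
    import datetime
    from racnlp.predictor import ClientWindow
    enc = TransformerEncoder(tiny_config(tokenizer.vocab_size), seed=1)
    head = BinaryHead(enc.hidden_size + 46, seed=2)
    model = MalnutritionPredictor(enc, tokenizer, head, ClassifierConfig(), catalogue)
    win = ClientWindow(client_id="c0", index_date=datetime.date(2024, 3, 1), notes=[],
                       aggregated_text="poor appetite noted. resident ate lunch " * 20,
                       label=1)
    before = model.predict_proba([win])
    model.save(tmp_path / "pred")
    loaded = MalnutritionPredictor.load(tmp_path / "pred")
    assert [f.factor_id for f in loaded.catalogue.factors] == \
        [f.factor_id for f in catalogue.factors]
    assert np.allclose(loaded.predict_proba([win]), before, atol=1e-12)
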