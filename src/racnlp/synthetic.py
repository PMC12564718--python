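"""Synthetic aged-care nursing-note corpus generator.

The real EHR behind this pipeline cannot be shared, so every
downstream stage is exercised on generated data that reproduces the
statistical structure the pipeline assumes: short template-based notes
(mean 64 tokens), roughly 2.3 review notes per client per week so a
30-day window aggregates to ~644 tokens, sex-stratified malnutrition
prevalence (26% of females, 30% of males), keyword-borne malnutrition
signal whose strength is a dial, and factor mentions that are
sometimes emitted inside negation templates.

Text is assembled from subject/action/object/quantity/filler templates
with injectable risk-factor phrases. Note lengths are drawn from a
negative binomial around the target mean, over-dispersed like real
notes, which keeps a healthy share of aggregated windows above the
512-token encoder limit.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .records import ClientRecord, Note

BASE_DATE = dt.date(2024, 1, 1)
HISTORY_DAYS = 70
WINDOW_DAYS = 30

SUBJECTS = ["resident", "client", "she", "he"]
VERBS = ["ate", "refused", "required", "tolerated", "attended", "reported",
         "received", "completed", "mobilised", "slept"]
OBJECTS = ["breakfast", "lunch", "dinner", "supper", "supplement", "fluids",
           "medication", "shower", "physio session", "pureed diet", "soft diet",
           "morning tea"]
QUANTITIES = ["25%", "50%", "75%", "100%", "all", "half", "most"]
# includes aged-care shorthand absent from general English, so domain
# adaptation has something to adapt to
FILLERS = ["well", "today", "overnight", "this morning", "with assistance",
           "without issue", "as charted", "prn given", "bd dose", "nbm overnight",
           "obs stable", "wt recorded", "repositioned 2hrly", "family visited",
           "gp review booked", "adls attended", "settled", "no concerns",
           "continence managed", "diet as tolerated"]

MALNUTRITION_PHRASES = ["malnutrition", "malnourished", "severe weight loss",
                        "significant weight loss"]
NEGATION_TEMPLATES = ["no sign of {}", "no {}", "denies {}", "without {}",
                      "no evidence of {}"]

# canonical factor phrases injected into note text (a subset of the
# default catalogue's names; the extractor matches the full catalogue)
FACTOR_PHRASES = ["poor appetite", "weight loss", "dysphagia", "nausea",
                  "vomiting", "dehydration", "dementia", "depression", "cancer",
                  "constipation", "fatigue", "frailty", "chronic pain",
                  "food refusal", "poor oral intake", "pressure injury",
                  "infection", "dry mouth", "immobility", "taste changes"]


@dataclass
class SyntheticConfig:
    n_clients: int = 200
    female_fraction: float = 2797 / 4405  # typical RAC cohort mix
    prevalence_female: float = 0.26
    prevalence_male: float = 0.30
    mean_short_note_tokens: int = 64
    mean_window_tokens: int = 644
    notes_per_client_per_week: float | None = None  # derived when None
    signal_strength: float = 0.8
    negation_rate: float = 0.15
    length_dispersion: float = 12.0  # negative-binomial shape
    vocab: dict = field(default_factory=dict)  # optional template overrides
    seed: int = 0

    def __post_init__(self):
        for name in ("female_fraction", "prevalence_female", "prevalence_male",
                     "signal_strength", "negation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        for name in ("n_clients", "mean_short_note_tokens", "mean_window_tokens"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.notes_per_client_per_week is not None and self.notes_per_client_per_week <= 0:
            raise ValueError("notes_per_client_per_week must be positive")

    @property
    def note_rate_per_day(self) -> float:
        """Daily note probability; defaults to the rate that makes a
        30-day window average mean_window_tokens."""
        if self.notes_per_client_per_week is not None:
            return min(self.notes_per_client_per_week / 7.0, 1.0)
        return min(self.mean_window_tokens / self.mean_short_note_tokens / WINDOW_DAYS, 1.0)


def _draw_length(cfg: SyntheticConfig, rng: np.random.Generator) -> int:
    """Over-dispersed note length (words) with mean mean_short_note_tokens."""
    r = cfg.length_dispersion
    mean = cfg.mean_short_note_tokens
    p = r / (r + mean)
    return max(3, int(rng.negative_binomial(r, p)))


def _filler_sentences(rng: np.random.Generator, n_words: int) -> list[str]:
    """Template sentences totalling exactly ``n_words`` words."""
    words: list[str] = []
    while len(words) < n_words:
        words.append(str(rng.choice(SUBJECTS)))
        words.append(str(rng.choice(VERBS)))
        words.append(str(rng.choice(OBJECTS)))
        if rng.random() < 0.5:
            words.append(str(rng.choice(QUANTITIES)))
        for _ in range(rng.integers(1, 4)):
            words.extend(str(rng.choice(FILLERS)).split())
    words = words[:n_words]
    sentences = []
    i = 0
    while i < len(words):
        step = int(rng.integers(6, 10))
        sentences.append(" ".join(words[i:i + step]) + ".")
        i += step
    return sentences


def _make_note_text(cfg: SyntheticConfig, rng: np.random.Generator,
                    mention_malnutrition: bool, client_label: int) -> tuple[str, int]:
    """Assemble one note; returns (text, note_label).

    The note label marks a *confirmed* malnutrition mention. Risk-factor
    phrases are injected at a rate elevated by ``signal_strength`` for
    malnourished clients; a fraction ``negation_rate`` of factor
    emissions is wrapped in a negation template. Notes of well-nourished
    clients occasionally carry a *negated* malnutrition phrase, which
    keeps the note task honest without flipping its label. Injected
    phrases consume the length budget, so the word count matches the
    drawn target length except for the rare note whose injections alone
    exceed it.
    """
    target = _draw_length(cfg, rng)
    pieces: list[str] = []
    used = 0
    note_label = 0

    def add(phrase: str):
        nonlocal used
        pieces.append(phrase if phrase.endswith(".") else phrase + ".")
        used += len(phrase.split())

    if mention_malnutrition:
        note_label = 1
        for _ in range(int(rng.integers(1, 3))):
            add(str(rng.choice(MALNUTRITION_PHRASES)) + " noted")
    elif rng.random() < cfg.negation_rate * 0.25:
        add(str(rng.choice(NEGATION_TEMPLATES)).format(rng.choice(MALNUTRITION_PHRASES)))

    lam = 0.4 + 1.2 * cfg.signal_strength if client_label == 1 else 0.4
    for _ in range(rng.poisson(lam)):
        factor = str(rng.choice(FACTOR_PHRASES))
        if rng.random() < cfg.negation_rate:
            add(str(rng.choice(NEGATION_TEMPLATES)).format(factor))
        else:
            add(factor + " noted")

    if used < target:
        pieces.extend(_filler_sentences(rng, target - used))
    rng.shuffle(pieces)
    return " ".join(pieces), note_label


def _mention_prob(cfg: SyntheticConfig, client_label: int) -> float:
    # identical across labels at signal_strength = 0 (exchangeability)
    base = 0.05
    return base + 0.75 * cfg.signal_strength if client_label == 1 else base


def generate_clients(config: SyntheticConfig) -> list[ClientRecord]:
    """Generate a cohort of clients with note histories.

    Deterministic given ``config.seed``. Sex-conditional malnutrition
    prevalence follows the configured rates; malnourished clients get
    an onset date placed so that several review notes fall inside the
    preceding 30 days.
    """
    rng = np.random.default_rng(config.seed)
    clients: list[ClientRecord] = []
    rate = config.note_rate_per_day
    for i in range(config.n_clients):
        sex = "female" if rng.random() < config.female_fraction else "male"
        prev = config.prevalence_female if sex == "female" else config.prevalence_male
        label = int(rng.random() < prev)
        age = float(np.clip(rng.normal(85.0, 7.0), 65.0, 105.0))
        start = BASE_DATE + dt.timedelta(days=int(rng.integers(0, 28)))
        note_days = [d for d in range(HISTORY_DAYS) if rng.random() < rate]
        if label == 1:
            onset_day = int(rng.integers(WINDOW_DAYS + 10, HISTORY_DAYS))
            in_window = [d for d in note_days if onset_day - WINDOW_DAYS <= d < onset_day]
            forced = [onset_day - 21, onset_day - 14, onset_day - 7]
            while len(in_window) < 3:
                d = forced.pop()
                if d not in note_days:
                    note_days.append(d)
                    in_window.append(d)
            note_days.sort()
        else:
            if not note_days:
                note_days = [3]
            onset_day = note_days[-1]  # controls anchored at latest note
        onset_date = start + dt.timedelta(days=onset_day)
        client_id = f"c{i:05d}"
        notes = []
        mention_p = _mention_prob(config, label)
        for order, d in enumerate(note_days):
            mention = rng.random() < mention_p
            text, note_label = _make_note_text(config, rng, mention, label)
            notes.append(Note(client_id=client_id, timestamp=start + dt.timedelta(days=d),
                              text=text, label=note_label, order=order))
        clients.append(ClientRecord(client_id=client_id, sex=sex, age=age, label=label,
                                    onset_date=onset_date, notes=notes))
    return clients


def generate_pretrain_corpus(config: SyntheticConfig, n_notes: int) -> list[str]:
    """Raw text lines for masked-language-model pretraining."""
    if n_notes < 1:
        raise ValueError("n_notes must be >= 1")
    rng = np.random.default_rng(config.seed + 1)
    overall_prev = (config.female_fraction * config.prevalence_female
                    + (1 - config.female_fraction) * config.prevalence_male)
    lines = []
    for _ in range(n_notes):
        label = int(rng.random() < overall_prev)
        mention = rng.random() < _mention_prob(config, label)
        text, _ = _make_note_text(config, rng, mention, label)
        lines.append(text)
    return lines


# -- JSONL fixtures -----------------------------------------------------

def write_fixture(records: list[ClientRecord], path: str | Path) -> None:
    """Serialise clients to JSONL, one note per line.

    Client-level fields (sex, age, outcome label, onset date) ride along
    on every line so the file round-trips losslessly.
    """
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            for note in rec.sorted_notes():
                fh.write(json.dumps({
                    "client_id": rec.client_id,
                    "timestamp": note.timestamp.isoformat(),
                    "text": note.text,
                    "label": note.label,
                    "sex": rec.sex,
                    "age": round(rec.age, 2),
                    "client_label": rec.label,
                    "onset_date": rec.onset_date.isoformat(),
                }, sort_keys=True) + "\n")


def read_fixture(path: str | Path) -> list[ClientRecord]:
    """Read a JSONL note fixture back into ClientRecords."""
    by_client: dict[str, ClientRecord] = {}
    with Path(path).open() as fh:
        for line in fh:
            if not line.strip():
                continue
            row = json.loads(line)
            cid = row["client_id"]
            if cid not in by_client:
                by_client[cid] = ClientRecord(
                    client_id=cid,
                    sex=row.get("sex", "female"),
                    age=float(row.get("age", 85.0)),
                    label=int(row.get("client_label", 0)),
                    onset_date=dt.date.fromisoformat(row["onset_date"])
                    if "onset_date" in row else dt.date.fromisoformat(row["timestamp"]),
                )
            rec = by_client[cid]
            rec.notes.append(Note(client_id=cid,
                                  timestamp=dt.date.fromisoformat(row["timestamp"]),
                                  text=row["text"],
                                  label=row.get("label"),
                                  order=len(rec.notes)))
    return list(by_client.values())


def all_notes(records: list[ClientRecord]) -> list[Note]:
    return [n for rec in records for n in rec.sorted_notes()]
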