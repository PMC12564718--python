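"""Core record types shared across the pipeline."""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field


@dataclass
class Note:
    """One timestamped free-text clinical note for one client."""

    client_id: str
    timestamp: dt.date
    text: str
    label: int | None = None  # 1 = reports malnutrition, 0 = normal status
    order: int = 0  # insertion order, breaks timestamp ties


@dataclass
class ClientRecord:
    """A client with demographic fields, outcome label and note history.

    ``onset_date`` is the recorded malnutrition onset for cases and the
    index date used for window assembly for controls.
    """

    client_id: str
    sex: str  # "female" | "male"
    age: float
    label: int  # 1 = malnourished, 0 = well-nourished
    onset_date: dt.date
    notes: list[Note] = field(default_factory=list)

    def sorted_notes(self) -> list[Note]:
        return sorted(self.notes, key=lambda n: (n.timestamp, n.order))
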