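"""Cumulative qualitative vestibular-syndrome score.

Each typical post-lesional symptom carries a fixed weight — tumbling 5,
retropulsion 4, circling 3, bobbing 2, head tilt 1 — and the score of an
observation is the sum of the weights of the symptoms present (0–15).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["SYMPTOM_WEIGHTS", "SymptomChecklist", "syndrome_score", "score_checklist_table"]

SYMPTOM_WEIGHTS: dict[str, int] = {
    "tumbling": 5,
    "retropulsion": 4,
    "circling": 3,
    "bobbing": 2,
    "head_tilt": 1,
}

MAX_SCORE: int = sum(SYMPTOM_WEIGHTS.values())


@dataclass(frozen=True)
class SymptomChecklist:
    tumbling: bool = False
    retropulsion: bool = False
    circling: bool = False
    bobbing: bool = False
    head_tilt: bool = False


def syndrome_score(checklist: SymptomChecklist) -> int:
    """Weighted sum of the symptoms present (integer, 0–15)."""
    return sum(w for s, w in SYMPTOM_WEIGHTS.items() if getattr(checklist, s))


def score_checklist_table(df: pd.DataFrame) -> pd.DataFrame:
    """Append a ``score`` column to a checklist table.

    Expects one boolean column per symptom (``tumbling`` … ``head_tilt``);
    other columns (animal_id, group, timepoint) pass through untouched.
    """
    missing = [s for s in SYMPTOM_WEIGHTS if s not in df.columns]
    if missing:
        raise ValueError(f"checklist table missing symptom columns {missing}")
    out = df.copy()
    out["score"] = sum(
        df[s].astype(bool).astype(int) * w for s, w in SYMPTOM_WEIGHTS.items()
    )
    return out
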