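"""Behavioural scores: movement laterality index, modified Motor Activity
Log (MAL) score, and chronic phantom-pain magnitude.

Laterality index
    ``(intact − residual) / (intact + residual)`` over detected movement
    counts.  +1 means exclusive intact-hand use, 0 balanced use, −1
    exclusive residual-arm use.  A ratio, rather than absolute counts, is
    used so that whole-body co-movements and unequal wear times cancel.

Modified MAL
    A 27-item inventory of daily activities; respondents rate how
    frequently they incorporate the residual arm (never / sometimes /
    very often → 0 / 1 / 2).  The score is the item sum divided by 54,
    i.e. a fraction of the maximum possible raw sum, on a 0–1 scale.
    Frequency, not movement quality, is rated.

Chronic pain magnitude
    Pain intensity (0 "no pain" – 10 "worst pain imaginable") divided by
    a frequency code (1 "all the time" … 5 "once or less per month"), so
    intense, constant pain scores highest.
"""

from __future__ import annotations

from collections.abc import Sequence

import pandas as pd

from .io import ValidationError

__all__ = [
    "MAL_ITEMS",
    "MAL_MAX_RAW_SUM",
    "laterality_index",
    "score_mal",
    "chronic_pain_score",
    "read_mal_table",
]

#: The 27 inventory items, in fixed order; keys are the column short codes
#: used in questionnaire input tables.
MAL_ITEMS: dict[str, str] = {
    "wallet": "taking money out of wallet",
    "envelope": "opening envelope",
    "glasses": "picking up/lifting glasses",
    "phone": "picking up/holding up a phone",
    "wipe_counter": "wiping off a kitchen counter or other surface",
    "out_of_car": "getting out of a car",
    "stabilize_paper": "stabilizing paper while writing",
    "stabilize_dishes": "stabilizing dishes while carrying",
    "carry_cup": "carrying a cup or a can",
    "carry_bags": "carrying bags",
    "chair_armrests": "getting up from a chair with arm rests",
    "pull_chair": "pulling chair away from table before sitting down",
    "hold_book": "holding a book or a magazine/turning pages",
    "keyboard": "typing on a keyboard/pressing mouse buttons",
    "mouse": "controlling a computer mouse",
    "socks": "putting on your socks",
    "shoes": "putting on your shoes",
    "shoe_laces": "tying shoe laces",
    "sleeve": "inserting your (intact) arm through a sleeve",
    "face_cream": "putting on makeup base, lotion, or shaving cream on face",
    "wash_face": "washing hand or face",
    "dry_face": "drying your hand or face",
    "comb_hair": "combing your hair",
    "button_shirt": "buttoning a shirt",
    "zip_coat": "zipping up a coat",
    "peel_fruit": "peeling fruit skin",
    "fork_spoon": "using a fork or spoon for eating",
}

N_MAL_ITEMS = len(MAL_ITEMS)  # 27
MAL_MAX_RAW_SUM = 2 * N_MAL_ITEMS  # 54, the normalisation constant


def laterality_index(n_intact: int, n_residual: int) -> float:
    """Movement laterality index ``(intact − residual)/(intact + residual)``.

    Positive values mean relatively more intact-hand movements.  Raises if
    both counts are zero: an index of 0 would wrongly encode balanced use.
    """
    if n_intact < 0 or n_residual < 0:
        raise ValidationError("movement counts must be non-negative")
    total = n_intact + n_residual
    if total == 0:
        raise ValidationError("laterality index undefined: both movement counts are zero")
    return (n_intact - n_residual) / total


def score_mal(ratings: Sequence[int]) -> float:
    """Score a complete 27-item modified MAL response: ``sum / 54`` in [0, 1].

    Incomplete questionnaires are rejected rather than prorated — the /54
    normalisation presumes 27 answered items.
    """
    ratings = list(ratings)
    if len(ratings) != N_MAL_ITEMS:
        raise ValidationError(f"expected {N_MAL_ITEMS} item ratings, got {len(ratings)}")
    codes = list(MAL_ITEMS)
    for i, r in enumerate(ratings):
        if r not in (0, 1, 2):
            raise ValidationError(f"item {i + 1} ({codes[i]!r}): rating must be 0, 1 or 2, got {r!r}")
    return sum(ratings) / MAL_MAX_RAW_SUM


def chronic_pain_score(intensity: float, frequency: int) -> float:
    """Chronic pain magnitude: intensity (0–10) divided by frequency code (1–5)."""
    if not 0 <= intensity <= 10:
        raise ValidationError(f"pain intensity must be in [0, 10], got {intensity!r}")
    if frequency not in (1, 2, 3, 4, 5):
        raise ValidationError(f"pain frequency code must be in 1..5, got {frequency!r}")
    return intensity / frequency


def read_mal_table(path) -> pd.DataFrame:
    """Read a questionnaire table (participant_id + one column per item code)
    and return a frame with participant_id and the computed ``mal_score``."""
    df = pd.read_csv(path)
    missing = [c for c in MAL_ITEMS if c not in df.columns]
    if missing:
        raise ValidationError(f"questionnaire table missing item columns {missing}")
    scores = []
    for _, row in df.iterrows():
        ratings = [row[c] for c in MAL_ITEMS]
        if any(pd.isna(r) for r in ratings):
            raise ValidationError(
                f"{row.get('participant_id', '<row>')}: incomplete questionnaire (missing item)"
            )
        scores.append(score_mal([int(r) for r in ratings]))
    return pd.DataFrame({"participant_id": df["participant_id"], "mal_score": scores})
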