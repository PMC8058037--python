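"""Regex feature extraction from free-text drink notes.

Three case-insensitive dictionaries: numeric amounts, volumetric container
terms, and beverage/alcohol-content terms; plus a has-note flag and the sum
of the three counts.
"""
from __future__ import annotations

import re

import pandas as pd

NUMERIC_RE = re.compile(r"\b\d+(?:\.\d+)?\b|\b(?:one|two|three|four|five|six|"
                        r"seven|eight|nine|ten|couple|few)\b", re.IGNORECASE)
CONTAINER_RE = re.compile(r"\b(?:glass(?:es)?|bottle[s]?|tumbler[s]?|can[s]?|"
                          r"pint[s]?|shot[s]?|cup[s]?|flask[s]?|stein[s]?|"
                          r"snifter[s]?|oz|ounce[s]?|ml)\b", re.IGNORECASE)
BEVERAGE_RE = re.compile(r"\b(?:beer[s]?|wine[s]?|whisk(?:e)?y[s]?|vodka|gin|"
                         r"rum|tequila|cider[s]?|ale[s]?|lager[s]?|stout[s]?|"
                         r"champagne|prosecco|sake|brandy|cognac|bourbon|"
                         r"scotch|liquor|cocktail[s]?|margarita[s]?|"
                         r"martini[s]?|mead)\b", re.IGNORECASE)

FEATURES = ["has_note", "note_numeric_count", "note_container_count",
            "note_beverage_count", "note_nlp_total"]


def nlp_note_features(note) -> dict:
    """Dictionary-count features for one note (None/empty = no note)."""
    if note is None or (isinstance(note, float) and pd.isna(note)) or note == "":
        return dict.fromkeys(FEATURES, 0)
    text = str(note)
    n_num = len(NUMERIC_RE.findall(text))
    n_con = len(CONTAINER_RE.findall(text))
    n_bev = len(BEVERAGE_RE.findall(text))
    return {"has_note": 1, "note_numeric_count": n_num,
            "note_container_count": n_con, "note_beverage_count": n_bev,
            "note_nlp_total": n_num + n_con + n_bev}


def note_feature_frame(notes: pd.Series) -> pd.DataFrame:
    """Vectorized note features for a series of notes."""
    s = notes.fillna("").astype(str)
    out = pd.DataFrame(index=s.index)
    out["has_note"] = (s != "").astype(int)
    out["note_numeric_count"] = s.str.count(NUMERIC_RE)
    out["note_container_count"] = s.str.count(CONTAINER_RE)
    out["note_beverage_count"] = s.str.count(BEVERAGE_RE)
    out["note_nlp_total"] = (out["note_numeric_count"]
                             + out["note_container_count"]
                             + out["note_beverage_count"])
    return out
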