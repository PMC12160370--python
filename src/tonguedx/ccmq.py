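"""Scoring of the Constitution in Chinese Medicine Questionnaire (CCMQ).

The CCMQ is a 9-subscale instrument.  Each subscale is a set of 5-point Likert
items; the raw score is the sum of its item responses and is rescaled to a
0-100 *transformation score*:

    transformation = (raw - n_entries) / (n_entries * 4) * 100

Constitution determination uses two rules on the nine transformation scores:

* **Balanced rule** — Gentleness (balanced constitution) when the balanced
  subscale scores >= 60 *and* all eight imbalanced subscales score < 30.
* **Imbalanced rule** — an imbalanced subscale scoring >= 40 flags that type.

Four imbalanced types (Qi-deficiency, Yang-deficiency, Wetness-heat,
Qi-depression) are the studied classes; when exactly one of them is flagged
the call is that type.  When only non-studied types are flagged the call is
``OTHER_IMBALANCED``; any ambiguity (no rule fires, multiple studied flags, or
a studied/non-studied mix) yields ``INDETERMINATE`` — mirroring the exclusion
of subjects whose constitution could not be determined.  Scores in the
30 <= s < 40 band carry no call on their own and fall through to
``INDETERMINATE`` unless another rule fires.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd

from .constitutions import Constitution

__all__ = [
    "SUBSCALE_ENTRIES",
    "STUDIED_IMBALANCED",
    "Call",
    "SubscaleScore",
    "ConstitutionCall",
    "transform_score",
    "score_subscales",
    "determine_constitution",
    "score_questionnaire",
    "read_item_responses",
    "write_calls_json",
]

#: Published per-subscale entry counts; overridable wherever a scorer accepts
#: an ``entries`` mapping.
SUBSCALE_ENTRIES: dict[str, int] = {
    "gentleness": 8,
    "qi_deficiency": 8,
    "yang_deficiency": 7,
    "yin_deficiency": 8,
    "phlegm_wetness": 8,
    "wetness_heat": 6,
    "blood_stasis": 7,
    "qi_depression": 7,
    "special": 7,
}

STUDIED_IMBALANCED = ("qi_deficiency", "yang_deficiency", "wetness_heat", "qi_depression")

BALANCED_THRESHOLD = 60.0
OTHERS_BELOW = 30.0
IMBALANCED_THRESHOLD = 40.0


class Call(str, Enum):
    """Outcome of constitution determination."""

    GENTLENESS = "gentleness"
    QI_DEFICIENCY = "qi_deficiency"
    YANG_DEFICIENCY = "yang_deficiency"
    WETNESS_HEAT = "wetness_heat"
    QI_DEPRESSION = "qi_depression"
    OTHER_IMBALANCED = "other_imbalanced"
    INDETERMINATE = "indeterminate"

    @classmethod
    def from_constitution(cls, c: Constitution) -> "Call":
        return cls(c.value)


@dataclass(frozen=True)
class SubscaleScore:
    n_entries: int
    raw_score: int
    transformation_score: float


@dataclass(frozen=True)
class ConstitutionCall:
    call: Call
    subscale_scores: dict[str, SubscaleScore] = field(default_factory=dict)

    @property
    def transformation_scores(self) -> dict[str, float]:
        return {k: v.transformation_score for k, v in self.subscale_scores.items()}


def transform_score(raw_score: int, n_entries: int) -> float:
    """Rescale a subscale raw score to the 0-100 transformation score."""
    if n_entries < 1:
        raise ValueError(f"n_entries must be >= 1, got {n_entries}")
    if not n_entries <= raw_score <= 5 * n_entries:
        raise ValueError(
            f"raw score {raw_score} outside feasible range "
            f"[{n_entries}, {5 * n_entries}] for {n_entries} entries "
            "(malformed questionnaire)"
        )
    return (raw_score - n_entries) / (n_entries * 4) * 100.0


def score_subscales(
    items: dict[str, int], entries: dict[str, int] | None = None
) -> dict[str, SubscaleScore]:
    """Score item responses keyed ``<subscale>_<i>`` into nine subscale records."""
    entries = dict(SUBSCALE_ENTRIES if entries is None else entries)
    out: dict[str, SubscaleScore] = {}
    for sub, n in entries.items():
        vals = [items[f"{sub}_{i}"] for i in range(1, n + 1)]
        for v in vals:
            if not 1 <= int(v) <= 5:
                raise ValueError(f"item response {v} for subscale {sub!r} outside 1..5")
        raw = int(sum(int(v) for v in vals))
        out[sub] = SubscaleScore(n, raw, transform_score(raw, n))
    return out


def determine_constitution(transformation_scores: dict[str, float]) -> ConstitutionCall:
    """Apply the balanced / imbalanced determination rules to nine scores."""
    ts = transformation_scores
    missing = set(SUBSCALE_ENTRIES) - set(ts)
    if missing:
        raise ValueError(f"missing subscale scores: {sorted(missing)}")
    for name, s in ts.items():
        if not 0.0 <= s <= 100.0:
            raise ValueError(f"transformation score {s} for {name!r} outside [0, 100]")

    others = {k: v for k, v in ts.items() if k != "gentleness"}
    scores = {k: SubscaleScore(SUBSCALE_ENTRIES.get(k, 0), 0, v) for k, v in ts.items()}

    if ts["gentleness"] >= BALANCED_THRESHOLD and all(v < OTHERS_BELOW for v in others.values()):
        return ConstitutionCall(Call.GENTLENESS, scores)

    flagged = [k for k, v in others.items() if v >= IMBALANCED_THRESHOLD]
    studied = [k for k in flagged if k in STUDIED_IMBALANCED]
    non_studied = [k for k in flagged if k not in STUDIED_IMBALANCED]
    if len(studied) == 1 and not non_studied:
        return ConstitutionCall(Call(studied[0]), scores)
    if flagged and not studied:
        return ConstitutionCall(Call.OTHER_IMBALANCED, scores)
    return ConstitutionCall(Call.INDETERMINATE, scores)


def score_questionnaire(
    items: dict[str, int], entries: dict[str, int] | None = None
) -> ConstitutionCall:
    """Score raw item responses and determine the constitution in one step."""
    sub = score_subscales(items, entries)
    call = determine_constitution({k: v.transformation_score for k, v in sub.items()})
    return ConstitutionCall(call.call, sub)


def read_item_responses(path: str | Path) -> pd.DataFrame:
    """Read a questionnaire CSV (one row per subject, item columns)."""
    df = pd.read_csv(path, index_col=0)
    expected = [f"{s}_{i}" for s, n in SUBSCALE_ENTRIES.items() for i in range(1, n + 1)]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"questionnaire CSV missing item columns: {missing[:5]}...")
    return df


def write_calls_json(calls: dict[str, ConstitutionCall], path: str | Path) -> None:
    payload = {
        sid: {"call": c.call.value, "transformation_scores": c.transformation_scores}
        for sid, c in calls.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2))
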