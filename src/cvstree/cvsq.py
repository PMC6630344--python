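"""Scoring of the 16-item Computer Vision Syndrome Questionnaire (CVS-Q).

The instrument asks, for each of 16 ocular and visual symptoms, how often
the symptom occurs during or right after computer work (never /
occasionally / often-or-always) and, when it occurs, how intense it is
(moderate / intense).  Each item contributes a severity in {0, 1, 2}
obtained by recoding the frequency x intensity product, the total score is
the sum over the 16 items (range 0-32), and a worker scoring 6 or more is
classified as symptomatic (suffering CVS).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

#: The 16 symptoms, in instrument order.
SYMPTOMS: tuple[str, ...] = (
    "burning",
    "itching",
    "foreign_body_sensation",
    "tearing",
    "excessive_blinking",
    "eye_redness",
    "eye_pain",
    "heavy_eyelids",
    "dryness",
    "blurred_vision",
    "double_vision",
    "difficulty_focusing_near",
    "light_sensitivity",
    "colored_halos",
    "worsening_sight_feeling",
    "headache",
)

FREQUENCY_NEVER, FREQUENCY_OCCASIONALLY, FREQUENCY_OFTEN = 0, 1, 2
INTENSITY_MODERATE, INTENSITY_INTENSE = 1, 2

#: Recode of the frequency x intensity product into an item severity.
#: This map is the single place to change should a different published
#: recode of the instrument be preferred.
SEVERITY_RECODE: dict[int, int] = {0: 0, 1: 1, 2: 1, 4: 2}

MAX_SCORE = 32
SYMPTOMATIC_CUTOFF = 6


def score_item(frequency: int, intensity: int | None, *, symptom: str = "item") -> int:
    """Severity contribution of one symptom item.

    A never-experienced symptom (frequency 0) contributes 0 regardless of
    the intensity answer, which is therefore not validated in that case —
    partially filled questionnaires with blank intensity on "never" rows
    are accepted.
    """
    if frequency not in (0, 1, 2):
        raise ValueError(f"{symptom}: frequency must be 0, 1 or 2, got {frequency!r}")
    if frequency == 0:
        return 0
    if intensity not in (1, 2):
        raise ValueError(f"{symptom}: intensity must be 1 or 2, got {intensity!r}")
    return SEVERITY_RECODE[frequency * intensity]


@dataclass(frozen=True)
class SymptomItem:
    """One answered item: a symptom with its frequency and intensity."""

    symptom: str
    frequency: int
    intensity: int | None = None

    def __post_init__(self) -> None:
        if self.symptom not in SYMPTOMS:
            raise ValueError(f"unknown symptom {self.symptom!r}")
        # validates the ordinals; result discarded
        score_item(self.frequency, self.intensity, symptom=self.symptom)

    @property
    def severity(self) -> int:
        return score_item(self.frequency, self.intensity, symptom=self.symptom)


@dataclass(frozen=True)
class CvsqResponse:
    """A complete questionnaire response: exactly one item per symptom."""

    items: tuple[SymptomItem, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        seen = [item.symptom for item in self.items]
        missing = set(SYMPTOMS) - set(seen)
        if missing:
            raise ValueError(f"missing symptom items: {sorted(missing)}")
        if len(seen) != len(set(seen)):
            raise ValueError("duplicate symptom items in response")

    @property
    def score(self) -> int:
        return score_cvsq(self)


def score_cvsq(response: CvsqResponse | Iterable[SymptomItem]) -> int:
    """Total CVS-Q score: sum of item severities, an integer in [0, 32]."""
    items = response.items if isinstance(response, CvsqResponse) else tuple(response)
    if not isinstance(response, CvsqResponse):
        response = CvsqResponse(items)  # validates completeness
    return sum(item.severity for item in response.items)


def classify_symptomatic(score: int) -> bool:
    """True when the score reaches the symptomatic cutoff (>= 6)."""
    if score < 0:
        raise ValueError(f"score must be non-negative, got {score}")
    return score >= SYMPTOMATIC_CUTOFF


# ---------------------------------------------------------------------------
# Tabular layout: one row per subject, 32 answer columns


def default_column_map() -> dict[str, tuple[str, str]]:
    """symptom -> (frequency column, intensity column) for the flat layout."""
    return {s: (f"{s}_frequency", f"{s}_intensity") for s in SYMPTOMS}


def score_questionnaires(
    frame: pd.DataFrame,
    column_map: Mapping[str, tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Score every row of a questionnaire table.

    Returns a copy of ``frame`` with two added columns: ``cvsq_score`` and
    ``cvs_case`` (the >= 6 classification, as 0/1).
    """
    cmap = dict(column_map) if column_map is not None else default_column_map()
    missing_symptoms = set(SYMPTOMS) - set(cmap)
    if missing_symptoms:
        raise ValueError(f"column map lacks symptoms: {sorted(missing_symptoms)}")
    for s, (fcol, icol) in cmap.items():
        if fcol not in frame.columns:
            raise ValueError(f"missing frequency column {fcol!r} for symptom {s!r}")
        if icol not in frame.columns:
            raise ValueError(f"missing intensity column {icol!r} for symptom {s!r}")

    scores = []
    for idx, row in frame.iterrows():
        total = 0
        for s, (fcol, icol) in cmap.items():
            freq = int(row[fcol])
            raw_int = row[icol]
            inten = None if pd.isna(raw_int) else int(raw_int)
            total += score_item(freq, inten, symptom=s)
        scores.append(total)
    out = frame.copy()
    out["cvsq_score"] = scores
    out["cvs_case"] = [int(classify_symptomatic(s)) for s in scores]
    return out


def read_questionnaires(
    path, column_map: Mapping[str, tuple[str, str]] | None = None
) -> pd.DataFrame:
    """Read a delimited questionnaire table and append score columns."""
    frame = pd.read_csv(path)
    return score_questionnaires(frame, column_map)


def write_scored(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)
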