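"""Synthetic cohorts with the structure of the reference hospital study.

The original subject-level data were never deposited, so everything here
is generated: a table of ~343 hospital workers described by ~255 encoded
predictors — mostly 0/1 indicators (departments, shifts, ocular history,
lens wear) plus a handful of continuous exposures (age, seniority in
years, daily hours of screen work) — and an integer CVS-Q score in
[0, 32].

The score signal is deliberately tree-structured: a small set of
informative variables each contributes an additive shift when a threshold
rule fires (e.g. more than 20 years of occupational seniority, more than
4 h/day of screen work), on top of a calibrated base level and rounded
Gaussian noise, clipped to the instrument's range.  The generating rule is
recorded alongside the table so recovery of the planted variables can be
tested.  With zero noise and distinct shifts, a sufficiently deep tree on
the true variables reproduces the target exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import cvsq
from .reference_study import (
    EXCLUSION_COUNTS,
    OCULAR_DISEASE_SUBREASONS,
    RESPONDENTS,
    prevalence_fixture,
)
from .tree import BINARY, CONTINUOUS, CohortTable

#: Continuous exposure columns, always generated first, in this order.
CONTINUOUS_COLUMNS = (
    "occupational_seniority_years",
    "unit_seniority_years",
    "vdt_hours_work",
    "vdt_hours_outside",
    "age_years",
)

#: Named informative indicator columns (the rest of the binary block is
#: pure-noise ``ind_###`` dummies).
NAMED_BINARY = {
    "contact_lens_wearer": 0.155,
    "conjunctivitis_history": 0.30,
    "rotating_shifts_with_nights": 0.29,
}


@dataclass(frozen=True)
class EffectRule:
    """One planted effect: ``shift`` is added to the score when
    ``variable > threshold``."""

    variable: str
    threshold: float
    shift: float


#: Default planted signal: two continuous exposure thresholds plus three
#: history/shift indicators, mirroring the kind of variables the reference
#: study ranked highest.
DEFAULT_EFFECTS: tuple[EffectRule, ...] = (
    EffectRule("occupational_seniority_years", 20.0, 4.0),
    EffectRule("vdt_hours_work", 4.0, 3.0),
    EffectRule("contact_lens_wearer", 0.5, 3.0),
    EffectRule("conjunctivitis_history", 0.5, 2.0),
    EffectRule("rotating_shifts_with_nights", 0.5, 2.0),
)

#: Base score level, calibrated once so that the default spec yields a
#: symptomatic fraction (score >= 6) near the reference study's 56.9%.
DEFAULT_BASE_LEVEL = 1.2


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions of the emulated study.

    Defaults match the reference cohort: 343 subjects, 255 predictors (250
    indicators + 5 continuous exposures), a 5-variable planted signal, and
    noise giving realistic score dispersion.
    """

    n_subjects: int = 343
    n_binary: int = 250
    n_continuous: int = 5
    effects: tuple[EffectRule, ...] = DEFAULT_EFFECTS
    base_level: float = DEFAULT_BASE_LEVEL
    noise_sd: float = 2.0
    score_clip: tuple[int, int] = (0, cvsq.MAX_SCORE)
    binary_prevalence_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    @property
    def n_informative(self) -> int:
        return len(self.effects)

    def __post_init__(self) -> None:
        if self.n_subjects < 5:
            raise ValueError("n_subjects must be >= 5")
        if self.n_continuous > len(CONTINUOUS_COLUMNS):
            raise ValueError(
                f"at most {len(CONTINUOUS_COLUMNS)} continuous columns supported"
            )
        if self.n_binary < len(NAMED_BINARY):
            raise ValueError("n_binary must cover the named indicator columns")
        if self.n_informative > self.n_binary + self.n_continuous:
            raise ValueError("more informative variables than predictors")
        lo, hi = self.score_clip
        if not 0 <= lo < hi:
            raise ValueError("invalid score_clip")
        names = set(CONTINUOUS_COLUMNS[: self.n_continuous]) | set(NAMED_BINARY)
        for rule in self.effects:
            if rule.variable not in names:
                raise ValueError(f"effect on unknown variable {rule.variable!r}")


@dataclass
class SyntheticCohort:
    table: CohortTable
    informative: tuple[str, ...]
    effects: tuple[EffectRule, ...]
    base_level: float
    noise_sd: float
    seed: int

    def ground_truth(self) -> dict:
        return {
            "informative": list(self.informative),
            "effects": [
                {"variable": r.variable, "threshold": r.threshold, "shift": r.shift}
                for r in self.effects
            ],
            "base_level": self.base_level,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }


def _continuous_block(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Right-skewed seniorities (years), bounded daily screen hours, age."""
    cols = []
    # occupational seniority: gamma matched to mean 18.5, sd 11.5
    shape = (18.5 / 11.5) ** 2
    cols.append(rng.gamma(shape, 18.5 / shape, size=n))
    # hospital-unit seniority: mean 11.2, sd 11.0
    shape_u = (11.2 / 11.0) ** 2
    cols.append(rng.gamma(shape_u, 11.2 / shape_u, size=n))
    # screen hours at work: ~5 +/- 2.2 h/day, clipped to [0, 12]
    cols.append(np.clip(rng.normal(5.0, 2.2, size=n), 0.0, 12.0))
    # screen hours outside work: ~1.4 +/- 1.2 h/day, clipped to [0, 8]
    cols.append(np.clip(rng.normal(1.4, 1.2, size=n), 0.0, 8.0))
    # age: 22-67 years
    cols.append(np.clip(rng.normal(46.9, 10.9, size=n), 22.0, 67.0))
    out = np.column_stack(cols[:k])
    return np.round(out, 2)


def generate(spec: SimulationSpec | None = None) -> SyntheticCohort:
    """Generate one cohort per the spec; deterministic under the seed."""
    spec = spec or SimulationSpec()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects

    cont_names = list(CONTINUOUS_COLUMNS[: spec.n_continuous])
    Xc = (
        _continuous_block(n, spec.n_continuous, rng)
        if spec.n_continuous
        else np.empty((n, 0))
    )

    named = list(NAMED_BINARY)
    n_noise = spec.n_binary - len(named)
    bin_names = named + [f"ind_{i:03d}" for i in range(n_noise)]
    lo, hi = spec.binary_prevalence_range
    prevalences = np.concatenate(
        [
            np.array([NAMED_BINARY[c] for c in named]),
            rng.uniform(lo, hi, size=n_noise),
        ]
    )
    Xb = (rng.random((n, spec.n_binary)) < prevalences).astype(np.float64)

    columns = tuple(cont_names + bin_names)
    kinds = tuple([CONTINUOUS] * len(cont_names) + [BINARY] * len(bin_names))
    X = np.column_stack([Xc, Xb]) if cont_names else Xb
    col_index = {c: j for j, c in enumerate(columns)}

    signal = np.full(n, spec.base_level, dtype=np.float64)
    for rule in spec.effects:
        signal += rule.shift * (X[:, col_index[rule.variable]] > rule.threshold)
    noise = rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else 0.0
    y = np.clip(np.round(signal + noise), *spec.score_clip).astype(np.int64)

    table = CohortTable(X=X, y=y, columns=columns, kinds=kinds)
    return SyntheticCohort(
        table=table,
        informative=tuple(r.variable for r in spec.effects),
        effects=spec.effects,
        base_level=spec.base_level,
        noise_sd=spec.noise_sd,
        seed=spec.seed,
    )


def recovery_family_spec(seed: int = 0) -> SimulationSpec:
    """The smaller cohort family used for planted-signal recovery studies:
    400 subjects, 60 predictors (55 indicators + 5 continuous), the default
    5-variable signal and noise level."""
    return SimulationSpec(n_subjects=400, n_binary=55, n_continuous=5, seed=seed)


def generate_questionnaires(
    scores: np.ndarray, seed: int = 0
) -> pd.DataFrame:
    """Decompose integer CVS-Q totals into per-item answers.

    Each score s in [0, 32] is written as 2a + b with a items of severity
    2 (frequency often/always, intensity intense) and b items of severity
    1; a is drawn uniformly from its feasible range, the items and the
    severity-1 answer variants are randomised.  Re-scoring the emitted
    answers reproduces the input totals exactly.
    """
    scores = np.asarray(scores, dtype=np.int64)
    if scores.min() < 0 or scores.max() > cvsq.MAX_SCORE:
        raise ValueError("scores must lie in [0, 32]")
    rng = np.random.default_rng(seed)
    n_items = len(cvsq.SYMPTOMS)
    sev1_variants = [(1, 1), (1, 2), (2, 1)]  # all recode to severity 1

    rows = []
    for s in scores:
        s = int(s)
        a_lo, a_hi = max(0, s - n_items), s // 2
        a = int(rng.integers(a_lo, a_hi + 1))
        b = s - 2 * a
        order = rng.permutation(n_items)
        answers: dict[str, int | float] = {}
        for rank, item_idx in enumerate(order):
            symptom = cvsq.SYMPTOMS[item_idx]
            if rank < a:
                freq, inten = 2, 2
            elif rank < a + b:
                freq, inten = sev1_variants[rng.integers(len(sev1_variants))]
            else:
                freq, inten = 0, 1
            answers[f"{symptom}_frequency"] = freq
            answers[f"{symptom}_intensity"] = inten
        answers["cvsq_score"] = s
        rows.append(answers)
    return pd.DataFrame(rows)


def generate_exclusion_roster(seed: int = 0) -> pd.DataFrame:
    """A synthetic respondent roster reproducing the study's exclusion
    accounting: 539 questionnaires, first-match rule counts 66/116/13/1,
    final sample 343.

    Ocular-disease sub-reasons are distributed over the 66 excluded
    subjects with deliberate comorbidity (the sub-reason totals sum to 91),
    and a few diseased subjects also trip later rules to exercise
    first-match attribution.
    """
    rng = np.random.default_rng(seed)
    n = RESPONDENTS
    frame = pd.DataFrame(
        {f"ocular_disease_{r}": np.zeros(n, dtype=bool) for r in OCULAR_DISEASE_SUBREASONS}
    )
    for flag in ("non_computer_user", "out_of_scope_occupation", "missing_seniority"):
        frame[flag] = np.zeros(n, dtype=bool)

    n_disease = EXCLUSION_COUNTS["ocular_disease"]
    # deal sub-reasons round-robin over the diseased block so every diseased
    # subject has >= 1 reason and totals match the published sub-counts
    slots = []
    for reason, count in OCULAR_DISEASE_SUBREASONS.items():
        slots.extend([reason] * count)
    rng.shuffle(slots)
    for i, reason in enumerate(slots):
        row = i % n_disease
        col = f"ocular_disease_{reason}"
        if frame.at[row, col]:
            # find another diseased row without this sub-reason
            free = np.flatnonzero(~frame[col].to_numpy()[:n_disease])
            row = int(rng.choice(free))
        frame.at[row, col] = True
    # comorbid overlap with later rules: first-match keeps them under disease
    frame.loc[: min(9, n_disease - 1), "non_computer_user"] = True

    start = n_disease
    frame.loc[start : start + EXCLUSION_COUNTS["non_computer_user"] - 1, "non_computer_user"] = True
    start += EXCLUSION_COUNTS["non_computer_user"]
    frame.loc[start : start + EXCLUSION_COUNTS["out_of_scope_occupation"] - 1, "out_of_scope_occupation"] = True
    start += EXCLUSION_COUNTS["out_of_scope_occupation"]
    frame.loc[start : start + EXCLUSION_COUNTS["missing_seniority"] - 1, "missing_seniority"] = True

    # shuffle rows so rule order, not row order, drives attribution
    frame = frame.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    frame.insert(0, "subject_id", np.arange(1, n + 1))
    return frame


def table1_fixture() -> pd.DataFrame:
    """The packaged stratified prevalence counts of the reference cohort."""
    return prevalence_fixture()
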