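"""Descriptive epidemiology: exclusion accounting and stratified prevalence.

Reproduces the reporting layer of a cross-sectional occupational-health
study exactly from counts: a response-rate / exclusion ledger (eligible
workers -> respondents -> analysable sample) and a stratified prevalence
table with chi-square association tests per grouping variable.

The association test is the Pearson chi-square without continuity
correction on the cases x strata contingency table; the continuity-
corrected variant is available behind a flag.  Percentages use half-up
rounding to match printed tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

#: Exclusion rules in application order; a record is attributed to the
#: first rule it trips.
EXCLUSION_RULES = (
    "ocular_disease",
    "non_computer_user",
    "out_of_scope_occupation",
    "missing_seniority",
)


def rate(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage with half-up rounding at the requested precision."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must be in [0, denominator]")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class ExclusionLedger:
    initial_count: int
    excluded: dict[str, int] = field(default_factory=dict)

    @property
    def total_excluded(self) -> int:
        return sum(self.excluded.values())

    @property
    def final_count(self) -> int:
        return self.initial_count - self.total_excluded

    def to_frame(self) -> pd.DataFrame:
        rows = [("initial", self.initial_count)]
        rows += [(rule, -count) for rule, count in self.excluded.items()]
        rows.append(("final", self.final_count))
        return pd.DataFrame(rows, columns=["step", "count"])


def _rule_flags(records: pd.DataFrame, rule: str) -> pd.Series:
    """Eligibility flag for one rule; sub-reason columns (``rule_*``) are
    OR-ed together, so a record with several comorbid sub-reasons still
    counts once."""
    if rule in records.columns:
        return records[rule].astype(bool)
    sub = [c for c in records.columns if c.startswith(f"{rule}_")]
    if not sub:
        raise ValueError(f"records lack the eligibility flag {rule!r}")
    return records[sub].astype(bool).any(axis=1)


def apply_exclusions(records: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionLedger]:
    """Filter a respondent roster, attributing each exclusion to the first
    rule it trips (rules applied in the published order)."""
    remaining = pd.Series(True, index=records.index)
    ledger = ExclusionLedger(initial_count=len(records))
    for rule in EXCLUSION_RULES:
        tripped = _rule_flags(records, rule) & remaining
        ledger.excluded[rule] = int(tripped.sum())
        remaining &= ~tripped
    return records[remaining].copy(), ledger


def chi_square(counts: np.ndarray, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square statistic and p-value for a strata x 2 table.

    ``counts`` rows are strata, columns are (cases, non-cases).  By
    default no continuity correction is applied (even for 2 x 2 tables),
    matching the convention reverse-engineered from the reference study's
    printed p-values.
    """
    counts = np.asarray(counts, dtype=np.float64)
    stat, p, _, _ = stats.chi2_contingency(counts, correction=correction)
    return float(stat), float(p)


def prevalence_table(
    frame: pd.DataFrame,
    grouping_variables: list[str],
    case_column: str = "cvs_case",
    correction: bool = False,
) -> pd.DataFrame:
    """Stratified prevalence with one chi-square test per grouping variable.

    One row per stratum: n_subjects, n_cases, prevalence percent (1
    decimal, half-up), the grouping variable's p-value (repeated on each
    of its rows) and a ``low_expected`` flag raised when any expected cell
    count is < 5 (the chi-square approximation is then doubtful).
    """
    if case_column not in frame.columns:
        raise ValueError(f"missing case column {case_column!r}")
    cases = frame[case_column].astype(int)
    if not cases.isin((0, 1)).all():
        raise ValueError("case column must be 0/1")
    rows = [
        {
            "variable": "overall",
            "stratum": "all",
            "n_subjects": len(frame),
            "n_cases": int(cases.sum()),
            "prevalence_pct": rate(int(cases.sum()), len(frame)) if len(frame) else np.nan,
            "p_value": np.nan,
            "low_expected": False,
        }
    ]
    for var in grouping_variables:
        if var not in frame.columns:
            raise ValueError(f"missing grouping variable {var!r}")
        strata = frame.groupby(var, sort=True)[case_column].agg(["size", "sum"])
        counts = np.column_stack([strata["sum"], strata["size"] - strata["sum"]])
        nonzero = counts.sum(axis=1) > 0
        if nonzero.sum() >= 2 and counts[nonzero].sum(axis=0).min() > 0:
            stat, p = chi_square(counts[nonzero], correction=correction)
            expected = stats.contingency.expected_freq(counts[nonzero])
            low_expected = bool((expected < 5).any())
        else:
            p, low_expected = np.nan, True
        for stratum, row in strata.iterrows():
            n_s, n_c = int(row["size"]), int(row["sum"])
            rows.append(
                {
                    "variable": var,
                    "stratum": stratum,
                    "n_subjects": n_s,
                    "n_cases": n_c,
                    "prevalence_pct": rate(n_c, n_s) if n_s else np.nan,
                    "p_value": p,
                    "low_expected": low_expected,
                }
            )
    return pd.DataFrame(rows)


def prevalence_from_counts(fixture: pd.DataFrame, correction: bool = False) -> pd.DataFrame:
    """Prevalence report computed from a pre-aggregated count table.

    ``fixture`` needs columns variable / stratum / n_subjects / n_cases
    (the packaged reference-study layout).  Percentages and chi-square
    tests are recomputed from the counts; an overall row (whole-cohort
    prevalence) leads the report.
    """
    first = fixture[fixture["variable"] == fixture["variable"].iloc[0]]
    n_total = int(first["n_subjects"].sum())
    n_cases_total = int(first["n_cases"].sum())
    rows = [
        {
            "variable": "overall",
            "stratum": "all",
            "n_subjects": n_total,
            "n_cases": n_cases_total,
            "prevalence_pct": rate(n_cases_total, n_total),
            "p_value": np.nan,
            "low_expected": False,
        }
    ]
    for var, block in fixture.groupby("variable", sort=False):
        counts = np.column_stack(
            [block["n_cases"], block["n_subjects"] - block["n_cases"]]
        )
        if len(block) >= 2 and counts.sum(axis=0).min() > 0:
            stat, p = chi_square(counts, correction=correction)
            expected = stats.contingency.expected_freq(counts)
            low_expected = bool((expected < 5).any())
        else:
            p, low_expected = np.nan, True
        for _, row in block.iterrows():
            rows.append(
                {
                    "variable": var,
                    "stratum": row["stratum"],
                    "n_subjects": int(row["n_subjects"]),
                    "n_cases": int(row["n_cases"]),
                    "prevalence_pct": rate(int(row["n_cases"]), int(row["n_subjects"])),
                    "p_value": p,
                    "low_expected": low_expected,
                }
            )
    return pd.DataFrame(rows)
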