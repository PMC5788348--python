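"""Validation of suggested mutations against experimental ΔT records.

A suggested substitution is matched to thermal-denaturation measurements by
(wild type, position, mutant).  A matched suggestion is successful when its
measured melting-temperature change ΔT is positive and failed otherwise
(ΔT = 0 counts as failure: no improvement).  The success rate is computed
over distinct mutations, not over pattern-hit rows — the same substitution
suggested via many patterns is still one experimental outcome; the per-row
rate is also reported for transparency.

Some mutations carry several, occasionally contradictory, records.  The
conflict policy decides the call:

* ``conservative`` (default) — any non-positive record makes the suggestion a
  failure;
* ``first`` — the first record in table order decides;
* ``mean`` — the sign of the mean ΔT decides.

Every mutation with records of opposing outcome is surfaced in the report's
``conflicts`` listing regardless of policy.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from .mutation_suggest import SuggestionList
from .seq_data import DeltaTRecord, parse_mutation

__all__ = [
    "SuccessReport",
    "evaluate_suggestions",
    "summarize_report",
    "write_report_tsv",
]

ConflictPolicy = Literal["conservative", "first", "mean"]


@dataclass
class SuccessReport:
    """Outcome of joining suggestions with ΔT records."""

    n_suggested: int
    n_matched: int
    n_success: int
    n_fail: int
    unmatched: list[str] = field(default_factory=list)
    conflicts: dict[str, list[float]] = field(default_factory=dict)
    outcomes: dict[str, tuple[str, list[float]]] = field(default_factory=dict)
    n_record_rows: int = 0
    n_record_rows_positive: int = 0

    def __post_init__(self) -> None:
        if self.n_success + self.n_fail != self.n_matched:
            raise ValueError("n_success + n_fail must equal n_matched")
        if self.n_matched > self.n_suggested:
            raise ValueError("n_matched cannot exceed n_suggested")

    @property
    def success_rate(self) -> float | None:
        """Percent of matched suggestions that are successful; None when no
        suggestion matched a record."""
        if self.n_matched == 0:
            return None
        return 100.0 * self.n_success / self.n_matched

    @property
    def per_record_success_rate(self) -> float | None:
        """Percent of matched (suggestion, record) rows with positive ΔT."""
        if self.n_record_rows == 0:
            return None
        return 100.0 * self.n_record_rows_positive / self.n_record_rows

    def to_dict(self) -> dict:
        return {
            "n_suggested": self.n_suggested,
            "n_matched": self.n_matched,
            "n_success": self.n_success,
            "n_fail": self.n_fail,
            "success_rate_percent": self.success_rate,
            "success_rate_percent_rounded": (
                None if self.success_rate is None else round(self.success_rate)
            ),
            "per_record_success_rate_percent": self.per_record_success_rate,
            "unmatched": list(self.unmatched),
            "conflicts": {m: list(v) for m, v in self.conflicts.items()},
        }


def _mutation_keys(suggestions) -> list[tuple[str, int, str]]:
    """Distinct (wt, pos, mut) keys, input order preserved."""
    keys: list[tuple[str, int, str]] = []
    seen = set()
    if isinstance(suggestions, SuggestionList):
        items: Iterable = (
            (s.wild_type, s.position, s.mutant) for s in suggestions
        )
    else:
        items = (
            parse_mutation(s) if isinstance(s, str) else tuple(s)
            for s in suggestions
        )
    for key in items:
        if key not in seen:
            seen.add(key)
            keys.append(key)  # type: ignore[arg-type]
    return keys


def evaluate_suggestions(
    suggestions,
    records: Sequence[DeltaTRecord],
    conflict_policy: ConflictPolicy = "conservative",
) -> SuccessReport:
    """Join suggestions with ΔT records and score them.

    Parameters
    ----------
    suggestions : SuggestionList, or iterable of mutation strings / (wt, pos,
        mut) triples.  Duplicates are collapsed.
    records : experimental ΔT measurements.
    conflict_policy : {"conservative", "first", "mean"}
        How multiple records for one mutation are resolved (see module docs).
    """
    if conflict_policy not in ("conservative", "first", "mean"):
        raise ValueError(f"unknown conflict policy {conflict_policy!r}")
    keys = _mutation_keys(suggestions)

    by_mutation: dict[tuple[str, int, str], list[float]] = {}
    for rec in records:
        by_mutation.setdefault((rec.wild_type, rec.position, rec.mutant), []).append(
            rec.delta_t
        )

    n_success = n_fail = 0
    n_rows = n_rows_pos = 0
    unmatched: list[str] = []
    conflicts: dict[str, list[float]] = {}
    outcomes: dict[str, tuple[str, list[float]]] = {}
    for key in keys:
        wt, pos, mut = key
        name = f"{wt}{pos}{mut}"
        values = by_mutation.get(key)
        if not values:
            unmatched.append(name)
            continue
        n_rows += len(values)
        n_rows_pos += sum(1 for v in values if v > 0)
        row_outcomes = {v > 0 for v in values}
        if len(row_outcomes) > 1:
            conflicts[name] = list(values)
        if conflict_policy == "conservative":
            success = all(v > 0 for v in values)
        elif conflict_policy == "first":
            success = values[0] > 0
        else:  # mean
            success = (sum(values) / len(values)) > 0
        if success:
            n_success += 1
        else:
            n_fail += 1
        outcomes[name] = ("success" if success else "fail", list(values))

    return SuccessReport(
        n_suggested=len(keys),
        n_matched=n_success + n_fail,
        n_success=n_success,
        n_fail=n_fail,
        unmatched=unmatched,
        conflicts=conflicts,
        outcomes=outcomes,
        n_record_rows=n_rows,
        n_record_rows_positive=n_rows_pos,
    )


def summarize_report(report: SuccessReport) -> str:
    """Human-readable multi-line summary of a SuccessReport."""
    lines = [
        f"suggested mutations (distinct): {report.n_suggested}",
        f"matched to a ΔT record:         {report.n_matched}",
        f"successful (ΔT > 0):            {report.n_success}",
        f"failed (ΔT <= 0):               {report.n_fail}",
    ]
    if report.success_rate is None:
        lines.append("success rate: undefined (no suggestion matched a record)")
    else:
        lines.append(
            f"success rate: {report.success_rate:.1f}% "
            f"({round(report.success_rate)}% nearest integer)"
        )
        if report.per_record_success_rate is not None:
            lines.append(
                f"per-record success rate: {report.per_record_success_rate:.1f}%"
            )
    if report.conflicts:
        lines.append("conflicting records:")
        for name, values in report.conflicts.items():
            lines.append(f"  {name}: ΔT = {values}")
    if report.unmatched:
        lines.append(f"unmatched suggestions ({len(report.unmatched)}):")
        lines.append("  " + " ".join(report.unmatched))
    return "\n".join(lines)


def write_report_tsv(report: SuccessReport, path: str | Path) -> None:
    """Write per-mutation outcomes as TSV (mutation, delta_t, outcome)."""
    rows = []
    for name, (outcome, values) in report.outcomes.items():
        for v in values:
            rows.append({"mutation": name, "delta_t": v, "outcome": outcome})
    for name in report.unmatched:
        rows.append({"mutation": name, "delta_t": math.nan, "outcome": "unmatched"})
    pd.DataFrame(rows, columns=["mutation", "delta_t", "outcome"]).to_csv(
        path, sep="\t", index=False
    )


def write_report_json(report: SuccessReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2) + "\n")
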