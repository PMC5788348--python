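"""Point-mutation suggestion from thermophilic-enriched patterns.

Given the screened pattern statistics of a family, every significant pattern
AXB whose mean count is higher in the thermophilic group drives two scans of
the target sequence:

* AXY sites — the first residue A is in place at position i and the residue
  at i + X + 1 is some Y ≠ B: suggest Y → B at position i + X + 1;
* ZXB sites — the second residue B is in place at i + X + 1 and the residue
  at i is some Z ≠ A: suggest Z → A at position i.

Each suggested substitution therefore completes at least one occurrence of a
thermophilic-enriched pattern.  The same substitution often arises from many
patterns; suggestions are unique by (position, wild type, mutant) with all
supporting (pattern, anchor, side) evidence merged, and are reported sorted
by their best supporting p-value, then position.  Positions holding
ambiguity codes are never anchors and never mutation sites.  No structural
or conservation filter is applied: the procedure is purely sequence-driven.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd
from sklearn.base import BaseEstimator

from .pattern_count import PatternKey
from .pattern_screen import PatternScreen, PatternStat
from .seq_data import STANDARD_AA_INDEX, format_mutation

__all__ = [
    "Support",
    "MutationSuggestion",
    "SuggestionList",
    "suggest_mutations",
    "apply_mutation",
    "MutationSuggester",
    "write_suggestions_tsv",
    "read_suggestions_tsv",
]

Side = Literal["AXY", "ZXB"]


@dataclass(frozen=True)
class Support:
    """One pattern occurrence-to-be backing a suggestion.

    ``anchor_position`` (1-based) is where the already-present pattern
    residue sits: the first residue A for an AXY site, the second residue B
    for a ZXB site.  ``p_value`` is the supporting pattern's screening
    p-value.
    """

    pattern: PatternKey
    anchor_position: int
    side: Side
    p_value: float


@dataclass
class MutationSuggestion:
    """A proposed single-residue substitution with its pattern evidence."""

    position: int  # 1-based
    wild_type: str
    mutant: str
    support: list[Support] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.wild_type == self.mutant:
            raise ValueError(
                f"degenerate suggestion at position {self.position}: "
                "wild type equals mutant"
            )
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if not self.support:
            raise ValueError("a suggestion requires at least one support entry")

    @property
    def mutation(self) -> str:
        return format_mutation(self.wild_type, self.position, self.mutant)

    @property
    def best_p_value(self) -> float:
        return min(s.p_value for s in self.support)

    def key(self) -> tuple[int, str, str]:
        return (self.position, self.wild_type, self.mutant)


@dataclass
class SuggestionList:
    """Deduplicated suggestions for one target sequence."""

    target_id: str
    suggestions: list[MutationSuggestion] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [s.key() for s in self.suggestions]
        if len(keys) != len(set(keys)):
            raise ValueError("suggestions are not deduplicated by (pos, wt, mut)")

    def __len__(self) -> int:
        return len(self.suggestions)

    def __iter__(self):
        return iter(self.suggestions)

    def mutations(self) -> list[str]:
        return [s.mutation for s in self.suggestions]


def _enriched_stats(stats, alpha: float) -> list[tuple[PatternKey, float]]:
    """Extract (pattern, p_value) pairs with p < alpha and ave_the > ave_mes."""
    if isinstance(stats, PatternScreen):
        stats = stats.stats()
    if isinstance(stats, pd.DataFrame):
        records = [
            PatternStat(
                PatternKey.from_string(str(row["pattern"])),
                float(row["p_value"]),
                float(row["ave_the"]),
                float(row["ave_mes"]),
            )
            for _, row in stats.iterrows()
        ]
    else:
        records = list(stats)
    return [
        (s.pattern, s.p_value)
        for s in records
        if s.p_value < alpha and s.ave_the > s.ave_mes
    ]


def suggest_mutations(
    target: str,
    stats,
    alpha: float = 0.05,
    target_id: str = "target",
) -> SuggestionList:
    """Generate stabilizing point-mutation suggestions for a target sequence.

    Parameters
    ----------
    target : str
        Residue string of the protein to engineer (ambiguity codes allowed;
        they are inert).
    stats : PatternScreen, DataFrame or iterable of PatternStat
        Screened pattern statistics carrying p_value, ave_the, ave_mes.
    alpha : float, default 0.05
        Significance cut applied to the supporting p-values.

    Returns
    -------
    SuggestionList
        Unique (position, wild type, mutant) suggestions with merged support,
        sorted by best supporting p-value then position.
    """
    if not target:
        raise ValueError("target sequence is empty")
    target = target.upper()
    bad = sorted(set(target) - set("ACDEFGHIKLMNPQRSTVWYBJOUXZ"))
    if bad:
        raise ValueError(f"target contains invalid residue code(s): {bad}")

    enriched = _enriched_stats(stats, alpha)
    found: dict[tuple[int, str, str], MutationSuggestion] = {}
    L = len(target)
    for pattern, p_value in enriched:
        step = pattern.spacing + 1
        for i in range(L - step):
            left, right = target[i], target[i + step]
            left_std = left in STANDARD_AA_INDEX
            right_std = right in STANDARD_AA_INDEX
            # AXY: A in place at i, Y != B at i + X + 1 -> Y -> B
            if left == pattern.first and right_std and right != pattern.second:
                _add(
                    found,
                    position=i + step + 1,
                    wild_type=right,
                    mutant=pattern.second,
                    support=Support(pattern, i + 1, "AXY", p_value),
                )
            # ZXB: B in place at i + X + 1, Z != A at i -> Z -> A
            if right == pattern.second and left_std and left != pattern.first:
                _add(
                    found,
                    position=i + 1,
                    wild_type=left,
                    mutant=pattern.first,
                    support=Support(pattern, i + step + 1, "ZXB", p_value),
                )
    ordered = sorted(found.values(), key=lambda s: (s.best_p_value, s.position, s.mutant))
    return SuggestionList(target_id=target_id, suggestions=ordered)


def _add(
    found: dict,
    position: int,
    wild_type: str,
    mutant: str,
    support: Support,
) -> None:
    key = (position, wild_type, mutant)
    if key in found:
        found[key].support.append(support)
    else:
        found[key] = MutationSuggestion(position, wild_type, mutant, [support])


def apply_mutation(target: str, suggestion: MutationSuggestion) -> str:
    """Apply a single suggested substitution to the target sequence.

    Verifies the wild-type residue at the suggested position before
    substituting, guarding against coordinate bugs.
    """
    pos = suggestion.position
    if not 1 <= pos <= len(target):
        raise ValueError(
            f"position {pos} outside target of length {len(target)}"
        )
    if target[pos - 1].upper() != suggestion.wild_type:
        raise ValueError(
            f"wild-type mismatch at position {pos}: target has "
            f"{target[pos - 1]!r}, suggestion expects {suggestion.wild_type!r}"
        )
    return target[: pos - 1] + suggestion.mutant + target[pos:]


class MutationSuggester(BaseEstimator):
    """End-to-end suggester: screen a labelled family, then propose mutations.

    Composes :class:`PatternScreen` with the AXY/ZXB scan.  ``fit`` learns
    the thermophilic-enriched patterns from labelled family sequences;
    ``suggest`` (or ``predict``) scans one target sequence.

    Parameters mirror :class:`PatternScreen`.

    Attributes
    ----------
    screen_ : PatternScreen
        The fitted screen.
    enriched_ : list of (PatternKey, p_value)
        Significant thermophilic-enriched patterns used by the scan.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        max_spacing: int = 10,
        min_group_size: int = 20,
        correction: str = "none",
    ):
        self.alpha = alpha
        self.max_spacing = max_spacing
        self.min_group_size = min_group_size
        self.correction = correction

    def fit(self, X, y=None, force: bool = False) -> "MutationSuggester":
        self.screen_ = PatternScreen(
            alpha=self.alpha,
            max_spacing=self.max_spacing,
            min_group_size=self.min_group_size,
            correction=self.correction,
        ).fit(X, y, force=force)
        self.enriched_ = _enriched_stats(self.screen_, self.alpha)
        return self

    def suggest(self, target: str, target_id: str = "target") -> SuggestionList:
        if not hasattr(self, "screen_"):
            raise ValueError("MutationSuggester is not fitted yet")
        return suggest_mutations(
            target, self.screen_, alpha=self.alpha, target_id=target_id
        )

    def predict(self, X: Sequence[str]) -> list[SuggestionList]:
        """Suggestion lists for a batch of target sequences."""
        return [self.suggest(t, target_id=f"target_{i}") for i, t in enumerate(X)]


def write_suggestions_tsv(suggestions: SuggestionList, path: str | Path) -> None:
    """Write suggestions with one row per supporting pattern occurrence.

    Columns: pattern, anchor_position, side, mutation, p_value — the layout
    pairs each pattern hit with the substitution it supports.
    """
    rows = [
        {
            "pattern": str(sup.pattern),
            "anchor_position": sup.anchor_position,
            "side": sup.side,
            "mutation": s.mutation,
            "p_value": sup.p_value,
        }
        for s in suggestions
        for sup in s.support
    ]
    pd.DataFrame(
        rows, columns=["pattern", "anchor_position", "side", "mutation", "p_value"]
    ).to_csv(path, sep="\t", index=False)


def read_suggestions_tsv(path: str | Path, target_id: str = "target") -> SuggestionList:
    """Re-assemble a SuggestionList from its TSV form."""
    # "NA" is a valid pattern string, not a missing value
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
    if df.empty:
        return SuggestionList(target_id=target_id, suggestions=[])
    from .seq_data import parse_mutation

    found: dict = {}
    for _, row in df.iterrows():
        wt, pos, mut = parse_mutation(str(row["mutation"]))
        _add(
            found,
            position=pos,
            wild_type=wt,
            mutant=mut,
            support=Support(
                PatternKey.from_string(str(row["pattern"])),
                int(row["anchor_position"]),
                str(row["side"]),
                float(row.get("p_value", float("nan"))),
            ),
        )
    ordered = sorted(found.values(), key=lambda s: (s.best_p_value, s.position, s.mutant))
    return SuggestionList(target_id=target_id, suggestions=ordered)
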