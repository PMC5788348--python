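"""Gapped residue-pair (AXB) pattern enumeration and counting.

An AXB pattern is an ordered pair of standard amino acids A and B separated
by exactly X intervening residues, X = 0..max_spacing (default 10): "ER"
(≡ E0R) matches adjacent E then R, "A1V" matches A, any residue, V.  With 20
standard residues and 11 spacings the full grid holds 4,400 patterns.

Counting conventions:

* all ordered index pairs (i, i + X + 1) are counted, so overlapping and
  self-overlapping occurrences each count ("AAA" has A0A = 2);
* a window whose two residues are not both standard (ambiguity codes
  B, J, O, U, X, Z) matches no pattern;
* counts are raw per-sequence occurrence numbers — no length normalization
  by default (an optional per-window normalization divides by L − X − 1).

For all-standard sequences of length L the counts at fixed spacing X sum to
L − X − 1 over the 400 residue pairs, which makes the raw convention easy to
audit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .seq_data import STANDARD_AA, STANDARD_AA_INDEX, LabeledSequence

__all__ = [
    "PatternKey",
    "PatternCountVector",
    "pattern_grid",
    "count_pattern",
    "count_all_patterns",
    "count_matrix",
    "GappedPairCounter",
    "counts_to_wide_tsv",
    "counts_to_sparse_tsv",
]

DEFAULT_MAX_SPACING = 10

_PATTERN_RE = re.compile(r"^([A-Z])(\d*)([A-Z])$")


@dataclass(frozen=True, order=True)
class PatternKey:
    """An (A, X, B) gapped residue pair.

    ``first`` and ``second`` are standard one-letter residue codes and
    ``spacing`` the number of intervening residues.  The canonical string
    form is ``"ER"`` for spacing 0 and ``"E1R"`` / ``"E10R"`` otherwise.
    """

    first: str
    spacing: int
    second: str

    def __post_init__(self) -> None:
        if self.first not in STANDARD_AA_INDEX:
            raise ValueError(f"first residue {self.first!r} is not standard")
        if self.second not in STANDARD_AA_INDEX:
            raise ValueError(f"second residue {self.second!r} is not standard")
        if self.spacing < 0:
            raise ValueError(f"spacing must be >= 0, got {self.spacing}")

    def __str__(self) -> str:
        if self.spacing == 0:
            return f"{self.first}{self.second}"
        return f"{self.first}{self.spacing}{self.second}"

    @classmethod
    def from_string(cls, token: str) -> "PatternKey":
        m = _PATTERN_RE.match(token.strip().upper())
        if not m:
            raise ValueError(f"unparsable pattern string {token!r}")
        first, digits, second = m.groups()
        return cls(first=first, spacing=int(digits) if digits else 0, second=second)


def pattern_grid(max_spacing: int = DEFAULT_MAX_SPACING) -> list[PatternKey]:
    """The full pattern grid in (spacing, first, second) order.

    This ordering matches the columns produced by :func:`count_all_patterns`
    and :class:`GappedPairCounter`.
    """
    if max_spacing < 0:
        raise ValueError(f"max_spacing must be >= 0, got {max_spacing}")
    return [
        PatternKey(a, x, b)
        for x in range(max_spacing + 1)
        for a in STANDARD_AA
        for b in STANDARD_AA
    ]


def encode_residues(residues: str) -> np.ndarray:
    """Encode residues as integers 0..19; ambiguity codes become −1."""
    return np.array(
        [STANDARD_AA_INDEX.get(c, -1) for c in residues], dtype=np.int64
    )


def count_pattern(residues: str, pattern: PatternKey) -> int:
    """Count occurrences of one AXB pattern in a sequence.

    Counts every index pair (i, i + spacing + 1) with the first residue at i
    and the second at i + spacing + 1; occurrences may overlap.
    """
    if not isinstance(pattern, PatternKey):
        pattern = PatternKey.from_string(str(pattern))
    step = pattern.spacing + 1
    if len(residues) <= step:
        return 0
    enc = encode_residues(residues.upper())
    a = STANDARD_AA_INDEX[pattern.first]
    b = STANDARD_AA_INDEX[pattern.second]
    return int(np.count_nonzero((enc[:-step] == a) & (enc[step:] == b)))


def _count_row(enc: np.ndarray, max_spacing: int) -> np.ndarray:
    """Counts over the full grid for one encoded sequence.

    Returns a flat array of length 400 × (max_spacing + 1) in
    (spacing, first, second) order.
    """
    n_sp = max_spacing + 1
    out = np.zeros(400 * n_sp, dtype=np.int64)
    for x in range(n_sp):
        step = x + 1
        if len(enc) <= step:
            continue
        a, b = enc[:-step], enc[step:]
        mask = (a >= 0) & (b >= 0)
        if mask.any():
            out[x * 400 : (x + 1) * 400] = np.bincount(
                a[mask] * 20 + b[mask], minlength=400
            )
    return out


class PatternCountVector:
    """Per-sequence counts over the full AXB grid.

    Supports lookup by :class:`PatternKey` or canonical pattern string, and
    exposes the flat numpy array via :attr:`values` (grid order: spacing
    outermost, then first, then second residue).
    """

    def __init__(self, values: np.ndarray, sequence_length: int, max_spacing: int):
        self.values = values
        self.sequence_length = sequence_length
        self.max_spacing = max_spacing

    def __getitem__(self, pattern: PatternKey | str) -> int:
        if not isinstance(pattern, PatternKey):
            pattern = PatternKey.from_string(pattern)
        if pattern.spacing > self.max_spacing:
            raise KeyError(f"pattern {pattern} exceeds max_spacing {self.max_spacing}")
        idx = (
            pattern.spacing * 400
            + STANDARD_AA_INDEX[pattern.first] * 20
            + STANDARD_AA_INDEX[pattern.second]
        )
        return int(self.values[idx])

    def __len__(self) -> int:
        return len(self.values)

    def to_dict(self) -> dict[PatternKey, int]:
        return {
            key: int(v)
            for key, v in zip(pattern_grid(self.max_spacing), self.values)
        }

    def spacing_totals(self) -> np.ndarray:
        """Total count per spacing (length max_spacing + 1)."""
        return self.values.reshape(self.max_spacing + 1, 400).sum(axis=1)


def count_all_patterns(
    residues: str, max_spacing: int = DEFAULT_MAX_SPACING
) -> PatternCountVector:
    """Count all AXB patterns of a sequence over the full grid."""
    if max_spacing < 0:
        raise ValueError(f"max_spacing must be >= 0, got {max_spacing}")
    if not residues:
        raise ValueError("cannot count patterns of an empty sequence")
    enc = encode_residues(residues.upper())
    return PatternCountVector(_count_row(enc, max_spacing), len(residues), max_spacing)


def count_matrix(
    sequences: Sequence[LabeledSequence | tuple[str, str] | str],
    max_spacing: int = DEFAULT_MAX_SPACING,
) -> list[PatternCountVector]:
    """Count patterns for a collection of sequences, order preserved."""
    vectors = []
    for i, seq in enumerate(sequences):
        residues, sid = _residues_of(seq, i)
        try:
            vectors.append(count_all_patterns(residues, max_spacing))
        except ValueError as exc:
            raise ValueError(f"sequence {sid}: {exc}") from exc
    return vectors


def _residues_of(seq, index: int) -> tuple[str, str]:
    if isinstance(seq, LabeledSequence):
        return seq.residues, repr(seq.id)
    if isinstance(seq, tuple):
        return seq[1], repr(seq[0])
    return str(seq), f"#{index}"


class GappedPairCounter(TransformerMixin, BaseEstimator):
    """Vectorize protein sequences into AXB pattern-count features.

    A stateless transformer in the spirit of ``CountVectorizer``: each
    sequence maps to a row of 400 × (max_spacing + 1) raw occurrence counts
    over the gapped residue-pair grid.

    Parameters
    ----------
    max_spacing : int, default 10
        Largest number of intervening residues X considered (inclusive).
    normalize : bool, default False
        If true, divide counts at spacing X by the number of windows
        L − X − 1 (zero rows where no window exists).

    Attributes
    ----------
    patterns_ : list of PatternKey
        Column keys of the transformed matrix, set by :meth:`fit`.
    """

    def __init__(self, max_spacing: int = DEFAULT_MAX_SPACING, normalize: bool = False):
        self.max_spacing = max_spacing
        self.normalize = normalize

    def fit(self, X: Sequence, y=None) -> "GappedPairCounter":
        if self.max_spacing < 0:
            raise ValueError(f"max_spacing must be >= 0, got {self.max_spacing}")
        self.patterns_ = pattern_grid(self.max_spacing)
        return self

    def transform(self, X: Sequence) -> np.ndarray:
        if not hasattr(self, "patterns_"):
            self.fit(X)
        rows = np.zeros((len(X), 400 * (self.max_spacing + 1)), dtype=float)
        for i, seq in enumerate(X):
            residues, sid = _residues_of(seq, i)
            if not residues:
                raise ValueError(f"sequence {sid}: empty residue string")
            enc = encode_residues(residues.upper())
            row = _count_row(enc, self.max_spacing).astype(float)
            if self.normalize:
                L = len(residues)
                for x in range(self.max_spacing + 1):
                    windows = L - x - 1
                    if windows > 0:
                        row[x * 400 : (x + 1) * 400] /= windows
            rows[i] = row
        return rows

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        if not hasattr(self, "patterns_"):
            self.fit([])
        return np.array([str(p) for p in self.patterns_], dtype=object)


def counts_to_wide_tsv(
    ids: Iterable[str],
    vectors: Sequence[PatternCountVector],
    path: str | Path,
) -> None:
    """Write counts as a wide TSV: rows = sequences, columns = patterns."""
    if not vectors:
        pd.DataFrame(index=pd.Index([], name="id")).to_csv(path, sep="\t")
        return
    columns = [str(p) for p in pattern_grid(vectors[0].max_spacing)]
    df = pd.DataFrame(
        np.vstack([v.values for v in vectors]),
        index=pd.Index(list(ids), name="id"),
        columns=columns,
    )
    df.to_csv(path, sep="\t")


def counts_to_sparse_tsv(
    ids: Iterable[str],
    vectors: Sequence[PatternCountVector],
    path: str | Path,
) -> None:
    """Write non-zero counts as a three-column TSV (id, pattern, count)."""
    rows = []
    for sid, vec in zip(ids, vectors):
        grid = pattern_grid(vec.max_spacing)
        nz = np.nonzero(vec.values)[0]
        rows.extend(
            {"sequence_id": sid, "pattern": str(grid[j]), "count": int(vec.values[j])}
            for j in nz
        )
    pd.DataFrame(rows, columns=["sequence_id", "pattern", "count"]).to_csv(
        path, sep="\t", index=False
    )
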