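"""Sequence and table I/O, alphabet validation, and growth-temperature
classification.

Microorganisms are binned by optimal growth temperature (GT) into three
thermostability categories — psychrophilic (GT < 20 °C), mesophilic
(20 °C ≤ GT ≤ 40 °C) and thermophilic (GT > 40 °C) — and each of their
proteins inherits the organism's category.  Sequences from one protein
family (e.g. one Pfam accession) labelled this way form a
:class:`SequenceFamily`, the unit on which pattern screening operates.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "STANDARD_AA",
    "AMBIGUITY_AA",
    "ALPHABET",
    "ThermoCategory",
    "LabeledSequence",
    "SequenceFamily",
    "DeltaTRecord",
    "classify_growth_temperature",
    "read_fasta",
    "write_fasta",
    "read_labels",
    "read_delta_t_table",
    "parse_mutation",
    "format_mutation",
    "assemble_family",
]

#: The 20 standard one-letter amino-acid codes.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: Ambiguity / non-standard codes tolerated in input sequences.  They are
#: accepted (real UniProt entries contain them) but never participate in
#: pattern windows or mutation sites.
AMBIGUITY_AA = "BJOUXZ"
ALPHABET = frozenset(STANDARD_AA + AMBIGUITY_AA)

STANDARD_AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}


class ThermoCategory(enum.Enum):
    """Thermostability category of an organism (and, by proxy, its proteins).

    The ordering psychrophilic < mesophilic < thermophilic follows growth
    temperature and is used for reporting.
    """

    PSYCHROPHILIC = "psychrophilic"
    MESOPHILIC = "mesophilic"
    THERMOPHILIC = "thermophilic"

    def __lt__(self, other: "ThermoCategory") -> bool:
        if not isinstance(other, ThermoCategory):
            return NotImplemented
        return _CATEGORY_ORDER[self] < _CATEGORY_ORDER[other]

    def __le__(self, other: "ThermoCategory") -> bool:
        if not isinstance(other, ThermoCategory):
            return NotImplemented
        return _CATEGORY_ORDER[self] <= _CATEGORY_ORDER[other]

    def __gt__(self, other: "ThermoCategory") -> bool:
        if not isinstance(other, ThermoCategory):
            return NotImplemented
        return _CATEGORY_ORDER[self] > _CATEGORY_ORDER[other]

    def __ge__(self, other: "ThermoCategory") -> bool:
        if not isinstance(other, ThermoCategory):
            return NotImplemented
        return _CATEGORY_ORDER[self] >= _CATEGORY_ORDER[other]

    @classmethod
    def from_string(cls, token: str) -> "ThermoCategory":
        try:
            return cls(token.strip().lower())
        except ValueError:
            raise ValueError(
                f"unknown thermostability category {token!r}; expected one of "
                f"{[c.value for c in cls]}"
            ) from None


_CATEGORY_ORDER = {
    ThermoCategory.PSYCHROPHILIC: 0,
    ThermoCategory.MESOPHILIC: 1,
    ThermoCategory.THERMOPHILIC: 2,
}


def classify_growth_temperature(gt: float) -> ThermoCategory:
    """Map an optimal growth temperature in °C to a thermostability category.

    Psychrophilic below 20 °C, thermophilic above 40 °C, mesophilic otherwise.
    The boundary values 20 and 40 are assigned to the mesophilic (closed)
    interval.

    Raises
    ------
    ValueError
        If ``gt`` is not a finite real number.
    """
    gt = float(gt)
    if not math.isfinite(gt):
        raise ValueError(f"growth temperature must be finite, got {gt!r}")
    if gt < 20.0:
        return ThermoCategory.PSYCHROPHILIC
    if gt > 40.0:
        return ThermoCategory.THERMOPHILIC
    return ThermoCategory.MESOPHILIC


def _validate_residues(residues: str, context: str = "sequence") -> str:
    if not residues:
        raise ValueError(f"{context}: residue string is empty")
    residues = residues.upper()
    bad = sorted(set(residues) - ALPHABET)
    if bad:
        raise ValueError(
            f"{context}: invalid residue code(s) {bad}; allowed are the 20 "
            f"standard amino acids plus ambiguity codes {sorted(AMBIGUITY_AA)}"
        )
    if not any(c in STANDARD_AA_INDEX for c in residues):
        warnings.warn(
            f"{context}: sequence consists entirely of ambiguity codes and "
            "will contribute to no pattern",
            stacklevel=3,
        )
    return residues


@dataclass
class LabeledSequence:
    """A protein sequence carrying a thermostability category label."""

    id: str
    residues: str
    category: ThermoCategory
    growth_temperature: float | None = None
    family_id: str | None = None

    def __post_init__(self) -> None:
        self.residues = _validate_residues(self.residues, f"sequence {self.id!r}")
        if isinstance(self.category, str):
            self.category = ThermoCategory.from_string(self.category)
        if self.growth_temperature is not None:
            expected = classify_growth_temperature(self.growth_temperature)
            if expected is not self.category:
                raise ValueError(
                    f"sequence {self.id!r}: category {self.category.value} "
                    f"inconsistent with growth temperature "
                    f"{self.growth_temperature} °C ({expected.value})"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SequenceFamily:
    """A protein family's members partitioned by thermostability category."""

    family_id: str
    members: list[LabeledSequence] = field(default_factory=list)

    def __post_init__(self) -> None:
        for m in self.members:
            if m.family_id is not None and m.family_id != self.family_id:
                raise ValueError(
                    f"member {m.id!r} carries family_id {m.family_id!r} but "
                    f"was placed in family {self.family_id!r}"
                )

    def bin(self, category: ThermoCategory) -> list[LabeledSequence]:
        return [m for m in self.members if m.category is category]

    @property
    def psychrophilic(self) -> list[LabeledSequence]:
        return self.bin(ThermoCategory.PSYCHROPHILIC)

    @property
    def mesophilic(self) -> list[LabeledSequence]:
        return self.bin(ThermoCategory.MESOPHILIC)

    @property
    def thermophilic(self) -> list[LabeledSequence]:
        return self.bin(ThermoCategory.THERMOPHILIC)

    def bin_sizes(self) -> dict[str, int]:
        return {c.value: len(self.bin(c)) for c in ThermoCategory}

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class DeltaTRecord:
    """An experimental melting-temperature change for one point mutation.

    ``delta_t`` is the measured change in melting/denaturation temperature
    (°C) of the mutant relative to wild type; positive values mark
    stabilizing mutations.
    """

    wild_type: str
    position: int
    mutant: str
    delta_t: float

    def __post_init__(self) -> None:
        if self.wild_type not in STANDARD_AA_INDEX:
            raise ValueError(f"wild-type residue {self.wild_type!r} is not standard")
        if self.mutant not in STANDARD_AA_INDEX:
            raise ValueError(f"mutant residue {self.mutant!r} is not standard")
        if self.wild_type == self.mutant:
            raise ValueError(
                f"degenerate mutation {self.wild_type}{self.position}"
                f"{self.mutant}: wild type equals mutant"
            )
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")

    @property
    def mutation(self) -> str:
        return f"{self.wild_type}{self.position}{self.mutant}"


def parse_mutation(token: str) -> tuple[str, int, str]:
    """Parse a compact mutation string like ``"H62R"`` into (wt, pos, mut)."""
    token = token.strip().upper()
    if len(token) < 3:
        raise ValueError(f"unparsable mutation string {token!r}")
    wt, digits, mut = token[0], token[1:-1], token[-1]
    if not digits.isdigit() or wt not in STANDARD_AA_INDEX or mut not in STANDARD_AA_INDEX:
        raise ValueError(f"unparsable mutation string {token!r}")
    return wt, int(digits), mut


def format_mutation(wild_type: str, position: int, mutant: str) -> str:
    return f"{wild_type}{position}{mutant}"


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(id, residues)`` pairs in file order.

    Residues are upper-cased and validated against the amino-acid alphabet
    (20 standard codes plus ambiguity codes).
    """
    records: list[tuple[str, str]] = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        residues = str(rec.seq).replace(" ", "").replace("\t", "")
        if not rec.id:
            raise ValueError(f"{path}: record {i + 1} has an empty header")
        if not residues:
            raise ValueError(f"{path}: record {i + 1} ({rec.id!r}) is empty")
        records.append((rec.id, _validate_residues(residues, f"record {rec.id!r}")))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(residues), id=str(rid), description="")
        for rid, residues in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else None
    return pd.read_csv(path, sep=sep, engine="python")


def read_labels(
    path: str | Path,
) -> dict[str, tuple[ThermoCategory, float | None]]:
    """Read a delimited label table into ``id -> (category, growth_temp)``.

    The table must have an ``id`` column and either a ``category`` column
    (tokens psychrophilic / mesophilic / thermophilic) or a ``growth_temp_c``
    column (°C, converted via :func:`classify_growth_temperature`).
    """
    df = _read_table(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    if "id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'id'")
    has_cat = "category" in df.columns
    has_gt = "growth_temp_c" in df.columns
    if not (has_cat or has_gt):
        raise ValueError(
            f"{path}: need a 'category' or 'growth_temp_c' column, "
            f"found {list(df.columns)}"
        )
    dupes = df["id"].astype(str)[df["id"].astype(str).duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate sequence id(s): {dupes}")

    labels: dict[str, tuple[ThermoCategory, float | None]] = {}
    for _, row in df.iterrows():
        sid = str(row["id"])
        gt: float | None = None
        if has_gt and not pd.isna(row["growth_temp_c"]):
            gt = float(row["growth_temp_c"])
            category = classify_growth_temperature(gt)
        elif has_cat and not pd.isna(row["category"]):
            category = ThermoCategory.from_string(str(row["category"]))
        else:
            raise ValueError(f"{path}: row for id {sid!r} has neither label")
        labels[sid] = (category, gt)
    return labels


def read_delta_t_table(path: str | Path) -> list[DeltaTRecord]:
    """Read experimental ΔT records from a delimited table.

    Accepts either a compact ``mutation`` column (``"H62R"``) or separate
    ``wt``, ``pos``, ``mut`` columns, plus a ``delta_t_c`` column.
    Duplicate records for the same mutation are retained; conflict policy is
    applied downstream at evaluation time.
    """
    df = _read_table(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    if "delta_t_c" not in df.columns:
        raise ValueError(f"{path}: missing required column 'delta_t_c'")
    records: list[DeltaTRecord] = []
    for i, row in df.iterrows():
        if "mutation" in df.columns:
            wt, pos, mut = parse_mutation(str(row["mutation"]))
        elif {"wt", "pos", "mut"} <= set(df.columns):
            wt, pos, mut = str(row["wt"]).upper(), int(row["pos"]), str(row["mut"]).upper()
        else:
            raise ValueError(
                f"{path}: need a 'mutation' column or 'wt'/'pos'/'mut' columns"
            )
        try:
            records.append(DeltaTRecord(wt, pos, mut, float(row["delta_t_c"])))
        except ValueError as exc:
            raise ValueError(f"{path}: row {i + 1}: {exc}") from exc
    return records


def assemble_family(
    sequences: Sequence[tuple[str, str]],
    labels: Mapping[str, tuple[ThermoCategory, float | None] | ThermoCategory],
    family_id: str,
) -> SequenceFamily:
    """Join sequences with labels into a category-partitioned family.

    Every sequence id must have a label; labels without a matching sequence
    are ignored with a warning.
    """
    missing = [sid for sid, _ in sequences if sid not in labels]
    if missing:
        raise ValueError(f"no label for sequence id(s): {missing}")
    orphans = set(labels) - {sid for sid, _ in sequences}
    if orphans:
        warnings.warn(
            f"{len(orphans)} label(s) reference unknown sequence ids and are "
            f"ignored: {sorted(orphans)[:5]}{'...' if len(orphans) > 5 else ''}",
            stacklevel=2,
        )
    members = []
    for sid, residues in sequences:
        label = labels[sid]
        if isinstance(label, ThermoCategory):
            category, gt = label, None
        else:
            category, gt = label
        members.append(
            LabeledSequence(
                id=sid,
                residues=residues,
                category=category,
                growth_temperature=gt,
                family_id=family_id,
            )
        )
    return SequenceFamily(family_id=family_id, members=members)
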