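"""Synthetic labelled sequence families with planted pattern enrichments.

The generator emulates the statistical structure the pattern screen assumes:
two groups of protein sequences whose residues are drawn i.i.d. from a
common background distribution, with selected AXB patterns occurring at an
elevated rate in the thermophilic group.  Enrichment is planted by
overwriting residue pairs: for each thermophilic sequence and each planted
pattern, an extra occurrence count is drawn from a Poisson law with the
configured mean, and each occurrence claims an unreserved anchor pair
(i, i + X + 1) chosen uniformly, writing A and B over the background.
Overwriting (rather than inserting) preserves sequence length; clashes with
already-reserved positions are resolved by redrawing anchors a bounded
number of times, after which the configuration is declared infeasible.

All randomness flows from one integer seed through a single
``numpy.random.Generator`` in documented order: mesophilic sequences first
(residues per sequence), then thermophilic sequences (residues, then
injections per planted pattern in configuration order).  Identical
configurations and seeds therefore reproduce identical families.

By construction the families have no phylogenetic correlation between
members and no positional composition structure — features real Pfam
alignments do have; an optional first-order Markov background is available
for robustness experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .mutation_suggest import MutationSuggestion, SuggestionList, Support
from .pattern_count import PatternKey
from .pattern_screen import PatternStat
from .seq_data import (
    STANDARD_AA,
    LabeledSequence,
    SequenceFamily,
    ThermoCategory,
)

__all__ = [
    "SyntheticFamilyConfig",
    "GroundTruth",
    "generate_family",
    "generate_target_with_sites",
    "pattern_stats_for",
    "write_family",
]

_MAX_INJECTION_ATTEMPTS = 200


@dataclass
class SyntheticFamilyConfig:
    """Parameters of one synthetic family.

    ``planted`` maps patterns to the expected number of extra occurrences
    per thermophilic sequence.  ``length`` may be an int or an inclusive
    (low, high) range.  ``background`` is a length-20 frequency vector over
    the standard residues in alphabetical order (uniform when omitted).
    """

    n_meso: int = 30
    n_thermo: int = 30
    length: int | tuple[int, int] = 150
    background: Sequence[float] | None = None
    planted: list[tuple[PatternKey, float]] = field(default_factory=list)
    seed: int = 0
    family_id: str = "SYN00001"
    markov: np.ndarray | None = None  # optional (20, 20) transition matrix

    def __post_init__(self) -> None:
        if self.n_meso < 1 or self.n_thermo < 1:
            raise ValueError("group sizes must be >= 1")
        lo, hi = self.length_range
        if lo < 2 or hi < lo:
            raise ValueError(f"invalid length specification {self.length!r}")
        self.planted = [
            (PatternKey.from_string(p) if isinstance(p, str) else p, float(rate))
            for p, rate in self.planted
        ]
        for pattern, rate in self.planted:
            if rate < 0:
                raise ValueError(f"extra_rate must be >= 0, got {rate} for {pattern}")
            if lo <= pattern.spacing + 1:
                raise ValueError(
                    f"length {lo} cannot hold planted pattern {pattern} "
                    f"(needs length > {pattern.spacing + 1})"
                )
        if self.background is not None:
            bg = np.asarray(self.background, dtype=float)
            if bg.shape != (20,):
                raise ValueError("background must have 20 frequencies")
            if (bg < 0).any() or abs(bg.sum() - 1.0) > 1e-9:
                raise ValueError("background frequencies must be >= 0 and sum to 1")
            self.background = bg

    @property
    def length_range(self) -> tuple[int, int]:
        if isinstance(self.length, tuple):
            return self.length
        return (self.length, self.length)


@dataclass
class GroundTruth:
    """What was planted: configured rates plus realized per-sequence counts."""

    planted: list[tuple[PatternKey, float]]
    realized: dict[str, list[int]]  # canonical pattern string -> per-thermophilic counts

    def realized_mean(self, pattern: PatternKey | str) -> float:
        counts = self.realized[str(pattern)]
        return float(np.mean(counts)) if counts else 0.0

    def to_dict(self) -> dict:
        return {
            "planted": [
                {"pattern": str(p), "extra_rate": rate} for p, rate in self.planted
            ],
            "realized_counts": self.realized,
        }


def _draw_sequence(rng: np.random.Generator, length: int, config) -> np.ndarray:
    if config.markov is not None:
        trans = np.asarray(config.markov, dtype=float)
        seq = np.empty(length, dtype=np.int64)
        p0 = config.background if config.background is not None else np.full(20, 0.05)
        seq[0] = rng.choice(20, p=p0)
        for i in range(1, length):
            seq[i] = rng.choice(20, p=trans[seq[i - 1]])
        return seq
    p = config.background if config.background is not None else None
    return rng.choice(20, size=length, p=p)


def _inject(
    rng: np.random.Generator,
    seq: np.ndarray,
    pattern: PatternKey,
    k: int,
    reserved: set[int],
) -> int:
    """Overwrite k occurrences of pattern at non-clashing anchors."""
    step = pattern.spacing + 1
    a = STANDARD_AA.index(pattern.first)
    b = STANDARD_AA.index(pattern.second)
    n_anchors = len(seq) - step
    placed = 0
    for _ in range(k):
        for _attempt in range(_MAX_INJECTION_ATTEMPTS):
            i = int(rng.integers(0, n_anchors))
            if i not in reserved and i + step not in reserved:
                seq[i] = a
                seq[i + step] = b
                reserved.update((i, i + step))
                placed += 1
                break
        else:
            raise ValueError(
                f"infeasible injection: could not place occurrence "
                f"{placed + 1}/{k} of {pattern} in a sequence of length "
                f"{len(seq)} (too many planted occurrences)"
            )
    return placed


def generate_family(
    config: SyntheticFamilyConfig,
) -> tuple[SequenceFamily, GroundTruth]:
    """Generate one labelled mesophilic/thermophilic family.

    Returns the family plus the ground truth of planted enrichments
    (configured rates and the Poisson counts actually injected per
    thermophilic sequence).
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    members: list[LabeledSequence] = []
    for i in range(config.n_meso):
        length = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        seq = _draw_sequence(rng, length, config)
        members.append(
            LabeledSequence(
                id=f"MESO_{i + 1:04d}",
                residues="".join(STANDARD_AA[j] for j in seq),
                category=ThermoCategory.MESOPHILIC,
                family_id=config.family_id,
            )
        )
    realized: dict[str, list[int]] = {str(p): [] for p, _ in config.planted}
    for i in range(config.n_thermo):
        length = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        seq = _draw_sequence(rng, length, config)
        reserved: set[int] = set()
        for pattern, rate in config.planted:
            k = int(rng.poisson(rate)) if rate > 0 else 0
            _inject(rng, seq, pattern, k, reserved)
            realized[str(pattern)].append(k)
        members.append(
            LabeledSequence(
                id=f"THERMO_{i + 1:04d}",
                residues="".join(STANDARD_AA[j] for j in seq),
                category=ThermoCategory.THERMOPHILIC,
                family_id=config.family_id,
            )
        )
    family = SequenceFamily(family_id=config.family_id, members=members)
    return family, GroundTruth(planted=list(config.planted), realized=realized)


def pattern_stats_for(
    patterns: Sequence[PatternKey | str],
    p_value: float = 0.01,
    ave_the: float = 1.0,
    ave_mes: float = 0.0,
) -> list[PatternStat]:
    """Wrap bare patterns as thermophilic-enriched screening statistics.

    Convenience for driving the suggestion algorithm with a hand-picked
    pattern list (every pattern gets the same p-value and group means).
    """
    keys = [
        PatternKey.from_string(p) if isinstance(p, str) else p for p in patterns
    ]
    return [PatternStat(k, p_value, ave_the, ave_mes) for k in keys]


def _merge(
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


def _definitional_suggestions(
    target: str,
    patterns: Sequence[PatternKey],
    p_values: dict[str, float],
    target_id: str,
) -> SuggestionList:
    """Position-major scan straight from the suggestion rules.

    Independent bookkeeping used to derive the expected suggestion list for
    generated fixtures: for every window (i, i + X + 1) of every pattern,
    emit the AXY and ZXB near-miss substitutions.
    """
    found: dict[tuple[int, str, str], MutationSuggestion] = {}
    L = len(target)
    for i in range(L):
        for pattern in patterns:
            step = pattern.spacing + 1
            j = i + step
            if j < L:
                if target[i] == pattern.first and target[j] != pattern.second:
                    _merge(
                        found,
                        j + 1,
                        target[j],
                        pattern.second,
                        Support(pattern, i + 1, "AXY", p_values[str(pattern)]),
                    )
                if target[j] == pattern.second and target[i] != pattern.first:
                    _merge(
                        found,
                        i + 1,
                        target[i],
                        pattern.first,
                        Support(pattern, j + 1, "ZXB", p_values[str(pattern)]),
                    )
    ordered = sorted(
        found.values(), key=lambda s: (s.best_p_value, s.position, s.mutant)
    )
    return SuggestionList(target_id=target_id, suggestions=ordered)


def generate_target_with_sites(
    length: int,
    enriched_patterns: Sequence[PatternKey | str],
    n_sites: int,
    seed: int = 0,
    p_value: float = 0.01,
    target_id: str = "synthetic_target",
) -> tuple[str, SuggestionList]:
    """Construct a target holding exactly ``n_sites`` near-miss sites.

    The target is built on an inert filler residue (one that appears in no
    enriched pattern), onto which pattern residues are placed far enough
    apart that every near-miss window involves exactly one placed residue.
    The returned expected :class:`SuggestionList` is derived by an
    independent position-major scan of the final sequence, and placement is
    retried until the induced support count equals ``n_sites`` exactly.
    """
    patterns = [
        PatternKey.from_string(p) if isinstance(p, str) else p
        for p in enriched_patterns
    ]
    if n_sites < 0:
        raise ValueError("n_sites must be >= 0")
    if n_sites and not patterns:
        raise ValueError("cannot place sites without enriched patterns")
    used = {p.first for p in patterns} | {p.second for p in patterns}
    fillers = [aa for aa in STANDARD_AA if aa not in used]
    if not fillers:
        raise ValueError(
            "no inert filler residue available: the enriched patterns use all "
            "20 standard residues"
        )
    max_spacing = max((p.spacing for p in patterns), default=0)
    p_values = {str(p): p_value for p in patterns}
    rng = np.random.default_rng(seed)
    filler = fillers[int(rng.integers(0, len(fillers)))]

    if n_sites == 0:
        target = filler * length
        return target, SuggestionList(target_id=target_id, suggestions=[])

    for _attempt in range(_MAX_INJECTION_ATTEMPTS):
        target_arr = [filler] * length
        placed_positions: list[int] = []
        ok = True
        for s in range(n_sites):
            pattern = patterns[s % len(patterns)]
            side = "AXY" if rng.integers(0, 2) == 0 else "ZXB"
            step = pattern.spacing + 1
            residue = pattern.first if side == "AXY" else pattern.second
            # candidate positions where the near-miss window stays in bounds
            if side == "AXY":
                candidates = [i for i in range(0, length - step)]
            else:
                candidates = [i for i in range(step, length)]
            # keep placed residues separated beyond any window span
            candidates = [
                i
                for i in candidates
                if all(abs(i - q) > max_spacing + 1 for q in placed_positions)
            ]
            if not candidates:
                ok = False
                break
            i = candidates[int(rng.integers(0, len(candidates)))]
            target_arr[i] = residue
            placed_positions.append(i)
        if not ok:
            continue
        target = "".join(target_arr)
        expected = _definitional_suggestions(target, patterns, p_values, target_id)
        n_support = sum(len(s.support) for s in expected)
        if n_support == n_sites:
            return target, expected
    raise ValueError(
        f"could not place exactly {n_sites} near-miss sites for "
        f"{len(patterns)} pattern(s) in length {length}"
    )


def write_family(
    family: SequenceFamily,
    truth: GroundTruth,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write a family as FASTA + labels TSV + ground-truth JSON."""
    from .seq_data import write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = out / f"{family.family_id}.fasta"
    labels = out / f"{family.family_id}_labels.tsv"
    truth_path = out / f"{family.family_id}_truth.json"
    write_fasta([(m.id, m.residues) for m in family.members], fasta)
    with open(labels, "w") as fh:
        fh.write("id\tcategory\n")
        for m in family.members:
            fh.write(f"{m.id}\t{m.category.value}\n")
    truth_path.write_text(json.dumps(truth.to_dict(), indent=2) + "\n")
    return {"fasta": fasta, "labels": labels, "ground_truth": truth_path}
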