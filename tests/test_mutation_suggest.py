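import numpy as np
import pytest

import thermopattern as tp
from thermopattern.mutation_suggest import (
    MutationSuggester,
    MutationSuggestion,
    SuggestionList,
    Support,
    apply_mutation,
    read_suggestions_tsv,
    suggest_mutations,
    write_suggestions_tsv,
)
from thermopattern.pattern_count import PatternKey, count_pattern
from thermopattern.pattern_screen import PatternStat
from thermopattern.seq_data import STANDARD_AA, STANDARD_AA_INDEX
from thermopattern.synthetic_data import pattern_stats_for

from conftest import random_protein


def oracle_suggestions(target: str, patterns) -> set[tuple[int, str, str]]:
    """Brute force: try every (position, mutant) substitution and keep those
    creating a new enriched-pattern occurrence anchored at an existing
    residue (first residue in place for AXY, second for ZXB)."""
    out = set()
    L = len(target)
    for pos in range(L):  # 0-based
        wt = target[pos]
        if wt not in STANDARD_AA_INDEX:
            continue
        for mutant in STANDARD_AA:
            if mutant == wt:
                continue
            for p in patterns:
                step = p.spacing + 1
                creates = False
                # mutated residue becomes the second residue (Y -> B)
                if (
                    mutant == p.second
                    and pos - step >= 0
                    and target[pos - step] == p.first
                    and wt != p.second
                ):
                    creates = True
                # mutated residue becomes the first residue (Z -> A)
                if (
                    mutant == p.first
                    and pos + step < L
                    and target[pos + step] == p.second
                    and wt != p.first
                ):
                    creates = True
                if creates:
                    out.add((pos + 1, wt, mutant))
    return out


@pytest.mark.parametrize(
    "pattern, target, expected",
    [
        ("ER", "MEHA", {(3, "H", "R")}),        # AXY: E in place, H -> R
        ("A1V", "GGV", {(1, "G", "A")}),         # ZXB: V in place, G -> A
        ("A1V", "AGV", set()),                   # pattern already satisfied
        ("N3N", "MNAAADAA", {(6, "D", "N")}),    # N at 2, D at 6 -> D6N
    ],
)
def test_suggestion_hand_traces(pattern, target, expected):
    stats = pattern_stats_for([pattern])
    got = {s.key() for s in suggest_mutations(target, stats)}
    assert got == expected


def test_mesophilic_enriched_patterns_are_never_used():
    stats = [PatternStat(PatternKey("E", 0, "R"), 0.001, ave_the=1.0, ave_mes=2.0)]
    assert len(suggest_mutations("MEHA", stats)) == 0


def test_insignificant_patterns_are_never_used():
    stats = [PatternStat(PatternKey("E", 0, "R"), 0.2, ave_the=2.0, ave_mes=1.0)]
    assert len(suggest_mutations("MEHA", stats, alpha=0.05)) == 0


def test_duplicate_mutations_merge_support():
    # E0R and E1R both suggest H -> R at position 3 of "MEHHA"? build a case:
    # target MEH: E at 2; patterns ER (AXY at 3) and M1R (AXY: M at 1, H at 3)
    stats = pattern_stats_for(["ER", "M1R"])
    result = suggest_mutations("MEH", stats)
    assert len(result) == 1
    (sugg,) = list(result)
    assert sugg.key() == (3, "H", "R")
    assert {(str(s.pattern), s.anchor_position, s.side) for s in sugg.support} == {
        ("ER", 2, "AXY"),
        ("M1R", 1, "AXY"),
    }


def test_suggestions_sorted_by_best_p_value_then_position():
    stats = [
        PatternStat(PatternKey("E", 0, "R"), 0.04, 2.0, 1.0),
        PatternStat(PatternKey("M", 0, "K"), 0.001, 2.0, 1.0),
    ]
    result = suggest_mutations("MEHA", stats)
    # M0K fires first (better p): E -> K at 2; then E0R: H -> R at 3
    assert [s.mutation for s in result] == ["E2K", "H3R"]


def test_ambiguity_codes_are_inert():
    stats = pattern_stats_for(["ER"])
    # X cannot be mutated, B cannot anchor
    assert len(suggest_mutations("EX", stats)) == 0
    assert len(suggest_mutations("XB", stats)) == 0
    got = {s.key() for s in suggest_mutations("EHXEH", stats)}
    assert got == {(2, "H", "R"), (5, "H", "R")}


def test_suggestion_validation():
    sup = Support(PatternKey("E", 0, "R"), 1, "AXY", 0.01)
    with pytest.raises(ValueError, match="wild type equals mutant"):
        MutationSuggestion(3, "R", "R", [sup])
    with pytest.raises(ValueError, match="support"):
        MutationSuggestion(3, "H", "R", [])
    with pytest.raises(ValueError, match="deduplicated"):
        SuggestionList(
            "t",
            [MutationSuggestion(3, "H", "R", [sup]), MutationSuggestion(3, "H", "R", [sup])],
        )


def test_apply_mutation_and_involution():
    stats = pattern_stats_for(["ER"])
    (sugg,) = list(suggest_mutations("MEHA", stats))
    mutated = apply_mutation("MEHA", sugg)
    assert mutated == "MERA"
    back = MutationSuggestion(sugg.position, sugg.mutant, sugg.wild_type, sugg.support)
    assert apply_mutation(mutated, back) == "MEHA"


def test_apply_mutation_guards_coordinates():
    sup = Support(PatternKey("E", 0, "R"), 1, "AXY", 0.01)
    with pytest.raises(ValueError, match="mismatch"):
        apply_mutation("MEHA", MutationSuggestion(2, "H", "R", [sup]))
    with pytest.raises(ValueError, match="outside"):
        apply_mutation("MEHA", MutationSuggestion(9, "H", "R", [sup]))


def test_every_suggestion_creates_a_new_supporting_occurrence():
    """Each suggested substitution completes the pattern occurrence of every
    one of its support entries, and never lowers a supporting pattern's
    total count.  (The total can stay flat when the substituted residue was
    itself part of an overlapping occurrence of the same pattern, e.g.
    pattern AB on "AAB": A2B gives "ABB", creating (1,2) but losing (2,3).)
    """
    rng = np.random.default_rng(17)
    for _ in range(25):
        target = random_protein(rng, 50, ambiguity_frac=0.05)
        keys = {
            PatternKey(
                STANDARD_AA[rng.integers(0, 20)],
                int(rng.integers(0, 11)),
                STANDARD_AA[rng.integers(0, 20)],
            )
            for _ in range(8)
        }
        stats = pattern_stats_for(sorted(keys, key=str))
        for sugg in suggest_mutations(target, stats):
            assert sugg.wild_type != sugg.mutant
            assert target[sugg.position - 1] == sugg.wild_type
            mutated = apply_mutation(target, sugg)
            for s in sugg.support:
                step = s.pattern.spacing + 1
                if s.side == "AXY":
                    i, j = s.anchor_position - 1, s.anchor_position - 1 + step
                else:
                    i, j = s.anchor_position - 1 - step, s.anchor_position - 1
                # the anchored window did not match before and does now
                assert (target[i], target[j]) != (s.pattern.first, s.pattern.second)
                assert (mutated[i], mutated[j]) == (s.pattern.first, s.pattern.second)
                assert count_pattern(mutated, s.pattern) >= count_pattern(
                    target, s.pattern
                )


def test_overlap_corner_case_keeps_count_flat_but_creates_occurrence():
    stats = pattern_stats_for(["AC"])
    suggs = {s.key(): s for s in suggest_mutations("AAC", stats)}
    sugg = suggs[(2, "A", "C")]
    assert apply_mutation("AAC", sugg) == "ACC"
    assert count_pattern("ACC", PatternKey("A", 0, "C")) == count_pattern(
        "AAC", PatternKey("A", 0, "C")
    )


def test_suggestions_match_bruteforce_oracle_small():
    rng = np.random.default_rng(23)
    for _ in range(40):
        target = random_protein(rng, int(rng.integers(2, 45)), ambiguity_frac=0.1)
        keys = sorted(
            {
                PatternKey(
                    STANDARD_AA[rng.integers(0, 20)],
                    int(rng.integers(0, 11)),
                    STANDARD_AA[rng.integers(0, 20)],
                )
                for _ in range(rng.integers(1, 10))
            },
            key=str,
        )
        got = {s.key() for s in suggest_mutations(target, pattern_stats_for(keys))}
        assert got == oracle_suggestions(target, keys)


def test_empty_stats_grid_yields_empty_list():
    result = suggest_mutations("MEHA", [])
    assert len(result) == 0 and isinstance(result, SuggestionList)


def test_invalid_target_rejected():
    with pytest.raises(ValueError):
        suggest_mutations("", pattern_stats_for(["ER"]))
    with pytest.raises(ValueError, match="invalid residue"):
        suggest_mutations("ME1A", pattern_stats_for(["ER"]))


def test_suggestions_tsv_roundtrip(tmp_path):
    stats = pattern_stats_for(["ER", "M1R"])
    result = suggest_mutations("MEHMEH", stats)
    path = tmp_path / "suggestions.tsv"
    write_suggestions_tsv(result, path)
    back = read_suggestions_tsv(path)
    assert {s.key() for s in back} == {s.key() for s in result}
    assert sum(len(s.support) for s in back) == sum(len(s.support) for s in result)


def test_mutation_suggester_end_to_end():
    config = tp.SyntheticFamilyConfig(
        n_meso=30, n_thermo=30, length=150, planted=[("ER", 2.0)], seed=8
    )
    family, _ = tp.generate_family(config)
    suggester = MutationSuggester().fit(family)
    assert PatternKey("E", 0, "R") in [p for p, _ in suggester.enriched_]
    # a target with an E followed by a non-R must draw an E0R-backed suggestion
    result = suggester.suggest("MEHAAAA", target_id="toy")
    assert any(
        str(sup.pattern) == "ER" and s.key() == (3, "H", "R")
        for s in result
        for sup in s.support
    )
    assert suggester.get_params()["alpha"] == 0.05
    batch = suggester.predict(["MEHA", "AAAA"])
    assert len(batch) == 2
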