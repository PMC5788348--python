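from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import thermopattern as tp
from thermopattern.pattern_screen import (
    PatternScreen,
    ScreenConfig,
    eligible_family,
    rank_sum_test,
    read_screen_tsv,
    screen_patterns,
    write_screen_tsv,
)
from thermopattern.seq_data import LabeledSequence, SequenceFamily, ThermoCategory

from conftest import random_protein


def enumeration_p_value(a, b) -> float:
    """Exhaustive two-sided rank-sum p-value over all C(n+m, n) assignments.

    Computes the Mann–Whitney U directly from pairwise comparisons, without
    ranks, so it is an independent check of the implementation.
    """
    pooled = list(a) + list(b)
    n, m = len(a), len(b)

    def u_stat(group_idx):
        group = [pooled[i] for i in group_idx]
        rest = [pooled[i] for i in range(n + m) if i not in set(group_idx)]
        return sum(
            1.0 if x > y else (0.5 if x == y else 0.0) for x in group for y in rest
        )

    u_obs = u_stat(tuple(range(n)))
    dev = abs(u_obs - n * m / 2.0)
    hits = total = 0
    for idx in combinations(range(n + m), n):
        total += 1
        if abs(u_stat(idx) - n * m / 2.0) >= dev - 1e-12:
            hits += 1
    return hits / total


def make_family(meso_seqs, thermo_seqs, family_id="PF_TEST"):
    members = [
        LabeledSequence(f"m{i}", s, ThermoCategory.MESOPHILIC, family_id=family_id)
        for i, s in enumerate(meso_seqs)
    ] + [
        LabeledSequence(f"t{i}", s, ThermoCategory.THERMOPHILIC, family_id=family_id)
        for i, s in enumerate(thermo_seqs)
    ]
    return SequenceFamily(family_id, members)


def test_rank_sum_identical_groups():
    assert rank_sum_test([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
    assert rank_sum_test([0], [0]) == 1.0


def test_rank_sum_complete_separation_exact():
    assert rank_sum_test([1, 1, 1, 1], [5, 5, 5, 5]) == pytest.approx(2 / 70, abs=1e-15)


def test_rank_sum_rejects_empty_group():
    with pytest.raises(ValueError):
        rank_sum_test([], [1.0])


@settings(max_examples=60, derandomize=True)
@given(
    a=st.lists(st.integers(0, 5), min_size=1, max_size=7),
    b=st.lists(st.integers(0, 5), min_size=1, max_size=7),
)
def test_rank_sum_is_symmetric(a, b):
    assert rank_sum_test(a, b) == pytest.approx(rank_sum_test(b, a), abs=1e-12)


def test_rank_sum_exact_matches_enumeration_with_ties():
    rng = np.random.default_rng(11)
    for _ in range(20):
        n, m = rng.integers(1, 6, size=2)
        a = rng.integers(0, 4, size=n).tolist()
        b = rng.integers(0, 4, size=m).tolist()
        assert rank_sum_test(a, b) == pytest.approx(
            enumeration_p_value(a, b), abs=1e-12
        )


def test_large_sample_approximation_is_finite_and_bounded():
    rng = np.random.default_rng(3)
    a = rng.poisson(1.0, size=30)
    b = rng.poisson(1.5, size=30)
    p = rank_sum_test(a, b)
    assert 0.0 < p <= 1.0


def test_screen_config_validation():
    with pytest.raises(ValueError):
        ScreenConfig(alpha=0.0)
    with pytest.raises(ValueError):
        ScreenConfig(min_group_size=0)
    with pytest.raises(ValueError):
        ScreenConfig(correction="bonferroni")


@pytest.mark.parametrize(
    "n_meso, n_thermo, expected",
    [(21, 21, True), (20, 50, False), (0, 100, False), (50, 20, False)],
)
def test_family_eligibility_is_strict(n_meso, n_thermo, expected):
    family = make_family(["VE"] * n_meso, ["EV"] * n_thermo)
    assert eligible_family(family, ScreenConfig()) is expected


def test_screen_identical_groups_yields_nothing_significant():
    rng = np.random.default_rng(4)
    seqs = [random_protein(rng, 60) for _ in range(25)]
    family = make_family(seqs, seqs)
    results = screen_patterns(family, ScreenConfig())
    assert not results["significant"].any()
    assert (results["p_value"] == 1.0).all()


def test_screen_requires_eligible_family_unless_forced():
    rng = np.random.default_rng(6)
    family = make_family(
        [random_protein(rng, 40) for _ in range(5)],
        [random_protein(rng, 40) for _ in range(5)],
    )
    with pytest.raises(ValueError, match="not eligible"):
        screen_patterns(family)
    with pytest.warns(UserWarning, match="not eligible"):
        results = screen_patterns(family, force=True)
    assert len(results) == 4400


def test_screen_recovers_planted_pattern():
    config = tp.SyntheticFamilyConfig(
        n_meso=30, n_thermo=30, length=150, planted=[("ER", 2.0)], seed=42
    )
    family, _ = tp.generate_family(config)
    screen = PatternScreen().fit(family)
    results = screen.results()
    row = results[results["pattern"] == "ER"].iloc[0]
    assert row["significant"]
    assert row["enriched_in"] == "thermophilic"
    assert tp.PatternKey("E", 0, "R") in screen.enriched_patterns()


def test_enrichment_direction_matches_group_means():
    config = tp.SyntheticFamilyConfig(n_meso=25, n_thermo=25, length=100, seed=9)
    family, _ = tp.generate_family(config)
    results = screen_patterns(family)
    the_gt = results["ave_the"] > results["ave_mes"]
    the_lt = results["ave_the"] < results["ave_mes"]
    assert (results.loc[the_gt, "enriched_in"] == "thermophilic").all()
    assert (results.loc[the_lt, "enriched_in"] == "mesophilic").all()
    assert (
        results.loc[~the_gt & ~the_lt, "enriched_in"] == "none"
    ).all()


def test_benjamini_hochberg_is_no_less_conservative():
    config = tp.SyntheticFamilyConfig(
        n_meso=25, n_thermo=25, length=120, planted=[("ER", 1.5)], seed=12
    )
    family, _ = tp.generate_family(config)
    raw = PatternScreen().fit(family)
    bh = PatternScreen(correction="benjamini_hochberg").fit(family)
    assert bh.significant_.sum() <= raw.significant_.sum()
    np.testing.assert_array_equal(raw.p_values_, bh.p_values_)


def test_screen_accepts_sequences_plus_labels():
    rng = np.random.default_rng(21)
    seqs = [random_protein(rng, 80) for _ in range(50)]
    y = ["mesophilic"] * 25 + ["thermophilic"] * 25
    screen = PatternScreen().fit(seqs, y)
    assert screen.n_mesophilic_ == 25 and screen.n_thermophilic_ == 25
    assert screen.get_support().shape == (4400,)


def test_psychrophilic_members_are_ignored():
    rng = np.random.default_rng(22)
    family = make_family(
        [random_protein(rng, 60) for _ in range(21)],
        [random_protein(rng, 60) for _ in range(21)],
    )
    family.members.append(
        LabeledSequence("p0", "MEHA", ThermoCategory.PSYCHROPHILIC, family_id="PF_TEST")
    )
    screen = PatternScreen().fit(family)
    assert screen.n_mesophilic_ == 21 and screen.n_thermophilic_ == 21


def test_screen_tsv_roundtrip(tmp_path):
    config = tp.SyntheticFamilyConfig(n_meso=21, n_thermo=21, length=80, seed=2)
    family, _ = tp.generate_family(config)
    results = screen_patterns(family)
    path = tmp_path / "screen.tsv"
    write_screen_tsv(results, path)
    back = read_screen_tsv(path)
    assert len(back) == len(results)
    assert np.allclose(back["p_value"], results["p_value"])
    with pytest.raises(ValueError, match="missing screen columns"):
        bad = tmp_path / "bad.tsv"
        bad.write_text("pattern\tp\nER\t0.1\n")
        read_screen_tsv(bad)
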