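"""thermopattern: sequence-based protein thermostability engineering.

Counts gapped residue-pair (AXB) patterns in thermostability-labelled
protein families, screens patterns that statistically separate mesophilic
from thermophilic sequences with a rank-sum test, suggests stabilizing point
mutations on a target sequence from the thermophilic-enriched patterns, and
validates suggestions against experimental melting-temperature changes (ΔT).
"""

from importlib import resources

import pandas as pd

from .mutation_suggest import (
    MutationSuggester,
    MutationSuggestion,
    SuggestionList,
    Support,
    apply_mutation,
    suggest_mutations,
)
from .pattern_count import (
    GappedPairCounter,
    PatternCountVector,
    PatternKey,
    count_all_patterns,
    count_matrix,
    count_pattern,
    pattern_grid,
)
from .pattern_screen import (
    PatternScreen,
    PatternStat,
    ScreenConfig,
    eligible_family,
    rank_sum_test,
    screen_patterns,
)
from .seq_data import (
    DeltaTRecord,
    LabeledSequence,
    SequenceFamily,
    ThermoCategory,
    assemble_family,
    classify_growth_temperature,
    read_delta_t_table,
    read_fasta,
    read_labels,
    write_fasta,
)
from .synthetic_data import (
    GroundTruth,
    SyntheticFamilyConfig,
    generate_family,
    generate_target_with_sites,
    pattern_stats_for,
)
from .validation import SuccessReport, evaluate_suggestions, summarize_report

__version__ = "0.1.0"

__all__ = [
    "ThermoCategory",
    "LabeledSequence",
    "SequenceFamily",
    "DeltaTRecord",
    "classify_growth_temperature",
    "read_fasta",
    "write_fasta",
    "read_labels",
    "read_delta_t_table",
    "assemble_family",
    "PatternKey",
    "PatternCountVector",
    "pattern_grid",
    "count_pattern",
    "count_all_patterns",
    "count_matrix",
    "GappedPairCounter",
    "PatternStat",
    "ScreenConfig",
    "rank_sum_test",
    "eligible_family",
    "screen_patterns",
    "PatternScreen",
    "Support",
    "MutationSuggestion",
    "SuggestionList",
    "suggest_mutations",
    "apply_mutation",
    "MutationSuggester",
    "SuccessReport",
    "evaluate_suggestions",
    "summarize_report",
    "SyntheticFamilyConfig",
    "GroundTruth",
    "generate_family",
    "generate_target_with_sites",
    "pattern_stats_for",
    "load_example_mutations",
]


def load_example_mutations() -> pd.DataFrame:
    """Load the bundled worked example: ProTherm-derived ΔT records for
    pattern-suggested mutations in E. coli ribonuclease HI (Pfam PF00075).

    One row per supporting pattern hit, columns: pattern, positions,
    mutation (compact, e.g. ``H62R``), delta_t_c, p_value, ave_the, ave_mes.
    """
    with resources.files("thermopattern.data").joinpath(
        "rnase_hi_mutations.tsv"
    ).open("r") as fh:
        return pd.read_csv(fh, sep="\t")
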