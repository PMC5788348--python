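import numpy as np
import pytest

import thermopattern as tp
from thermopattern.seq_data import STANDARD_AA, AMBIGUITY_AA, DeltaTRecord, parse_mutation


def random_protein(rng: np.random.Generator, length: int, ambiguity_frac: float = 0.0) -> str:
    """Random residue string; optionally mix in ambiguity codes."""
    alphabet = STANDARD_AA
    seq = [alphabet[i] for i in rng.integers(0, 20, size=length)]
    if ambiguity_frac > 0:
        for i in range(length):
            if rng.random() < ambiguity_frac:
                seq[i] = AMBIGUITY_AA[int(rng.integers(0, len(AMBIGUITY_AA)))]
    return "".join(seq)


@pytest.fixture(scope="session")
def example_table():
    """The bundled RNase HI pattern/mutation/ΔT worked-example table."""
    return tp.load_example_mutations()


@pytest.fixture(scope="session")
def example_records(example_table):
    """ΔT records parsed from the worked-example table."""
    records = []
    for _, row in example_table.iterrows():
        wt, pos, mut = parse_mutation(str(row["mutation"]))
        records.append(DeltaTRecord(wt, pos, mut, float(row["delta_t_c"])))
    return records
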