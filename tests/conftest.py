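import numpy as np
import pytest

from edafreq import (
    ClassifierSpec,
    GeneratorParams,
    assemble_sequence_features,
    extract_base_features,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def cohort_seed1():
    """The default synthetic cohort at seed 1 (6 subjects)."""
    return simulate_cohort(GeneratorParams(seed=1))


@pytest.fixture(scope="session")
def base_table_seed1(cohort_seed1):
    """Per-segment base features of the seed-1 cohort (default segmentation)."""
    return extract_base_features(cohort_seed1)


@pytest.fixture(scope="session")
def seq_table_seed1(base_table_seed1):
    """Sequence-feature table (w=7) of the seed-1 cohort."""
    return assemble_sequence_features(base_table_seed1, 7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
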