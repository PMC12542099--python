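import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from tmemorph import CohortConfig, assemble_cohort_table, generate_cohort

# Planted-effect study conditions used by the end-to-end experiments:
# 140 training / 60 evaluation patients, effect size 1.5, fixed seeds.
TRAIN_CONFIG = CohortConfig(n_patients=140, pcr_fraction=0.5, effect_size=1.5,
                            seed=7)
EVAL_CONFIG = CohortConfig(n_patients=60, pcr_fraction=0.5, effect_size=1.5,
                           seed=1007)


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-patient cohort for fast structural tests."""
    return generate_cohort(CohortConfig(n_patients=12, seed=5))


@pytest.fixture(scope="session")
def planted_tables():
    """Feature tables for the planted-effect train/eval cohorts."""
    train = assemble_cohort_table(generate_cohort(TRAIN_CONFIG))
    eval_ = assemble_cohort_table(generate_cohort(EVAL_CONFIG))
    return train, eval_
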