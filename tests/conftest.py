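import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from lncscout import exprcore, simdata


@pytest.fixture(scope="session")
def desk_cohort():
    """One desk-scale cohort shared by read-only tests."""
    cohort = simdata.generate_cohort(simdata.desk_config(seed=0))
    return cohort


@pytest.fixture(scope="session")
def desk_fpkm(desk_cohort):
    lengths = desk_cohort.annotation.lengths(desk_cohort.patients.gene_ids)
    return exprcore.fpkm(desk_cohort.patients, lengths)


@pytest.fixture(scope="session")
def desk_cl_fpkm(desk_cohort):
    lengths = desk_cohort.annotation.lengths(desk_cohort.cell_lines.gene_ids)
    return exprcore.fpkm(desk_cohort.cell_lines, lengths)


@pytest.fixture(scope="session")
def demo_cohort():
    return simdata.generate_cohort(simdata.demo_config(seed=0))
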