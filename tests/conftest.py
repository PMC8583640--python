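import logging

import pytest

from oralrisk.io_cli import load_fixtures

# the median/mean fallback warnings are expected for several factor rows
logging.getLogger("oralrisk.distributions").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def fixtures():
    """(concentrations, exposure factors, RfD table) from the shipped files."""
    return load_fixtures()


@pytest.fixture(scope="session")
def conc_table(fixtures):
    return fixtures[0]


@pytest.fixture(scope="session")
def factor_table(fixtures):
    return fixtures[1]


@pytest.fixture(scope="session")
def rfd_table(fixtures):
    return fixtures[2]


def diet_values(cohort, metal, group=None):
    """Diet concentrations of one metal, optionally for one age group."""
    out = []
    for child in cohort:
        if group is not None and child.age_group.value != group:
            continue
        out.append(
            next(
                r.value
                for r in child.concentrations
                if r.metal.value == metal and r.pathway.value == "food"
            )
        )
    return out
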