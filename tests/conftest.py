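import numpy as np
import pytest

from pittrap import DesignSpec, fit_marginals, tasmania_dataset


@pytest.fixture(scope="session")
def tasmania():
    return tasmania_dataset()


@pytest.fixture(scope="session")
def tas_null(tasmania):
    return DesignSpec(tasmania.design_table, "block+treatment")


@pytest.fixture(scope="session")
def tas_alt(tasmania):
    return DesignSpec(tasmania.design_table, "block*treatment")


@pytest.fixture(scope="session")
def tas_fits(tasmania, tas_null):
    """Null-model (main effects) NB fits to the Tasmania counts."""
    return fit_marginals(
        tasmania.Y, tas_null, "negative.binomial", var_names=tasmania.var_names
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
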