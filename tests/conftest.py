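import numpy as np
import pytest

from neuropbpk.io import (
    apply_fitted_pk,
    load_descriptor_table,
    load_drug_table,
    load_fitted_table,
    load_permeability_table,
)


@pytest.fixture(scope="session")
def drug_table():
    return load_drug_table()


@pytest.fixture(scope="session")
def perm_table():
    return load_permeability_table()


@pytest.fixture(scope="session")
def fitted_tables():
    pk, sc = load_fitted_table()
    return pk, sc


@pytest.fixture(scope="session")
def fitted_drugs(drug_table, fitted_tables):
    """Drug parameters with the fitted V_d/k_el/k_a overlaid."""
    return apply_fitted_pk(drug_table, fitted_tables[0])


@pytest.fixture(scope="session")
def logp_table():
    return load_descriptor_table()


@pytest.fixture(scope="session")
def study_keys(perm_table):
    return sorted(perm_table)


def rel_err(a, b):
    return abs(a - b) / abs(b)


@pytest.fixture(scope="session")
def sim_grid():
    """Dense grid factory over five elimination half-lives."""

    def _grid(drug, n=201):
        return np.linspace(0.0, 5 * np.log(2) / drug.k_el, n)

    return _grid
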