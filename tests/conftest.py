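import numpy as np
import pandas as pd
import pytest

import methaxis as mx
from methaxis.io_formats import CPG


@pytest.fixture(scope="session")
def sim_default():
    """Default synthetic HPO-like dataset, fixed seed."""
    return mx.simulate(mx.SimConfig(seed=1))


@pytest.fixture(scope="session")
def design():
    return mx.Design.default()


@pytest.fixture(scope="session")
def levels_default(sim_default, design):
    filtered = mx.filter_sites(sim_default.sites)
    return mx.add_levels(filtered, design)


@pytest.fixture(scope="session")
def cpg_filtered(sim_default):
    filtered = mx.filter_sites(sim_default.sites)
    return filtered[filtered["context"] == CPG].reset_index(drop=True)


def make_two_group_table(m_a, n_a, m_b, n_b, pos=None):
    """Wide site table for one or more sites and a 3v3 A/B design.

    ``m_a`` etc. are (n_sites, n_reps) arrays or lists of per-replicate
    values for a single site.
    """
    m_a, n_a = np.atleast_2d(m_a), np.atleast_2d(n_a)
    m_b, n_b = np.atleast_2d(m_b), np.atleast_2d(n_b)
    k = m_a.shape[0]
    data = {
        "chrom": ["chr1"] * k,
        "pos": pos if pos is not None else np.arange(1, k + 1) * 10,
        "strand": ["+"] * k,
        "context": [CPG] * k,
    }
    for i in range(m_a.shape[1]):
        data[f"m_A{i}"] = m_a[:, i]
        data[f"u_A{i}"] = n_a[:, i] - m_a[:, i]
    for i in range(m_b.shape[1]):
        data[f"m_B{i}"] = m_b[:, i]
        data[f"u_B{i}"] = n_b[:, i] - m_b[:, i]
    return pd.DataFrame(data)


@pytest.fixture
def two_group_table():
    return make_two_group_table
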