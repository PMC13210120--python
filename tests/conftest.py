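import numpy as np
import pytest

from dqcryst import ProtonSiteGroup, enumerate_pair_distances
from dqcryst.dipolar import build_pair_table, model_fractions
from dqcryst.synthetic_data import make_methyl_structure, make_random_structure


@pytest.fixture
def methyl_structure():
    return make_methyl_structure(176.0, 178.0, 179.0)


@pytest.fixture
def methyl_group():
    return ProtonSiteGroup("CH3", ("H1", "H2", "H3"))


@pytest.fixture
def methyl_pair(methyl_structure, methyl_group):
    return enumerate_pair_distances(methyl_structure, [methyl_group], 1000.0)[0]


@pytest.fixture
def random_system():
    """Six-site random toy cell with per-site groups and its model fractions."""
    structure = make_random_structure(6, seed=11)
    groups = [
        ProtonSiteGroup(f"G{i+1}", (s.label,), shift=float(1 + 2 * i))
        for i, s in enumerate(structure.sites)
    ]
    pairs = enumerate_pair_distances(structure, groups, 1000.0)
    table = build_pair_table(pairs, groups)
    return structure, groups, table, model_fractions(table)
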