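import itertools
from fractions import Fraction

import pytest

from qcfnet.cfengine import cf_table
from qcfnet.fixtures import NamedNetworkSpec, make_named, random_params


def tables_equal(t1, t2):
    if set(t1.data) != set(t2.data):
        return False
    return all(t1.data[k] == t2.data[k] for k in t1.data)


@pytest.fixture(scope="session")
def na_net():
    return make_named(random_params("Na", seed=101))


@pytest.fixture(scope="session")
def na_table(na_net):
    return cf_table(na_net)


@pytest.fixture(scope="session")
def ns_net():
    return make_named(random_params("Ns", seed=202))


def rational_specs(name, n, start_seed=0):
    return [random_params(name, seed=start_seed + i) for i in range(n)]
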