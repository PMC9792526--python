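import numpy as np
import pytest

from qideep.schema import default_schema
from qideep import synthetic as syn
from qideep import tabular as tab
from qideep.experiments import default_generator_spec


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def small_table(schema):
    """A small generated table under the default study conditions."""
    spec = default_generator_spec(n_samples=600, seed=7)
    return syn.generate(spec, schema)


@pytest.fixture(scope="session")
def small_split(schema, small_table):
    table = tab.clean(small_table, schema)
    ds = tab.encode(table, schema, fit_scaler=True)
    return tab.split(ds, tab.SplitSpec(test_fraction=0.2, seed=3))
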