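import numpy as np
import pandas as pd
import pytest

from prodesc.dataset import PatientTable
from prodesc.schema import VariableSchema


@pytest.fixture
def mixed_schema():
    """One 3-code discrete and one continuous variable."""
    return [
        VariableSchema("color", "discrete", cardinality=3),
        VariableSchema("size", "continuous"),
    ]


@pytest.fixture
def mixed_table(mixed_schema):
    X = pd.DataFrame({"color": [1, 2, 1, 3], "size": [1.0, 2.0, 3.0, 4.0]})
    y = np.array([1, -1, 0, 0])
    return PatientTable(X=X, y=y, ids=np.arange(4), schema=mixed_schema)


def make_table(values_by_col, y=None, schema=None):
    """Build a PatientTable from a dict of columns."""
    X = pd.DataFrame(values_by_col)
    n = len(X)
    if y is None:
        y = np.zeros(n, dtype=np.int64)
    if schema is None:
        schema = []
        for name in X.columns:
            if pd.api.types.is_integer_dtype(X[name]):
                schema.append(VariableSchema(name, "discrete", cardinality=int(X[name].max())))
            else:
                schema.append(VariableSchema(name, "continuous"))
    return PatientTable(X=X, y=np.asarray(y), ids=np.arange(n), schema=schema)
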