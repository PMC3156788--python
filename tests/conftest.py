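import numpy as np
import pandas as pd
import pytest

from kinomet.io import ClinicalTable, ExpressionMatrix


def make_clinical(times, events, index=None, **covariates) -> ClinicalTable:
    times = np.asarray(times, dtype=float)
    if index is None:
        index = [f"s{i + 1}" for i in range(len(times))]
    data = pd.DataFrame(
        {"dfs_months": times, "event": np.asarray(events, dtype=float)},
        index=index)
    for name, vals in covariates.items():
        data[name] = np.asarray(vals, dtype=float)
    return ClinicalTable(data)


def make_matrix(values, genes=None, samples=None, **kw) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i + 1}" for i in range(values.shape[0])]
    samples = samples or [f"s{j + 1}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes,
                                         columns=samples), **kw)


@pytest.fixture
def expr3x2() -> ExpressionMatrix:
    return make_matrix([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
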