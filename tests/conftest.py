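import numpy as np
import pandas as pd
import pytest

from dcnet.expression import ExpressionMatrix
from dcnet.ontology import OntologyDAG


def make_expr(values, condition, time=None, genes=None):
    """Build an ExpressionMatrix from a plain array."""
    values = np.asarray(values, dtype=float)
    n_rows, n_cols = values.shape
    genes = genes or [f"g{i}" for i in range(n_rows)]
    condition = list(condition)
    if time is None:
        time = []
        seen = {}
        for c in condition:
            seen[c] = seen.get(c, -1) + 1
            time.append(seen[c] * 10.0)
    cols = [f"{c}{i}" for i, c in enumerate(condition)]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=cols),
                            condition, time)


@pytest.fixture
def chain_dag():
    """Three-term chain root -> A -> B with hand-set probabilities
    p = 1 / 0.5 / 0.25."""
    dag = OntologyDAG({"R": set(), "A": {"R"}, "B": {"A"}})
    ic = {"R": 1.0, "A": 0.5, "B": 0.25}
    return dag, ic


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
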