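import numpy as np
import pytest

from methylbn.preprocess import BinaryDataset
from methylbn.scoring import Dag
from methylbn.synthetic import GroundTruthBN


def make_dataset(values, variables=None, condition_name=None):
    """BinaryDataset from a plain nested list, naming variables V1..Vk.

    The last variable doubles as the condition unless one is named explicitly.
    """
    values = np.asarray(values)
    if variables is None:
        variables = [f"V{i + 1}" for i in range(values.shape[1])]
    cond = condition_name or variables[-1]
    return BinaryDataset(
        samples=tuple(f"s{i + 1}" for i in range(values.shape[0])),
        variables=tuple(variables),
        values=values,
        condition_name=cond,
    )


def make_bn(arcs, cpts, condition_name="Treatment"):
    nodes = sorted({n for a in arcs for n in a} | set(cpts))
    return GroundTruthBN(dag=Dag(nodes, arcs), cpts={k: np.asarray(v, dtype=float) for k, v in cpts.items()},
                         condition_name=condition_name)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def chain_bn():
    """Treatment -> F1 -> F2 with strong dependence."""
    return make_bn(
        [("Treatment", "F1"), ("F1", "F2")],
        {
            "Treatment": [0.5],
            "F1": [0.15, 0.85],  # P(1 | parent=0), P(1 | parent=1)
            "F2": [0.2, 0.8],
        },
    )
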