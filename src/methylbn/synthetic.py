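"""Ground-truth network generation and zero-inflated count sampling.

The generator produces a random DAG over feature nodes plus one binary
condition node, equips every node with a randomized CPT, and samples count
matrices whose binarization exactly recovers the latent binary states:
state 0 maps to count 0, state 1 to a positive count drawn from a truncated
shifted-Poisson on ``[1, max_count]``.  Zero is kept the most frequent state
by bounding the CPT probabilities of state 1 below 1/2 on average.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .exceptions import CycleError, InvalidConditionError, InvalidCountError
from .scoring import Dag

DEFAULT_CONDITION = "Treatment"
STUDY_MAX_COUNT = 39  # largest count observed in the study data
STUDY_N_SAMPLES = 46
STUDY_N_FEATURES = 60
STUDY_CONDITION_RATE = 24 / 46  # 22 control / 24 stress


@dataclass(frozen=True)
class CountMatrix:
    """Sample x feature table of non-negative integer counts plus condition."""

    samples: Tuple[str, ...]
    features: Tuple[str, ...]
    counts: np.ndarray  # shape (n_samples, n_features)
    condition: np.ndarray  # shape (n_samples,), values in {0, 1}
    condition_name: str = DEFAULT_CONDITION

    def __post_init__(self):
        object.__setattr__(self, "samples", tuple(self.samples))
        object.__setattr__(self, "features", tuple(self.features))
        counts = np.asarray(self.counts)
        cond = np.asarray(self.condition)
        if counts.shape != (len(self.samples), len(self.features)):
            raise ValueError(f"counts shape {counts.shape} mismatches sample/feature lists")
        if np.issubdtype(counts.dtype, np.integer):
            pass
        elif np.issubdtype(counts.dtype, np.floating) and (np.floor(counts) == counts).all():
            counts = counts.astype(np.int64)
        else:
            raise InvalidCountError("counts must be integers")
        if (counts < 0).any():
            i, j = np.argwhere(counts < 0)[0]
            raise InvalidCountError(
                f"negative count at sample {self.samples[i]!r}, feature {self.features[j]!r}"
            )
        if not np.isin(cond, (0, 1)).all():
            raise InvalidConditionError(
                f"condition column {self.condition_name!r} holds values outside {{0, 1}}"
            )
        if self.condition_name in self.features:
            raise ValueError(f"feature named like condition column {self.condition_name!r}")
        object.__setattr__(self, "counts", counts.astype(np.int64))
        object.__setattr__(self, "condition", cond.astype(np.int8))

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        """Tab-file dialect layout: feature columns then the condition column."""
        df = pd.DataFrame(self.counts, index=list(self.samples), columns=list(self.features))
        df[self.condition_name] = self.condition
        return df


@dataclass(frozen=True)
class GroundTruthBN:
    """A known DAG with per-node CPTs for binary variables.

    ``cpts[node]`` holds P(node = 1) for every parent configuration; parent
    bits are ordered by sorted parent name, first parent most significant.
    ``zero_inflation`` is the (Monte-Carlo estimated) marginal probability of
    state 0 per feature.
    """

    dag: Dag
    cpts: Dict[str, np.ndarray]
    condition_name: str = DEFAULT_CONDITION
    zero_inflation: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.dag.topological_order()  # raises CycleError on a cyclic graph
        for node in self.dag.nodes:
            if node not in self.cpts:
                raise ValueError(f"node {node!r} has no CPT")
            cpt = np.asarray(self.cpts[node], dtype=float)
            q = 1 << len(self.dag.parents(node))
            if cpt.shape != (q,):
                raise ValueError(
                    f"CPT for {node!r} has shape {cpt.shape}, expected ({q},)"
                )
            if (cpt < 0).any() or (cpt > 1).any():
                raise ValueError(f"CPT for {node!r} holds probabilities outside [0, 1]")
            self.cpts[node] = cpt

    @property
    def features(self) -> Tuple[str, ...]:
        return tuple(v for v in self.dag.nodes if v != self.condition_name)

    def parent_config(self, node: str, states: Dict[str, int]) -> int:
        code = 0
        for p in sorted(self.dag.parents(node)):
            code = (code << 1) | states[p]
        return code


def _sample_states(bn: GroundTruthBN, n_samples: int, rng: np.random.Generator) -> pd.DataFrame:
    order = bn.dag.topological_order()
    cols: Dict[str, np.ndarray] = {}
    for node in order:
        parents = sorted(bn.dag.parents(node))
        if parents:
            code = np.zeros(n_samples, dtype=np.int64)
            for p in parents:
                code = (code << 1) | cols[p]
            p1 = bn.cpts[node][code]
        else:
            p1 = np.full(n_samples, bn.cpts[node][0])
        cols[node] = (rng.random(n_samples) < p1).astype(np.int8)
    return pd.DataFrame({v: cols[v] for v in bn.dag.nodes})


def generate_ground_truth(
    n_features: int,
    max_parents: int = 3,
    arc_density: float = 0.15,
    seed: Optional[int] = None,
    cpt_floor: float = 0.05,
    p_one_max: float = 0.5,
    condition_rate: float = STUDY_CONDITION_RATE,
    condition_name: str = DEFAULT_CONDITION,
) -> GroundTruthBN:
    """Random DAG over ``n_features`` features plus one condition node.

    A uniformly random topological order is drawn; each order-respecting arc
    is included with probability ``arc_density`` while the child has fewer
    than ``max_parents`` parents.  CPT probabilities of state 1 are uniform on
    ``[cpt_floor, p_one_max]`` — bounded away from 0/1 degeneracy and biased
    so that state 0 dominates, as in the study's count data.  A root
    condition node uses ``condition_rate`` instead (study split 22/24).
    Deterministic for a fixed seed.
    """
    if n_features < 1:
        raise ValueError(f"n_features must be >= 1, got {n_features}")
    if max_parents < 1:
        raise ValueError(f"max_parents must be >= 1, got {max_parents}")
    if not (0 <= arc_density < 1):
        raise ValueError(f"arc_density must lie in [0, 1), got {arc_density}")
    if not (0 < cpt_floor < p_one_max <= 1 - cpt_floor):
        raise ValueError("require 0 < cpt_floor < p_one_max <= 1 - cpt_floor")
    rng = np.random.default_rng(seed)
    nodes = [f"F{i + 1}" for i in range(n_features)] + [condition_name]
    order = [nodes[i] for i in rng.permutation(len(nodes))]
    dag = Dag(nodes)
    for j in range(1, len(order)):
        child = order[j]
        for i in range(j):
            if len(dag.parents(child)) >= max_parents:
                break
            if rng.random() < arc_density:
                dag.add_arc(order[i], child)
    cpts: Dict[str, np.ndarray] = {}
    for node in nodes:
        q = 1 << len(dag.parents(node))
        if node == condition_name and q == 1:
            cpts[node] = np.array([condition_rate])
        else:
            cpts[node] = rng.uniform(cpt_floor, p_one_max, size=q)
    bn = GroundTruthBN(dag=dag, cpts=cpts, condition_name=condition_name)
    zi_states = _sample_states(bn, 4096, np.random.default_rng(rng.integers(2**63)))
    zero_inflation = {f: float((zi_states[f] == 0).mean()) for f in bn.features}
    return GroundTruthBN(
        dag=dag, cpts=cpts, condition_name=condition_name, zero_inflation=zero_inflation
    )


def sample_counts(
    bn: GroundTruthBN,
    n_samples: int,
    max_count: int = STUDY_MAX_COUNT,
    count_lambda: float = 4.0,
    seed: Optional[int] = None,
    return_states: bool = False,
):
    """Ancestrally sample binary states and emit a zero-inflated CountMatrix.

    State 0 maps to count 0; state 1 to ``1 + Poisson(count_lambda)``
    truncated (by redraw) to ``[1, max_count]``.  The condition node becomes
    the condition column.  With ``return_states=True`` also returns the latent
    binary state table for recovery checks.
    """
    if n_samples < 1:
        raise ValueError(f"n_samples must be >= 1, got {n_samples}")
    if max_count < 1:
        raise ValueError(f"max_count must be >= 1, got {max_count}")
    try:
        bn.dag.topological_order()
    except CycleError:
        raise CycleError("ground-truth network is cyclic") from None
    rng = np.random.default_rng(seed)
    states = _sample_states(bn, n_samples, rng)
    features = list(bn.features)
    S = states[features].to_numpy(dtype=np.int64)
    counts = np.zeros_like(S)
    active = S == 1
    draws = 1 + rng.poisson(count_lambda, size=int(active.sum()))
    for _ in range(100):
        over = draws > max_count
        if not over.any():
            break
        draws[over] = 1 + rng.poisson(count_lambda, size=int(over.sum()))
    counts[active] = np.minimum(draws, max_count)
    m = CountMatrix(
        samples=tuple(f"S{i + 1}" for i in range(n_samples)),
        features=tuple(features),
        counts=counts,
        condition=states[bn.condition_name].to_numpy(),
        condition_name=bn.condition_name,
    )
    if return_states:
        return m, states
    return m
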