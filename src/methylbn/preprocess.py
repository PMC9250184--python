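"""Discretization of counts and chi-square contingency screening.

Counts are binarized with the threshold-at-zero rule (0 stays 0, any positive
count becomes 1) and the binary condition column is carried through unchanged.
Pairwise chi-square tests on the binary variables then produce a blocklist of
directed arcs whose endpoints show no evidence of dependence.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .exceptions import InvalidCountError

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import CountMatrix

Arc = Tuple[str, str]


@dataclass(frozen=True)
class BinaryDataset:
    """A 0/1 sample x variable table; variables = features + condition."""

    samples: Tuple[str, ...]
    variables: Tuple[str, ...]
    values: np.ndarray  # shape (n_samples, n_variables), dtype integer 0/1
    condition_name: str = "Treatment"

    def __post_init__(self):
        object.__setattr__(self, "samples", tuple(self.samples))
        object.__setattr__(self, "variables", tuple(self.variables))
        vals = np.asarray(self.values)
        if vals.shape != (len(self.samples), len(self.variables)):
            raise ValueError(
                f"values shape {vals.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variables)} variables"
            )
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("binary dataset holds values outside {0, 1}")
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("variable names are not unique")
        if self.variables.count(self.condition_name) != 1:
            raise ValueError(
                f"condition variable {self.condition_name!r} must appear exactly once"
            )
        object.__setattr__(self, "values", vals.astype(np.int8))

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def column(self, variable: str) -> np.ndarray:
        return self.values[:, self.variables.index(variable)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.samples), columns=list(self.variables))


@dataclass(frozen=True)
class ArcBlocklist:
    """Directed arcs excluded from structure search, with their p-values.

    ``blocked`` is direction-symmetric by construction: a pair that fails the
    dependence screen is blocked in both orientations.
    """

    blocked: frozenset
    pvalues: pd.DataFrame = field(repr=False)
    cutoff: float = 0.25

    def __post_init__(self):
        object.__setattr__(self, "blocked", frozenset(self.blocked))

    @classmethod
    def empty(cls, variables: Sequence[str] = ()) -> "ArcBlocklist":
        idx = list(variables)
        return cls(frozenset(), pd.DataFrame(np.nan, index=idx, columns=idx), 1.0)

    def is_blocked(self, u: str, v: str) -> bool:
        return (u, v) in self.blocked

    def __len__(self) -> int:
        return len(self.blocked)


def possible_arcs(variables: Sequence[str]) -> List[Arc]:
    """All ordered pairs of distinct variables, i.e. every arc a DAG could hold."""
    return [(u, v) for u, v in itertools.permutations(variables, 2)]


def binarize_counts(m: "CountMatrix") -> BinaryDataset:
    """Threshold counts at zero: count 0 -> state 0, count > 0 -> state 1.

    The condition column is appended unchanged as the last variable
    (0 = control, 1 = stress).
    """
    counts = np.asarray(m.counts)
    if not np.issubdtype(counts.dtype, np.integer):
        ints = np.floor(counts)
        bad = np.argwhere(ints != counts)
        if bad.size:
            i, j = bad[0]
            raise InvalidCountError(
                f"non-integer count {counts[i, j]!r} at sample "
                f"{m.samples[i]!r}, feature {m.features[j]!r}"
            )
        counts = counts.astype(np.int64)
    neg = np.argwhere(counts < 0)
    if neg.size:
        i, j = neg[0]
        raise InvalidCountError(
            f"negative count {counts[i, j]} at sample "
            f"{m.samples[i]!r}, feature {m.features[j]!r}"
        )
    values = np.concatenate(
        [(counts > 0).astype(np.int8), np.asarray(m.condition).reshape(-1, 1)], axis=1
    )
    return BinaryDataset(
        samples=tuple(m.samples),
        variables=tuple(m.features) + (m.condition_name,),
        values=values,
        condition_name=m.condition_name,
    )


def pairwise_chisq(d: BinaryDataset, yates: bool = True) -> pd.DataFrame:
    """Chi-square independence p-value for every unordered variable pair.

    Each pair is summarized as a 2x2 table of joint state counts and tested
    with Pearson's chi-square (Yates continuity correction by default, as in
    standard R ``chisq.test``; disable with ``yates=False``).  A variable that
    is constant across samples yields p = 1 against every partner — no
    evidence of dependence — and a warning is emitted.

    Returns a symmetric DataFrame with NaN on the diagonal.
    """
    if len(d.variables) < 2:
        raise ValueError("need at least 2 variables for pairwise tests")
    X = d.values
    names = d.variables
    for j, name in enumerate(names):
        if X[:, j].min() == X[:, j].max():
            warnings.warn(
                f"variable {name!r} is constant; its pairwise p-values are set to 1",
                UserWarning,
                stacklevel=2,
            )
    v = len(names)
    P = np.full((v, v), np.nan)
    for i, j in itertools.combinations(range(v), 2):
        table = np.bincount(2 * X[:, i] + X[:, j], minlength=4).reshape(2, 2)
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            p = 1.0  # zero-margin convention: maximally consistent with independence
        else:
            p = float(chi2_contingency(table, correction=yates).pvalue)
        P[i, j] = P[j, i] = p
    return pd.DataFrame(P, index=list(names), columns=list(names))


def build_blocklist(pvals: pd.DataFrame, cutoff: float = 0.25) -> ArcBlocklist:
    """Block both orientations of every pair with p-value >= ``cutoff``.

    The rule is inclusive: a pair at exactly the cut-off is blocked.
    """
    if not (0 < cutoff <= 1):
        raise ValueError(f"cutoff must lie in (0, 1], got {cutoff}")
    names = list(pvals.index)
    if list(pvals.columns) != names:
        raise ValueError("p-value table must be square with matching labels")
    blocked = set()
    arr = pvals.to_numpy()
    for i, j in itertools.combinations(range(len(names)), 2):
        p = arr[i, j]
        if np.isnan(p):
            raise ValueError(f"missing p-value for pair ({names[i]!r}, {names[j]!r})")
        if p >= cutoff:
            blocked.add((names[i], names[j]))
            blocked.add((names[j], names[i]))
    return ArcBlocklist(frozenset(blocked), pvals.copy(), cutoff)
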