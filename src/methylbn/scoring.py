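"""Bayesian Dirichlet equivalent (BDe) scoring of discrete DAGs on binary data.

The score decomposes over node families (child plus its parent set).  Each
family is scored with the Dirichlet-multinomial marginal likelihood under a
uniform prior that spreads the equivalent sample size (``ess``) evenly over
parent configurations and child states.  All arithmetic is done in the log
domain via :func:`scipy.special.gammaln`.
"""

from __future__ import annotations

from typing import TYPE_CHECKING, Iterable, Iterator, Optional, Tuple

import numpy as np
from scipy.special import gammaln

from .exceptions import CycleError

if TYPE_CHECKING:  # pragma: no cover
    from .preprocess import BinaryDataset

Arc = Tuple[str, str]

#: Move opcodes understood by :func:`delta_score` and the tabu search.
ADD, DELETE, REVERSE = "add", "delete", "reverse"


class Dag:
    """A directed acyclic graph over named nodes.

    Acyclicity is enforced on construction and after every mutation; a
    violating mutation raises :class:`~methylbn.exceptions.CycleError` and
    leaves the graph unchanged.
    """

    __slots__ = ("_nodes", "_pa", "_ch")

    def __init__(self, nodes: Iterable[str], arcs: Iterable[Arc] = ()) -> None:
        self._nodes: Tuple[str, ...] = tuple(nodes)
        if len(set(self._nodes)) != len(self._nodes):
            raise ValueError("duplicate node names")
        self._pa = {v: set() for v in self._nodes}
        self._ch = {v: set() for v in self._nodes}
        for u, v in arcs:
            self.add_arc(u, v)

    # -- introspection ----------------------------------------------------
    @property
    def nodes(self) -> Tuple[str, ...]:
        return self._nodes

    @property
    def arcs(self) -> set:
        return {(u, v) for v, ps in self._pa.items() for u in ps}

    @property
    def n_arcs(self) -> int:
        return sum(len(ps) for ps in self._pa.values())

    def parents(self, v: str) -> frozenset:
        return frozenset(self._pa[v])

    def children(self, v: str) -> frozenset:
        return frozenset(self._ch[v])

    def has_arc(self, u: str, v: str) -> bool:
        return u in self._pa[v]

    def has_path(self, u: str, v: str, skip_arc: Optional[Arc] = None) -> bool:
        """True if a directed path u -> ... -> v exists (``skip_arc`` ignored)."""
        if u == v:
            return True
        stack, seen = [u], {u}
        while stack:
            x = stack.pop()
            for y in self._ch[x]:
                if skip_arc is not None and (x, y) == skip_arc:
                    continue
                if y == v:
                    return True
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return False

    # -- mutation ---------------------------------------------------------
    def add_arc(self, u: str, v: str) -> None:
        if u not in self._pa or v not in self._pa:
            raise ValueError(f"unknown node in arc ({u!r}, {v!r})")
        if u == v:
            raise ValueError(f"self-loop on {u!r}")
        if u in self._pa[v]:
            raise ValueError(f"arc ({u!r}, {v!r}) already present")
        if self.has_path(v, u):
            raise CycleError(f"adding ({u!r}, {v!r}) would create a cycle")
        self._pa[v].add(u)
        self._ch[u].add(v)

    def remove_arc(self, u: str, v: str) -> None:
        if u not in self._pa.get(v, ()):
            raise ValueError(f"arc ({u!r}, {v!r}) not present")
        self._pa[v].remove(u)
        self._ch[u].remove(v)

    def reverse_arc(self, u: str, v: str) -> None:
        if not self.has_arc(u, v):
            raise ValueError(f"arc ({u!r}, {v!r}) not present")
        if self.has_path(u, v, skip_arc=(u, v)):
            raise CycleError(f"reversing ({u!r}, {v!r}) would create a cycle")
        self.remove_arc(u, v)
        self._pa[u].add(v)
        self._ch[v].add(u)

    # -- utilities --------------------------------------------------------
    def copy(self) -> "Dag":
        g = Dag.__new__(Dag)
        g._nodes = self._nodes
        g._pa = {v: set(ps) for v, ps in self._pa.items()}
        g._ch = {v: set(cs) for v, cs in self._ch.items()}
        return g

    def topological_order(self) -> list:
        indeg = {v: len(self._pa[v]) for v in self._nodes}
        ready = [v for v in self._nodes if indeg[v] == 0]
        order = []
        while ready:
            x = ready.pop()
            order.append(x)
            for y in self._ch[x]:
                indeg[y] -= 1
                if indeg[y] == 0:
                    ready.append(y)
        if len(order) != len(self._nodes):  # unreachable through public API
            raise CycleError("graph contains a cycle")
        return order

    def descendant_map(self) -> dict:
        """Node -> set of nodes reachable from it (excluding itself)."""
        desc = {v: set() for v in self._nodes}
        for v in reversed(self.topological_order()):
            for c in self._ch[v]:
                desc[v].add(c)
                desc[v] |= desc[c]
        return desc

    def __eq__(self, other) -> bool:
        if not isinstance(other, Dag):
            return NotImplemented
        return set(self._nodes) == set(other._nodes) and self.arcs == other.arcs

    def __hash__(self):
        return hash((frozenset(self._nodes), frozenset(self.arcs)))

    def __iter__(self) -> Iterator[str]:
        return iter(self._nodes)

    def __repr__(self) -> str:
        return f"Dag({len(self._nodes)} nodes, {self.n_arcs} arcs)"


class BDeCache:
    """Per-dataset family-score cache.

    Keys are ``(child, frozenset(parents))``; the 100-search protocol revisits
    the same families heavily, so the cache is shared across searches of a
    batch.
    """

    def __init__(self, data: "BinaryDataset", ess: float = 1.0) -> None:
        if ess <= 0:
            raise ValueError(f"ess must be positive, got {ess}")
        self.ess = float(ess)
        self.variables = tuple(data.variables)
        self._col = {v: i for i, v in enumerate(self.variables)}
        self._X = np.ascontiguousarray(data.values, dtype=np.int64)
        self.n_samples = self._X.shape[0]
        self._fam: dict = {}

    def family(self, child: str, parents: Iterable[str]) -> float:
        key = (child, frozenset(parents))
        hit = self._fam.get(key)
        if hit is not None:
            return hit
        score = self._compute(child, key[1])
        self._fam[key] = score
        return score

    def _compute(self, child: str, parents: frozenset) -> float:
        if child in parents:
            raise ValueError(f"child {child!r} cannot be its own parent")
        try:
            ci = self._col[child]
            pis = [self._col[p] for p in sorted(parents)]
        except KeyError as e:
            raise ValueError(f"unknown variable {e.args[0]!r}") from None
        X = self._X
        q = 1 << len(pis)
        a = self.ess / (2.0 * q)
        pcode = np.zeros(X.shape[0], dtype=np.int64)
        for p in pis:
            pcode <<= 1
            pcode |= X[:, p]
        joint = (pcode << 1) | X[:, ci]
        Njk = np.bincount(joint, minlength=2 * q).reshape(q, 2)
        Nj = Njk.sum(axis=1)
        score = float(
            np.sum(gammaln(2 * a) - gammaln(2 * a + Nj))
            + np.sum(gammaln(a + Njk) - gammaln(a))
        )
        return score


def family_score(
    data: "BinaryDataset", child: str, parents: Iterable[str], ess: float = 1.0
) -> float:
    """Log marginal likelihood contribution of one node family.

    For ``q`` parent configurations and 2 child states the prior pseudo-counts
    are ``alpha_jk = ess / (2 q)``, and the score is the sum over parent
    configurations ``j`` of::

        lnG(alpha_j) - lnG(alpha_j + N_j) + sum_k [lnG(alpha_jk + N_jk) - lnG(alpha_jk)]

    with ``alpha_j = sum_k alpha_jk`` and ``N_j = sum_k N_jk``.  With zero
    samples the score is 0 (empty product).
    """
    return BDeCache(data, ess).family(child, parents)


def bde_score(
    data: "BinaryDataset",
    g: Dag,
    ess: float = 1.0,
    cache: Optional[BDeCache] = None,
) -> float:
    """Total BDe log-score of ``g``: sum of family scores over all nodes."""
    if set(g.nodes) != set(data.variables):
        raise ValueError("graph nodes do not match dataset variables")
    c = cache if cache is not None else BDeCache(data, ess)
    return sum(c.family(v, g.parents(v)) for v in g.nodes)


def delta_score(
    data: "BinaryDataset",
    g: Dag,
    move: Tuple[str, str, str],
    ess: float = 1.0,
    cache: Optional[BDeCache] = None,
) -> Optional[float]:
    """Score change of one arc move, or ``None`` if the move is illegal.

    ``move`` is ``(op, u, v)`` with op one of ``"add"``, ``"delete"``,
    ``"reverse"``.  Only the affected families are recomputed: the child for
    add/delete, both endpoints for reverse.  Illegal moves (arc missing /
    present / cycle-creating) yield ``None`` rather than an exception so the
    search loop can treat them as a signal.
    """
    op, u, v = move
    if u == v or u not in g._pa or v not in g._pa:
        return None
    c = cache if cache is not None else BDeCache(data, ess)
    pa_v = g.parents(v)
    if op == ADD:
        if u in pa_v or g.has_path(v, u):
            return None
        return c.family(v, pa_v | {u}) - c.family(v, pa_v)
    if op == DELETE:
        if u not in pa_v:
            return None
        return c.family(v, pa_v - {u}) - c.family(v, pa_v)
    if op == REVERSE:
        if u not in pa_v or g.has_path(u, v, skip_arc=(u, v)):
            return None
        pa_u = g.parents(u)
        return (
            c.family(v, pa_v - {u})
            - c.family(v, pa_v)
            + c.family(u, pa_u | {v})
            - c.family(u, pa_u)
        )
    raise ValueError(f"unknown move op {op!r}")
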