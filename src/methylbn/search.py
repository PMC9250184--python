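"""Random-start tabu search over DAGs maximizing the BDe score.

Each search iterates over legal single-arc moves (add / delete / reverse),
excluding blocked arcs and cycle-creating moves, and accepts the best non-tabu
move each iteration (best-improvement with aspiration).  A batch runs
``n_starts`` independent searches from fresh random DAGs, with per-search
seeds derived deterministically from the master seed.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .preprocess import ArcBlocklist, BinaryDataset
from .scoring import ADD, DELETE, REVERSE, BDeCache, Dag

_TOL = 1e-12


@dataclass(frozen=True)
class SearchParams:
    """Knobs of one batch of tabu searches."""

    n_starts: int = 100
    tabu_length: int = 10
    max_stall: int = 10  # consecutive accepted non-improving moves before stopping
    max_iter: int = 10_000
    ess: float = 1.0
    seed: int = 0
    max_parents: Optional[int] = None
    arc_prob: Optional[float] = None  # None -> 2 / (n_nodes - 1)

    def __post_init__(self):
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.tabu_length < 0:
            raise ValueError("tabu_length must be >= 0")
        if self.ess <= 0:
            raise ValueError("ess must be positive")


@dataclass(frozen=True)
class ScoredNetwork:
    dag: Dag
    score: float
    search_id: int = 0
    seed: int = 0
    n_iterations: int = 0


def random_dag(
    nodes: Sequence[str],
    blocklist: Optional[ArcBlocklist] = None,
    arc_prob: float = 0.1,
    seed: Optional[int] = None,
    max_parents: Optional[int] = None,
) -> Dag:
    """Acyclic-by-construction random DAG.

    Draws a uniformly random topological order, then includes each
    order-respecting, non-blocked arc independently with probability
    ``arc_prob`` (subject to an optional parent cap).
    """
    nodes = list(nodes)
    if not nodes:
        raise ValueError("nodes must be non-empty")
    rng = np.random.default_rng(seed)
    order = [nodes[i] for i in rng.permutation(len(nodes))]
    g = Dag(nodes)
    for j in range(1, len(order)):
        child = order[j]
        for i in range(j):
            if max_parents is not None and len(g.parents(child)) >= max_parents:
                break
            if blocklist is not None and blocklist.is_blocked(order[i], child):
                continue
            if rng.random() < arc_prob:
                g.add_arc(order[i], child)
    return g


def _inverse(move: Tuple[str, str, str]) -> Tuple[str, str, str]:
    op, u, v = move
    if op == ADD:
        return (DELETE, u, v)
    if op == DELETE:
        return (ADD, u, v)
    return (REVERSE, v, u)


def tabu_search(
    d: BinaryDataset,
    blocklist: Optional[ArcBlocklist],
    start: Dag,
    params: SearchParams,
    cache: Optional[BDeCache] = None,
    search_id: int = 0,
    seed: int = 0,
) -> ScoredNetwork:
    """Best-improvement tabu search from ``start``; returns the best DAG visited.

    The tabu list holds the inverses of recently applied moves; a tabu move is
    only admitted when it beats the best score seen (aspiration).  After the
    score stops improving, up to ``params.max_stall`` consecutive
    non-improving best moves are still accepted to escape local optima.  Ties
    between equal-delta moves break to the lexicographically smallest
    ``(from, to, op)``, making the trajectory deterministic.
    """
    blk = blocklist if blocklist is not None else ArcBlocklist.empty(d.variables)
    for u, v in start.arcs:
        if blk.is_blocked(u, v):
            raise ValueError(f"starting graph contains blocked arc ({u!r}, {v!r})")
    if set(start.nodes) != set(d.variables):
        raise ValueError("start graph nodes do not match dataset variables")
    c = cache if cache is not None else BDeCache(d, params.ess)
    g = start.copy()
    fam = {v: c.family(v, g.parents(v)) for v in g.nodes}
    cur = sum(fam.values())
    best_g, best_s = g.copy(), cur
    tabu: deque = deque(maxlen=max(params.tabu_length, 1))
    cap = params.max_parents
    names = sorted(d.variables)
    stall = 0
    iters = 0
    while iters < params.max_iter:
        iters += 1
        desc = g.descendant_map()
        best_move = None
        best_delta = -np.inf
        for u in names:
            pa_u = g.parents(u)
            for v in names:
                if u == v:
                    continue
                pa_v = g.parents(v)
                if g.has_arc(u, v):
                    # delete u -> v
                    move = (DELETE, u, v)
                    delta = c.family(v, pa_v - {u}) - fam[v]
                    if delta > best_delta + _TOL and (
                        move not in tabu or cur + delta > best_s + _TOL
                    ):
                        best_move, best_delta = move, delta
                    # reverse u -> v
                    if (
                        not blk.is_blocked(v, u)
                        and (cap is None or len(pa_u) < cap)
                        and not g.has_path(u, v, skip_arc=(u, v))
                    ):
                        move = (REVERSE, u, v)
                        delta = (
                            c.family(v, pa_v - {u})
                            - fam[v]
                            + c.family(u, pa_u | {v})
                            - fam[u]
                        )
                        if delta > best_delta + _TOL and (
                            move not in tabu or cur + delta > best_s + _TOL
                        ):
                            best_move, best_delta = move, delta
                elif not g.has_arc(v, u):
                    # add u -> v
                    if blk.is_blocked(u, v) or u in desc[v]:
                        continue
                    if cap is not None and len(pa_v) >= cap:
                        continue
                    move = (ADD, u, v)
                    delta = c.family(v, pa_v | {u}) - fam[v]
                    if delta > best_delta + _TOL and (
                        move not in tabu or cur + delta > best_s + _TOL
                    ):
                        best_move, best_delta = move, delta
        if best_move is None:
            break
        op, u, v = best_move
        if op == ADD:
            g.add_arc(u, v)
            fam[v] = c.family(v, g.parents(v))
        elif op == DELETE:
            g.remove_arc(u, v)
            fam[v] = c.family(v, g.parents(v))
        else:
            g.reverse_arc(u, v)
            fam[v] = c.family(v, g.parents(v))
            fam[u] = c.family(u, g.parents(u))
        cur += best_delta
        if params.tabu_length:
            tabu.append(_inverse(best_move))
        if cur > best_s + _TOL:
            best_s, best_g = cur, g.copy()
            stall = 0
        else:
            stall += 1
            if stall > params.max_stall:
                break
    return ScoredNetwork(
        dag=best_g, score=best_s, search_id=search_id, seed=seed, n_iterations=iters
    )


def derive_seeds(master_seed: int, n: int) -> List[int]:
    """Deterministic, order-independent child seeds from a master seed."""
    return [
        int(np.random.SeedSequence(master_seed, spawn_key=(i,)).generate_state(1)[0])
        for i in range(n)
    ]


def run_search_batch(
    d: BinaryDataset,
    blocklist: Optional[ArcBlocklist],
    params: SearchParams,
    cache: Optional[BDeCache] = None,
) -> List[ScoredNetwork]:
    """``params.n_starts`` independent tabu searches from fresh random DAGs.

    All searches of a batch share one family-score cache; identical master
    seed implies an identical batch regardless of execution order (per-search
    seeds are derived by an indexed scheme, not by sequential consumption).
    """
    c = cache if cache is not None else BDeCache(d, params.ess)
    nodes = list(d.variables)
    arc_prob = params.arc_prob
    if arc_prob is None:
        arc_prob = 2.0 / max(len(nodes) - 1, 1)
    seeds = derive_seeds(params.seed, params.n_starts)
    batch = []
    for i, s in enumerate(seeds):
        start = random_dag(
            nodes, blocklist, arc_prob=arc_prob, seed=s, max_parents=params.max_parents
        )
        batch.append(
            tabu_search(d, blocklist, start, params, cache=c, search_id=i, seed=s)
        )
    return batch
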