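"""Multi-repetition consensus network and Markov-blanket extraction.

The batch -> average -> classify -> select cycle is repeated with independent
derived seeds; the consensus keeps the directed arcs selected in every
repetition, weighted by the arithmetic mean of their per-repetition
probabilities.  The Markov blanket of the condition node (parents, children,
spouses) is read off the consensus arc structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .averaging import arc_probabilities, classify_arcs, select_high_arcs
from .preprocess import ArcBlocklist, BinaryDataset
from .scoring import BDeCache
from .search import SearchParams, derive_seeds, run_search_batch

Arc = Tuple[str, str]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConsensusNetwork:
    """Directed arcs common to all repetitions, with averaged probabilities."""

    arcs: Dict[Arc, float]
    nodes: Tuple[str, ...]  # variables incident to >= 1 consensus arc
    n_repetitions: int
    universe: Optional[Tuple[str, ...]] = None  # all variables, incident or not

    def skeleton(self) -> set:
        return {frozenset(a) for a in self.arcs}


@dataclass(frozen=True)
class MarkovBlanketResult:
    target: str
    members: Tuple[str, ...]  # parents + children + spouses, sorted


def run_repetitions(
    d: BinaryDataset,
    blocklist: Optional[ArcBlocklist],
    params: SearchParams,
    n_reps: int = 50,
    prob_min: float = 0.5,
    unc_max: float = 0.01,
    cache: Optional[BDeCache] = None,
) -> List[Dict[Arc, float]]:
    """Selected high-probability arc sets (with probabilities) per repetition.

    Repetition seeds are derived from ``params.seed`` by an indexed scheme, so
    runs with the same master seed agree repetition-by-repetition and a longer
    run extends a shorter one.  The family-score cache is shared across
    repetitions (scores depend only on data and ess).
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    c = cache if cache is not None else BDeCache(d, params.ess)
    results = []
    for rep, rep_seed in enumerate(derive_seeds(params.seed, n_reps)):
        batch = run_search_batch(d, blocklist, replace(params, seed=rep_seed), cache=c)
        table = arc_probabilities(batch)
        if table.entries:
            cls = classify_arcs(table, fallback_threshold=prob_min)
            selected = select_high_arcs(cls, prob_min=prob_min, unc_max=unc_max)
        else:  # every top network was arc-free
            selected = {}
        logger.info(
            "repetition %d/%d: %d arcs selected (best score %.4f)",
            rep + 1, n_reps, len(selected), max(sn.score for sn in batch),
        )
        results.append(selected)
    return results


def build_consensus(
    reps: Sequence[Dict[Arc, float]],
    universe: Optional[Sequence[str]] = None,
    directed: bool = True,
) -> ConsensusNetwork:
    """Intersect per-repetition arc sets and average their probabilities.

    With ``directed=False`` the intersection is skeleton-level: an arc counts
    as common when either orientation was selected in every repetition; the
    orientation reported is the one from the first repetition, and the mean is
    taken over whichever orientation each repetition selected.
    """
    if not reps:
        raise ValueError("no repetition results given")
    if directed:
        common = set(reps[0])
        for r in reps[1:]:
            common &= set(r)
        arcs = {a: sum(r[a] for r in reps) / len(reps) for a in common}
    else:
        common_skel = {frozenset(a) for a in reps[0]}
        for r in reps[1:]:
            common_skel &= {frozenset(a) for a in r}
        arcs = {}
        for a in reps[0]:
            if frozenset(a) not in common_skel:
                continue
            vals = []
            for r in reps:
                if a in r:
                    vals.append(r[a])
                else:
                    vals.append(r[(a[1], a[0])])
            arcs[a] = sum(vals) / len(reps)
    if not arcs:
        logger.warning("consensus is empty: no arc survived all %d repetitions", len(reps))
    nodes = tuple(sorted({n for a in arcs for n in a}))
    return ConsensusNetwork(
        arcs=arcs,
        nodes=nodes,
        n_repetitions=len(reps),
        universe=tuple(universe) if universe is not None else None,
    )


def markov_blanket(c: ConsensusNetwork, target: str) -> MarkovBlanketResult:
    """Parents, children, and co-parents of children of ``target``.

    The consensus graph is treated as a directed graph as-is (it is an arc
    summary, not necessarily a single DAG).  A target with no incident arcs
    has an empty blanket.
    """
    known = c.universe if c.universe is not None else c.nodes
    if target not in known:
        raise ValueError(f"unknown target variable {target!r}")
    parents = {u for (u, v) in c.arcs if v == target}
    children = {v for (u, v) in c.arcs if u == target}
    spouses = {u for (u, v) in c.arcs if v in children}
    members = (parents | children | spouses) - {target}
    return MarkovBlanketResult(target=target, members=tuple(sorted(members)))
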