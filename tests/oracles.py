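"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: scores are recomputed
with plain Python loops and ``math.lgamma``, DAGs are enumerated exhaustively,
and Markov blankets / equivalence classes are derived via networkx
d-separation.
"""

import itertools
from math import lgamma

import networkx as nx


def naive_family_score(rows, child_idx, parent_idxs, ess=1.0):
    """Dirichlet-multinomial family log-score by explicit enumeration."""
    k = len(parent_idxs)
    q = 2 ** k
    a = ess / (2.0 * q)
    score = 0.0
    for j in range(q):
        bits = [(j >> (k - 1 - i)) & 1 for i in range(k)]
        njk = [0, 0]
        for row in rows:
            if all(row[p] == bits[i] for i, p in enumerate(parent_idxs)):
                njk[row[child_idx]] += 1
        nj = njk[0] + njk[1]
        score += lgamma(2 * a) - lgamma(2 * a + nj)
        for c in range(2):
            score += lgamma(a + njk[c]) - lgamma(a)
    return score


def naive_bde(rows, variables, arcs, ess=1.0):
    """Whole-graph BDe log-score without caching or vectorization."""
    idx = {v: i for i, v in enumerate(variables)}
    total = 0.0
    for v in variables:
        parents = [u for (u, w) in arcs if w == v]
        total += naive_family_score(rows, idx[v], [idx[p] for p in parents], ess)
    return total


def enumerate_dags(nodes):
    """All labeled DAGs over ``nodes`` as lists of arcs (brute force)."""
    pairs = list(itertools.permutations(nodes, 2))
    dags = []
    for mask in range(2 ** len(pairs)):
        arcs = [pairs[i] for i in range(len(pairs)) if mask >> i & 1]
        g = nx.DiGraph(arcs)
        g.add_nodes_from(nodes)
        if nx.is_directed_acyclic_graph(g):
            dags.append(arcs)
    return dags


def cpdag_class(nodes, arcs):
    """Markov-equivalence key: (skeleton, v-structures)."""
    skeleton = frozenset(frozenset(a) for a in arcs)
    arcset = set(arcs)
    vstructs = set()
    for (a, c), (b, c2) in itertools.permutations(arcs, 2):
        if c == c2 and a != b and frozenset((a, b)) not in skeleton:
            vstructs.add((frozenset((a, b)), c))
    return (skeleton, frozenset(vstructs))


def has_cycle(nodes, arcs):
    """DFS three-color cycle detection, independent of the package's Dag."""
    adj = {n: [] for n in nodes}
    for u, v in arcs:
        adj[u].append(v)
    color = {n: 0 for n in nodes}

    def visit(n):
        color[n] = 1
        for m in adj[n]:
            if color[m] == 1 or (color[m] == 0 and visit(m)):
                return True
        color[n] = 2
        return False

    return any(color[n] == 0 and visit(n) for n in nodes)


def dsep_markov_blanket(nodes, arcs, target):
    """w is in MB(target) iff target and w are NOT d-separated given all others."""
    g = nx.DiGraph(arcs)
    g.add_nodes_from(nodes)
    members = set()
    for w in nodes:
        if w == target:
            continue
        rest = set(nodes) - {target, w}
        if not nx.is_d_separator(g, {target}, {w}, rest):
            members.add(w)
    return members
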