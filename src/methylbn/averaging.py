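"""Score-weighted arc-probability model averaging and high/low classification.

Networks are weighted by a softmax over their BDe log-scores (posterior-
proportional weighting); an arc's probability is the total weight of the
networks containing it.  Arc probabilities are then clustered into a high and
a low group with a two-component 1-D Gaussian mixture fitted by EM, and the
highly probable arcs are selected with inclusive probability / uncertainty
cut-offs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.special import logsumexp

from .search import ScoredNetwork

Arc = Tuple[str, str]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ArcProbabilityTable:
    """Arc -> probability of belonging to a high-scoring network."""

    entries: Dict[Arc, float]
    weights: np.ndarray  # normalized per-network weights, sum to 1

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)

    def probability(self, arc: Arc) -> float:
        return self.entries.get(arc, 0.0)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class ArcClassification:
    """High/low cluster label and membership uncertainty per arc."""

    probabilities: Dict[Arc, float]
    labels: Dict[Arc, str]  # "high" | "low"
    uncertainties: Dict[Arc, float]  # 1 - posterior of the assigned cluster
    fallback: bool = False  # True when the degenerate-input rule was used
    cluster_means: Optional[Tuple[float, float]] = None  # (low, high)


def arc_probabilities(batch: Sequence[ScoredNetwork]) -> ArcProbabilityTable:
    """Softmax-weighted frequency of each arc over a batch of scored networks.

    Weight of network i is ``exp(s_i - s_max) / sum_j exp(s_j - s_max)``;
    duplicates keep their weight mass.  Arcs absent from every network are
    omitted (probability 0 implicitly).
    """
    if not batch:
        raise ValueError("batch of scored networks is empty")
    scores = np.array([sn.score for sn in batch], dtype=float)
    w = np.exp(scores - scores.max())
    w /= w.sum()
    entries: Dict[Arc, float] = {}
    for sn, wi in zip(batch, w):
        for arc in sn.dag.arcs:
            entries[arc] = entries.get(arc, 0.0) + float(wi)
    entries = {a: min(p, 1.0) for a, p in entries.items()}
    return ArcProbabilityTable(entries=entries, weights=w)


def _em_two_gaussians(
    x: np.ndarray, max_iter: int, tol: float, var_floor: float = 1e-10
):
    """EM for a 2-component 1-D Gaussian mixture, quantile-initialized.

    Returns (responsibilities, means) or None on collapse.  Deterministic:
    component means start at the 25th/75th percentiles, variances at the
    overall variance, weights at 1/2.
    """
    mu = np.percentile(x, [25.0, 75.0])
    var = np.full(2, max(x.var(), var_floor))
    pi = np.array([0.5, 0.5])
    prev_ll = -np.inf
    r = None
    for _ in range(max_iter):
        log_pdf = (
            -0.5 * (x[:, None] - mu[None, :]) ** 2 / var[None, :]
            - 0.5 * (np.log(var[None, :]) + _LOG_2PI)
            + np.log(pi[None, :])
        )
        norm = logsumexp(log_pdf, axis=1)
        r = np.exp(log_pdf - norm[:, None])
        ll = float(norm.sum())
        nk = r.sum(axis=0)
        if (nk < 1e-9).any():
            return None  # a component lost all mass
        pi = nk / len(x)
        mu = (r * x[:, None]).sum(axis=0) / nk
        var = (r * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        var = np.maximum(var, var_floor)
        if abs(ll - prev_ll) < tol:
            break
        prev_ll = ll
    if r is None or not np.isfinite(mu).all():
        return None
    return r, mu


def classify_arcs(
    table: ArcProbabilityTable,
    max_iter: int = 500,
    tol: float = 1e-8,
    fallback_threshold: float = 0.5,
) -> ArcClassification:
    """Two-cluster (high/low) classification of arc probabilities via EM.

    The component with the larger mean is labeled "high"; per-arc uncertainty
    is ``1 - max posterior responsibility``.  Inputs with fewer than 4
    distinct probability values (or an EM collapse) fall back to a hard
    threshold at ``fallback_threshold`` with zero uncertainty, flagged via
    ``fallback=True``.
    """
    if not table.entries:
        raise ValueError("arc probability table is empty")
    arcs = sorted(table.entries)
    x = np.array([table.entries[a] for a in arcs], dtype=float)
    fit = None
    if len(np.unique(x)) >= 4:
        fit = _em_two_gaussians(x, max_iter=max_iter, tol=tol)
    if fit is None:
        labels = {a: ("high" if p >= fallback_threshold else "low") for a, p in zip(arcs, x)}
        return ArcClassification(
            probabilities=dict(zip(arcs, map(float, x))),
            labels=labels,
            uncertainties={a: 0.0 for a in arcs},
            fallback=True,
        )
    r, mu = fit
    hi = int(np.argmax(mu))
    assign = np.argmax(r, axis=1)
    labels = {a: ("high" if k == hi else "low") for a, k in zip(arcs, assign)}
    unc = {a: float(1.0 - r[i, assign[i]]) for i, a in enumerate(arcs)}
    lo_mean, hi_mean = float(mu[1 - hi]), float(mu[hi])
    return ArcClassification(
        probabilities=dict(zip(arcs, map(float, x))),
        labels=labels,
        uncertainties=unc,
        fallback=False,
        cluster_means=(lo_mean, hi_mean),
    )


def select_high_arcs(
    c: ArcClassification, prob_min: float = 0.5, unc_max: float = 0.01
) -> Dict[Arc, float]:
    """Arcs labeled high with probability >= prob_min and uncertainty <= unc_max.

    Both bounds are inclusive; the label gate precedes the thresholds.  An
    empty result is valid.
    """
    return {
        a: c.probabilities[a]
        for a in c.probabilities
        if c.labels[a] == "high"
        and c.probabilities[a] >= prob_min
        and c.uncertainties[a] <= unc_max
    }
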