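"""Readers and writers for the tab-delimited file dialects.

Count matrices use the layout of the study data: a header row of feature
names plus the condition column ("Treatment"), one row per individual.  Arc
tables use columns ``arc`` (index), ``from``, ``to``, ``Average.Probability``.
All files are plain text and round-trip losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .averaging import ArcClassification
from .exceptions import (
    DuplicateFeatureError,
    InvalidCountError,
    MissingConditionError,
)
from .preprocess import ArcBlocklist, BinaryDataset
from .scoring import Dag
from .search import ScoredNetwork
from .consensus import ConsensusNetwork
from .synthetic import CountMatrix, GroundTruthBN

Arc = Tuple[str, str]

#: Probability bands used as edge attributes (Fig.-style color coding).
BANDS = [
    (0.90, "0.90-1.00", "black"),
    (0.80, "0.80-0.89", "blue"),
    (0.70, "0.70-0.79", "grey"),
    (0.60, "0.60-0.69", "orange"),
]

_SAMPLE_COLUMNS = {"", "Sample", "sample", "Unnamed: 0"}


def probability_band(p: float) -> str:
    for lo, band, _ in BANDS:
        if p >= lo:
            return band
    return "<0.60"


def _band_color(p: float) -> str:
    for lo, _, color in BANDS:
        if p >= lo:
            return color
    return "gray50"


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

def read_count_matrix(path, condition_name: str = "Treatment") -> CountMatrix:
    """Parse a tab-delimited count table into a CountMatrix.

    Column order is preserved.  An optional leading sample-identifier column
    (named "Sample" or unnamed) is honoured; otherwise samples are named
    ``S1..Sn``.  Raises distinct errors for a duplicated feature name, a
    missing condition column, and a non-integer cell.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    body = [c for c in header if c not in _SAMPLE_COLUMNS]
    dupes = {c for c in body if body.count(c) > 1}
    if dupes:
        raise DuplicateFeatureError(f"duplicate feature name(s): {sorted(dupes)}")
    if condition_name not in body:
        raise MissingConditionError(
            f"condition column {condition_name!r} not found in {path.name}"
        )
    df = pd.read_csv(path, sep="\t", dtype=str)
    first = df.columns[0]
    if first in _SAMPLE_COLUMNS:
        samples = [str(s) for s in df[first]]
        df = df.drop(columns=[first])
    else:
        samples = [f"S{i + 1}" for i in range(len(df))]
    features = [c for c in df.columns if c != condition_name]
    values = np.empty((len(df), len(df.columns)), dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            try:
                values[i, j] = int(cell)
            except (TypeError, ValueError):
                raise InvalidCountError(
                    f"non-integer value {cell!r} at sample {samples[i]!r}, column {col!r}"
                ) from None
    fidx = [df.columns.get_loc(c) for c in features]
    return CountMatrix(
        samples=tuple(samples),
        features=tuple(features),
        counts=values[:, fidx],
        condition=values[:, df.columns.get_loc(condition_name)],
        condition_name=condition_name,
    )


def write_count_matrix(m: CountMatrix, path, include_samples: bool = False) -> None:
    df = m.to_frame()
    if include_samples:
        df.index.name = "Sample"
    df.to_csv(path, sep="\t", index=include_samples)


# ---------------------------------------------------------------------------
# binary datasets
# ---------------------------------------------------------------------------

def write_binary_dataset(d: BinaryDataset, path) -> None:
    d.to_frame().to_csv(path, sep="\t", index=False)


def read_binary_dataset(path, condition_name: str = "Treatment") -> BinaryDataset:
    df = pd.read_csv(path, sep="\t")
    first = df.columns[0]
    if first in _SAMPLE_COLUMNS:
        samples = tuple(str(s) for s in df[first])
        df = df.drop(columns=[first])
    else:
        samples = tuple(f"S{i + 1}" for i in range(len(df)))
    return BinaryDataset(
        samples=samples,
        variables=tuple(df.columns),
        values=df.to_numpy(dtype=np.int8),
        condition_name=condition_name,
    )


# ---------------------------------------------------------------------------
# p-values and blocklists
# ---------------------------------------------------------------------------

def write_pvalue_matrix(pvals: pd.DataFrame, path) -> None:
    pvals.to_csv(path, sep="\t")


def read_pvalue_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")


def write_blocklist(blk: ArcBlocklist, path) -> None:
    rows = sorted(blk.blocked)
    with open(path, "w") as fh:
        fh.write("from\tto\n")
        for u, v in rows:
            fh.write(f"{u}\t{v}\n")


def read_blocklist(path, pvalues: Optional[pd.DataFrame] = None,
                   cutoff: float = 0.25) -> ArcBlocklist:
    df = pd.read_csv(path, sep="\t")
    blocked = frozenset((str(u), str(v)) for u, v in zip(df["from"], df["to"]))
    if pvalues is None:
        names = sorted({n for a in blocked for n in a})
        pvalues = pd.DataFrame(np.nan, index=names, columns=names)
    return ArcBlocklist(blocked, pvalues, cutoff)


# ---------------------------------------------------------------------------
# arc tables (consensus / per-repetition)
# ---------------------------------------------------------------------------

def write_arc_table(arcs: Dict[Arc, float], path) -> None:
    """Columns arc, from, to, Average.Probability; ordered by descending
    probability then lexicographic (from, to)."""
    items = sorted(arcs.items(), key=lambda kv: (-kv[1], kv[0]))
    df = pd.DataFrame(
        {
            "arc": range(1, len(items) + 1),
            "from": [a[0] for a, _ in items],
            "to": [a[1] for a, _ in items],
            "Average.Probability": [p for _, p in items],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_arc_table(path) -> Dict[Arc, float]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return {
        (str(u), str(v)): float(p)
        for u, v, p in zip(df["from"], df["to"], df["Average.Probability"])
    }


def write_classified_arcs(cls: ArcClassification, path) -> None:
    items = sorted(
        cls.probabilities.items(), key=lambda kv: (-kv[1], kv[0])
    )
    df = pd.DataFrame(
        {
            "from": [a[0] for a, _ in items],
            "to": [a[1] for a, _ in items],
            "probability": [p for _, p in items],
            "cluster": [cls.labels[a] for a, _ in items],
            "uncertainty": [cls.uncertainties[a] for a, _ in items],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# search batches
# ---------------------------------------------------------------------------

def write_batch(batch: Sequence[ScoredNetwork], edges_path, scores_path) -> None:
    """Edge-list-per-network archive plus a scores sidecar file."""
    with open(edges_path, "w") as fh:
        fh.write("search_id\tfrom\tto\n")
        for sn in batch:
            for u, v in sorted(sn.dag.arcs):
                fh.write(f"{sn.search_id}\t{u}\t{v}\n")
    with open(scores_path, "w") as fh:
        fh.write("search_id\tseed\titerations\tscore\n")
        for sn in batch:
            fh.write(f"{sn.search_id}\t{sn.seed}\t{sn.n_iterations}\t{sn.score!r}\n")


def read_batch(edges_path, scores_path, variables: Sequence[str]) -> List[ScoredNetwork]:
    edges = pd.read_csv(edges_path, sep="\t")
    scores = pd.read_csv(scores_path, sep="\t", float_precision="round_trip")
    arcs_by_id: Dict[int, list] = {int(i): [] for i in scores["search_id"]}
    for i, u, v in zip(edges["search_id"], edges["from"], edges["to"]):
        arcs_by_id[int(i)].append((str(u), str(v)))
    batch = []
    for _, row in scores.iterrows():
        sid = int(row["search_id"])
        batch.append(
            ScoredNetwork(
                dag=Dag(variables, arcs_by_id.get(sid, [])),
                score=float(row["score"]),
                search_id=sid,
                seed=int(row["seed"]),
                n_iterations=int(row["iterations"]),
            )
        )
    return batch


# ---------------------------------------------------------------------------
# graph exports
# ---------------------------------------------------------------------------

def consensus_to_nx(c: ConsensusNetwork) -> nx.DiGraph:
    g = nx.DiGraph()
    for n in c.nodes:
        g.add_node(n)
    for (u, v), p in sorted(c.arcs.items()):
        g.add_edge(u, v, probability=float(p), band=probability_band(p))
    return g


def write_graphml(c: ConsensusNetwork, path) -> None:
    nx.write_graphml(consensus_to_nx(c), path)


def write_dot(c: ConsensusNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("digraph consensus {\n")
        for n in c.nodes:
            fh.write(f'  "{n}";\n')
        for (u, v), p in sorted(c.arcs.items()):
            fh.write(
                f'  "{u}" -> "{v}" [label="{p:.2f}", weight={p:.6f}, '
                f'color="{_band_color(p)}", band="{probability_band(p)}"];\n'
            )
        fh.write("}\n")


def write_truth_edges(bn: GroundTruthBN, path) -> None:
    with open(path, "w") as fh:
        fh.write("from\tto\n")
        for u, v in sorted(bn.dag.arcs):
            fh.write(f"{u}\t{v}\n")


def write_truth_graphml(bn: GroundTruthBN, path) -> None:
    g = nx.DiGraph()
    for n in bn.dag.nodes:
        g.add_node(n)
    for u, v in sorted(bn.dag.arcs):
        g.add_edge(u, v)
    nx.write_graphml(g, path)


# ---------------------------------------------------------------------------
# provenance
# ---------------------------------------------------------------------------

def write_provenance(record: dict, path) -> None:
    record = dict(record)
    record.setdefault("versions", {})
    record["versions"].update(
        {
            "methylbn": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "networkx": nx.__version__,
        }
    )
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")
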