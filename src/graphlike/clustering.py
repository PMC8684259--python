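"""Agglomerative hierarchical clustering with dendrogram "crop" selection.

Rows (entities) of any visible or selected submatrix are clustered under a
chosen distance (cosine, correlation, euclidean) and linkage (average,
complete, single). The resulting binary merge tree supports cropping: any
node's leaf set becomes an entity selection that can be pushed back into
the linked data browser, synchronising the heatmap view with every other
table.

Merging is deterministic: ties on merge distance are broken by the
lexicographically smallest leaf labels of the candidate pair, so permuting
input rows yields an isomorphic tree. Missing values are handled by
pairwise-complete distance computation; rows that leave some pairwise
distance undefined (fewer than 2 shared observations) are dropped with a
warning.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .formats_io import FormatWarning

__all__ = [
    "DendroNode",
    "Dendrogram",
    "pairwise_distances",
    "hierarchical_cluster",
    "crop",
    "cophenetic_distances",
]

DISTANCES = ("cosine", "correlation", "euclidean")
LINKAGES = ("average", "complete", "single")


@dataclasses.dataclass
class DendroNode:
    node_id: str
    height: float
    leaves: frozenset[str]
    children: tuple[str, str] | None = None  # None for leaves


@dataclasses.dataclass
class Dendrogram:
    """Binary merge tree; leaves are entity labels, internal nodes 'n<i>'."""

    nodes: dict[str, DendroNode]
    root: str
    leaf_order: list[str]  # left-to-right traversal order
    merges: pd.DataFrame  # step, left, right, height, size

    def internal_nodes(self) -> list[str]:
        return [n for n, node in self.nodes.items() if node.children is not None]

    def to_nested(self, node_id: str | None = None) -> dict:
        node = self.nodes[self.root if node_id is None else node_id]
        if node.children is None:
            return {"id": node.node_id, "height": 0.0, "leaf": node.node_id}
        return {
            "id": node.node_id,
            "height": node.height,
            "children": [self.to_nested(c) for c in node.children],
        }


def crop(dendrogram: Dendrogram, node_id: str) -> set[str]:
    """Leaf set of a dendrogram node — the 'cropped' cluster selection."""
    if node_id not in dendrogram.nodes:
        raise KeyError(f"unknown dendrogram node: {node_id!r}")
    return set(dendrogram.nodes[node_id].leaves)


# ---------------------------------------------------------------------------
# distances


def _pair_distance(u: np.ndarray, v: np.ndarray, metric: str) -> float:
    shared = ~np.isnan(u) & ~np.isnan(v)
    if shared.sum() < 2:
        return np.nan
    a, b = u[shared], v[shared]
    if metric == "euclidean":
        return float(np.sqrt(np.sum((a - b) ** 2)))
    if metric == "cosine":
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0 or nb == 0:
            return np.nan
        return float(1.0 - np.dot(a, b) / (na * nb))
    # correlation
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return np.nan
    return float(1.0 - np.dot(a, b) / (na * nb))


def pairwise_distances(values: pd.DataFrame, metric: str = "cosine") -> pd.DataFrame:
    """Pairwise-complete row distances; NaN where <2 shared observations."""
    if metric not in DISTANCES:
        raise ValueError(f"unknown distance: {metric!r} (use one of {DISTANCES})")
    X = values.to_numpy(dtype=float)
    n = X.shape[0]
    if metric == "correlation":
        for label, row in zip(values.index, X):
            obs = row[~np.isnan(row)]
            if len(obs) and obs.std() == 0:
                raise ValueError(
                    f"row {label!r} has zero variance; correlation distance undefined"
                )
    complete = not np.isnan(X).any()
    D = np.zeros((n, n))
    if complete and metric == "euclidean":
        sq = (X[:, None, :] - X[None, :, :]) ** 2
        D = np.sqrt(sq.sum(axis=2))
    elif complete and metric in ("cosine", "correlation"):
        Y = X - X.mean(axis=1, keepdims=True) if metric == "correlation" else X
        norms = np.linalg.norm(Y, axis=1)
        if np.any(norms == 0):
            bad = values.index[np.flatnonzero(norms == 0)[0]]
            raise ValueError(f"row {bad!r} has zero norm; {metric} distance undefined")
        D = 1.0 - (Y @ Y.T) / np.outer(norms, norms)
        np.fill_diagonal(D, 0.0)
    else:
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = _pair_distance(X[i], X[j], metric)
    return pd.DataFrame(D, index=values.index, columns=values.index)


def _drop_undefined(D: pd.DataFrame) -> pd.DataFrame:
    """Greedily drop rows involved in NaN distances, worst offender first."""
    D = D.copy()
    while True:
        nan_counts = D.isna().sum(axis=1)
        if nan_counts.max() == 0:
            return D
        worst = nan_counts.idxmax()
        warnings.warn(
            f"dropping row {worst!r}: too few shared observations for distances",
            FormatWarning,
            stacklevel=3,
        )
        D = D.drop(index=worst, columns=worst)


# ---------------------------------------------------------------------------
# agglomeration


def hierarchical_cluster(
    values: pd.DataFrame,
    distance: str = "cosine",
    linkage: str = "average",
) -> Dendrogram:
    """Agglomerative clustering of the rows of ``values``.

    Cluster distances are updated with the Lance-Williams recurrences for
    the chosen linkage (average = unweighted pair-group mean). Returns the
    full merge tree with per-node heights and leaf sets.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage: {linkage!r} (use one of {LINKAGES})")
    if len(values) < 2:
        raise ValueError("clustering needs at least 2 rows")
    if values.index.has_duplicates:
        raise ValueError("row labels must be unique")
    D = _drop_undefined(pairwise_distances(values, metric=distance))
    labels = [str(x) for x in D.index]
    if len(labels) < 2:
        raise ValueError("fewer than 2 rows remain after dropping undefined distances")

    nodes: dict[str, DendroNode] = {
        lab: DendroNode(node_id=lab, height=0.0, leaves=frozenset([lab])) for lab in labels
    }
    # active cluster id -> (size, min leaf label)
    active: dict[str, tuple[int, str]] = {lab: (1, lab) for lab in labels}
    dist: dict[frozenset[str], float] = {}
    arr = D.to_numpy()
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            dist[frozenset((labels[i], labels[j]))] = float(arr[i, j])

    merges = []
    step = 0
    while len(active) > 1:
        # deterministic pick: smallest distance, ties by smallest leaf labels
        best = min(
            (
                (dist[frozenset((a, b))], *sorted((active[a][1], active[b][1])), a, b)
                for idx, a in enumerate(sorted(active))
                for b in sorted(active)[idx + 1:]
            ),
        )
        d, _, _, a, b = best
        # orient children so the lexicographically smaller min-leaf comes first
        if active[b][1] < active[a][1]:
            a, b = b, a
        new_id = f"n{step}"
        leaves = nodes[a].leaves | nodes[b].leaves
        nodes[new_id] = DendroNode(node_id=new_id, height=d, leaves=leaves, children=(a, b))
        size_a, min_a = active.pop(a)
        size_b, min_b = active.pop(b)
        for other in active:
            da = dist.pop(frozenset((a, other)))
            db = dist.pop(frozenset((b, other)))
            if linkage == "single":
                dn = min(da, db)
            elif linkage == "complete":
                dn = max(da, db)
            else:  # average (UPGMA)
                dn = (size_a * da + size_b * db) / (size_a + size_b)
            dist[frozenset((new_id, other))] = dn
        dist.pop(frozenset((a, b)), None)
        active[new_id] = (size_a + size_b, min(min_a, min_b))
        merges.append((step, a, b, d, size_a + size_b))
        step += 1

    root = next(iter(active))

    def leaf_order(node_id: str) -> list[str]:
        node = nodes[node_id]
        if node.children is None:
            return [node_id]
        return leaf_order(node.children[0]) + leaf_order(node.children[1])

    return Dendrogram(
        nodes=nodes,
        root=root,
        leaf_order=leaf_order(root),
        merges=pd.DataFrame(merges, columns=["step", "left", "right", "height", "size"]),
    )


def cophenetic_distances(dendrogram: Dendrogram) -> pd.DataFrame:
    """Leaf x leaf matrix of merge heights at the lowest common ancestor."""
    leaves = dendrogram.leaf_order
    out = pd.DataFrame(0.0, index=leaves, columns=leaves)
    for node_id in dendrogram.internal_nodes():
        node = dendrogram.nodes[node_id]
        left = sorted(dendrogram.nodes[node.children[0]].leaves)
        right = sorted(dendrogram.nodes[node.children[1]].leaves)
        for u in left:
            for v in right:
                out.loc[u, v] = out.loc[v, u] = node.height
    return out


def snapshot(
    values: pd.DataFrame, dendrogram: Dendrogram, zscore_rows: bool = True
) -> pd.DataFrame:
    """'Take snapshot' export: the matrix in dendrogram leaf order.

    Rows are z-scored for display by default (the heatmap convention);
    disable to export the raw values.
    """
    ordered = values.loc[dendrogram.leaf_order]
    if zscore_rows:
        arr = ordered.to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(arr, axis=1, keepdims=True)
            sd = np.nanstd(arr, axis=1, ddof=1, keepdims=True)
        sd = np.where(sd == 0, 1.0, sd)
        ordered = pd.DataFrame((arr - mean) / sd, index=ordered.index, columns=ordered.columns)
    return ordered
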