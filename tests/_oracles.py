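"""Independent brute-force oracles, kept deliberately naive.

Each function here re-derives an expected result straight from the
definitions (edge-tuple enumeration, Fraction arithmetic, literal step-up
sorting, from-scratch cluster distances) without touching the package's
optimised code paths, so agreement is meaningful.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# graph connectivity


def edge_sets(graph_file):
    """Raw edge tuples by kind, straight from the file frame."""
    enc, par, mem = set(), set(), set()
    for row in graph_file.edges.itertuples(index=False):
        if row.edge_kind == "encodes":
            enc.add((row.source_id, row.target_id))
        elif row.edge_kind == "participates":
            par.add((row.source_id, row.target_id))
        else:
            mem.add((row.source_id, row.target_id))
    return enc, par, mem


def oracle_connected(graph_file, a: str, b: str) -> bool:
    """Literal enumeration of the allowed path patterns."""
    kind = dict(zip(graph_file.nodes["node_id"], graph_file.nodes["node_kind"]))
    enc, par, mem = edge_sets(graph_file)
    ka, kb = kind[a], kind[b]
    if ka == kb:
        return a == b
    order = ["transcript", "protein", "metabolite", "reaction", "pathway"]
    if order.index(ka) > order.index(kb):
        a, b, ka, kb = b, a, kb, ka
    proteins = {p for (t, p) in enc if t == a} if ka == "transcript" else {a}
    if (ka, kb) == ("transcript", "protein"):
        return (a, b) in enc
    if (ka, kb) in (("protein", "reaction"), ("metabolite", "reaction")):
        return (a, b) in par
    if (ka, kb) == ("reaction", "pathway"):
        return (a, b) in mem
    if (ka, kb) == ("transcript", "reaction"):
        return any((p, b) in par for p in proteins)
    if kb == "metabolite":
        # transcript/protein to metabolite through one shared reaction
        sources = proteins if ka == "transcript" else {a}
        return any(
            (s, r) in par and (b, r) in par
            for s in sources
            for r in {r for (_, r) in par}
        )
    if kb == "pathway":
        sources = proteins if ka == "transcript" else {a}
        return any(
            (s, r) in par and (r, b) in mem
            for s in sources
            for (r, _) in mem
        )
    raise AssertionError(f"unhandled pair {ka}/{kb}")


def oracle_visible(graph_file, groups, kind: str) -> set[str]:
    """The forall/exists selection definition, evaluated literally."""
    nodes = set(
        graph_file.nodes.loc[graph_file.nodes["node_kind"] == kind, "node_id"]
    )
    out = set()
    for x in nodes:
        if all(any(oracle_connected(graph_file, x, y) for y in ids) for _, ids in groups):
            out.add(x)
    return out


def random_graph_file(rng: np.random.Generator, max_nodes: int = 60):
    """A random, invariant-respecting small graph file (isolates allowed)."""
    from graphlike.formats_io import GraphFile

    n_t = int(rng.integers(1, 12))
    n_p = int(rng.integers(1, 12))
    n_m = int(rng.integers(1, 8))
    n_r = int(rng.integers(1, 10))
    n_pw = int(rng.integers(1, 6))
    while n_t + n_p + n_m + n_r + n_pw > max_nodes:
        n_t = max(1, n_t - 1)
    ts = [f"T{i}" for i in range(n_t)]
    ps = [f"P{i}" for i in range(n_p)]
    ms = [f"M{i}" for i in range(n_m)]
    rs = [f"R{i}" for i in range(n_r)]
    pws = [f"W{i}" for i in range(n_pw)]
    nodes = [
        (x, k, x)
        for group, k in (
            (ts, "transcript"),
            (ps, "protein"),
            (ms, "metabolite"),
            (rs, "reaction"),
            (pws, "pathway"),
        )
        for x in group
    ]
    edges = set()
    for t in ts:
        if rng.random() < 0.8:
            edges.add((t, str(rng.choice(ps)), "encodes"))
    for p in ps:
        for _ in range(int(rng.integers(0, 3))):
            edges.add((p, str(rng.choice(rs)), "participates"))
    for m in ms:
        for _ in range(int(rng.integers(0, 3))):
            edges.add((m, str(rng.choice(rs)), "participates"))
    for r in rs:
        for _ in range(int(rng.integers(0, 3))):
            edges.add((r, str(rng.choice(pws)), "member"))
    return GraphFile(
        nodes=pd.DataFrame(nodes, columns=["node_id", "node_kind", "display_name"]),
        edges=pd.DataFrame(
            sorted(edges), columns=["source_id", "target_id", "edge_kind"]
        ),
    )


# ---------------------------------------------------------------------------
# statistics


def oracle_hypergeom_tail(N: int, K: int, n: int, k: int) -> Fraction:
    """Exact P(X >= k) by summing binomial-coefficient ratios."""
    total = comb(N, n)
    acc = 0
    for j in range(max(k, max(0, n + K - N)), min(K, n) + 1):
        acc += comb(K, j) * comb(N - K, n - j)
    return Fraction(acc, total)


def oracle_bh(pvalues) -> np.ndarray:
    """Literal step-up: adj_(i) = min_{j>=i} m*p_(j)/j, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running_min = np.inf
    for rank in range(m, 0, -1):
        running_min = min(running_min, m * p[order[rank - 1]] / rank)
        adj_sorted[rank - 1] = min(running_min, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def oracle_enrichment_score(ranked_stats, in_set, weight: float):
    """Running-sum ES by an explicit position-by-position loop."""
    ranked_stats = list(ranked_stats)
    in_set = list(in_set)
    N = len(ranked_stats)
    K = sum(in_set)
    denom = sum(abs(r) ** weight for r, h in zip(ranked_stats, in_set) if h)
    running, total = [], 0.0
    for r, h in zip(ranked_stats, in_set):
        if h:
            total += (abs(r) ** weight) / denom if denom > 0 else 1.0 / K
        else:
            total -= 1.0 / (N - K)
        running.append(total)
    es = max(running, key=abs)
    return es, running


# ---------------------------------------------------------------------------
# clustering


def oracle_linkage(D: pd.DataFrame, linkage: str):
    """From-scratch agglomeration: cluster distances recomputed from the
    original matrix at every step (no Lance-Williams updates)."""
    clusters = [frozenset([str(lab)]) for lab in D.index]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = clusters[i], clusters[j]
                pair_d = [D.loc[u, v] for u in a for v in b]
                if linkage == "single":
                    d = min(pair_d)
                elif linkage == "complete":
                    d = max(pair_d)
                else:
                    d = sum(pair_d) / len(pair_d)
                key = (d, *sorted((min(a), min(b))))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (d, *_), a, b = best
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
        merges.append((frozenset((a, b)), float(d)))
    return merges
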