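"""Pathway activity and enrichment analysis: ORA, GSEA, PLAGE, GO.

Three complementary rankings of pathways (or any entity sets):

* ORA - hypergeometric over-representation of differentially expressed
  entities in a set, against the measured background universe.
* GSEA - running-sum enrichment score over an entity ranking (signal-to-
  noise between two groups), with significance from permutations.
* PLAGE - per-set activity level = first right singular vector of the
  standardised member submatrix; significance from a Welch t-test of the
  activity levels between groups.

Set membership can come from a GMT collection or be derived from the
knowledge graph (entities connected to each pathway, restricted to the
measured universe so that ORA's background is honest).

Multi-omics integration runs each omics separately and intersects the
significant pathways with a logical AND (see
:func:`~graphlike.query_engine.combine_pathway_queries`).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .diff_stats import bh_adjust
from .formats_io import (
    FormatWarning,
    GeneSetCollection,
    GoAnnotation,
    MeasurementTable,
    OMICS_KINDS,
)
from .knowledge_graph import KnowledgeGraph
from .linked_selection import NamedGroup
from .query_engine import combine_pathway_queries as combine_multiomics  # noqa: F401

__all__ = [
    "EnrichmentResult",
    "ActivityMatrix",
    "DEFAULT_MIN_SET_SIZE",
    "DEFAULT_MAX_SET_SIZE",
    "pathway_sets_from_graph",
    "restrict_sets",
    "hypergeom_tail",
    "ora",
    "collect_de_entities",
    "gsea",
    "plage",
    "go_enrichment",
    "combine_multiomics",
]

DEFAULT_MIN_SET_SIZE = 3
DEFAULT_MAX_SET_SIZE = 500

RESULT_COLUMNS = [
    "set_id",
    "set_name",
    "size",
    "overlap",
    "statistic",
    "p",
    "padj",
    "method",
    "omics",
]


@dataclasses.dataclass
class EnrichmentResult:
    """Per-set statistics plus the sets excluded from testing (with reasons).

    ``frame`` columns: set_id, set_name, size, overlap, statistic, p, padj,
    method, omics (overlap is NaN for non-ORA methods). ``meta`` records
    run parameters such as the permutation scheme used.
    """

    frame: pd.DataFrame
    excluded: pd.DataFrame  # columns: set_id, reason
    method: str
    omics: str = ""
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        p, padj = self.frame["p"], self.frame["padj"]
        ok = p.notna() & padj.notna()
        if ((padj[ok] < p[ok] - 1e-12) | (padj[ok] > 1) | (p[ok] < 0)).any():
            raise ValueError("invalid p/padj in enrichment result")


@dataclasses.dataclass
class ActivityMatrix:
    """PLAGE pathway x sample activity levels (unit-norm singular vectors)."""

    values: pd.DataFrame
    sign_convention: str = "positive correlation with mean member profile"


def _as_set_dict(sets) -> dict[str, tuple[str, tuple[str, ...]]]:
    if isinstance(sets, GeneSetCollection):
        return dict(sets.sets)
    out = {}
    for name, members in dict(sets).items():
        if isinstance(members, tuple) and len(members) == 2 and isinstance(members[0], str):
            out[name] = (members[0], tuple(members[1]))
        else:
            out[name] = (name, tuple(members))
    return out


def pathway_sets_from_graph(
    graph: KnowledgeGraph, omics_kind: str, measured_only: bool = True
) -> GeneSetCollection:
    """Per-pathway member sets of one omics kind, derived from connectivity.

    With ``measured_only`` (the default) members are restricted to measured
    entities, which keeps the ORA background equal to the measured universe;
    pathways left without members are dropped.
    """
    if omics_kind not in OMICS_KINDS:
        raise KeyError(f"unknown omics kind: {omics_kind!r}")
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    for pathway in sorted(graph.nodes_of_kind("pathway")):
        members = graph.neighbors_of_kind(pathway, omics_kind)
        if measured_only:
            members &= graph.measured
        if members:
            sets[pathway] = (graph.display_name.get(pathway, pathway), tuple(sorted(members)))
    return GeneSetCollection(sets=sets)


def restrict_sets(sets, background) -> dict[str, tuple[str, tuple[str, ...]]]:
    """Intersect every set with a background universe, keeping descriptions."""
    background = set(background)
    out = {}
    for name, (desc, members) in _as_set_dict(sets).items():
        kept = tuple(m for m in members if m in background)
        out[name] = (desc, kept)
    return out


# ---------------------------------------------------------------------------
# ORA


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Inclusive upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N background entities, K set members, n significant entities, k overlap.
    """
    if not (0 <= n <= N and 1 <= K <= N and 0 <= k):
        raise ValueError(f"invalid hypergeometric setup N={N}, K={K}, n={n}, k={k}")
    return float(min(stats.hypergeom.sf(k - 1, N, K, n), 1.0))


def ora(
    background,
    sets,
    significant,
    min_size: int = DEFAULT_MIN_SET_SIZE,
    max_size: int = DEFAULT_MAX_SET_SIZE,
    method_label: str = "ora",
    omics: str = "",
) -> EnrichmentResult:
    """Hypergeometric over-representation of ``significant`` in each set.

    With N background entities, K set members (after restriction to the
    background), n significant entities and k = |set & significant|, the
    raw p is the inclusive upper tail P(X >= k) for
    X ~ Hypergeometric(N, K, n); BH is applied across all tested sets. The
    reported statistic is the fold enrichment (k/n) / (K/N).
    """
    background = set(background)
    significant = set(significant) & background
    N, n = len(background), len(significant)
    if N == 0:
        raise ValueError("empty background universe")
    restricted = restrict_sets(sets, background)
    rows, excluded = [], []
    for name in restricted:
        desc, members = restricted[name]
        K = len(members)
        if K == 0:
            excluded.append((name, "no members mapped to the background"))
            continue
        if K < min_size:
            excluded.append((name, f"fewer than {min_size} members"))
            continue
        if K > max_size:
            excluded.append((name, f"more than {max_size} members"))
            continue
        k = len(set(members) & significant)
        p = hypergeom_tail(N, K, n, k)
        enrich = (k / n) / (K / N) if n > 0 else np.nan
        rows.append((name, desc, K, k, enrich, p))
    frame = pd.DataFrame(rows, columns=["set_id", "set_name", "size", "overlap", "statistic", "p"])
    frame["padj"] = bh_adjust(frame["p"].to_numpy()) if len(frame) else np.nan
    frame["method"] = method_label
    frame["omics"] = omics
    frame = frame[RESULT_COLUMNS].sort_values(["p", "set_id"], kind="stable").reset_index(drop=True)
    return EnrichmentResult(
        frame=frame,
        excluded=pd.DataFrame(excluded, columns=["set_id", "reason"]),
        method=method_label,
        omics=omics,
        meta={"N": N, "n": n, "min_size": min_size, "max_size": max_size},
    )


def collect_de_entities(
    tables: dict[str, MeasurementTable],
    threshold: float = 0.05,
    comparison: str | None = None,
) -> dict[str, set[str]]:
    """Per-omics significant entity IDs: padj <= threshold (inclusive).

    The 0.05 default mirrors the usual significance convention for feeding
    multi-omics ORA; the union across omics is the caller's to take.
    """
    out: dict[str, set[str]] = {}
    for omics, table in tables.items():
        names = table.comparisons
        cmp_name = comparison
        if cmp_name is None:
            if len(names) != 1:
                raise KeyError(
                    f"{omics} table needs an explicit comparison (available: {names})"
                )
            cmp_name = names[0]
        padj = table.padj(cmp_name)
        if padj is None:
            raise KeyError(f"{omics} table has no padj column for {cmp_name!r}")
        out[omics] = set(padj.index[padj.notna() & (padj <= threshold)])
    return out


# ---------------------------------------------------------------------------
# GSEA


def _signal_to_noise(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Per-row signal-to-noise ratio (m1 - m2) / (s1 + s2), sd floored."""
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    s1, s2 = x1.std(axis=1, ddof=1), x2.std(axis=1, ddof=1)
    denom = s1 + s2
    denom = np.where(denom <= 1e-12, 1e-12, denom)
    return (m1 - m2) / denom


def enrichment_score(
    ranked_stats: np.ndarray, in_set: np.ndarray, weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Running-sum enrichment score over a ranked list.

    Hits increment by |r|^weight normalised over the set, misses decrement
    by 1/(N-K); the ES is the running sum's maximum signed deviation from
    zero. Always lies in [-1, 1].
    """
    ranked_stats = np.asarray(ranked_stats, dtype=float)
    in_set = np.asarray(in_set, dtype=bool)
    N = len(ranked_stats)
    K = int(in_set.sum())
    if K == 0:
        raise ValueError("set has no members in the ranked list")
    if K == N:
        raise ValueError("set equals the whole background; miss decrement undefined")
    w = np.abs(ranked_stats) ** weight
    denom = w[in_set].sum()
    if denom <= 0:
        hit_steps = np.full(N, 1.0 / K)
    else:
        hit_steps = w / denom
    steps = np.where(in_set, hit_steps, -1.0 / (N - K))
    running = np.cumsum(steps)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def _perm_pvalue(es: float, null_es: np.ndarray) -> float:
    """Nominal p against the same-signed portion of the permutation null."""
    null_es = np.asarray(null_es, dtype=float)
    if es >= 0:
        side = null_es[null_es >= 0]
        exceed = int((side >= es).sum())
    else:
        side = null_es[null_es < 0]
        exceed = int((side <= es).sum())
    return (1 + exceed) / (1 + len(side))


def gsea(
    table: MeasurementTable,
    sets,
    group1: str,
    group2: str,
    n_perm: int = 1000,
    seed: int | None = None,
    weight: float = 1.0,
    min_size: int = DEFAULT_MIN_SET_SIZE,
    max_size: int = DEFAULT_MAX_SET_SIZE,
    omics: str = "",
) -> EnrichmentResult:
    """Gene Set Enrichment Analysis of ``group1`` vs ``group2``.

    Entities are ranked by signal-to-noise; each set's ES is the running-sum
    maximum deviation (weight exponent 1 by default). The nominal p comes
    from ``n_perm`` permutations: phenotype (sample-label) permutation when
    both groups have at least 7 samples, else entity-label permutation; the
    scheme used is recorded in ``meta``. BH across sets.
    """
    if seed is None:
        raise ValueError("gsea requires an explicit seed for its permutations")
    rng = np.random.default_rng(seed)
    s1, s2 = table.samples_of_group(group1), table.samples_of_group(group2)
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError("gsea needs at least 2 samples per group")
    values = table.values.dropna(axis=0)
    n_dropped = len(table.values) - len(values)
    if n_dropped:
        warnings.warn(
            f"gsea dropped {n_dropped} entities with missing values",
            FormatWarning,
            stacklevel=2,
        )
    ids = np.array(values.index)
    x = values[s1 + s2].to_numpy(dtype=float)
    n1 = len(s1)
    ranking = _signal_to_noise(x[:, :n1], x[:, n1:])
    order = np.argsort(-ranking, kind="stable")
    ranked_ids = ids[order]
    ranked_stats = ranking[order]
    position = {e: i for i, e in enumerate(ranked_ids)}
    N = len(ranked_ids)

    restricted = restrict_sets(sets, set(ids))
    scheme = "phenotype" if min(n1, len(s2)) >= 7 else "entity"

    # phenotype permutations share rankings across sets
    perm_orders: list[tuple[np.ndarray, np.ndarray]] = []
    if scheme == "phenotype":
        cols = np.arange(x.shape[1])
        for _ in range(n_perm):
            perm = rng.permutation(cols)
            r = _signal_to_noise(x[:, perm[:n1]], x[:, perm[n1:]])
            o = np.argsort(-r, kind="stable")
            perm_orders.append((ids[o], r[o]))

    rows, excluded = [], []
    for name in restricted:
        desc, members = restricted[name]
        K = len(members)
        if K == 0:
            excluded.append((name, "no members in the measured table"))
            continue
        if K < min_size:
            excluded.append((name, f"fewer than {min_size} members"))
            continue
        if K > max_size:
            excluded.append((name, f"more than {max_size} members"))
            continue
        if K == N:
            raise ValueError(f"set {name!r} equals the whole background")
        in_set = np.zeros(N, dtype=bool)
        in_set[[position[m] for m in members]] = True
        es, _ = enrichment_score(ranked_stats, in_set, weight)
        null_es = np.empty(n_perm)
        if scheme == "phenotype":
            member_set = set(members)
            for j, (p_ids, p_stats) in enumerate(perm_orders):
                p_in = np.fromiter((e in member_set for e in p_ids), bool, N)
                null_es[j], _ = enrichment_score(p_stats, p_in, weight)
        else:
            for j in range(n_perm):
                p_in = np.zeros(N, dtype=bool)
                p_in[rng.choice(N, size=K, replace=False)] = True
                null_es[j], _ = enrichment_score(ranked_stats, p_in, weight)
        rows.append((name, desc, K, np.nan, es, _perm_pvalue(es, null_es)))

    frame = pd.DataFrame(rows, columns=["set_id", "set_name", "size", "overlap", "statistic", "p"])
    frame["padj"] = bh_adjust(frame["p"].to_numpy()) if len(frame) else np.nan
    frame["method"] = "gsea"
    frame["omics"] = omics
    frame = frame[RESULT_COLUMNS].sort_values(["p", "set_id"], kind="stable").reset_index(drop=True)
    return EnrichmentResult(
        frame=frame,
        excluded=pd.DataFrame(excluded, columns=["set_id", "reason"]),
        method="gsea",
        omics=omics,
        meta={"permutation_scheme": scheme, "n_perm": n_perm, "weight": weight, "seed": seed},
    )


# ---------------------------------------------------------------------------
# PLAGE


def plage(
    table: MeasurementTable,
    sets,
    group1: str,
    group2: str,
    min_size: int = 1,
    max_size: int = DEFAULT_MAX_SET_SIZE,
    omics: str = "",
) -> tuple[ActivityMatrix, EnrichmentResult]:
    """Pathway Level Analysis of Gene Expression.

    Per set: standardise each member row to mean 0 / sd 1 across all
    samples, take the SVD of the standardised submatrix, and use the first
    right singular vector as the per-sample activity level. The sign is
    fixed so the activity correlates non-negatively with the mean
    standardised member profile. Significance is a two-sided Welch t-test
    of the activity between the two groups, BH-adjusted across sets.
    """
    s1, s2 = table.samples_of_group(group1), table.samples_of_group(group2)
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError("plage needs at least 2 samples per group")
    values = table.values.dropna(axis=0)
    ids = set(values.index)
    restricted = restrict_sets(sets, ids)
    samples = table.sample_ids
    idx1 = [samples.index(s) for s in s1]
    idx2 = [samples.index(s) for s in s2]

    rows, excluded, activities = [], [], {}
    for name in restricted:
        desc, members = restricted[name]
        if len(members) == 0:
            excluded.append((name, "no members in the measured table"))
            continue
        if len(members) < min_size:
            excluded.append((name, f"fewer than {min_size} members"))
            continue
        if len(members) > max_size:
            excluded.append((name, f"more than {max_size} members"))
            continue
        sub = values.loc[list(members)].to_numpy(dtype=float)
        sd = sub.std(axis=1, ddof=1)
        usable = sd > 0
        if not np.any(usable):
            excluded.append((name, "all members constant"))
            continue
        sub = sub[usable]
        z = (sub - sub.mean(axis=1, keepdims=True)) / sd[usable, None]
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        activity = vt[0]
        mean_profile = z.mean(axis=0)
        if np.dot(activity, mean_profile) < 0:
            activity = -activity
        activities[name] = activity
        t_stat, p = stats.ttest_ind(activity[idx1], activity[idx2], equal_var=False)
        rows.append((name, desc, int(usable.sum()), np.nan, float(t_stat), float(p)))

    frame = pd.DataFrame(rows, columns=["set_id", "set_name", "size", "overlap", "statistic", "p"])
    frame["padj"] = bh_adjust(frame["p"].to_numpy()) if len(frame) else np.nan
    frame["method"] = "plage"
    frame["omics"] = omics
    frame = frame[RESULT_COLUMNS].sort_values(["p", "set_id"], kind="stable").reset_index(drop=True)
    activity_frame = pd.DataFrame.from_dict(activities, orient="index", columns=samples)
    activity_frame.index.name = "set_id"
    return (
        ActivityMatrix(values=activity_frame),
        EnrichmentResult(
            frame=frame,
            excluded=pd.DataFrame(excluded, columns=["set_id", "reason"]),
            method="plage",
            omics=omics,
        ),
    )


# ---------------------------------------------------------------------------
# GO enrichment


def propagate_annotations(annotation: GoAnnotation) -> dict[str, set[str]]:
    """Term -> entity sets after true-path propagation to ancestor terms."""
    term_entities: dict[str, set[str]] = {}
    for entity, terms in annotation.entity_to_terms.items():
        for term in terms:
            term_entities.setdefault(term, set()).add(entity)
            for ancestor in annotation.ancestors(term):
                term_entities.setdefault(ancestor, set()).add(entity)
    return term_entities


def go_enrichment(
    group: NamedGroup,
    annotation: GoAnnotation,
    background,
    min_size: int = 1,
    max_size: int = DEFAULT_MAX_SET_SIZE,
) -> EnrichmentResult:
    """Hypergeometric GO-term enrichment of a named group vs a background.

    Annotations are first propagated to ancestor terms (true-path rule);
    terms annotating nothing in the background are excluded.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background universe")
    members = set(group.ids) & background
    if not (set(group.ids) & set(annotation.entity_to_terms)):
        raise ValueError("annotation covers no member of the group")
    term_entities = propagate_annotations(annotation)
    sets = {
        term: (annotation.term_names.get(term, term), tuple(sorted(entities)))
        for term, entities in term_entities.items()
    }
    result = ora(
        background,
        sets,
        members,
        min_size=min_size,
        max_size=max_size,
        method_label="go",
        omics=group.table,
    )
    result.meta["group"] = group.name
    return result
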