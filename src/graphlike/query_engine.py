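"""Rule-based multi-omics queries over differential-expression statistics.

A query is a conjunction of comparison rules, each constraining one omics
kind's adjusted p-value or (absolute) fold change for a named group
comparison, e.g. ``transcript.padj < 0.05 AND transcript.abs_fold_change >=
0.5 AND protein.padj < 0.05``. Evaluation yields one selection group per
omics kind mentioned, so the linked tables then show only entities passing
their own rules AND connected to passers of every other mentioned kind.
"""

from __future__ import annotations

import dataclasses
import re
import warnings

import numpy as np
import pandas as pd

from .formats_io import FormatWarning, MeasurementTable, OMICS_KINDS
from .knowledge_graph import KnowledgeGraph
from .linked_selection import SelectionGroup, SelectionState

__all__ = [
    "QueryRule",
    "QueryExpression",
    "parse_rule",
    "evaluate",
    "combine_pathway_queries",
]

FIELDS = ("padj", "fold_change", "abs_fold_change")
OPS = {
    "<": np.less,
    "<=": np.less_equal,
    ">": np.greater,
    ">=": np.greater_equal,
}


@dataclasses.dataclass(frozen=True)
class QueryRule:
    """One comparison rule on one omics kind's DE statistics.

    ``comparison`` names the ``[g1]_vs_[g2]`` pair the rule refers to; it may
    be ``None`` when the table carries exactly one comparison.
    """

    omics: str
    field: str
    op: str
    threshold: float
    comparison: str | None = None

    def __post_init__(self) -> None:
        if self.omics not in OMICS_KINDS + ("pathway",):
            raise ValueError(f"unknown omics kind in rule: {self.omics!r}")
        if self.field not in FIELDS:
            raise ValueError(f"unknown field in rule: {self.field!r}")
        if self.op not in OPS:
            raise ValueError(f"unknown comparison operator: {self.op!r}")
        if not np.isfinite(self.threshold):
            raise ValueError("rule threshold must be finite")


@dataclasses.dataclass(frozen=True)
class QueryExpression:
    """AND-conjunction of rules (the only combination the builder offers)."""

    rules: tuple[QueryRule, ...]

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError("query expression must contain at least one rule")

    @property
    def omics_kinds(self) -> list[str]:
        seen: list[str] = []
        for rule in self.rules:
            if rule.omics not in seen:
                seen.append(rule.omics)
        return seen


_RULE_RE = re.compile(
    r"^\s*(?P<omics>\w+)\.(?P<field>\w+)\s*(?P<op><=|>=|<|>)\s*(?P<value>\S+)\s*$"
)


def parse_rule(text: str, comparison: str | None = None) -> QueryRule:
    """Parse ``"transcript.padj<0.05"``-style rule strings (CLI form)."""
    m = _RULE_RE.match(text)
    if not m:
        raise ValueError(f"cannot parse rule: {text!r}")
    return QueryRule(
        omics=m.group("omics"),
        field=m.group("field"),
        op=m.group("op"),
        threshold=float(m.group("value")),
        comparison=comparison,
    )


def _resolve_comparison(table: MeasurementTable, rule: QueryRule) -> str:
    if rule.comparison is not None:
        if rule.comparison not in table.comparisons:
            raise KeyError(
                f"comparison {rule.comparison!r} not found in the {rule.omics} table "
                f"(available: {table.comparisons})"
            )
        return rule.comparison
    names = table.comparisons
    if len(names) == 1:
        return names[0]
    raise KeyError(
        f"rule on {rule.omics} must name a comparison; table has {names or 'none'}"
    )


def _rule_series(table: MeasurementTable, rule: QueryRule) -> pd.Series:
    comparison = _resolve_comparison(table, rule)
    if rule.field == "padj":
        series = table.padj(comparison)
        what = f"padj_{comparison}"
    else:
        series = table.fold_change(comparison)
        what = f"FC_{comparison}"
    if series is None:
        raise KeyError(f"{rule.omics} table has no {what} column")
    if rule.field == "abs_fold_change":
        series = series.abs()
    return series


def evaluate(
    expr: QueryExpression,
    tables: dict[str, MeasurementTable],
    graph: KnowledgeGraph | None = None,
) -> SelectionState:
    """Evaluate a query: one selection group per omics kind mentioned.

    Entities with a missing value for a referenced statistic fail that rule
    (conservative; the count of such exclusions is reported as a warning).
    When a graph is supplied, passing entities absent from it are dropped
    from the selection (they cannot constrain linked tables) and counted.
    """
    groups: list[SelectionGroup] = []
    for omics in expr.omics_kinds:
        if omics == "pathway":
            raise ValueError(
                "pathway rules are evaluated by combine_pathway_queries, not evaluate"
            )
        if omics not in tables:
            raise KeyError(f"query references omics kind {omics!r} with no uploaded table")
        table = tables[omics]
        mask = pd.Series(True, index=table.values.index)
        missing_any = pd.Series(False, index=table.values.index)
        for rule in expr.rules:
            if rule.omics != omics:
                continue
            series = _rule_series(table, rule)
            missing = series.isna()
            missing_any |= missing
            mask &= OPS[rule.op](series, rule.threshold) & ~missing
        n_missing = int(missing_any.sum())
        if n_missing:
            warnings.warn(
                f"{n_missing} {omics} entities had missing statistics for the query "
                "and were excluded",
                FormatWarning,
                stacklevel=2,
            )
        passing = set(table.values.index[mask])
        if graph is not None:
            in_graph = passing & graph.nodes_of_kind(omics)
            if len(in_graph) < len(passing):
                warnings.warn(
                    f"{len(passing) - len(in_graph)} passing {omics} entities are not "
                    "mapped to the graph and were dropped from the selection",
                    FormatWarning,
                    stacklevel=2,
                )
            passing = in_graph
        groups.append(SelectionGroup(table=omics, ids=frozenset(passing)))
    return SelectionState(groups=tuple(groups))


def combine_pathway_queries(
    results: dict[str, pd.DataFrame],
    threshold: float = 0.05,
    omics: list[str] | None = None,
) -> set[str]:
    """Pathways significant in EVERY named omics' activity results.

    ``results`` maps omics kind -> an enrichment result frame with
    ``set_id`` and ``padj`` columns. A pathway passes iff its adjusted p is
    <= ``threshold`` in each named omics; pathways absent from some omics'
    universe cannot pass and are reported via a warning.
    """
    if omics is None:
        omics = list(results)
    missing = [o for o in omics if o not in results]
    if missing:
        raise KeyError(f"no pathway activity results for omics: {missing}")
    passing_per_omics: list[set[str]] = []
    universes: list[set[str]] = []
    for o in omics:
        frame = results[o]
        universe = set(frame["set_id"])
        universes.append(universe)
        ok = frame.loc[frame["padj"].notna() & (frame["padj"] <= threshold), "set_id"]
        passing_per_omics.append(set(ok))
    shared = set.intersection(*universes) if universes else set()
    everything = set.union(*universes) if universes else set()
    if everything - shared:
        warnings.warn(
            f"{len(everything - shared)} pathways are not shared across all omics "
            "universes and cannot pass the combined filter",
            FormatWarning,
            stacklevel=2,
        )
    return set.intersection(*passing_per_omics) & shared if passing_per_omics else set()
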