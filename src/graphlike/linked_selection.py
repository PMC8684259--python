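"""Linked drill-down selections over the five entity tables.

The data browser shows one table per node kind (transcripts, proteins,
metabolites, reactions, pathways). Users select rows in any table, in any
order; every table then shows only the rows connected to the selection.

The selection algebra: a :class:`SelectionState` is an ordered list of
selection groups, each a set of ids from one table. Within a group the
selected ids act disjunctively (connected to *any* of them), across groups
conjunctively (must satisfy *every* group). An empty state hides nothing.
This reproduces the drill-down behaviour where selecting three pathways and
then two metabolites leaves visible exactly the entities connected to at
least one of the two metabolites AND at least one of the three pathways.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

from .formats_io import NODE_KINDS
from .knowledge_graph import KnowledgeGraph

__all__ = [
    "SelectionGroup",
    "SelectionState",
    "NamedGroup",
    "GroupStore",
    "visible_set",
    "add_selection",
    "clear_selection",
    "save_group",
    "load_group",
]


@dataclasses.dataclass(frozen=True)
class SelectionGroup:
    table: str
    ids: frozenset[str]


@dataclasses.dataclass(frozen=True)
class SelectionState:
    """Ordered list of selection groups; empty means 'show everything'."""

    groups: tuple[SelectionGroup, ...] = ()

    def __len__(self) -> int:
        return len(self.groups)


def _validate_group(graph: KnowledgeGraph, table: str, ids) -> frozenset[str]:
    if table not in NODE_KINDS:
        raise KeyError(f"unknown table kind: {table!r}")
    ids = frozenset(str(i) for i in ids)
    for node in ids:
        if node not in graph:
            raise KeyError(f"selected id {node!r} is not in the graph")
        if graph.kind_of[node] != table:
            raise ValueError(
                f"id {node!r} has kind {graph.kind_of[node]!r}, not {table!r}"
            )
    return ids


def visible_set(graph: KnowledgeGraph, state: SelectionState, table: str) -> set[str]:
    """Rows of ``table`` visible under ``state``.

    ``{x of kind table : for every group (T_j, S_j), exists y in S_j with
    connected(x, y)}``; with no groups, all nodes of the kind.
    """
    candidates = graph.nodes_of_kind(table)
    for group in state.groups:
        ids = _validate_group(graph, group.table, group.ids)
        hits: set[str] = set()
        for y in ids:
            hits |= graph.neighbors_of_kind(y, table)
        candidates &= hits
        if not candidates:
            break
    return candidates


def add_selection(
    state: SelectionState,
    graph: KnowledgeGraph,
    table: str,
    ids,
    replace: bool = False,
) -> SelectionState:
    """Append a selection group (default) or replace prior groups on ``table``.

    Appending a second group on the same table refines (AND); pass
    ``replace=True`` to extend/redo the existing selection instead.
    """
    ids = _validate_group(graph, table, ids)
    if not ids:
        raise ValueError("cannot add an empty selection")
    groups = tuple(g for g in state.groups if not (replace and g.table == table))
    return SelectionState(groups=groups + (SelectionGroup(table=table, ids=ids),))


def clear_selection(state: SelectionState) -> SelectionState:
    return SelectionState()


@dataclasses.dataclass(frozen=True)
class NamedGroup:
    """A saved selection: a named, annotatable id set from one table."""

    name: str
    table: str
    ids: frozenset[str]
    annotation: str = ""

    def __post_init__(self) -> None:
        if not self.ids:
            raise ValueError(f"named group {self.name!r} must be non-empty")


class GroupStore:
    """Named-group registry, optionally persisted as JSON files."""

    def __init__(self, directory: Path | str | None = None):
        self.directory = Path(directory) if directory is not None else None
        self._groups: dict[str, NamedGroup] = {}
        if self.directory is not None and self.directory.is_dir():
            for path in sorted(self.directory.glob("*.json")):
                with open(path, encoding="utf-8") as fh:
                    doc = json.load(fh)
                group = NamedGroup(
                    name=doc["name"],
                    table=doc["table"],
                    ids=frozenset(doc["ids"]),
                    annotation=doc.get("annotation", ""),
                )
                self._groups[group.name] = group

    def add(self, group: NamedGroup) -> None:
        if group.name in self._groups:
            raise ValueError(f"group name {group.name!r} already exists")
        self._groups[group.name] = group
        if self.directory is not None:
            self.directory.mkdir(parents=True, exist_ok=True)
            doc = {
                "name": group.name,
                "table": group.table,
                "ids": sorted(group.ids),
                "annotation": group.annotation,
            }
            with open(self.directory / f"{group.name}.json", "w", encoding="utf-8") as fh:
                json.dump(doc, fh, indent=1)
                fh.write("\n")

    def get(self, name: str) -> NamedGroup:
        return self._groups[name]

    def names(self) -> list[str]:
        return sorted(self._groups)

    def __contains__(self, name: str) -> bool:
        return name in self._groups


def save_group(
    graph: KnowledgeGraph,
    state: SelectionState,
    table: str,
    name: str,
    store: GroupStore | None = None,
    annotation: str = "",
) -> NamedGroup:
    """Save the currently visible ids of ``table`` as a named group."""
    ids = frozenset(visible_set(graph, state, table))
    if not ids:
        raise ValueError(f"nothing visible in table {table!r} to save")
    group = NamedGroup(name=name, table=table, ids=ids, annotation=annotation)
    if store is not None:
        store.add(group)
    return group


def load_group(group: NamedGroup) -> SelectionState:
    """Rebuild a selection state whose visible sets match the saved group."""
    return SelectionState(groups=(SelectionGroup(table=group.table, ids=group.ids),))
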