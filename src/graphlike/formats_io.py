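"""Flat-file input/output for the integration toolkit.

Everything the toolkit reads or writes goes through this module: per-omics
measurement matrices (CSV, with an optional embedded ``group`` row and
optional externally computed differential-expression columns), experimental
design tables, the entity-reaction-pathway graph export (JSON or paired
TSVs), GMT gene-set collections, and GO annotation tables.

The CSV dialect is fixed: comma delimiter, ``.`` decimal separator, UTF-8.
The first column of a measurement CSV always holds the entity identifiers
regardless of its header text. Empty cells are missing values and are
propagated as NaN; statistics downstream exclude them pairwise.
"""

from __future__ import annotations

import dataclasses
import json
import re
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "OMICS_KINDS",
    "NODE_KINDS",
    "EDGE_KINDS",
    "FormatError",
    "FormatWarning",
    "MeasurementTable",
    "DesignTable",
    "GraphFile",
    "GeneSetCollection",
    "GoAnnotation",
    "read_measurement_csv",
    "write_measurement_csv",
    "read_design_csv",
    "apply_design",
    "read_graph_file",
    "write_graph_file",
    "read_gmt",
    "write_gmt",
    "read_go_annotation",
    "write_table_csv",
]

OMICS_KINDS = ("transcript", "protein", "metabolite")
NODE_KINDS = OMICS_KINDS + ("reaction", "pathway")
EDGE_KINDS = ("encodes", "participates", "member")

#: edge kind -> (allowed source kinds, allowed target kinds)
EDGE_ENDPOINT_KINDS = {
    "encodes": ({"transcript"}, {"protein"}),
    "participates": ({"protein", "metabolite"}, {"reaction"}),
    "member": ({"reaction"}, {"pathway"}),
}

#: beyond this many samples, performance degrades noticeably in interactive use
SAMPLE_COUNT_WARN = 200

_DE_COLUMN_RE = re.compile(r"^(FC|padj)_(.+)_vs_(.+)$")


class FormatError(ValueError):
    """A file violates the expected dialect or an internal invariant."""


class FormatWarning(UserWarning):
    """Recoverable oddity in an input file (e.g. FC column without padj)."""


# ---------------------------------------------------------------------------
# measurement tables


@dataclasses.dataclass
class MeasurementTable:
    """One omics type's labelled measurement matrix.

    Parameters
    ----------
    omics_kind:
        One of ``transcript``, ``protein``, ``metabolite``.
    values:
        Entities x samples real matrix (NaN = missing), entity IDs on the
        index, sample IDs on the columns.
    group_of:
        Sample -> experimental group label. May be empty if no grouping was
        provided.
    de:
        Entities x DE-columns frame holding externally supplied or computed
        ``FC_[g1]_vs_[g2]`` / ``padj_[g1]_vs_[g2]`` columns, aligned 1:1
        with ``values.index``. May be empty.
    """

    omics_kind: str
    values: pd.DataFrame
    group_of: dict[str, str] = dataclasses.field(default_factory=dict)
    de: pd.DataFrame = dataclasses.field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.de.empty and len(self.de.index) != len(self.values.index):
            self.de = pd.DataFrame(index=self.values.index)
        self.validate()

    # -- accessors ---------------------------------------------------------

    @property
    def entity_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def comparisons(self) -> list[str]:
        """Comparison names (``g1_vs_g2``) with at least one DE column."""
        names: list[str] = []
        for col in self.de.columns:
            m = _DE_COLUMN_RE.match(col)
            if m:
                name = f"{m.group(2)}_vs_{m.group(3)}"
                if name not in names:
                    names.append(name)
        return names

    def samples_of_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.group_of.get(s) == group]

    def fold_change(self, comparison: str) -> pd.Series | None:
        col = f"FC_{comparison}"
        return self.de[col] if col in self.de.columns else None

    def padj(self, comparison: str) -> pd.Series | None:
        col = f"padj_{comparison}"
        return self.de[col] if col in self.de.columns else None

    def set_de(self, comparison: str, fold_change, padj) -> None:
        """Attach (or overwrite) one comparison's FC and padj vectors."""
        self.de[f"FC_{comparison}"] = np.asarray(fold_change, dtype=float)
        self.de[f"padj_{comparison}"] = np.asarray(padj, dtype=float)

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        if self.omics_kind not in OMICS_KINDS:
            raise FormatError(f"unknown omics kind: {self.omics_kind!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise FormatError(f"duplicate entity IDs: {sorted(dups)}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise FormatError(f"duplicate sample IDs: {sorted(dups)}")
        if not self.de.index.equals(self.values.index):
            raise FormatError("de columns do not align with entity IDs")
        unknown = set(self.group_of) - set(self.values.columns)
        if unknown:
            raise FormatError(f"group assignment for unknown samples: {sorted(unknown)}")
        if self.group_of and set(self.group_of) != set(self.values.columns):
            missing = set(self.values.columns) - set(self.group_of)
            raise FormatError(f"samples without a group assignment: {sorted(missing)}")


def read_measurement_csv(path, omics_kind: str) -> MeasurementTable:
    """Parse one omics measurement CSV.

    Layout: first column = entity IDs (whatever its header says), remaining
    columns = samples, except columns named ``FC_[g1]_vs_[g2]`` /
    ``padj_[g1]_vs_[g2]`` which carry externally computed differential
    results. If the first data row's leading cell is ``group`` it is consumed
    as the sample -> group assignment instead of a measurement row.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    if raw.shape[1] < 1:
        raise FormatError(f"{path}: no columns found")
    id_col = raw.columns[0]
    ids = raw[id_col].astype(str)

    group_of: dict[str, str] = {}
    if len(raw) and ids.iloc[0] == "group":
        group_row = raw.iloc[0]
        raw = raw.iloc[1:].reset_index(drop=True)
        ids = raw[id_col].astype(str)
    else:
        group_row = None

    de_cols = [c for c in raw.columns[1:] if _DE_COLUMN_RE.match(c)]
    # 'name'/'measured' are the annotation columns our own exports add;
    # skipping them keeps every exported table re-ingestable
    meta_cols = [c for c in raw.columns[1:] if c in ("name", "measured")]
    sample_cols = [c for c in raw.columns[1:] if c not in de_cols and c not in meta_cols]

    dup = ids[ids.duplicated()].unique()
    if len(dup):
        raise FormatError(f"{path}: duplicate entity IDs: {sorted(dup)}")

    def _parse_block(cols: list[str], what: str) -> pd.DataFrame:
        out = {}
        for c in cols:
            parsed = []
            for i, cell in enumerate(raw[c]):
                cell = cell.strip()
                if cell == "":
                    parsed.append(np.nan)
                    continue
                try:
                    parsed.append(float(cell))
                except ValueError:
                    raise FormatError(
                        f"{path}: non-numeric {what} cell {cell!r} at "
                        f"row {ids.iloc[i]!r}, column {c!r}"
                    ) from None
            out[c] = parsed
        return pd.DataFrame(out, index=pd.Index(ids, name="id"), dtype=float)

    values = _parse_block(sample_cols, "measurement")
    de = _parse_block(de_cols, "DE")

    if group_row is not None:
        for c in sample_cols:
            label = str(group_row[c]).strip()
            if label:
                group_of[c] = label
        missing = [c for c in sample_cols if c not in group_of]
        if missing:
            raise FormatError(f"{path}: group row leaves samples unassigned: {missing}")

    # warn about lone FC columns (padj is what filtering runs on)
    for name in {f"{m.group(2)}_vs_{m.group(3)}" for c in de_cols if (m := _DE_COLUMN_RE.match(c))}:
        if f"FC_{name}" in de.columns and f"padj_{name}" not in de.columns:
            warnings.warn(
                f"{path}: FC column for comparison {name!r} has no matching padj column",
                FormatWarning,
                stacklevel=2,
            )
    if len(sample_cols) > SAMPLE_COUNT_WARN:
        warnings.warn(
            f"{path}: {len(sample_cols)} samples; interactive use degrades beyond "
            f"{SAMPLE_COUNT_WARN}",
            FormatWarning,
            stacklevel=2,
        )
    return MeasurementTable(omics_kind=omics_kind, values=values, group_of=group_of, de=de)


def write_measurement_csv(table: MeasurementTable, path) -> None:
    """Write a measurement table back to the upload dialect (round-trips)."""
    path = Path(path)
    frame = pd.concat([table.values, table.de], axis=1)
    frame.index.name = "id"
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(",".join(["id", *frame.columns]) + "\n")
        if table.group_of:
            cells = ["group"]
            for c in frame.columns:
                cells.append(table.group_of.get(c, ""))
            fh.write(",".join(cells) + "\n")
        frame.to_csv(fh, header=False)


# ---------------------------------------------------------------------------
# design tables


@dataclasses.dataclass
class DesignTable:
    """Sample -> group assignment plus any extra experimental factors."""

    group_of: dict[str, str]
    factors: pd.DataFrame  # samples x extra factor columns (may be empty)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.group_of)

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for g in self.group_of.values():
            if g not in seen:
                seen.append(g)
        return seen


def read_design_csv(path) -> DesignTable:
    """Parse a design CSV: ``sample`` then ``group`` columns, extras kept."""
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    if list(raw.columns[:2]) != ["sample", "group"]:
        raise FormatError(
            f"{path}: first two columns must be 'sample','group' "
            f"(got {list(raw.columns[:2])})"
        )
    samples = raw["sample"].astype(str)
    dup = samples[samples.duplicated()].unique()
    if len(dup):
        raise FormatError(f"{path}: duplicate sample names: {sorted(dup)}")
    groups = raw["group"].astype(str)
    empty = samples[groups.str.strip() == ""]
    if len(empty):
        raise FormatError(f"{path}: empty group for samples: {list(empty)}")
    factors = raw.drop(columns=["sample", "group"]).set_index(pd.Index(samples, name="sample"))
    return DesignTable(group_of=dict(zip(samples, groups)), factors=factors)


def apply_design(table: MeasurementTable, design: DesignTable) -> MeasurementTable:
    """Overlay a design table's groups onto a measurement table.

    The design file is the more explicit artefact, so it wins over an
    embedded ``group`` row; a warning reports any conflicts.
    """
    new_groups = {s: g for s, g in design.group_of.items() if s in table.values.columns}
    conflicts = {
        s: (table.group_of[s], g)
        for s, g in new_groups.items()
        if s in table.group_of and table.group_of[s] != g
    }
    if conflicts:
        warnings.warn(
            f"design file overrides in-matrix group labels for samples: {sorted(conflicts)}",
            FormatWarning,
            stacklevel=2,
        )
    merged = dict(table.group_of)
    merged.update(new_groups)
    return MeasurementTable(
        omics_kind=table.omics_kind, values=table.values, group_of=merged, de=table.de
    )


# ---------------------------------------------------------------------------
# graph files


@dataclasses.dataclass
class GraphFile:
    """File-level representation of the entity-reaction-pathway graph.

    ``nodes`` columns: node_id, node_kind, display_name.
    ``edges`` columns: source_id, target_id, edge_kind.
    """

    nodes: pd.DataFrame
    edges: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for col in ("node_id", "node_kind", "display_name"):
            if col not in self.nodes.columns:
                raise FormatError(f"graph nodes table lacks column {col!r}")
        for col in ("source_id", "target_id", "edge_kind"):
            if col not in self.edges.columns:
                raise FormatError(f"graph edges table lacks column {col!r}")
        ids = self.nodes["node_id"]
        dup = ids[ids.duplicated()].unique()
        if len(dup):
            raise FormatError(f"duplicate node IDs: {sorted(dup)}")
        bad_kind = self.nodes.loc[~self.nodes["node_kind"].isin(NODE_KINDS)]
        if len(bad_kind):
            raise FormatError(f"unknown node kinds: {sorted(bad_kind['node_kind'].unique())}")
        kind_of = dict(zip(self.nodes["node_id"], self.nodes["node_kind"]))
        for row in self.edges.itertuples(index=False):
            if row.edge_kind not in EDGE_KINDS:
                raise FormatError(f"unknown edge kind in edge {tuple(row)}")
            for endpoint in (row.source_id, row.target_id):
                if endpoint not in kind_of:
                    raise FormatError(f"edge {tuple(row)} references unknown node {endpoint!r}")
            src_ok, dst_ok = EDGE_ENDPOINT_KINDS[row.edge_kind]
            if kind_of[row.source_id] not in src_ok or kind_of[row.target_id] not in dst_ok:
                raise FormatError(
                    f"edge {tuple(row)} is kind-incompatible: "
                    f"{kind_of[row.source_id]} -[{row.edge_kind}]-> {kind_of[row.target_id]}"
                )


def read_graph_file(path) -> GraphFile:
    """Read a graph export: a JSON document or a directory of paired TSVs."""
    path = Path(path)
    if path.is_dir():
        nodes = pd.read_csv(path / "nodes.tsv", sep="\t", dtype=str)
        edges = pd.read_csv(path / "edges.tsv", sep="\t", dtype=str)
    else:
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        if not isinstance(doc, dict) or "nodes" not in doc or "edges" not in doc:
            raise FormatError(f"{path}: graph JSON must have top-level 'nodes' and 'edges'")
        nodes = pd.DataFrame(doc["nodes"], columns=["node_id", "node_kind", "display_name"])
        edges = pd.DataFrame(doc["edges"], columns=["source_id", "target_id", "edge_kind"])
    if "display_name" not in nodes.columns:
        nodes["display_name"] = nodes["node_id"]
    nodes = nodes.fillna({"display_name": ""}).reset_index(drop=True)
    edges = edges.reset_index(drop=True)
    return GraphFile(nodes=nodes, edges=edges)


def write_graph_file(graph: GraphFile, path) -> None:
    """Write a graph file as JSON (``.json``) or paired TSVs (directory)."""
    path = Path(path)
    if path.suffix == ".json":
        doc = {
            "nodes": graph.nodes.to_dict(orient="records"),
            "edges": graph.edges.to_dict(orient="records"),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)
            fh.write("\n")
    else:
        path.mkdir(parents=True, exist_ok=True)
        graph.nodes.to_csv(path / "nodes.tsv", sep="\t", index=False)
        graph.edges.to_csv(path / "edges.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT) and GO annotations


@dataclasses.dataclass
class GeneSetCollection:
    """Named entity sets with free-text descriptions (GMT semantics)."""

    sets: dict[str, tuple[str, tuple[str, ...]]]

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} has no members")

    def members(self, name: str) -> tuple[str, ...]:
        return self.sets[name][1]

    def description(self, name: str) -> str:
        return self.sets[name][0]

    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: per line, set name TAB description TAB members..."""
    path = Path(path)
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields (<3)")
            name, desc, *members = fields
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = (desc, tuple(m for m in members if m))
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


@dataclasses.dataclass
class GoAnnotation:
    """Entity -> GO term annotations with an optional term parent relation."""

    entity_to_terms: dict[str, frozenset[str]]
    term_parents: dict[str, frozenset[str]] = dataclasses.field(default_factory=dict)
    term_names: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 1 = on stack, 2 = done

        def visit(term: str, stack: list[str]) -> None:
            state[term] = 1
            for parent in sorted(self.term_parents.get(term, ())):
                if state.get(parent) == 1:
                    cycle = stack[stack.index(parent):] if parent in stack else [parent]
                    raise FormatError(f"GO parent relation has a cycle through {parent!r}: {cycle}")
                if state.get(parent) != 2:
                    visit(parent, stack + [parent])
            state[term] = 2

        for term in list(self.term_parents):
            if state.get(term) != 2:
                visit(term, [term])

    def ancestors(self, term: str) -> frozenset[str]:
        """All (transitive) parents of a term, excluding the term itself."""
        out: set[str] = set()
        frontier = list(self.term_parents.get(term, ()))
        while frontier:
            t = frontier.pop()
            if t not in out:
                out.add(t)
                frontier.extend(self.term_parents.get(t, ()))
        return frozenset(out)

    def terms(self) -> list[str]:
        all_terms: set[str] = set()
        for ts in self.entity_to_terms.values():
            all_terms |= ts
        for t, ps in self.term_parents.items():
            all_terms.add(t)
            all_terms |= ps
        return sorted(all_terms)


def read_go_annotation(path, parents_path=None) -> GoAnnotation:
    """Read ``entity<TAB>term`` annotations, optionally ``term<TAB>parent``."""
    entity_to_terms: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected entity<TAB>term")
            entity_to_terms.setdefault(fields[0], set()).add(fields[1])
    term_parents: dict[str, set[str]] = {}
    if parents_path is not None:
        with open(parents_path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise FormatError(f"{parents_path}:{lineno}: expected term<TAB>parent")
                term_parents.setdefault(fields[0], set()).add(fields[1])
    return GoAnnotation(
        entity_to_terms={e: frozenset(ts) for e, ts in entity_to_terms.items()},
        term_parents={t: frozenset(ps) for t, ps in term_parents.items()},
    )


def write_go_annotation(annotation: GoAnnotation, path, parents_path=None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for entity in sorted(annotation.entity_to_terms):
            for term in sorted(annotation.entity_to_terms[entity]):
                fh.write(f"{entity}\t{term}\n")
    if parents_path is not None:
        with open(parents_path, "w", encoding="utf-8", newline="") as fh:
            for term in sorted(annotation.term_parents):
                for parent in sorted(annotation.term_parents[term]):
                    fh.write(f"{term}\t{parent}\n")


# ---------------------------------------------------------------------------
# generic table export


def write_table_csv(table: pd.DataFrame, path, index: bool = False) -> None:
    """Export a result table exactly as ordered/filtered in memory."""
    table.to_csv(Path(path), index=index, encoding="utf-8")
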