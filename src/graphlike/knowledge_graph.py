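"""The integrated entity-reaction-pathway knowledge graph.

Horizontal integration maps each uploaded entity onto a typed graph:
transcripts are linked to the proteins they encode, proteins and metabolites
to the reactions they participate in, and reactions to the pathways that
contain them. Every linked-table filter in the toolkit reduces to the
``connected`` predicate defined here.

Connectivity is deliberately *not* general graph reachability. Unrestricted
reachability would connect nearly everything through hub pathways; instead
two nodes are connected iff they match one of a fixed list of biologically
meaningful path patterns (e.g. a transcript reaches a metabolite only
through a reaction its encoded protein participates in).
"""

from __future__ import annotations

import dataclasses
import warnings

from .formats_io import (
    FormatWarning,
    GraphFile,
    MeasurementTable,
    NODE_KINDS,
    OMICS_KINDS,
)

__all__ = ["KnowledgeGraph", "MappingSummary", "build_graph"]


class KnowledgeGraph:
    """Typed node sets plus typed adjacency, queried as an undirected graph.

    Attributes
    ----------
    kind_of:
        node id -> node kind.
    measured:
        Set of entity node ids that appear in an uploaded measurement table.
        Only transcript/protein/metabolite nodes can be measured.
    """

    def __init__(self, graph_file: GraphFile):
        self.kind_of: dict[str, str] = dict(
            zip(graph_file.nodes["node_id"], graph_file.nodes["node_kind"])
        )
        self.display_name: dict[str, str] = dict(
            zip(graph_file.nodes["node_id"], graph_file.nodes["display_name"])
        )
        self._by_kind: dict[str, set[str]] = {k: set() for k in NODE_KINDS}
        for node, kind in self.kind_of.items():
            self._by_kind[kind].add(node)

        # typed adjacency, both directions
        self.proteins_of_transcript: dict[str, set[str]] = {}
        self.transcripts_of_protein: dict[str, set[str]] = {}
        self.reactions_of_entity: dict[str, set[str]] = {}  # protein/metabolite -> reactions
        self.participants_of_reaction: dict[str, set[str]] = {}
        self.pathways_of_reaction: dict[str, set[str]] = {}
        self.reactions_of_pathway: dict[str, set[str]] = {}
        for row in graph_file.edges.itertuples(index=False):
            s, t, kind = row.source_id, row.target_id, row.edge_kind
            if kind == "encodes":
                self.proteins_of_transcript.setdefault(s, set()).add(t)
                self.transcripts_of_protein.setdefault(t, set()).add(s)
            elif kind == "participates":
                self.reactions_of_entity.setdefault(s, set()).add(t)
                self.participants_of_reaction.setdefault(t, set()).add(s)
            else:  # member
                self.pathways_of_reaction.setdefault(s, set()).add(t)
                self.reactions_of_pathway.setdefault(t, set()).add(s)

        self.measured: set[str] = set()

    # -- basic queries -----------------------------------------------------

    def __contains__(self, node: str) -> bool:
        return node in self.kind_of

    def nodes_of_kind(self, kind: str) -> set[str]:
        if kind not in NODE_KINDS:
            raise KeyError(f"unknown node kind: {kind!r}")
        return set(self._by_kind[kind])

    def mark_measured(self, entity_ids) -> None:
        for eid in entity_ids:
            if eid in self.kind_of:
                if self.kind_of[eid] not in OMICS_KINDS:
                    raise ValueError(f"cannot mark non-entity node {eid!r} as measured")
                self.measured.add(eid)

    def measured_of_kind(self, kind: str) -> set[str]:
        return {n for n in self.measured if self.kind_of[n] == kind}

    # -- reaction neighbourhoods ------------------------------------------

    def _reactions_of(self, node: str) -> set[str]:
        """Reactions a node touches: direct for proteins/metabolites, via the
        encoded protein(s) for transcripts, identity for reactions."""
        kind = self.kind_of[node]
        if kind == "reaction":
            return {node}
        if kind in ("protein", "metabolite"):
            return self.reactions_of_entity.get(node, set())
        if kind == "transcript":
            out: set[str] = set()
            for protein in self.proteins_of_transcript.get(node, ()):
                out |= self.reactions_of_entity.get(protein, set())
            return out
        raise ValueError(f"node {node!r} of kind {kind!r} has no reaction neighbourhood")

    # -- connectivity ------------------------------------------------------

    def connected(self, a: str, b: str) -> bool:
        """True iff ``a`` and ``b`` match one of the fixed path patterns.

        Patterns (symmetric): transcript-protein via an encodes edge;
        protein-reaction and metabolite-reaction via a participates edge;
        reaction-pathway via a member edge; transcript-reaction through the
        encoded protein; transcript-metabolite and protein-metabolite through
        a single shared reaction; any entity-pathway through a reaction that
        is a member of the pathway. Same-kind nodes are connected iff equal.
        """
        for node in (a, b):
            if node not in self.kind_of:
                raise KeyError(f"unknown node: {node!r}")
        ka, kb = self.kind_of[a], self.kind_of[b]
        if ka == kb:
            return a == b
        # order the pair canonically by kind
        if NODE_KINDS.index(ka) > NODE_KINDS.index(kb):
            a, b, ka, kb = b, a, kb, ka
        if (ka, kb) == ("transcript", "protein"):
            return b in self.proteins_of_transcript.get(a, ())
        if kb == "reaction":
            return b in self._reactions_of(a)
        if kb == "pathway":
            members = self.reactions_of_pathway.get(b, set())
            return not members.isdisjoint(self._reactions_of(a))
        # remaining cross-entity pairs share a reaction
        return not self._reactions_of(a).isdisjoint(self._reactions_of(b))

    def neighbors_of_kind(self, a: str, kind: str) -> set[str]:
        """All nodes of ``kind`` connected to ``a`` (bulk ``connected``)."""
        if a not in self.kind_of:
            raise KeyError(f"unknown node: {a!r}")
        ka = self.kind_of[a]
        if ka == kind:
            return {a}
        if ka == "pathway":
            if kind == "reaction":
                return set(self.reactions_of_pathway.get(a, set()))
            out: set[str] = set()
            for reaction in self.reactions_of_pathway.get(a, ()):
                out |= self._entities_of_reaction(reaction, kind)
            return out
        if kind == "reaction":
            return set(self._reactions_of(a))
        if kind == "pathway":
            out = set()
            for reaction in self._reactions_of(a):
                out |= self.pathways_of_reaction.get(reaction, set())
            return out
        if ka == "reaction":
            return self._entities_of_reaction(a, kind)
        if (ka, kind) in (("transcript", "protein"), ("protein", "transcript")):
            table = self.proteins_of_transcript if ka == "transcript" else self.transcripts_of_protein
            return set(table.get(a, set()))
        # cross-entity via shared reactions
        out = set()
        for reaction in self._reactions_of(a):
            out |= self._entities_of_reaction(reaction, kind)
        return out

    def _entities_of_reaction(self, reaction: str, kind: str) -> set[str]:
        participants = self.participants_of_reaction.get(reaction, set())
        if kind in ("protein", "metabolite"):
            return {p for p in participants if self.kind_of[p] == kind}
        if kind == "transcript":
            out: set[str] = set()
            for p in participants:
                if self.kind_of[p] == "protein":
                    out |= self.transcripts_of_protein.get(p, set())
            return out
        raise KeyError(f"unknown entity kind: {kind!r}")


@dataclasses.dataclass
class MappingSummary:
    """Coverage of the automated mapping step.

    ``mapped`` counts, per node kind, how much of the graph the upload
    touches: for omics kinds, uploaded IDs found in the graph; for reactions
    and pathways, those connected to at least one measured entity.
    ``unmapped`` counts uploaded IDs absent from the graph, per omics.
    """

    mapped: dict[str, int]
    unmapped: dict[str, int]
    uploaded: dict[str, int]

    def __post_init__(self) -> None:
        for kind in self.uploaded:
            if self.mapped.get(kind, 0) + self.unmapped.get(kind, 0) != self.uploaded[kind]:
                raise ValueError(f"mapping counts inconsistent for {kind!r}")


def build_graph(
    graph_file: GraphFile, tables: list[MeasurementTable]
) -> tuple[KnowledgeGraph, MappingSummary]:
    """Construct the knowledge graph and mark uploaded entities as measured.

    Uploaded IDs absent from the graph are retained only in the summary's
    unmapped counts (with a warning), mirroring how real uploads report
    coverage without failing.
    """
    graph = KnowledgeGraph(graph_file)
    mapped: dict[str, int] = {}
    unmapped: dict[str, int] = {}
    uploaded: dict[str, int] = {}
    for table in tables:
        ids = set(table.entity_ids)
        kind_nodes = graph.nodes_of_kind(table.omics_kind)
        hit = ids & kind_nodes
        miss = ids - kind_nodes
        graph.mark_measured(hit)
        uploaded[table.omics_kind] = uploaded.get(table.omics_kind, 0) + len(ids)
        mapped[table.omics_kind] = mapped.get(table.omics_kind, 0) + len(hit)
        unmapped[table.omics_kind] = unmapped.get(table.omics_kind, 0) + len(miss)
        if miss:
            warnings.warn(
                f"{len(miss)} uploaded {table.omics_kind} IDs not present in the graph "
                f"(e.g. {sorted(miss)[:5]})",
                FormatWarning,
                stacklevel=2,
            )
    touched_reactions = {
        r for e in graph.measured for r in graph._reactions_of(e)
    }
    touched_pathways: set[str] = set()
    for r in touched_reactions:
        touched_pathways |= graph.pathways_of_reaction.get(r, set())
    mapped["reaction"] = len(touched_reactions)
    mapped["pathway"] = len(touched_pathways)
    return graph, MappingSummary(mapped=mapped, unmapped=unmapped, uploaded=uploaded)
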