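"""Seeded synthetic multi-omics projects with planted signal.

Generates everything the toolkit ingests — an entity-reaction-pathway
graph, per-omics measurement CSVs with an embedded group row, a design
table, pathway GMT sets and GO annotations — without any external
downloads. The graph mimics the mapped structure of a curated pathway
database at toy scale: each pathway owns a pool of proteins (each encoded
by exactly one transcript) and metabolites, and each of its reactions draws
participants from those pools.

Measurements are i.i.d. Gaussian on a log-like scale (the toolkit assumes
processed, roughly symmetric values); planted effects shift chosen entities
by a stated number of within-group standard deviations in the second group,
which is what differential and pathway-activity analyses should recover.
Everything is deterministic under the spec's seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .formats_io import (
    GeneSetCollection,
    GoAnnotation,
    GraphFile,
    MeasurementTable,
    OMICS_KINDS,
    write_gmt,
    write_go_annotation,
    write_graph_file,
    write_measurement_csv,
)
from .knowledge_graph import KnowledgeGraph

__all__ = [
    "PlantedEffect",
    "FixtureSpec",
    "generate_graph",
    "generate_measurements",
    "generate_go_annotation",
    "pathway_gmt",
    "write_project_inputs",
]

_ID_PREFIX = {
    "transcript": "ENSG",
    "protein": "PROT",
    "metabolite": "CMPD",
    "reaction": "RXN",
    "pathway": "PWY",
}


@dataclasses.dataclass(frozen=True)
class PlantedEffect:
    """A differential signal planted into the measurements.

    Either an explicit entity list or a pathway id (resolved to that
    pathway's connected entities of each requested omics kind). ``shift``
    is expressed in units of the within-group noise SD and is added to the
    second group's samples.
    """

    shift: float
    pathway: str | None = None
    entities: tuple[str, ...] = ()
    omics: tuple[str, ...] = OMICS_KINDS

    def __post_init__(self) -> None:
        if not np.isfinite(self.shift):
            raise ValueError("planted shift must be finite")
        if (self.pathway is None) == (not self.entities):
            raise ValueError("specify exactly one of pathway or entities")


@dataclasses.dataclass(frozen=True)
class FixtureSpec:
    """Counts, noise and planted effects for one synthetic project.

    Defaults give 20 pathways of 3 reactions each, 10 proteins (and hence
    10 transcripts) plus 5 metabolites per pathway, and 6 samples in each
    of two groups with unit Gaussian noise — a small two-condition design
    of the shape the pathway-activity recovery analyses assume. By default
    one pathway (the first) carries a planted 2-SD shift across all omics,
    so a freshly generated demo project has real differential and
    pathway-activity signal to find; pass ``planted=()`` for a pure null.
    """

    seed: int = 0
    n_pathways: int = 20
    reactions_per_pathway: int = 3
    proteins_per_pathway: int = 10
    metabolites_per_pathway: int = 5
    proteins_per_reaction: int = 4
    metabolites_per_reaction: int = 2
    transcripts_per_protein: int = 1
    samples_per_group: int = 6
    groups: tuple[str, str] = ("distal", "proximal")
    noise_sd: float = 1.0
    planted: tuple[PlantedEffect, ...] = (PlantedEffect(shift=2.0, pathway="PWY0000"),)

    def __post_init__(self) -> None:
        counts = (
            self.n_pathways,
            self.reactions_per_pathway,
            self.proteins_per_pathway,
            self.metabolites_per_pathway,
            self.proteins_per_reaction,
            self.metabolites_per_reaction,
            self.transcripts_per_protein,
            self.samples_per_group,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all fixture counts must be positive")
        if self.proteins_per_reaction > self.proteins_per_pathway:
            raise ValueError("proteins_per_reaction exceeds the per-pathway pool")
        if self.metabolites_per_reaction > self.metabolites_per_pathway:
            raise ValueError("metabolites_per_reaction exceeds the per-pathway pool")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if len(self.groups) != 2 or self.groups[0] == self.groups[1]:
            raise ValueError("exactly two distinct group labels are required")

    # -- (de)serialisation for the CLI ------------------------------------

    def to_json(self) -> str:
        doc = dataclasses.asdict(self)
        doc["planted"] = [dataclasses.asdict(e) for e in self.planted]
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FixtureSpec":
        doc = json.loads(text)
        planted = tuple(
            PlantedEffect(
                shift=e["shift"],
                pathway=e.get("pathway"),
                entities=tuple(e.get("entities", ())),
                omics=tuple(e.get("omics", OMICS_KINDS)),
            )
            for e in doc.pop("planted", [])
        )
        doc["groups"] = tuple(doc.get("groups", ("distal", "proximal")))
        return cls(planted=planted, **doc)


def _seed_for(spec: FixtureSpec, stream: str) -> np.random.Generator:
    """Independent deterministic RNG per generator stage."""
    streams = {"graph": 0, "measurements": 1, "go": 2}
    return np.random.default_rng(np.random.SeedSequence([spec.seed, streams[stream]]))


def generate_graph(spec: FixtureSpec) -> GraphFile:
    """Build the synthetic entity-reaction-pathway graph.

    Node counts are closed-form in the spec: ``n_pathways`` pathways,
    ``n_pathways * reactions_per_pathway`` reactions, per-pathway protein
    and metabolite pools (disjoint across pathways), one-or-more
    transcripts per protein. Each reaction samples its participants from
    its own pathway's pools without replacement.
    """
    rng = _seed_for(spec, "graph")
    nodes, edges = [], []
    protein_counter = metabolite_counter = transcript_counter = reaction_counter = 0
    for p in range(spec.n_pathways):
        pathway_id = f"{_ID_PREFIX['pathway']}{p:04d}"
        nodes.append((pathway_id, "pathway", f"Pathway {p}"))
        proteins = []
        for _ in range(spec.proteins_per_pathway):
            pid = f"{_ID_PREFIX['protein']}{protein_counter:05d}"
            protein_counter += 1
            proteins.append(pid)
            nodes.append((pid, "protein", pid))
            for _ in range(spec.transcripts_per_protein):
                tid = f"{_ID_PREFIX['transcript']}{transcript_counter:05d}"
                transcript_counter += 1
                nodes.append((tid, "transcript", tid))
                edges.append((tid, pid, "encodes"))
        metabolites = []
        for _ in range(spec.metabolites_per_pathway):
            mid = f"{_ID_PREFIX['metabolite']}{metabolite_counter:05d}"
            metabolite_counter += 1
            metabolites.append(mid)
            nodes.append((mid, "metabolite", mid))
        for _ in range(spec.reactions_per_pathway):
            rid = f"{_ID_PREFIX['reaction']}{reaction_counter:05d}"
            reaction_counter += 1
            nodes.append((rid, "reaction", rid))
            edges.append((rid, pathway_id, "member"))
            for pid in sorted(rng.choice(proteins, size=spec.proteins_per_reaction, replace=False)):
                edges.append((pid, rid, "participates"))
            for mid in sorted(
                rng.choice(metabolites, size=spec.metabolites_per_reaction, replace=False)
            ):
                edges.append((mid, rid, "participates"))
    return GraphFile(
        nodes=pd.DataFrame(nodes, columns=["node_id", "node_kind", "display_name"]),
        edges=pd.DataFrame(edges, columns=["source_id", "target_id", "edge_kind"]),
    )


def _resolve_planted(
    spec: FixtureSpec, graph_file: GraphFile, omics_kind: str
) -> dict[str, float]:
    """Entity -> total shift for one omics kind."""
    graph = KnowledgeGraph(graph_file)
    known = set(graph_file.nodes["node_id"])
    shifts: dict[str, float] = {}
    for effect in spec.planted:
        if omics_kind not in effect.omics:
            continue
        if effect.pathway is not None:
            if effect.pathway not in known:
                raise KeyError(f"planted pathway {effect.pathway!r} is not in the graph")
            targets = graph.neighbors_of_kind(effect.pathway, omics_kind)
        else:
            missing = [e for e in effect.entities if e not in known]
            if missing:
                raise KeyError(f"planted entities not in the graph: {missing}")
            targets = {e for e in effect.entities if graph.kind_of[e] == omics_kind}
        for entity in targets:
            shifts[entity] = shifts.get(entity, 0.0) + effect.shift * spec.noise_sd
    return shifts


def sample_ids(spec: FixtureSpec) -> list[str]:
    return [f"{g}_{j + 1}" for g in spec.groups for j in range(spec.samples_per_group)]


def generate_measurements(
    spec: FixtureSpec, graph_file: GraphFile
) -> dict[str, MeasurementTable]:
    """Per-omics measurement tables with baseline noise and planted shifts."""
    rng = _seed_for(spec, "measurements")
    samples = sample_ids(spec)
    group_of = {s: s.rsplit("_", 1)[0] for s in samples}
    group2_cols = [i for i, s in enumerate(samples) if group_of[s] == spec.groups[1]]
    tables: dict[str, MeasurementTable] = {}
    by_kind = graph_file.nodes.groupby("node_kind")["node_id"]
    for omics in OMICS_KINDS:
        ids = sorted(by_kind.get_group(omics)) if omics in by_kind.groups else []
        values = rng.normal(0.0, spec.noise_sd, size=(len(ids), len(samples)))
        shifts = _resolve_planted(spec, graph_file, omics)
        for i, entity in enumerate(ids):
            if entity in shifts:
                values[i, group2_cols] += shifts[entity]
        frame = pd.DataFrame(values, index=pd.Index(ids, name="id"), columns=samples)
        tables[omics] = MeasurementTable(omics_kind=omics, values=frame, group_of=dict(group_of))
    return tables


def pathway_gmt(graph_file: GraphFile, omics_kind: str = "transcript") -> GeneSetCollection:
    """Pathway membership of one omics kind as a GMT-style collection."""
    graph = KnowledgeGraph(graph_file)
    sets = {}
    for pathway in sorted(graph.nodes_of_kind("pathway")):
        members = tuple(sorted(graph.neighbors_of_kind(pathway, omics_kind)))
        if members:
            sets[pathway] = (graph.display_name.get(pathway, pathway), members)
    return GeneSetCollection(sets=sets)


def generate_go_annotation(spec: FixtureSpec, graph_file: GraphFile) -> GoAnnotation:
    """Toy GO annotation: one term per pathway over its transcripts.

    Every pathway term is a child of a single root term, exercising the
    true-path propagation rule without mimicking the real ontology.
    """
    graph = KnowledgeGraph(graph_file)
    root = "GO:0000001"
    entity_to_terms: dict[str, set[str]] = {}
    term_parents: dict[str, frozenset[str]] = {}
    term_names = {root: "biological process (root)"}
    for i, pathway in enumerate(sorted(graph.nodes_of_kind("pathway"))):
        term = f"GO:{i + 2:07d}"
        term_parents[term] = frozenset([root])
        term_names[term] = f"process of {pathway}"
        for transcript in graph.neighbors_of_kind(pathway, "transcript"):
            entity_to_terms.setdefault(transcript, set()).add(term)
    return GoAnnotation(
        entity_to_terms={e: frozenset(ts) for e, ts in entity_to_terms.items()},
        term_parents=term_parents,
        term_names=term_names,
    )


def write_project_inputs(spec: FixtureSpec, outdir) -> dict[str, Path]:
    """Write a complete demo project's input files; returns their paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    graph_file = generate_graph(spec)
    tables = generate_measurements(spec, graph_file)
    paths: dict[str, Path] = {}

    paths["graph"] = outdir / "graph.json"
    write_graph_file(graph_file, paths["graph"])
    for omics, table in tables.items():
        paths[omics] = outdir / f"{omics}s.csv"
        write_measurement_csv(table, paths[omics])
    design = pd.DataFrame(
        {"sample": sample_ids(spec), "group": [s.rsplit("_", 1)[0] for s in sample_ids(spec)]}
    )
    paths["design"] = outdir / "design.csv"
    design.to_csv(paths["design"], index=False)
    paths["gmt"] = outdir / "pathways.gmt"
    write_gmt(pathway_gmt(graph_file), paths["gmt"])
    annotation = generate_go_annotation(spec, graph_file)
    paths["go"] = outdir / "go_annotation.tsv"
    paths["go_parents"] = outdir / "go_parents.tsv"
    write_go_annotation(annotation, paths["go"], paths["go_parents"])
    paths["spec"] = outdir / "fixture_spec.json"
    paths["spec"].write_text(spec.to_json() + "\n", encoding="utf-8")
    return paths
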