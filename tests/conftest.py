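from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from graphlike.formats_io import GraphFile, MeasurementTable
from graphlike.knowledge_graph import build_graph


@pytest.fixture
def five_node_graph_file() -> GraphFile:
    """The canonical minimal complete path: T1 -> Pr1 -> R1 -> P1, M1 -> R1."""
    nodes = pd.DataFrame(
        [
            ("T1", "transcript", "gene one"),
            ("Pr1", "protein", "protein one"),
            ("M1", "metabolite", "metabolite one"),
            ("R1", "reaction", "reaction one"),
            ("P1", "pathway", "pathway one"),
        ],
        columns=["node_id", "node_kind", "display_name"],
    )
    edges = pd.DataFrame(
        [
            ("T1", "Pr1", "encodes"),
            ("Pr1", "R1", "participates"),
            ("M1", "R1", "participates"),
            ("R1", "P1", "member"),
        ],
        columns=["source_id", "target_id", "edge_kind"],
    )
    return GraphFile(nodes=nodes, edges=edges)


@pytest.fixture
def five_node_graph(five_node_graph_file):
    graph, _ = build_graph(five_node_graph_file, [])
    return graph


def make_table(ids, samples, values, groups=None, omics="transcript", de=None):
    frame = pd.DataFrame(
        np.asarray(values, dtype=float), index=pd.Index(ids, name="id"), columns=samples
    )
    de_frame = pd.DataFrame(de if de is not None else {}, index=frame.index, dtype=float)
    return MeasurementTable(
        omics_kind=omics, values=frame, group_of=dict(groups or {}), de=de_frame
    )


@pytest.fixture
def grouped_table():
    """8 entities x 6 samples in two groups of 3, simple deterministic values."""
    rng = np.random.default_rng(42)
    ids = [f"g{i}" for i in range(8)]
    samples = [f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)]
    groups = {s: s[0] for s in samples}
    return make_table(ids, samples, rng.normal(size=(8, 6)), groups)
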