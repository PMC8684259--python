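import itertools

import numpy as np
import pandas as pd
import pytest

from graphlike import linked_selection as ls
from graphlike.fixtures import FixtureSpec, generate_graph
from graphlike.formats_io import GraphFile, NODE_KINDS
from graphlike.knowledge_graph import build_graph

from _oracles import oracle_visible, random_graph_file


@pytest.fixture(scope="module")
def drilldown_graph():
    """A multi-pathway fixture rich enough for pathway->metabolite drill-down."""
    graph_file = generate_graph(
        FixtureSpec(seed=9, n_pathways=5, reactions_per_pathway=2,
                    proteins_per_pathway=4, metabolites_per_pathway=3,
                    proteins_per_reaction=2, metabolites_per_reaction=2)
    )
    graph, _ = build_graph(graph_file, [])
    return graph_file, graph


def random_state(rng, graph_file, max_groups=3):
    groups = []
    for _ in range(int(rng.integers(0, max_groups + 1))):
        kind = str(rng.choice(NODE_KINDS))
        pool = list(
            graph_file.nodes.loc[graph_file.nodes["node_kind"] == kind, "node_id"]
        )
        if not pool:
            continue
        size = int(rng.integers(1, min(3, len(pool)) + 1))
        ids = rng.choice(pool, size=size, replace=False)
        groups.append((kind, frozenset(str(i) for i in ids)))
    return groups


def as_state(groups):
    return ls.SelectionState(
        groups=tuple(ls.SelectionGroup(table=k, ids=ids) for k, ids in groups)
    )


class TestVisibleSet:
    def test_empty_state_shows_everything(self, drilldown_graph):
        graph_file, graph = drilldown_graph
        for kind in NODE_KINDS:
            expected = set(
                graph_file.nodes.loc[graph_file.nodes["node_kind"] == kind, "node_id"]
            )
            assert ls.visible_set(graph, ls.SelectionState(), kind) == expected

    def test_pathways_then_metabolites_drilldown(self, drilldown_graph):
        """Selecting 3 pathways then 2 metabolites leaves exactly the
        transcripts connected to >=1 selected metabolite AND >=1 selected
        pathway (the drill-down algebra)."""
        graph_file, graph = drilldown_graph
        pathways = sorted(graph.nodes_of_kind("pathway"))[:3]
        state = ls.add_selection(ls.SelectionState(), graph, "pathway", pathways)
        mets = sorted(ls.visible_set(graph, state, "metabolite"))[:2]
        state = ls.add_selection(state, graph, "metabolite", mets)
        for kind in NODE_KINDS:
            expected = oracle_visible(
                graph_file, [("pathway", set(pathways)), ("metabolite", set(mets))], kind
            )
            assert ls.visible_set(graph, state, kind) == expected

    def test_pathway_without_reactions_empties_entity_tables(self):
        graph_file = GraphFile(
            nodes=pd.DataFrame(
                [("T1", "transcript", ""), ("W1", "pathway", ""), ("W2", "pathway", "")],
                columns=["node_id", "node_kind", "display_name"],
            ),
            edges=pd.DataFrame(columns=["source_id", "target_id", "edge_kind"]),
        )
        graph, _ = build_graph(graph_file, [])
        state = ls.add_selection(ls.SelectionState(), graph, "pathway", ["W1"])
        for kind in ("transcript", "protein", "metabolite", "reaction"):
            assert ls.visible_set(graph, state, kind) == set()
        assert ls.visible_set(graph, state, "pathway") == {"W1"}

    def test_invalid_id_in_state_is_an_error(self, five_node_graph):
        state = ls.SelectionState(
            groups=(ls.SelectionGroup(table="pathway", ids=frozenset(["nope"])),)
        )
        with pytest.raises(KeyError):
            ls.visible_set(five_node_graph, state, "transcript")

    def test_monotone_under_added_groups(self, drilldown_graph):
        graph_file, graph = drilldown_graph
        rng = np.random.default_rng(1)
        for _ in range(100):
            groups = random_state(rng, graph_file, max_groups=2)
            extra = random_state(rng, graph_file, max_groups=1)
            if not extra:
                continue
            before = as_state(groups)
            after = as_state(groups + extra)
            for kind in NODE_KINDS:
                assert ls.visible_set(graph, after, kind) <= ls.visible_set(
                    graph, before, kind
                )

    def test_order_invariant(self, drilldown_graph):
        graph_file, graph = drilldown_graph
        rng = np.random.default_rng(2)
        groups = None
        while not groups or len(groups) < 3:
            groups = random_state(rng, graph_file, max_groups=4)
        reference = {
            kind: ls.visible_set(graph, as_state(groups), kind) for kind in NODE_KINDS
        }
        for perm in itertools.permutations(groups):
            for kind in NODE_KINDS:
                assert ls.visible_set(graph, as_state(list(perm)), kind) == reference[kind]

    def test_matches_forall_exists_oracle_on_random_graphs(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            graph_file = random_graph_file(rng)
            graph, _ = build_graph(graph_file, [])
            groups = random_state(rng, graph_file)
            for kind in NODE_KINDS:
                assert ls.visible_set(graph, as_state(groups), kind) == oracle_visible(
                    graph_file, groups, kind
                )


class TestAddClear:
    def test_groups_append_in_order(self, five_node_graph):
        state = ls.add_selection(ls.SelectionState(), five_node_graph, "pathway", ["P1"])
        state = ls.add_selection(state, five_node_graph, "metabolite", ["M1"])
        assert [g.table for g in state.groups] == ["pathway", "metabolite"]

    def test_multiple_ids_in_one_call_form_one_group(self, drilldown_graph):
        _, graph = drilldown_graph
        pathways = sorted(graph.nodes_of_kind("pathway"))[:2]
        state = ls.add_selection(ls.SelectionState(), graph, "pathway", pathways)
        assert len(state) == 1
        assert state.groups[0].ids == frozenset(pathways)

    def test_replace_flag_drops_prior_groups_of_table(self, drilldown_graph):
        _, graph = drilldown_graph
        p1, p2 = sorted(graph.nodes_of_kind("pathway"))[:2]
        state = ls.add_selection(ls.SelectionState(), graph, "pathway", [p1])
        state = ls.add_selection(state, graph, "pathway", [p2], replace=True)
        assert len(state) == 1
        assert state.groups[0].ids == frozenset([p2])

    def test_wrong_kind_id_rejected(self, five_node_graph):
        with pytest.raises(ValueError, match="kind"):
            ls.add_selection(ls.SelectionState(), five_node_graph, "pathway", ["T1"])

    def test_empty_add_rejected(self, five_node_graph):
        with pytest.raises(ValueError, match="empty"):
            ls.add_selection(ls.SelectionState(), five_node_graph, "pathway", [])

    def test_clear_restores_unfiltered_sets(self, five_node_graph):
        state = ls.add_selection(ls.SelectionState(), five_node_graph, "metabolite", ["M1"])
        cleared = ls.clear_selection(state)
        assert cleared == ls.SelectionState()
        assert ls.visible_set(five_node_graph, cleared, "transcript") == {"T1"}


class TestNamedGroups:
    def test_save_then_load_reproduces_visible_set(self, drilldown_graph, tmp_path):
        _, graph = drilldown_graph
        pathway = sorted(graph.nodes_of_kind("pathway"))[0]
        state = ls.add_selection(ls.SelectionState(), graph, "pathway", [pathway])
        saved_transcripts = ls.visible_set(graph, state, "transcript")
        store = ls.GroupStore(tmp_path / "groups")
        group = ls.save_group(graph, state, "transcript", "DE_transcripts", store=store)
        assert group.ids == frozenset(saved_transcripts)
        reloaded = ls.load_group(ls.GroupStore(tmp_path / "groups").get("DE_transcripts"))
        assert ls.visible_set(graph, reloaded, "transcript") == saved_transcripts

    def test_duplicate_name_rejected(self, five_node_graph, tmp_path):
        store = ls.GroupStore(tmp_path)
        state = ls.SelectionState()
        ls.save_group(five_node_graph, state, "transcript", "g", store=store)
        with pytest.raises(ValueError, match="already exists"):
            ls.save_group(five_node_graph, state, "transcript", "g", store=store)

    def test_empty_selection_cannot_be_saved(self):
        graph_file = GraphFile(
            nodes=pd.DataFrame(
                [("W1", "pathway", ""), ("T1", "transcript", "")],
                columns=["node_id", "node_kind", "display_name"],
            ),
            edges=pd.DataFrame(columns=["source_id", "target_id", "edge_kind"]),
        )
        graph, _ = build_graph(graph_file, [])
        state = ls.add_selection(ls.SelectionState(), graph, "pathway", ["W1"])
        with pytest.raises(ValueError, match="nothing visible"):
            ls.save_group(graph, state, "transcript", "empty")
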