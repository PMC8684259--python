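import numpy as np
import pandas as pd
import pytest
from scipy import stats

from graphlike import pathway_activity as pa
from graphlike.diff_stats import welch_ttest_de
from graphlike.fixtures import FixtureSpec, PlantedEffect, generate_graph, generate_measurements
from graphlike.knowledge_graph import build_graph
from graphlike.linked_selection import NamedGroup
from graphlike.formats_io import GoAnnotation

from conftest import make_table
from _oracles import oracle_enrichment_score, oracle_hypergeom_tail


def sets_of(d):
    return {k: (k, tuple(v)) for k, v in d.items()}


class TestOra:
    def test_worked_hypergeometric_example(self):
        # N=10, K=4, n=5, k=3 -> P(X>=3) = 66/252
        background = [f"e{i}" for i in range(10)]
        members = background[:4]
        significant = background[:3] + background[4:6]  # overlap k=3
        result = pa.ora(background, sets_of({"S": members}), significant)
        assert result.frame.loc[0, "p"] == pytest.approx(66 / 252, abs=1e-12)
        assert result.frame.loc[0, "overlap"] == 3

    def test_exact_tail_matches_rational_oracle(self):
        for N in range(1, 15):
            for K in range(1, N + 1):
                for n in range(0, N + 1):
                    for k in range(0, min(n, K) + 1):
                        assert pa.hypergeom_tail(N, K, n, k) == pytest.approx(
                            float(oracle_hypergeom_tail(N, K, n, k)), abs=1e-12
                        )

    def test_saturated_de_list_gives_p1_everywhere(self):
        background = [f"e{i}" for i in range(8)]
        result = pa.ora(
            background, sets_of({"A": background[:3], "B": background[2:7]}), background
        )
        assert (result.frame["p"] == 1.0).all()
        assert (result.frame["overlap"] == result.frame["size"]).all()

    def test_zero_overlap_gives_p1(self):
        background = [f"e{i}" for i in range(10)]
        result = pa.ora(background, sets_of({"S": background[:3]}), background[5:7])
        assert result.frame.loc[0, "p"] == 1.0

    def test_unmapped_set_excluded_with_reason(self):
        background = ["a", "b", "c", "d"]
        result = pa.ora(background, sets_of({"S": ["x", "y", "z"]}), ["a"], min_size=1)
        assert len(result.frame) == 0
        assert "no members mapped" in result.excluded.loc[0, "reason"]

    def test_size_window_enforced(self):
        background = [f"e{i}" for i in range(10)]
        result = pa.ora(
            background,
            sets_of({"small": background[:2], "ok": background[:5]}),
            background[:2],
            min_size=3,
            max_size=4,
        )
        assert list(result.frame["set_id"]) == []
        reasons = dict(zip(result.excluded["set_id"], result.excluded["reason"]))
        assert "fewer" in reasons["small"]
        assert "more" in reasons["ok"]


class TestCollectDeEntities:
    def make(self, padj):
        return make_table(
            [f"e{i}" for i in range(len(padj))],
            ["s1"],
            [[0.0]] * len(padj),
            de={"padj_a_vs_b": padj},
        )

    def test_default_threshold_is_boundary_inclusive(self):
        tables = {"transcript": self.make([0.01, 0.05, 0.06])}
        out = pa.collect_de_entities(tables)
        assert out["transcript"] == {"e0", "e1"}

    def test_zero_threshold_keeps_only_exact_zeros(self):
        tables = {"transcript": self.make([0.01, 0.0])}
        assert pa.collect_de_entities(tables, threshold=0.0)["transcript"] == {"e1"}

    def test_threshold_one_keeps_all_with_padj(self):
        tables = {"transcript": self.make([0.2, 0.99, np.nan])}
        assert pa.collect_de_entities(tables, threshold=1.0)["transcript"] == {"e0", "e1"}

    def test_missing_padj_column_is_an_error(self):
        table = make_table(["e0"], ["s1"], [[0.0]])
        with pytest.raises(KeyError):
            pa.collect_de_entities({"transcript": table})


class TestGsea:
    def null_table(self, seed, n_entities=60, n1=4, n2=4):
        rng = np.random.default_rng(seed)
        samples = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
        return make_table(
            [f"e{i}" for i in range(n_entities)],
            samples,
            rng.normal(size=(n_entities, n1 + n2)),
            {s: s[0] for s in samples},
        )

    def test_weight_zero_worked_example(self):
        # hits at ranks 1 and 3 of 4: running sum 0.5, 0.0, 0.5, 0.0
        es, running = pa.enrichment_score(
            np.array([4.0, 3.0, 2.0, 1.0]), np.array([True, False, True, False]), weight=0.0
        )
        assert es == pytest.approx(0.5)
        np.testing.assert_allclose(running, [0.5, 0.0, 0.5, 0.0])

    def test_top_block_set_reaches_es_one(self):
        in_set = np.array([True] * 3 + [False] * 5)
        es, _ = pa.enrichment_score(np.linspace(5, 1, 8), in_set, weight=1.0)
        assert es == pytest.approx(1.0)

    def test_es_bounded_and_matches_naive_loop(self):
        rng = np.random.default_rng(20)
        for _ in range(50):
            n = int(rng.integers(4, 30))
            k = int(rng.integers(1, n))
            r = np.sort(rng.normal(size=n))[::-1]
            in_set = np.zeros(n, dtype=bool)
            in_set[rng.choice(n, size=k, replace=False)] = True
            for w in (0.0, 1.0):
                es, running = pa.enrichment_score(r, in_set, weight=w)
                es_o, running_o = oracle_enrichment_score(r, in_set, w)
                assert es == pytest.approx(es_o, abs=1e-12)
                np.testing.assert_allclose(running, running_o, atol=1e-12)
                assert -1 - 1e-12 <= es <= 1 + 1e-12

    def test_complement_set_has_opposite_sign_at_weight_zero(self):
        rng = np.random.default_rng(21)
        r = np.sort(rng.normal(size=12))[::-1]
        in_set = np.zeros(12, dtype=bool)
        in_set[[0, 2, 5]] = True
        es_a, _ = pa.enrichment_score(r, in_set, weight=0.0)
        es_b, _ = pa.enrichment_score(r, ~in_set, weight=0.0)
        assert np.sign(es_a) == -np.sign(es_b)

    def test_whole_background_set_rejected(self):
        with pytest.raises(ValueError, match="whole background"):
            pa.enrichment_score(np.array([2.0, 1.0]), np.array([True, True]))

    def test_seed_required(self, grouped_table):
        with pytest.raises(ValueError, match="seed"):
            pa.gsea(grouped_table, {"S": ["g0", "g1", "g2"]}, "a", "b")

    def test_entity_permutation_used_for_small_groups(self):
        table = self.null_table(22)
        sets = {f"S{j}": [f"e{i}" for i in range(5 * j, 5 * j + 5)] for j in range(4)}
        result = pa.gsea(table, sets, "a", "b", n_perm=100, seed=1)
        assert result.meta["permutation_scheme"] == "entity"
        assert set(result.frame.columns) == set(pa.RESULT_COLUMNS)
        assert result.frame["statistic"].between(-1, 1).all()

    def test_phenotype_permutation_for_large_groups(self):
        table = self.null_table(23, n_entities=30, n1=7, n2=7)
        sets = {"S0": [f"e{i}" for i in range(6)]}
        result = pa.gsea(table, sets, "a", "b", n_perm=50, seed=2)
        assert result.meta["permutation_scheme"] == "phenotype"

    def test_null_pvalues_roughly_uniform(self):
        table = self.null_table(24, n_entities=120)
        rng = np.random.default_rng(25)
        sets = {
            f"S{j}": [f"e{i}" for i in rng.choice(120, size=10, replace=False)]
            for j in range(30)
        }
        result = pa.gsea(table, sets, "a", "b", n_perm=300, seed=3)
        assert stats.kstest(result.frame["p"], "uniform").pvalue > 0.01


class TestPlage:
    def planted_tables(self, seed):
        spec = FixtureSpec(
            seed=seed,
            planted=(PlantedEffect(shift=2.0, pathway="PWY0000", omics=("protein",)),),
        )
        graph_file = generate_graph(spec)
        tables = generate_measurements(spec, graph_file)
        graph, _ = build_graph(graph_file, list(tables.values()))
        return spec, graph, tables

    def test_singleton_set_reduces_to_entity_t_test(self, grouped_table):
        activity, result = pa.plage(grouped_table, {"solo": ["g3"]}, "a", "b")
        welch = welch_ttest_de(grouped_table, "a", "b")
        t_set = abs(result.frame.loc[0, "statistic"])
        t_row = abs(welch.table.loc["g3", "t_statistic"])
        assert t_set == pytest.approx(t_row, abs=1e-8)
        # activity is the standardized profile up to scale
        row = grouped_table.values.loc["g3"].to_numpy()
        z = (row - row.mean()) / row.std(ddof=1)
        act = activity.values.loc["solo"].to_numpy()
        np.testing.assert_allclose(act / np.linalg.norm(act), z / np.linalg.norm(z), atol=1e-10)

    def test_rank_one_set_activity_proportional_to_profile(self):
        samples = [f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)]
        base = np.array([1.0, -2.0, 0.5, 3.0, -1.0, 0.25])
        rows = np.vstack([2 * base, -3 * base, 0.5 * base])
        table = make_table(["x", "y", "z"], samples, rows, {s: s[0] for s in samples})
        activity, _ = pa.plage(table, {"S": ["x", "y", "z"]}, "a", "b")
        act = activity.values.loc["S"].to_numpy()
        z = (base - base.mean()) / base.std(ddof=1)
        corr = np.corrcoef(act, z)[0, 1]
        assert abs(corr) == pytest.approx(1.0, abs=1e-10)

    def test_sign_follows_mean_member_profile(self, grouped_table):
        sets = {"S": ["g0", "g1", "g2", "g3"]}
        activity, _ = pa.plage(grouped_table, sets, "a", "b")
        act = activity.values.loc["S"].to_numpy()
        sub = grouped_table.values.loc[["g0", "g1", "g2", "g3"]].to_numpy()
        z = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, ddof=1, keepdims=True)
        assert np.dot(act, z.mean(axis=0)) >= 0

    def test_all_constant_set_excluded(self):
        samples = [f"a{i}" for i in range(2)] + [f"b{i}" for i in range(2)]
        table = make_table(
            ["c1", "c2", "v1", "v2"],
            samples,
            [[1, 1, 1, 1], [2, 2, 2, 2], [1, 2, 3, 4], [0, 1, 0, 1]],
            {s: s[0] for s in samples},
        )
        activity, result = pa.plage(table, {"C": ["c1", "c2"], "V": ["v1", "v2"]}, "a", "b")
        assert list(result.frame["set_id"]) == ["V"]
        assert "constant" in result.excluded.loc[0, "reason"]

    def test_invariant_to_member_row_order_and_constant_offsets(self, grouped_table):
        members = ["g0", "g1", "g2", "g4"]
        act1, _ = pa.plage(grouped_table, {"S": members}, "a", "b")
        shifted = grouped_table.values.copy()
        shifted.loc["g1"] += 100.0  # constant offset removed by standardization
        table2 = make_table(
            list(reversed(shifted.index)),
            shifted.columns,
            shifted.loc[list(reversed(shifted.index))].to_numpy(),
            grouped_table.group_of,
        )
        act2, _ = pa.plage(table2, {"S": list(reversed(members))}, "a", "b")
        np.testing.assert_allclose(
            act1.values.loc["S"].to_numpy(), act2.values.loc["S"].to_numpy(), atol=1e-8
        )

    def test_planted_pathway_recovered_across_seeds(self):
        hits = 0
        for seed in range(10):
            spec, graph, tables = self.planted_tables(seed)
            sets = pa.pathway_sets_from_graph(graph, "protein")
            _, result = pa.plage(tables["protein"], sets, *spec.groups)
            best = result.frame.sort_values(["p", "set_id"]).iloc[0]["set_id"]
            hits += best == "PWY0000"
        assert hits >= 9


class TestGoEnrichment:
    def fixture(self):
        background = [f"e{i}" for i in range(10)]
        group = NamedGroup(name="grp", table="transcript", ids=frozenset(background[:5]))
        annotation = GoAnnotation(
            entity_to_terms={
                **{e: frozenset(["GO:child"]) for e in background[:5]},
                background[6]: frozenset(["GO:other"]),
                "not_in_background": frozenset(["GO:absent"]),
            },
            term_parents={"GO:child": frozenset(["GO:parent"])},
        )
        return background, group, annotation

    def test_term_matching_group_exactly_is_most_significant(self):
        background, group, annotation = self.fixture()
        result = pa.go_enrichment(group, annotation, background)
        assert result.frame.iloc[0]["set_id"] in ("GO:child", "GO:parent")
        assert result.frame.iloc[0]["p"] == result.frame["p"].min()

    def test_child_annotations_propagate_to_parent(self):
        background, group, annotation = self.fixture()
        result = pa.go_enrichment(group, annotation, background)
        frame = result.frame.set_index("set_id")
        assert frame.loc["GO:parent", "overlap"] == frame.loc["GO:child", "overlap"] == 5

    def test_term_outside_background_excluded(self):
        background, group, annotation = self.fixture()
        result = pa.go_enrichment(group, annotation, background)
        assert "GO:absent" not in set(result.frame["set_id"])

    def test_empty_background_is_an_error(self):
        _, group, annotation = self.fixture()
        with pytest.raises(ValueError, match="background"):
            pa.go_enrichment(group, annotation, [])

    def test_uncovered_group_is_an_error(self):
        background, _, annotation = self.fixture()
        group = NamedGroup(name="g2", table="transcript", ids=frozenset(["unknown_entity"]))
        with pytest.raises(ValueError, match="covers no member"):
            pa.go_enrichment(group, annotation, background)


class TestResultContract:
    def test_frames_expose_sortable_schema(self, grouped_table):
        background = grouped_table.entity_ids
        result = pa.ora(background, sets_of({"S": background[:4]}), background[:2])
        assert list(result.frame.columns) == pa.RESULT_COLUMNS
        assert result.frame["padj"].between(0, 1).all()
        assert (result.frame["padj"] + 1e-12 >= result.frame["p"]).all()

    def test_combine_multiomics_is_reexported(self):
        from graphlike.query_engine import combine_pathway_queries

        assert pa.combine_multiomics is combine_pathway_queries
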