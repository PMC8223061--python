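import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mbsarc import (
    SubgroupLabels,
    aggregate_ranks,
    cross_validate,
    enumerate_combinations,
    rank_attributes,
    run_sarc,
    select_frontier,
    squared_weight_scores,
    train_pairwise,
)
from mbsarc.sarc_core import (
    AttributeRanking,
    EvaluationResult,
    GeneSetCandidate,
    load_panel,
)

from conftest import make_matrix


class TestTrainPairwise:
    def test_two_point_toy_analytic_solution(self, two_point_toy):
        # hard-margin between x1=(0,0) and x2=(2,0): w = 2(x2-x1)/||x2-x1||^2
        m, labels = two_point_toy
        model = train_pairwise(m, labels, ("WNT", "SHH"), C=1e6, standardize=False)
        np.testing.assert_allclose(model.weights, [1.0, 0.0], atol=1e-6)
        assert abs(model.bias - (-1.0)) < 1e-6

    def test_sign_convention_follows_canonical_pair_order(self, two_point_toy):
        # swapping the sample classes flips the separating direction
        m, _ = two_point_toy
        swapped = SubgroupLabels({"s1": "SHH", "s2": "WNT"})
        model = train_pairwise(m, swapped, ("SHH", "WNT"), C=1e6, standardize=False)
        assert model.class_pair == ("WNT", "SHH")  # sorted canonically
        np.testing.assert_allclose(model.weights, [-1.0, 0.0], atol=1e-6)
        assert abs(model.bias - 1.0) < 1e-6

    def test_separable_pair_reaches_training_accuracy_one(self):
        from mbsarc import SimulationConfig, simulate_expression

        cfg = SimulationConfig(
            n_per_class={"WNT": 20, "SHH": 20},
            n_noise_genes=30,
            markers_per_class=3,
            effect_size=5.0,
            seed=3,
        )
        m, labels, _ = simulate_expression(cfg)
        model = train_pairwise(m, labels, ("WNT", "SHH"))
        d = model.decision_values(m)
        pred = np.where(d > 0, "SHH", "WNT")
        truth = np.array([labels.assignments[s] for s in m.sample_ids])
        assert (pred == truth).all()

    def test_empty_class_rejected(self, two_point_toy):
        m, labels = two_point_toy
        with pytest.raises(ValueError, match="Group3"):
            train_pairwise(m, labels, ("WNT", "Group3"))

    def test_identical_samples_rejected(self):
        m = make_matrix([[1.0, 1.0], [2.0, 2.0]])
        labels = SubgroupLabels({"s1": "WNT", "s2": "SHH"})
        with pytest.raises(ValueError, match="identical"):
            train_pairwise(m, labels, ("WNT", "SHH"))


class TestRanking:
    def test_squared_weights_definition_and_sign_invariance(self, two_point_toy):
        m, labels = two_point_toy
        model = train_pairwise(m, labels, ("WNT", "SHH"), C=1e6, standardize=False)
        scores = squared_weight_scores(model)
        assert scores == {"g1": pytest.approx(1.0, abs=1e-6), "g2": pytest.approx(0.0, abs=1e-12)}
        flipped = {g: (-w) ** 2 for g, w in zip(model.gene_ids, model.weights)}
        assert flipped == pytest.approx(scores)

    def test_rank_examples(self):
        r = rank_attributes({"a": 0.25, "b": 4.0, "c": 1.0})
        assert r.ranks == {"b": 1, "c": 2, "a": 3}
        tied = rank_attributes({"a": 1.0, "b": 1.0})
        assert tied.ranks == {"a": 1, "b": 2}  # lexicographic tie-break

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError):
            rank_attributes({})

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=100), min_size=1, max_size=30))
    def test_matches_stable_sort_oracle_and_is_permutation(self, values):
        scores = {f"g{i:03d}": v for i, v in enumerate(values)}
        ranks = rank_attributes(scores).ranks
        # independent oracle: stable sort of (-score, id) pairs
        oracle = {g: i + 1 for i, (_, g) in enumerate(
            sorted(((-s, g) for g, s in scores.items())))}
        assert ranks == oracle
        assert sorted(ranks.values()) == list(range(1, len(values) + 1))


class TestAggregateRanks:
    def _ranking(self, pair, ranks):
        return AttributeRanking(pair, {g: 0.0 for g in ranks}, ranks)

    def test_sum_of_ranks(self):
        rankings = [
            self._ranking(("WNT", "SHH"), {"a": 2, "b": 1}),
            self._ranking(("WNT", "Group3"), {"a": 5, "b": 1}),
            self._ranking(("WNT", "Group4"), {"a": 1, "b": 2}),
        ]
        agg = aggregate_ranks("WNT", rankings)
        assert agg.total_rank == {"a": 8, "b": 4}
        assert agg.top_list == ["b", "a"]

    def test_all_firsts_is_necessarily_top(self):
        rankings = [
            self._ranking(("SHH", p), {"x": 1, "y": 2, "z": 3})
            for p in ("WNT", "Group3", "Group4")
        ]
        agg = aggregate_ranks("SHH", rankings)
        assert agg.total_rank["x"] == 3 and agg.top_list[0] == "x"

    def test_matches_exhaustive_oracle_small(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(5)]
        rankings = []
        for p in (("Group3", "WNT"), ("Group3", "SHH"), ("Group3", "Group4")):
            order = rng.permutation(genes)
            rankings.append(self._ranking(tuple(sorted(p, key=["WNT", "SHH", "Group3", "Group4"].index)),
                                          {g: i + 1 for i, g in enumerate(order)}))
        agg = aggregate_ranks("Group3", rankings)
        totals = {g: sum(r.ranks[g] for r in rankings) for g in genes}
        oracle = sorted(genes, key=lambda g: (totals[g], g))
        assert agg.top_list == oracle

    def test_rank_mass_conservation(self):
        # sum of total ranks over genes = 3 * n(n+1)/2
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(17)]
        rankings = []
        for p in (("WNT", "SHH"), ("WNT", "Group3"), ("WNT", "Group4")):
            scores = {g: float(v) for g, v in zip(genes, rng.random(len(genes)))}
            rankings.append(rank_attributes(scores, p))
        agg = aggregate_ranks("WNT", rankings)
        n = len(genes)
        assert sum(agg.total_rank.values()) == 3 * n * (n + 1) // 2

    def test_mismatched_universe_rejected(self):
        r1 = self._ranking(("WNT", "SHH"), {"a": 1})
        r2 = self._ranking(("WNT", "Group3"), {"b": 1})
        with pytest.raises(ValueError, match="universe"):
            aggregate_ranks("WNT", [r1, r2])


class TestEnumerateCombinations:
    def test_two_class_count(self):
        tops = {"WNT": ["a", "b"], "SHH": ["c", "d"]}
        cands = enumerate_combinations(tops, {c: [0, 1, 2] for c in tops}, k_max=2)
        assert len(cands) == 3 * 3 - 1
        k_vectors = {tuple(sorted(c.k_per_subgroup.items())) for c in cands}
        assert len(k_vectors) == len(cands)  # duplicate-free by k-vector

    def test_overlapping_top_genes_union(self):
        tops = {"WNT": ["shared"], "SHH": ["shared"]}
        cands = enumerate_combinations(tops, {c: [0, 1] for c in tops}, k_max=1)
        both = [c for c in cands if all(v == 1 for v in c.k_per_subgroup.values())]
        assert both[0].genes == ("shared",)

    def test_k_exceeding_top_list_rejected(self):
        with pytest.raises(ValueError, match="top-list"):
            enumerate_combinations({"WNT": ["a"], "SHH": ["b"]},
                                   {"WNT": [2], "SHH": [0]}, k_max=2)

    def test_candidate_gene_count_bounded_by_k_sum(self):
        tops = {"WNT": ["a", "b", "c"], "SHH": ["b", "c", "d"]}
        for c in enumerate_combinations(tops, {t: [0, 1, 2, 3] for t in tops}, 3):
            assert 0 < c.size <= sum(c.k_per_subgroup.values())


class TestCrossValidate:
    def test_perfectly_separating_gene(self):
        m = make_matrix([[0.1, 0.0, 10.0, 9.9]])
        labels = SubgroupLabels({"s1": "WNT", "s2": "WNT", "s3": "SHH", "s4": "SHH"})
        res = cross_validate(m, labels, ["g1"], folds=2, seed=0)
        assert res.accuracy == 1.0
        assert res.confusion.to_numpy().sum() == 4

    def test_uninformative_gene_near_chance(self):
        # a single exchangeable gene carries no signal; average accuracy over
        # seeds stays near the majority proportion (0.5 here)
        rng = np.random.default_rng(0)
        m = make_matrix(rng.normal(size=(1, 40)))
        labels = SubgroupLabels(
            {f"s{j+1}": ("WNT" if j < 20 else "SHH") for j in range(40)}
        )
        accs = [cross_validate(m, labels, ["g1"], folds=4, seed=s).accuracy
                for s in range(20)]
        assert np.mean(accs) <= 0.5 + 0.25

    def test_class_smaller_than_folds_rejected(self):
        m = make_matrix([[1.0, 2.0, 3.0]])
        labels = SubgroupLabels({"s1": "WNT", "s2": "WNT", "s3": "SHH"})
        with pytest.raises(ValueError, match="fewer than folds"):
            cross_validate(m, labels, ["g1"], folds=2, seed=0)

    def test_absent_gene_rejected(self, four_class_small):
        m, labels, _ = four_class_small
        with pytest.raises(KeyError):
            cross_validate(m, labels, ["NOT_A_GENE"], folds=2, seed=0)


class TestSelectFrontier:
    def _cand(self, size, acc):
        genes = tuple(f"g{i}" for i in range(size))
        hits = round(acc * 100)
        conf = pd.DataFrame([[hits, 100 - hits], [0, 0]],
                            index=["WNT", "SHH"], columns=["WNT", "SHH"])
        c = GeneSetCandidate({"WNT": size}, genes)
        c.evaluation = EvaluationResult.from_confusion(conf, folds=10, seed=0)
        return c

    def test_smallest_per_level_and_domination(self):
        cands = [self._cand(6, 0.93), self._cand(7, 0.93), self._cand(5, 0.82)]
        frontier = select_frontier(cands)
        assert [(c.size, round(c.evaluation.accuracy, 2)) for c in frontier] == \
            [(6, 0.93), (5, 0.82)]

    def test_single_candidate(self):
        c = self._cand(4, 0.9)
        assert select_frontier([c]) == [c]

    def test_matches_brute_force_pareto_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            cands = [self._cand(int(rng.integers(1, 20)),
                                round(float(rng.integers(50, 100)) / 100, 2))
                     for _ in range(int(rng.integers(1, 20)))]
            frontier = select_frontier(cands)
            # oracle: per rounded accuracy keep min size, then drop dominated
            levels = {}
            for c in cands:
                levels.setdefault(round(c.evaluation.accuracy, 2), []).append(c)
            keep = []
            for group in levels.values():
                smallest = min(c.size for c in group)
                keep += [c for c in group if c.size == smallest]
            expected = {
                id(c) for c in keep
                if not any(
                    (o.size <= c.size and o.evaluation.accuracy > c.evaluation.accuracy)
                    or (o.size < c.size and o.evaluation.accuracy >= c.evaluation.accuracy)
                    for o in keep)
            }
            assert {id(c) for c in frontier} == expected
            # monotone: ordered by accuracy descending, sizes must shrink too
            sizes = [c.size for c in frontier]
            assert sizes == sorted(sizes, reverse=True)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_frontier([])


class TestRunSarc:
    def test_recovers_planted_markers(self, four_class_small):
        m, labels, truth = four_class_small
        report = run_sarc(m, labels, k_grid={c: [0, 1, 2] for c in labels.classes},
                          folds=5, seed=1)
        for cls, markers in truth.items():
            top2 = set(report.aggregated[cls].top_list[:2])
            assert top2 == set(markers)
        assert report.best.evaluation.accuracy >= 0.95

    def test_same_seed_reproduces_report_exactly(self, four_class_small):
        m, labels, _ = four_class_small
        kwargs = dict(k_grid={c: [0, 2] for c in labels.classes}, folds=4, seed=9)
        a = run_sarc(m, labels, **kwargs)
        b = run_sarc(m, labels, **kwargs)
        pd.testing.assert_frame_equal(a.frontier_frame(), b.frontier_frame())
        pd.testing.assert_frame_equal(a.candidates_frame(), b.candidates_frame())
        pd.testing.assert_frame_equal(a.rankings_frame(), b.rankings_frame())

    def test_restrict_to_bounds_every_candidate(self, four_class_small):
        m, labels, truth = four_class_small
        panel = sorted({g for v in truth.values() for g in v}) + m.gene_ids[8:22]
        report = run_sarc(m, labels, restrict_to=panel,
                          k_grid={c: [0, 1, 2] for c in labels.classes},
                          folds=4, seed=2)
        for cand in report.candidates:
            assert set(cand.genes) <= set(panel)

    def test_global_scope_best_matches_exhaustive_cv_oracle(self):
        # tiny instance: best frontier accuracy must equal the max over
        # exhaustive cross_validate of every enumerated candidate's gene set
        from mbsarc import SimulationConfig, simulate_expression

        cfg = SimulationConfig(
            n_per_class={"WNT": 6, "SHH": 6}, n_noise_genes=4,
            markers_per_class=1, effect_size=3.0, seed=13,
        )
        m, labels, _ = simulate_expression(cfg)
        grid = {c: [0, 1, 2] for c in labels.classes}
        report = run_sarc(m, labels, k_grid=grid, folds=3, seed=4,
                          rank_scope="global")
        best = max(c.evaluation.accuracy for c in report.candidates)
        oracle = max(
            cross_validate(m, labels, list(c.genes), folds=3, seed=4).accuracy
            for c in report.candidates
        )
        assert best == oracle
        assert report.frontier[0].evaluation.accuracy == best

    def test_packaged_panels(self):
        p22 = load_panel("nanostring22")
        p6 = load_panel("six_gene")
        assert len(p22) == 22 and len(p6) == 6
        assert set(p6) <= set(p22)
        assert p6 == ["IMPG2", "NPR3", "KHDRBS2", "RBM24", "WIF1", "EMX2"]
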