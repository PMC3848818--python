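import numpy as np
import pandas as pd
import pytest

import naive
from conftest import random_pair, random_zmatrix
from dctopo import (
    correlation_matrices,
    dcglob_scores,
    exclusive_component_genes,
    generate,
    indicator_profiles,
    interval_to_pvalue,
    make_grid,
    max_run,
    network_at,
    toy_fixture,
)
from dctopo.synthdata import PlantedModule, SyntheticSpec


def _net_from_edges(genes, edges, t=0.5):
    from dctopo.corrnet import FisherZMatrix

    z = np.zeros((len(genes), len(genes)))
    idx = {g: i for i, g in enumerate(genes)}
    for u, v in edges:
        z[idx[u], idx[v]] = z[idx[v], idx[u]] = 1.0
    return network_at(FisherZMatrix(genes, z, 10), t)


class TestExclusiveSets:
    GENES = ("g1", "g2", "g3", "g4", "g5", "g6")

    def test_identical_networks_leave_nothing_exclusive(self):
        edges = [("g1", "g2"), ("g2", "g3"), ("g4", "g5"), ("g5", "g6")]
        net = _net_from_edges(self.GENES, edges)
        res = exclusive_component_genes(net, _net_from_edges(self.GENES, edges))
        assert res.a_tilde == frozenset() and res.b_tilde == frozenset()
        assert res.removed == frozenset(self.GENES)

    def test_component_only_in_one_condition_is_exclusive(self):
        net_a = _net_from_edges(
            self.GENES, [("g1", "g2"), ("g2", "g3"), ("g4", "g5"), ("g5", "g6")]
        )
        net_b = _net_from_edges(self.GENES, [("g1", "g2"), ("g2", "g3")])
        res = exclusive_component_genes(net_a, net_b)
        assert res.removed == frozenset(("g1", "g2", "g3"))
        assert res.a_tilde == frozenset(("g4", "g5", "g6"))
        assert res.b_tilde == frozenset()

    def test_induced_subnetwork_rule_is_conservative(self):
        # A: path g1-g2-g3-g4; B: component {g3,g4,g5}. Removing the shared
        # genes {g3,g4} leaves a pair in A and a singleton in B - nothing
        # large enough to count.
        genes = ("g1", "g2", "g3", "g4", "g5")
        net_a = _net_from_edges(genes, [("g1", "g2"), ("g2", "g3"), ("g3", "g4")])
        net_b = _net_from_edges(genes, [("g3", "g4"), ("g4", "g5")])
        res = exclusive_component_genes(net_a, net_b)
        assert res.removed == frozenset(("g3", "g4"))
        assert res.a_tilde == frozenset()
        assert res.b_tilde == frozenset()

    def test_gene_set_mismatch_rejected(self):
        net_a = _net_from_edges(("g1", "g2", "g3"), [("g1", "g2")])
        net_b = _net_from_edges(("g1", "g2", "g4"), [("g1", "g2")])
        with pytest.raises(ValueError, match="same gene set"):
            exclusive_component_genes(net_a, net_b)

    def test_matches_literal_set_algebra_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n = int(rng.integers(5, 30))
            za = random_zmatrix(n, seed=int(rng.integers(1 << 30)), scale=0.6)
            zb = random_zmatrix(n, seed=int(rng.integers(1 << 30)), scale=0.6)
            t = float(rng.uniform(0.2, 1.0))
            res = exclusive_component_genes(network_at(za, t), network_at(zb, t))
            removed, a_tilde, b_tilde = naive.naive_exclusive(za.z, zb.z, t)
            ids = za.gene_ids
            assert res.removed == frozenset(ids[i] for i in removed)
            assert res.a_tilde == frozenset(ids[i] for i in a_tilde)
            assert res.b_tilde == frozenset(ids[i] for i in b_tilde)


class TestIndicatorProfiles:
    def test_identical_conditions_give_all_zero_profiles(self):
        profiles = indicator_profiles(toy_fixture("identical"), make_grid(20, 2.0))
        assert not profiles.i_a.any() and not profiles.i_b.any()

    def test_profiles_match_single_threshold_recomputation(self):
        pair = toy_fixture("one_module_flip")
        grid = make_grid(15, 2.0)
        profiles = indicator_profiles(pair, grid)
        za, zb = correlation_matrices(pair)
        for m, t in enumerate(grid.thresholds):
            res = exclusive_component_genes(network_at(za, t), network_at(zb, t))
            ids = profiles.gene_ids
            assert {ids[g] for g in np.flatnonzero(profiles.i_a[:, m])} == set(res.a_tilde)
            assert {ids[g] for g in np.flatnonzero(profiles.i_b[:, m])} == set(res.b_tilde)

    def test_exclusive_sets_disjoint_at_every_threshold(self):
        pair = random_pair(15, 8, seed=23)
        profiles = indicator_profiles(pair, make_grid(25, 2.5))
        assert not (profiles.i_a & profiles.i_b).any()

    def test_planted_module_is_exclusive_over_a_threshold_range(self):
        spec = SyntheticSpec(
            n_genes=60, n_samples_per_group=100,
            modules=[PlantedModule(8, 0.8, 0.0)], seed=12,
        )
        pair, truth = generate(spec)
        grid = make_grid(40, 2.0)
        profiles = indicator_profiles(pair, grid)
        module = truth.loc[truth["dc_flag"], "gene_id"].tolist()
        idx = [profiles.gene_ids.index(g) for g in module]
        # Expected within-module z = atanh(0.8) = 1.099: every module gene
        # should be exclusive to A over a band of mid-range thresholds.
        band = (grid.thresholds > 0.7) & (grid.thresholds < 1.0)
        assert profiles.i_a[np.ix_(idx, np.flatnonzero(band))].all()
        assert not profiles.i_b[idx].any()


class TestMaxRun:
    GRID = make_grid(20, 2.0)

    def test_all_ones_spans_whole_grid(self):
        run = max_run(np.ones(20, bool), np.zeros(20, bool), self.GRID)
        assert run.direction == "A"
        assert run.run_start == pytest.approx(self.GRID.thresholds[0])
        assert run.run_end == pytest.approx(2.0)
        assert run.run_length == pytest.approx(2.0 - self.GRID.thresholds[0])

    def test_longest_run_wins_within_profile(self):
        i_a = np.zeros(20, bool)
        i_a[2:5] = True   # length-3 run (indices 2..4)
        i_a[8:13] = True  # length-5 run (indices 8..12)
        run = max_run(i_a, np.zeros(20, bool), self.GRID)
        assert (run.start_idx, run.end_idx) == (8, 12)
        assert run.run_length == pytest.approx(4 * self.GRID.delta)
        # exhaustive-scan cross-check
        lengths = [e - s for s, e in [(2, 4), (8, 12)]]
        assert run.end_idx - run.start_idx == max(lengths)

    def test_tie_between_conditions_prefers_higher_thresholds_then_a(self):
        i_a = np.zeros(20, bool)
        i_b = np.zeros(20, bool)
        i_a[1:4] = True
        i_b[10:13] = True
        run = max_run(i_a, i_b, self.GRID)
        assert run.direction == "B"  # same length, higher thresholds
        i_b2 = np.zeros(20, bool)
        i_b2[1:4] = True
        run = max_run(i_a, i_b2, self.GRID)
        assert run.direction == "A"  # exact tie -> A

    def test_empty_profiles_give_empty_run(self):
        run = max_run(np.zeros(20, bool), np.zeros(20, bool), self.GRID)
        assert run.direction == "none"
        assert run.run_length == 0.0
        assert np.isnan(run.run_start)

    def test_profile_length_must_match_grid(self):
        with pytest.raises(ValueError, match="length"):
            max_run(np.zeros(5, bool), np.zeros(5, bool), self.GRID)


class TestIntervalToPvalue:
    def test_zero_length_run_is_coin_flip(self):
        assert interval_to_pvalue(0.0, 100, 100) == pytest.approx(0.5)

    def test_cohort_scale_example(self):
        # SE = sqrt(2/205) = 0.09877 -> Z = 2.0248
        assert interval_to_pvalue(0.2, 208, 208) == pytest.approx(0.0214, abs=5e-5)

    def test_significance_boundary_at_cohort_scale(self):
        # p < 0.05 iff run_length > 1.6449 * sqrt(2/205) = 0.1625
        assert interval_to_pvalue(0.163, 208, 208) < 0.05
        assert interval_to_pvalue(0.162, 208, 208) > 0.05

    def test_p_non_increasing_in_run_length(self):
        lengths = np.linspace(0, 2, 30)
        pvals = [interval_to_pvalue(x, 50, 50) for x in lengths]
        assert all(p1 >= p2 for p1, p2 in zip(pvals, pvals[1:]))
        assert all(0 < p <= 1 for p in pvals)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            interval_to_pvalue(0.5, 3, 100)


class TestDcglobScores:
    def test_identical_conditions_score_nothing(self):
        table = dcglob_scores(toy_fixture("identical"), make_grid(30, 2.0))
        assert (table["p"] == 1.0).all()
        assert (table["direction"] == "none").all()

    def test_matches_naive_implementation(self):
        for seed in (1, 2, 3):
            pair = random_pair(n_genes=18, n_samples=10, seed=seed)
            grid = make_grid(12, 1.8)
            table = dcglob_scores(pair, grid).set_index("gene_id")
            za, zb = correlation_matrices(pair)
            oracle = naive.naive_dcglob(
                za.z, zb.z, grid.thresholds, pair.n_a, pair.n_b
            )
            for g, gene in enumerate(pair.gene_ids):
                direction, length, p = oracle[g]
                row = table.loc[gene]
                assert row["direction"] == direction
                assert row["run_length"] == pytest.approx(length, abs=1e-12)
                assert row["p"] == pytest.approx(p, abs=1e-12)

    def test_deterministic_output(self):
        pair = random_pair(10, 8, seed=3)
        grid = make_grid(15, 2.0)
        pd.testing.assert_frame_equal(dcglob_scores(pair, grid), dcglob_scores(pair, grid))

    def test_mirrored_fixture_scores_tie_across_directions(self):
        table = dcglob_scores(toy_fixture("tie_case"), make_grid(25, 2.5))
        by_gene = table.set_index("gene_id")
        for p_gene, q_gene in (("P1", "Q1"), ("P2", "Q2"), ("P3", "Q3")):
            assert by_gene.loc[p_gene, "p"] == by_gene.loc[q_gene, "p"]
        assert set(by_gene.loc[["P1", "P2", "P3"], "direction"]) == {"A"}
        assert set(by_gene.loc[["Q1", "Q2", "Q3"], "direction"]) == {"B"}

    def test_planted_module_ranks_at_top(self):
        ranks, aucs = [], []
        for seed in (0, 1, 2):
            spec = SyntheticSpec(
                n_genes=320, n_samples_per_group=80,
                modules=[PlantedModule(20, 0.8, 0.0)], seed=seed,
            )
            pair, truth = generate(spec)
            table = dcglob_scores(pair, make_grid(100, 2.5))
            position = pd.Series(
                np.arange(1, len(table) + 1), index=table["gene_id"]
            )
            flags = truth.set_index("gene_id")["dc_flag"]
            module_ranks = position[flags[flags].index]
            ranks.append(float(np.median(module_ranks)))
            scores = table.set_index("gene_id")["p"].reindex(flags.index)
            aucs.append(naive.auroc(flags.to_numpy(), -scores.to_numpy()))
        assert np.median(ranks) <= 25
        assert np.median(aucs) >= 0.95
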