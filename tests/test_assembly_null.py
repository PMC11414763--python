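import io

import numpy as np
import pytest

from mycoassembly import FeatureTable, patristic_distances, read_tree
from mycoassembly.assembly_null import (
    PROCESSES, beta_mntd, beta_nti, classify_pair, classify_processes,
    raup_crick_bray,
)
from mycoassembly.synthetic import ScenarioSpec, gen_tree, generate_scenario


@pytest.fixture
def balanced_tree():
    """((A:1,B:1):3,(C:1,D:1):3); — cross-clade tip distance is 8."""
    return read_tree(io.StringIO("((A:1,B:1):3,(C:1,D:1):3);"))


class TestBetaMntd:
    def test_identical_communities_score_zero(self, balanced_tree):
        ft = FeatureTable(["s1", "s2"], list("ABCD"),
                          np.array([[5, 5, 5, 5], [5, 5, 5, 5]]))
        dm = beta_mntd(ft, patristic_distances(balanced_tree))
        assert dm["s1", "s2"] == pytest.approx(0)

    def test_hand_enumerated_cross_clade_value(self, balanced_tree):
        # s1 = {A,B}, s2 = {C,D}: every taxon's nearest neighbour in the
        # other sample sits across the root: d = 1 + 3 + 3 + 1 = 8.
        # betaMNTD = 0.5 * (0.5*8 + 0.5*8 + 0.5*8 + 0.5*8) = 8.
        ft = FeatureTable(["s1", "s2"], list("ABCD"),
                          np.array([[1, 1, 0, 0], [0, 0, 1, 1]]))
        dm = beta_mntd(ft, patristic_distances(balanced_tree))
        assert dm["s1", "s2"] == pytest.approx(8, abs=1e-9)

    def test_weighted_equals_unweighted_for_even_abundances(self, balanced_tree):
        ft = FeatureTable(["s1", "s2"], list("ABCD"),
                          np.array([[2, 2, 0, 0], [0, 2, 2, 0]]))
        d = patristic_distances(balanced_tree)
        w = beta_mntd(ft, d, weighted=True)
        u = beta_mntd(ft, d, weighted=False)
        assert w["s1", "s2"] == pytest.approx(u["s1", "s2"])

    def test_brute_force_enumeration_random_case(self, rng):
        """betaMNTD equals an explicit loop over per-taxon minima."""
        tree = gen_tree(12, seed=5)
        dist = patristic_distances(tree)
        ids = list(dist.ids)
        counts = rng.integers(0, 4, size=(3, 12))
        counts[:, 0] += 1
        ft = FeatureTable(["x", "y", "z"], ids, counts)
        dm = beta_mntd(ft, dist)
        rel = ft.relative_abundance()
        d = np.asarray(dist.data)
        for k, l in [(0, 1), (0, 2), (1, 2)]:
            pk = np.flatnonzero(counts[k] > 0)
            pl = np.flatnonzero(counts[l] > 0)
            term_k = sum(rel[k, i] * d[i, pl].min() for i in pk)
            term_l = sum(rel[l, j] * d[j, pk].min() for j in pl)
            assert dm[ft.sample_ids[k], ft.sample_ids[l]] == pytest.approx(
                0.5 * (term_k + term_l), abs=1e-9
            )

    def test_scales_linearly_with_branch_lengths(self, balanced_tree, rng):
        ft = FeatureTable(["s1", "s2"], list("ABCD"),
                          np.array([[3, 1, 1, 0], [0, 1, 2, 2]]))
        d1 = patristic_distances(balanced_tree)
        from skbio import DistanceMatrix
        d3 = DistanceMatrix(np.asarray(d1.data) * 3.0, ids=d1.ids)
        m1 = beta_mntd(ft, d1)["s1", "s2"]
        m3 = beta_mntd(ft, d3)["s1", "s2"]
        assert m3 == pytest.approx(3 * m1)


class TestBetaNti:
    def test_seeded_runs_identical(self):
        spec = ScenarioSpec("null_exchangeable", seed=5, n_taxa=40, n_samples=6,
                            depth=500)
        table, tree, _ = generate_scenario(spec)
        dist = patristic_distances(tree, table.asv_ids)
        a = beta_nti(table, dist, 100, seed=9)
        b = beta_nti(table, dist, 100, seed=9)
        assert np.array_equal(a.beta_nti.data, b.beta_nti.data)

    def test_requires_100_randomizations(self, balanced_tree):
        ft = FeatureTable(["s1", "s2"], list("ABCD"),
                          np.array([[1, 1, 0, 0], [0, 0, 1, 1]]))
        with pytest.raises(Exception):
            beta_nti(ft, patristic_distances(balanced_tree), 10, seed=0)

    def test_null_scenario_centered_near_zero(self):
        spec = ScenarioSpec("null_exchangeable", seed=21, n_taxa=150,
                            n_samples=10, depth=1000)
        table, tree, _ = generate_scenario(spec)
        dist = patristic_distances(tree, table.asv_ids)
        res = beta_nti(table, dist, 199, seed=3)
        iu = np.triu_indices(table.n_samples, 1)
        vals = res.beta_nti.data[iu]
        assert abs(np.nanmean(vals)) < 0.75
        assert (np.abs(vals) >= 2).mean() < 0.25

    def test_filtering_scenario_detects_homogeneous_selection(self):
        spec = ScenarioSpec("filtered_shared_optimum", seed=6, n_taxa=600,
                            n_samples=10, depth=2000, richness=120)
        table, tree, _ = generate_scenario(spec)
        dist = patristic_distances(tree, table.asv_ids)
        res = beta_nti(table, dist, 199, seed=4)
        iu = np.triu_indices(table.n_samples, 1)
        assert np.nanmean(res.beta_nti.data[iu]) < -1.5


class TestRaupCrick:
    def test_identical_samples_near_minus_one(self):
        counts = np.array([[10, 5, 3, 2, 0, 0], [10, 5, 3, 2, 0, 0],
                           [4, 4, 4, 4, 4, 0]])
        ft = FeatureTable(["s1", "s2", "s3"], [f"a{i}" for i in range(6)], counts)
        rc = raup_crick_bray(ft, 199, seed=1)
        i, j = 0, 1
        assert rc.data[i, j] < -0.9

    def test_bounded_in_unit_interval(self, rng):
        ft = FeatureTable([f"s{i}" for i in range(6)], [f"a{j}" for j in range(30)],
                          rng.integers(0, 50, (6, 30)) + (rng.random((6, 30)) < 0.3))
        rc = raup_crick_bray(ft, 150, seed=2)
        assert (rc.data >= -1 - 1e-12).all() and (rc.data <= 1 + 1e-12).all()

    def test_pool_draws_centered(self):
        """Pairs drawn i.i.d. from the regional pool have RC near 0 on average."""
        spec = ScenarioSpec("null_exchangeable", seed=13, n_taxa=100,
                            n_samples=10, depth=800)
        table, _, _ = generate_scenario(spec)
        rc = raup_crick_bray(table, 199, seed=5)
        iu = np.triu_indices(10, 1)
        vals = rc.data[iu]
        assert abs(vals.mean()) < 0.5
        assert (np.abs(vals) > 0.95).mean() < 0.35

    def test_seeded_determinism(self, toy_table):
        a = raup_crick_bray(toy_table, 120, seed=8).data
        b = raup_crick_bray(toy_table, 120, seed=8).data
        assert np.array_equal(a, b)


class TestClassification:
    @pytest.mark.parametrize("bnti,rc,expected", [
        (-3.0, 0.99, "homogeneous_selection"),   # selection overrides RC
        (3.0, -0.99, "heterogeneous_selection"),
        (0.5, 0.99, "dispersal_limitation"),
        (0.5, -0.99, "homogenizing_dispersal"),
        (1.0, 0.0, "drift"),
        (-1.99, 0.5, "drift"),
    ])
    def test_threshold_rules(self, bnti, rc, expected):
        assert classify_pair(bnti, rc) == expected

    def test_printed_convention_differs_only_for_negative_tail(self):
        assert classify_pair(0.5, -0.99, "as_printed") == "homogenizing_dispersal"
        assert classify_pair(0.5, 0.5, "as_printed") == "drift"
        assert classify_pair(0.5, 0.99, "as_printed") == "dispersal_limitation"

    def test_fractions_sum_to_one_and_deterministic_split(self):
        spec = ScenarioSpec("null_exchangeable", seed=2, n_taxa=80, n_samples=8,
                            depth=600)
        table, tree, _ = generate_scenario(spec)
        dist = patristic_distances(tree, table.asv_ids)
        bnti = beta_nti(table, dist, 120, seed=1)
        rc = raup_crick_bray(table, 120, seed=2)
        rep = classify_processes(bnti, rc, {s: "g" for s in table.sample_ids})
        for _, row in rep.fractions.iterrows():
            assert sum(row[p] for p in PROCESSES) == pytest.approx(1, abs=1e-9)
            assert row["deterministic"] == pytest.approx(
                row["homogeneous_selection"] + row["heterogeneous_selection"]
            )

    def test_within_group_pairs_only_by_default(self):
        spec = ScenarioSpec("null_exchangeable", seed=3, n_taxa=60, n_samples=6,
                            depth=500)
        table, tree, _ = generate_scenario(spec)
        dist = patristic_distances(tree, table.asv_ids)
        bnti = beta_nti(table, dist, 100, seed=1)
        rc = raup_crick_bray(table, 100, seed=2)
        grouping = {s: ("g1" if i < 3 else "g2") for i, s in enumerate(table.sample_ids)}
        rep = classify_processes(bnti, rc, grouping)
        assert len(rep.pairs) == 6  # 2 * C(3,2)
        rep_all = classify_processes(bnti, rc, grouping, within_groups=False)
        assert len(rep_all.pairs) == 15
        assert (rep_all.pairs["group"] == "between").sum() == 9
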