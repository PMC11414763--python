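import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from mycoassembly import FeatureTable, ValidationError
from mycoassembly.diversity import (
    bray_curtis, nmds_embed, observed_richness, permanova, procrustes_test,
    shannon, shared_asv_partition,
)


class TestAlpha:
    @pytest.mark.parametrize("counts,expected", [
        ((5, 5, 5, 5), np.log(4)),
        ((7,), 0.0),
        ((1, 1, 2), -(2 * 0.25 * np.log(0.25) + 0.5 * np.log(0.5))),
    ])
    def test_shannon_values(self, counts, expected):
        assert shannon(counts) == pytest.approx(expected, abs=1e-4)

    def test_shannon_rejects_all_zero(self):
        with pytest.raises(ValidationError):
            shannon([0, 0])

    def test_richness(self, rng):
        v = rng.integers(0, 3, 100)
        assert observed_richness(v) == sum(1 for x in v if x > 0)
        assert observed_richness([0, 3, 0, 1]) == 2
        assert observed_richness([0, 0]) == 0


class TestBrayCurtis:
    def test_identical_zero_disjoint_one(self):
        ft = FeatureTable(["s1", "s2", "s3", "s4"], ["a", "b", "c"],
                          np.array([[2, 2, 0], [2, 2, 0], [1, 0, 0], [0, 1, 0]]))
        dm = bray_curtis(ft, use_relative=False)
        assert dm["s1", "s2"] == pytest.approx(0)
        assert dm["s3", "s4"] == pytest.approx(1)

    def test_closed_formula(self):
        ft = FeatureTable(["s1", "s2"], ["a", "b"], np.array([[6, 2], [2, 2]]))
        dm = bray_curtis(ft, use_relative=False)
        assert dm["s1", "s2"] == pytest.approx(4 / 12)

    def test_bounded_and_symmetric(self, rng):
        ft = FeatureTable([f"s{i}" for i in range(6)], [f"a{j}" for j in range(10)],
                          rng.integers(0, 20, (6, 10)) + 1)
        d = np.asarray(bray_curtis(ft).data)
        assert ((d >= 0) & (d <= 1)).all()
        assert np.allclose(d, d.T)


class TestPermanova:
    @staticmethod
    def _hand_case():
        """6 samples, 2 groups of 3, with a hand-computable SS partition."""
        coords = np.array([[0.0], [0.1], [0.2], [1.0], [1.1], [1.2]])
        d = squareform(pdist(coords))
        return DistanceMatrix(d, ids=[f"s{i}" for i in range(6)]), {
            f"s{i}": ("g1" if i < 3 else "g2") for i in range(6)
        }

    def test_pseudo_f_matches_hand_ss_partition(self):
        dm, grouping = self._hand_case()
        d2 = np.asarray(dm.data) ** 2
        n, a = 6, 2
        iu = np.triu_indices(6, 1)
        ss_total = d2[iu].sum() / n
        ss_within = (d2[:3, :3][np.triu_indices(3, 1)].sum()
                     + d2[3:, 3:][np.triu_indices(3, 1)].sum()) / 3
        f_expected = ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))
        res = permanova(dm, grouping, n_permutations=99, seed=0)
        assert res.pseudo_f == pytest.approx(f_expected, rel=1e-12)
        assert res.r2 == pytest.approx((ss_total - ss_within) / ss_total, rel=1e-12)

    def test_matches_skbio_statistic(self, rng):
        ft = FeatureTable([f"s{i}" for i in range(8)], [f"a{j}" for j in range(12)],
                          rng.integers(0, 30, (8, 12)) + 1)
        dm = bray_curtis(ft)
        grouping = {s: ("x" if i % 2 else "y") for i, s in enumerate(dm.ids)}
        mine = permanova(dm, grouping, n_permutations=99, seed=1)
        ref = skbio_permanova(dm, [grouping[s] for s in dm.ids], permutations=99)
        assert mine.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_perfect_separation(self):
        coords = np.array([[0.0]] * 5 + [[100.0]] * 5) + np.arange(10)[:, None] * 1e-4
        dm = DistanceMatrix(squareform(pdist(coords)), ids=[f"s{i}" for i in range(10)])
        res = permanova(dm, {f"s{i}": ("a" if i < 5 else "b") for i in range(10)},
                        n_permutations=999, seed=2)
        assert res.r2 > 0.999
        assert res.p_value < 0.02  # at the permutation floor

    def test_singleton_group_rejected(self):
        dm = DistanceMatrix(squareform(pdist(np.arange(4)[:, None])),
                            ids=list("abcd"))
        with pytest.raises(ValidationError):
            permanova(dm, {"a": "g1", "b": "g2", "c": "g2", "d": "g2"}, 99, 0)


class TestProcrustes:
    def test_rigid_rotation_gives_zero_m2(self, rng):
        a = rng.normal(size=(10, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        b = 3.0 * a @ rot + np.array([5.0, -2.0])
        res = procrustes_test(a, b, n_permutations=99, seed=0)
        assert res.m2 == pytest.approx(0, abs=1e-12)
        assert res.p_value == pytest.approx(1 / 100)

    def test_independent_noise_not_significant_on_average(self, rng):
        ps = [procrustes_test(rng.normal(size=(12, 2)), rng.normal(size=(12, 2)),
                              n_permutations=99, seed=i).p_value for i in range(20)]
        assert np.mean(ps) > 0.2

    def test_mirror_needs_reflection(self, rng):
        a = rng.normal(size=(10, 2))
        b = a * np.array([-1.0, 1.0])
        with_ref = procrustes_test(a, b, 99, seed=0, allow_reflection=True)
        without = procrustes_test(a, b, 99, seed=0, allow_reflection=False)
        assert with_ref.m2 == pytest.approx(0, abs=1e-12)
        assert without.m2 > 0.01

    def test_m2_invariant_to_rigid_transform_of_either_input(self, rng):
        a, b = rng.normal(size=(8, 2)), rng.normal(size=(8, 2))
        base = procrustes_test(a, b, 99, seed=0).m2
        rot = np.array([[0.0, -1.0], [1.0, 0.0]])
        assert procrustes_test(a @ rot + 7, b, 99, seed=0).m2 == pytest.approx(base)
        assert procrustes_test(a, 0.5 * b @ rot, 99, seed=0).m2 == pytest.approx(base)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValidationError):
            procrustes_test(rng.normal(size=(5, 2)), rng.normal(size=(6, 2)), 99, 0)


class TestSharedAsvs:
    def test_identical_incidence_shares_everything(self):
        ft = FeatureTable(["s1", "s2"], ["a", "b"], np.array([[1, 2], [3, 4]]))
        part = shared_asv_partition(ft, {"s1": "sp1", "s2": "sp2"})
        assert part.shared_fraction == pytest.approx(1)

    def test_disjoint_incidence_shares_nothing(self):
        ft = FeatureTable(["s1", "s2"], ["a", "b"], np.array([[1, 0], [0, 4]]))
        part = shared_asv_partition(ft, {"s1": "sp1", "s2": "sp2"})
        assert part.shared_fraction == 0
        assert part.unique_counts == {"sp1": 1, "sp2": 1}

    def test_cells_match_brute_force_set_algebra(self, rng):
        n_samples, n_asvs = 15, 200
        counts = (rng.random((n_samples, n_asvs)) < 0.15).astype(int)
        counts[:, 0] = 1  # keep every sample non-empty
        ids = [f"s{i}" for i in range(n_samples)]
        grouping = {s: f"sp{i % 5}" for i, s in enumerate(ids)}
        ft = FeatureTable(ids, [f"a{j}" for j in range(n_asvs)], counts)
        part = shared_asv_partition(ft, grouping)

        sets = {}
        for g in part.groups:
            rows = [i for i, s in enumerate(ids) if grouping[s] == g]
            sets[g] = {j for j in range(n_asvs) if counts[rows, j].sum() > 0}
        union = set().union(*sets.values())
        assert part.union_size == len(union)
        assert sum(part.cells.values()) == len(union)
        for key, size in part.cells.items():
            exact = set(union)
            for g in part.groups:
                exact = exact & sets[g] if g in key else exact - sets[g]
            assert size == len(exact)


class TestNmds:
    def test_square_embeds_with_low_stress(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        dm = DistanceMatrix(squareform(pdist(pts)), ids=list("abcd"))
        _, stress = nmds_embed(dm, k=2, seed=0, n_restarts=8)
        assert stress < 0.01

    def test_rank_order_preserved(self, rng):
        pts = rng.normal(size=(10, 3))
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(10)])
        coords, stress = nmds_embed(dm, k=2, seed=0)
        emb = pdist(coords)
        orig = pdist(pts)
        from scipy.stats import spearmanr
        assert spearmanr(emb, orig).statistic >= 0.95

    def test_k_too_large_rejected(self):
        dm = DistanceMatrix(squareform(pdist(np.arange(3)[:, None])), ids=list("abc"))
        with pytest.raises(ValidationError):
            nmds_embed(dm, k=3, seed=0)
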