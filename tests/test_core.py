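"""Core RDM/arrangement types, distance computation, normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multiarrange import (
    Arrangement,
    DegenerateRDMError,
    ItemSet,
    RDM,
    disparity,
    distances_from_arrangement,
    mds_embed,
    normalize_rdm,
    num_pairs,
    rdm_from_points,
)

UNIT_TETRAHEDRON = np.array(
    [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]
) / np.sqrt(8)


class TestItemSet:
    def test_basic(self):
        s = ItemSet(["a", "b", "c"])
        assert s.n == 3 and s.index("b") == 1 and "c" in s

    @pytest.mark.parametrize(
        "items", [["a"], ["a", "a"], ["a", ""], []]
    )
    def test_invalid(self, items):
        with pytest.raises(ValueError):
            ItemSet(items)


class TestNumPairs:
    @pytest.mark.parametrize(
        "n,expected",
        [(2, 1), (10, 45), (50, 1225), (96, 4560), (100, 4950), (1, 0)],
    )
    def test_values(self, n, expected):
        assert num_pairs(n) == expected

    def test_errors(self):
        with pytest.raises(TypeError):
            num_pairs(2.5)
        with pytest.raises(TypeError):
            num_pairs(True)
        with pytest.raises(ValueError):
            num_pairs(-1)

    def test_matches_full_rdm_upper_triangle(self, rng):
        rdm = rdm_from_points(list("abcdefg"), rng.normal(size=(7, 3)))
        assert num_pairs(7) == int(rdm.upper_defined().sum())


class TestRdmFromPoints:
    def test_unit_tetrahedron_all_ones(self):
        rdm = rdm_from_points(list("ABCD"), UNIT_TETRAHEDRON)
        assert np.allclose(rdm.upper_values(), 1.0, atol=1e-12)

    def test_3_4_5_triangle(self):
        rdm = rdm_from_points(["p", "q"], [[0, 0], [3, 4]])
        assert rdm.get("p", "q") == pytest.approx(5.0)

    def test_matches_brute_force_double_loop(self, rng):
        pts = rng.normal(size=(10, 3))
        rdm = rdm_from_points([f"i{k}" for k in range(10)], pts)
        for i in range(10):
            for j in range(10):
                expected = np.sqrt(np.sum((pts[i] - pts[j]) ** 2))
                assert rdm.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_duplicate_identifiers_rejected(self):
        with pytest.raises(ValueError):
            rdm_from_points(["a", "a"], [[0, 0], [1, 0]])

    def test_coincident_points_allowed(self):
        rdm = rdm_from_points(["a", "b"], [[1, 2], [1, 2]])
        assert rdm.get("a", "b") == 0.0

    def test_triangle_inequality_all_triples(self, rng):
        rdm = rdm_from_points([f"i{k}" for k in range(6)], rng.normal(size=(6, 4)))
        v = rdm.values
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert v[i, j] <= v[i, k] + v[k, j] + 1e-12


class TestRDMInvariants:
    def test_asymmetric_values_rejected(self):
        v = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError):
            RDM(ItemSet(["a", "b"]), v)

    def test_negative_values_rejected(self):
        v = np.array([[0, -1.0], [-1.0, 0]])
        with pytest.raises(ValueError):
            RDM(ItemSet(["a", "b"]), v)

    def test_diagonal_always_defined_and_zero(self):
        rdm = RDM(["a", "b"], np.array([[0, 2.0], [2.0, 0]]),
                  np.array([[False, True], [True, False]]))
        assert rdm.defined[0, 0] and rdm.values[0, 0] == 0

    def test_restrict_preserves_values(self, rng):
        rdm = rdm_from_points(list("abcd"), rng.normal(size=(4, 3)))
        sub = rdm.restrict(["d", "b"])
        assert sub.get("d", "b") == pytest.approx(rdm.get("b", "d"))


class TestDistancesFromArrangement:
    def test_two_item_distance(self):
        arr = Arrangement(1, ["a", "b"], [[0.0, 0.0], [0.4, 0.0]])
        partial = distances_from_arrangement(arr, ["a", "b", "c"])
        assert partial.get("a", "b") == pytest.approx(0.4)
        assert int(partial.upper_defined().sum()) == 1

    def test_full_set_matches_rdm_from_points(self, rng):
        pts = rng.uniform(-0.4, 0.4, size=(5, 2))
        items = [f"i{k}" for k in range(5)]
        arr = Arrangement(1, items, pts)
        assert np.allclose(
            distances_from_arrangement(arr, items).values,
            rdm_from_points(items, pts).values,
        )

    def test_subset_trial_defined_count(self, rng):
        items = [f"i{k}" for k in range(5)]
        arr = Arrangement(2, items[:3], rng.uniform(-0.3, 0.3, size=(3, 2)))
        partial = distances_from_arrangement(arr, items)
        defined = int(partial.upper_defined().sum())
        assert defined == num_pairs(3)
        assert num_pairs(5) - defined == 7

    def test_unknown_item_rejected(self):
        arr = Arrangement(1, ["a", "z"], [[0, 0], [0.1, 0]])
        with pytest.raises(KeyError):
            distances_from_arrangement(arr, ["a", "b"])

    @pytest.mark.parametrize("angle", [0.3, 2.0])
    def test_rigid_motion_invariance(self, rng, angle):
        pts = rng.uniform(-0.3, 0.3, size=(4, 2))
        items = list("abcd")
        rot = np.array([[np.cos(angle), -np.sin(angle)],
                        [np.sin(angle), np.cos(angle)]])
        moved = pts @ rot.T * np.array([1, -1]) + np.array([0.01, -0.02])
        d0 = distances_from_arrangement(Arrangement(1, items, pts), items)
        d1 = distances_from_arrangement(Arrangement(1, items, moved), items)
        assert np.allclose(d0.values, d1.values, atol=1e-12)


class TestArrangement:
    def test_out_of_arena_counted_not_rejected(self):
        arr = Arrangement(1, ["a", "b"], [[0.6, 0.0], [0.0, 0.0]],
                          arena_diameter=1.0)
        assert arr.out_of_arena() == 1

    def test_duplicate_subset_items_rejected(self):
        with pytest.raises(ValueError):
            Arrangement(1, ["a", "a"], [[0, 0], [0.1, 0]])

    def test_trial_index_positive(self):
        with pytest.raises(ValueError):
            Arrangement(0, ["a", "b"], [[0, 0], [0.1, 0]])


class TestNormalize:
    def test_all_ones_unchanged(self, toy_truth):
        out = normalize_rdm(toy_truth)
        assert np.allclose(out.values, toy_truth.values, atol=1e-15)

    def test_all_twos_becomes_ones(self, toy_truth):
        out = normalize_rdm(toy_truth.with_values(toy_truth.values * 2))
        assert np.allclose(out.upper_values(), 1.0, atol=1e-15)

    def test_partial_rms_is_one(self, rng):
        n = 6
        defined = np.zeros((n, n), dtype=bool)
        values = np.zeros((n, n))
        for i, j in [(0, 1), (1, 3), (2, 5), (0, 4)]:
            defined[i, j] = defined[j, i] = True
            values[i, j] = values[j, i] = rng.uniform(0.1, 2.0)
        rdm = RDM([f"i{k}" for k in range(n)], values, defined)
        out = normalize_rdm(rdm)
        vals = out.upper_values()[out.upper_defined()]
        assert np.sqrt(np.mean(vals**2)) == pytest.approx(1.0, abs=1e-12)

    @settings(derandomize=True, max_examples=30)
    @given(c=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariant_and_idempotent(self, c):
        rng = np.random.default_rng(7)
        rdm = rdm_from_points(list("abcde"), rng.normal(size=(5, 3)))
        base = normalize_rdm(rdm)
        scaled = normalize_rdm(rdm.with_values(rdm.values * c))
        assert np.allclose(base.values, scaled.values, atol=1e-10)
        again = normalize_rdm(base)
        assert np.allclose(base.values, again.values, atol=1e-12)

    def test_all_zero_degenerate(self):
        rdm = RDM(["a", "b"], np.zeros((2, 2)))
        with pytest.raises(DegenerateRDMError):
            normalize_rdm(rdm)


class TestDisparity:
    def test_identity_zero(self, rng):
        rdm = rdm_from_points(list("abcd"), rng.normal(size=(4, 3)))
        assert disparity(rdm, rdm) == pytest.approx(0.0, abs=1e-15)

    def test_scale_invariance(self, rng):
        rdm = rdm_from_points(list("abcd"), rng.normal(size=(4, 3)))
        assert disparity(rdm, rdm.with_values(2 * rdm.values)) < 1e-12

    def test_squeezed_2d_arrangement_has_positive_disparity(self, toy_truth):
        # a 3D structure forced into 2D is distorted, so the distance
        # matrix of its best 2D embedding differs from the truth
        coords = mds_embed(toy_truth, dims=2)
        flat = rdm_from_points(list(toy_truth.items), coords)
        assert disparity(flat, toy_truth) > 0.05

    def test_empty_common_set_rejected(self):
        items = ["a", "b", "c"]
        d1 = np.zeros((3, 3), dtype=bool)
        d1[0, 1] = d1[1, 0] = True
        d2 = np.zeros((3, 3), dtype=bool)
        d2[1, 2] = d2[2, 1] = True
        a = RDM(items, np.ones((3, 3)) - np.eye(3), d1)
        b = RDM(items, np.ones((3, 3)) - np.eye(3), d2)
        with pytest.raises(ValueError):
            disparity(a, b)

    def test_item_set_mismatch_rejected(self, rng):
        a = rdm_from_points(list("abc"), rng.normal(size=(3, 2)))
        b = rdm_from_points(list("abd"), rng.normal(size=(3, 2)))
        with pytest.raises(ValueError):
            disparity(a, b)
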