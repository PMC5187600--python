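"""Energy mathematics: local statistics, total energy, membership closed
form, incremental updates and the direct energy-change formula."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import oracles
from lofac import (
    DegeneratePatchError,
    apply_energy_change,
    compute_local_statistics,
    dice_coefficient,
    energy_change,
    incremental_prototype_update,
    make_disc_mask,
    membership_candidate,
    membership_candidate_at,
    total_localized_energy,
)


def random_instance(rng, shape=(16, 16), crisp=False):
    I = rng.random(shape)
    if crisp:
        u = (rng.random(shape) > 0.5).astype(float)
    else:
        u = rng.random(shape)
    return I, u


class TestLocalStatistics:
    def test_all_foreground_degenerate(self, rng):
        I = rng.random((10, 10))
        u = np.ones_like(I)
        mask = make_disc_mask(2)
        st_ = compute_local_statistics(I, u, mask, m=2.0)
        assert np.allclose(st_.c1, st_.patch_mean, atol=1e-12)
        assert np.allclose(st_.s2, 0.0, atol=1e-12)
        # empty background class falls back to the patch mean
        assert np.allclose(st_.c2, st_.patch_mean, atol=1e-12)

    def test_uniform_half_membership(self, rng):
        I = rng.random((12, 12))
        u = np.full_like(I, 0.5)
        mask = make_disc_mask(3)
        st_ = compute_local_statistics(I, u, mask, m=2.0)
        assert np.allclose(st_.s1, 0.25 * st_.patch_count, atol=1e-12)
        assert np.allclose(st_.s2, 0.25 * st_.patch_count, atol=1e-12)
        assert np.allclose(st_.c1, st_.patch_mean, atol=1e-12)
        assert np.allclose(st_.c2, st_.patch_mean, atol=1e-12)

    @pytest.mark.parametrize("m", [1.5, 2.0, 3.0])
    def test_matches_brute_force(self, rng, m):
        I, u = random_instance(rng)
        mask = make_disc_mask(3)
        st_ = compute_local_statistics(I, u, mask, m=m)
        s1, s2, c1, c2 = oracles.brute_patch_stats(I, u, 3, m)
        for got, want in [(st_.s1, s1), (st_.s2, s2), (st_.c1, c1), (st_.c2, c2)]:
            assert np.max(np.abs(got - want)) < 1e-12

    def test_prototypes_within_intensity_range(self, rng):
        I, u = random_instance(rng, crisp=True)
        st_ = compute_local_statistics(I, u, make_disc_mask(2), m=2.0)
        assert st_.c1.min() >= I.min() - 1e-12 and st_.c1.max() <= I.max() + 1e-12
        assert st_.c2.min() >= I.min() - 1e-12 and st_.c2.max() <= I.max() + 1e-12

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            compute_local_statistics(rng.random((4, 4)), rng.random((5, 5)),
                                     make_disc_mask(1), m=2.0)


class TestTotalEnergy:
    def test_perfect_two_region_partition_is_zero(self):
        I = np.full((12, 12), 0.2)
        I[:, 6:] = 0.8
        u = np.zeros_like(I)
        u[:, 6:] = 1.0
        mask = make_disc_mask(2)
        st_ = compute_local_statistics(I, u, mask, m=2.0)
        assert abs(total_localized_energy(I, u, st_, mask, m=2.0)) < 1e-9

    def test_constant_image_half_membership_is_zero(self):
        I = np.full((8, 8), 0.4)
        u = np.full_like(I, 0.5)
        mask = make_disc_mask(2)
        st_ = compute_local_statistics(I, u, mask, m=2.0)
        assert abs(total_localized_energy(I, u, st_, mask, m=2.0)) < 1e-10

    def test_matches_brute_force(self, rng):
        I, u = random_instance(rng, shape=(12, 12))
        mask = make_disc_mask(2)
        st_ = compute_local_statistics(I, u, mask, m=2.0)
        f = total_localized_energy(I, u, st_, mask, m=2.0)
        f_ref = oracles.brute_total_energy(I, u, 2, 2.0)
        assert abs(f - f_ref) < 1e-10 * max(1.0, abs(f_ref))

    def test_invariant_under_global_relabeling(self, rng):
        I, u = random_instance(rng, shape=(10, 10))
        mask = make_disc_mask(2)
        f = total_localized_energy(I, u, compute_local_statistics(I, u, mask, 2.0), mask, 2.0)
        v = 1.0 - u
        g = total_localized_energy(I, v, compute_local_statistics(I, v, mask, 2.0), mask, 2.0)
        assert abs(f - g) < 1e-9 * max(1.0, abs(f))


class TestMembershipCandidate:
    def test_equidistant_gives_half(self):
        assert membership_candidate(0.5, 0.3, 0.7, m=2.0) == pytest.approx(0.5, abs=1e-12)

    def test_limits(self):
        assert membership_candidate(0.1, 0.1, 0.5, m=2.0) == 1.0
        assert membership_candidate(0.5, 0.1, 0.5, m=2.0) == 0.0
        assert membership_candidate(0.3, 0.3, 0.3, m=2.0) == 0.5

    def test_hand_computed_value(self):
        # (0.2-0.1)^2 / (0.2-0.5)^2 = 1/9  ->  u = 1/(1 + 1/9) = 0.9
        assert membership_candidate(0.2, 0.1, 0.5, m=2.0) == pytest.approx(0.9, abs=1e-12)

    @given(
        st.floats(0, 1), st.floats(0, 1), st.floats(0, 1),
        st.sampled_from([1.5, 2.0, 3.0]),
    )
    def test_swap_symmetry_and_range(self, I0, c1, c2, m):
        u = membership_candidate(I0, c1, c2, m)
        v = membership_candidate(I0, c2, c1, m)
        assert 0.0 <= u <= 1.0
        assert u + v == pytest.approx(1.0, abs=1e-9)


class TestAggregatedCandidate:
    def test_reduces_to_scalar_form_for_constant_prototypes(self, rng):
        I = np.full((14, 14), 0.25)
        u = np.full_like(I, 0.5)  # constant field -> c1 = c2 = patch mean
        mask = make_disc_mask(2)
        st_ = compute_local_statistics(I, u, mask, 2.0)
        # overwrite with two distinct constant prototype maps
        st_.c1 = np.full_like(I, 0.1)
        st_.c2 = np.full_like(I, 0.5)
        got = membership_candidate_at(st_, mask, (7, 7), 0.2, 2.0)
        assert got == pytest.approx(membership_candidate(0.2, 0.1, 0.5, 2.0), abs=1e-12)

    def test_sees_background_through_neighboring_patches(self):
        # a lone background-labeled pixel deep inside a bright region: its
        # own patch's background class is just itself (a tie), but patches
        # centered closer to the true boundary break the tie
        I = np.full((24, 24), 0.2)
        I[6:18, 6:18] = 0.8
        u = (I > 0.5).astype(float)
        u[10, 10] = 0.0
        mask = make_disc_mask(4)
        st_ = compute_local_statistics(I, u, mask, 2.0)
        assert membership_candidate_at(st_, mask, (10, 10), 0.8, 2.0) > 0.5

    def test_point_outside_image_raises(self, rng):
        I = rng.random((8, 8))
        mask = make_disc_mask(1)
        st_ = compute_local_statistics(I, rng.random((8, 8)), mask, 2.0)
        with pytest.raises(ValueError):
            membership_candidate_at(st_, mask, (8, 0), 0.5, 2.0)


class TestIncrementalPrototypeUpdate:
    def test_no_change_is_identity(self):
        out = incremental_prototype_update(3.0, 2.0, 0.4, 0.6, u0=0.7, un=0.7, I0=0.5, m=2.0)
        assert out == (0.4, 0.6, 3.0, 2.0)

    def test_intensity_at_prototype_leaves_it_fixed(self):
        c1n, _, _, _ = incremental_prototype_update(
            3.0, 2.0, 0.4, 0.6, u0=0.2, un=0.9, I0=0.4, m=2.0)
        assert c1n == pytest.approx(0.4, abs=1e-15)

    def test_degenerate_denominator_raises(self):
        # s1 + (un^m - u0^m) = 1 + (0 - 1) = 0
        with pytest.raises(DegeneratePatchError):
            incremental_prototype_update(1.0, 1.0, 0.5, 0.5, u0=1.0, un=0.0, I0=0.5, m=2.0)

    @pytest.mark.parametrize("radius", [1, 2, 3])
    @pytest.mark.parametrize("m", [1.5, 2.0, 3.0])
    def test_matches_full_recomputation(self, rng, radius, m):
        I, u = random_instance(rng)
        H, W = I.shape
        py, px = rng.integers(0, H), rng.integers(0, W)
        un = float(rng.random())
        s1, s2, c1, c2 = oracles.brute_patch_stats(I, u, radius, m)
        # pick a patch center containing the changed pixel
        cy, cx = py, px
        got = incremental_prototype_update(
            s1[cy, cx], s2[cy, cx], c1[cy, cx], c2[cy, cx],
            u0=float(u[py, px]), un=un, I0=float(I[py, px]), m=m)
        u2 = u.copy()
        u2[py, px] = un
        r1, r2, rc1, rc2 = oracles.brute_patch_stats(I, u2, radius, m)
        assert got[0] == pytest.approx(rc1[cy, cx], abs=1e-12)
        assert got[1] == pytest.approx(rc2[cy, cx], abs=1e-12)
        assert got[2] == pytest.approx(r1[cy, cx], abs=1e-12)
        assert got[3] == pytest.approx(r2[cy, cx], abs=1e-12)


class TestEnergyChange:
    def test_no_change_gives_zero(self, rng):
        I, u = random_instance(rng, shape=(10, 10))
        mask = make_disc_mask(2)
        st_ = compute_local_statistics(I, u, mask, 2.0)
        ch = energy_change(st_, mask, (4, 5), I[4, 5], u[4, 5], u[4, 5], 2.0)
        assert ch.delta_f == 0.0

    def test_matches_direct_difference(self, rng):
        I, u = random_instance(rng, shape=(12, 12))
        mask = make_disc_mask(2)
        f_before = oracles.brute_total_energy(I, u, 2, 2.0)
        st_ = compute_local_statistics(I, u, mask, 2.0)
        for _ in range(10):
            py, px = int(rng.integers(0, 12)), int(rng.integers(0, 12))
            un = float(rng.random())
            ch = energy_change(st_, mask, (py, px), I[py, px], u[py, px], un, 2.0)
            u2 = u.copy()
            u2[py, px] = un
            f_after = oracles.brute_total_energy(I, u2, 2, 2.0)
            assert ch.delta_f == pytest.approx(
                f_after - f_before, abs=1e-8 * max(1.0, abs(f_before)))

    def test_perturbing_zero_energy_optimum_raises_energy(self):
        I = np.full((12, 12), 0.2)
        I[:, 6:] = 0.8
        u = (I > 0.5).astype(float)
        mask = make_disc_mask(2)
        st_ = compute_local_statistics(I, u, mask, 2.0)
        ch = energy_change(st_, mask, (5, 8), I[5, 8], u[5, 8], 0.0, 2.0)
        assert ch.delta_f > 0.0

    def test_apply_then_recompute_consistent(self, rng):
        I, u = random_instance(rng, shape=(10, 10))
        mask = make_disc_mask(2)
        st_ = compute_local_statistics(I, u, mask, 2.0)
        ch = energy_change(st_, mask, (3, 3), I[3, 3], u[3, 3], 0.9, 2.0)
        apply_energy_change(st_, ch)
        u[3, 3] = 0.9
        ref = compute_local_statistics(I, u, mask, 2.0)
        for a, b in [(st_.s1, ref.s1), (st_.s2, ref.s2), (st_.c1, ref.c1), (st_.c2, ref.c2)]:
            assert np.max(np.abs(a - b)) < 1e-12


class TestDice:
    def test_identical_masks(self):
        m = np.array([[1, 0], [1, 1]], dtype=bool)
        assert dice_coefficient(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.array([[1, 0], [0, 0]], dtype=bool)
        b = np.array([[0, 1], [0, 0]], dtype=bool)
        assert dice_coefficient(a, b) == 0.0

    def test_partial_overlap_formula(self):
        a = np.zeros((3, 3), dtype=bool)
        b = np.zeros((3, 3), dtype=bool)
        a.flat[:4] = True
        b.flat[2:4] = True
        assert dice_coefficient(a, b) == pytest.approx(2 * 2 / (4 + 2))

    def test_both_empty_convention(self):
        z = np.zeros((2, 2), dtype=bool)
        assert dice_coefficient(z, z) == 1.0

    @given(st.integers(0, 2**16 - 1), st.integers(0, 2**16 - 1))
    def test_symmetry(self, abits, bbits):
        a = np.array([(abits >> i) & 1 for i in range(16)], dtype=bool).reshape(4, 4)
        b = np.array([(bbits >> i) & 1 for i in range(16)], dtype=bool).reshape(4, 4)
        assert dice_coefficient(a, b) == dice_coefficient(b, a)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice_coefficient(np.zeros((2, 2), bool), np.zeros((3, 2), bool))
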