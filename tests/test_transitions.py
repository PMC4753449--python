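"""Transition vectors, cumulative overlaps, chance levels, Z-scores, morphs."""

from __future__ import annotations

import numpy as np
import pytest

import ringflex as rf
from ringflex.errors import DegenerateTransitionError


class TestTransitionVector:
    def test_pure_rigid_motion_is_degenerate(self, ring_c6):
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("z", 25, degrees=True).as_matrix()
        moved = ring_c6.with_positions(ring_c6.positions @ R.T + [4.0, 0, 0])
        with pytest.raises(DegenerateTransitionError):
            rf.transition_vector(ring_c6, moved)

    def test_unit_norm_and_label_bookkeeping(self, ring_c6, ring_c2_like):
        T = rf.transition_vector(ring_c6, ring_c2_like, "C6", "C2")
        assert np.linalg.norm(T.t) == pytest.approx(1.0, abs=1e-12)
        assert T.labels == ring_c6.labels
        assert T.frame == "C6"

    def test_hinge_rotation_supported_on_moved_domain(self):
        """Rotating one outer domain localises T on that domain's beads."""
        kw = dict(inner_beads=20, outer_beads=30)
        ref = rf.toy_calpha(rf.ToyRingSpec(**kw))
        one = rf.toy_calpha(rf.ToyRingSpec(**kw, angles_deg=(10, 0, 0, 0, 0, 0)))
        T = rf.transition_vector(ref, one)
        comp = T.t.reshape(-1, 3)
        moved = [
            i for i, (chain, num) in enumerate(ref.labels) if chain == "A" and num <= 30
        ]
        frac = np.sum(comp[moved] ** 2) / np.sum(comp**2)
        # the global re-superposition redistributes some displacement onto
        # the static beads; the moved domain (10% of beads) still carries
        # the large majority of the variance
        assert frac > 0.6
        worst = np.argmax(np.sum(comp**2, axis=1))
        assert worst in moved

    def test_antisymmetry_for_small_displacements(self, ring_c6):
        rng = np.random.default_rng(0)
        small = ring_c6.with_positions(
            ring_c6.positions + rng.standard_normal(ring_c6.positions.shape) * 0.05
        )
        T_fwd = rf.transition_vector(ring_c6, small)
        T_rev = rf.transition_vector(small, ring_c6)
        assert float(np.dot(T_fwd.t, T_rev.t)) == pytest.approx(-1.0, abs=1e-4)


class TestCumulativeOverlap:
    def test_mode_itself_gives_unity(self, modes_c6):
        v1 = modes_c6.eigenvectors[:, 0]
        for j in (1, 2, 5):
            assert rf.cumulative_overlap(modes_c6, v1, j) == pytest.approx(1.0)

    def test_orthogonal_vector_gives_zero(self, modes_c6):
        v_high = modes_c6.eigenvectors[:, -1]
        assert rf.cumulative_overlap(modes_c6, v_high, 5) == pytest.approx(0.0, abs=1e-12)

    def test_nondecreasing_in_j(self, modes_c6, ring_c6, ring_c3_like):
        T = rf.transition_vector(ring_c6, ring_c3_like)
        vals = [rf.cumulative_overlap(modes_c6, T, j) for j in (1, 2, 5, 10)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
        assert all(0 <= v <= 1 for v in vals)

    def test_invariant_to_sign_and_degenerate_rotation(self, modes_c6, ring_c6, ring_c2_like):
        """dot_j is unchanged by flipping modes or mixing a degenerate pair."""
        T = rf.transition_vector(ring_c6, ring_c2_like)
        base = rf.cumulative_overlap(modes_c6, T, 2)
        V = modes_c6.eigenvectors.copy()
        th = 0.7  # rotate inside the (degenerate) first pair and flip signs
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        V[:, :2] = V[:, :2] @ rot
        V[:, 1] *= -1
        mixed = rf.ModeSet(modes_c6.eigenvalues.copy(), V, modes_c6.dof)
        assert rf.cumulative_overlap(mixed, T, 2) == pytest.approx(base, abs=1e-9)

    def test_dimension_mismatch_raises(self, modes_c6):
        with pytest.raises(ValueError, match="mismatch"):
            rf.cumulative_overlap(modes_c6, np.ones(12) / np.sqrt(12), 2)

    def test_full_internal_basis_captures_everything(self):
        """After superposition T has no rigid component, so all 3N−6
        internal modes together explain ≈ 100% of it."""
        rng = np.random.default_rng(8)
        n = 10
        pos = 6.0 * rng.random(n)[:, None] ** (1 / 3) * (
            lambda d: d / np.linalg.norm(d, axis=1, keepdims=True)
        )(rng.standard_normal((n, 3)))
        ref = rf.CoordinateSet(pos, [("A", i + 1) for i in range(n)], {"A": (0, n)})
        bent = ref.with_positions(pos + 0.3 * rng.standard_normal(pos.shape))
        modes = rf.anm_modes(ref, n_modes=3 * n - 6, cutoff=13.0)
        T = rf.transition_vector(ref, bent)
        total = rf.cumulative_overlap(modes, T, modes.n_modes)
        assert total == pytest.approx(1.0, abs=1e-6)


class TestChanceAndZscore:
    def test_chance_closed_form(self):
        assert rf.chance_overlap(3618, 2) == pytest.approx(2 / 3618)
        assert rf.chance_overlap(10, 10) == 1.0
        with pytest.raises(ValueError):
            rf.chance_overlap(10, 11)

    def test_monte_carlo_mean_matches_chance(self, modes_c6):
        """Null mean of dot_j converges to j/dof (3 standard errors)."""
        rng = np.random.default_rng(123)
        n = 100_000
        dof, j = modes_c6.dof, 2
        V = modes_c6.eigenvectors[:, :j]
        vals = np.empty(n)
        for k in range(0, n, 20_000):
            g = rng.standard_normal((min(20_000, n - k), dof))
            g /= np.linalg.norm(g, axis=1, keepdims=True)
            vals[k : k + 20_000] = np.sum((g @ V) ** 2, axis=1)
        se = vals.std(ddof=1) / np.sqrt(n)
        assert abs(vals.mean() - j / dof) < 3 * se

    def test_mode_aligned_vector_has_huge_zscore(self, modes_c6):
        res = rf.overlap_zscore(
            modes_c6, modes_c6.eigenvectors[:, 0], j=2, n_random=2000, seed=1
        )
        assert res.dot_j == pytest.approx(1.0)
        assert res.zscore > 100

    def test_random_vector_zscore_is_small(self, modes_c6):
        rng = np.random.default_rng(9)
        u = rng.standard_normal(modes_c6.dof)
        u /= np.linalg.norm(u)
        res = rf.overlap_zscore(modes_c6, u, j=5, n_random=2000, seed=2)
        assert abs(res.zscore) < 5

    def test_seed_reproducibility(self, modes_c6, ring_c6, ring_c2_like):
        T = rf.transition_vector(ring_c6, ring_c2_like)
        a = rf.overlap_zscore(modes_c6, T, 2, n_random=500, seed=42)
        b = rf.overlap_zscore(modes_c6, T, 2, n_random=500, seed=42)
        assert a.zscore == b.zscore


class TestTransitionDotAndMorph:
    def test_self_dot_is_unity(self, ring_c6, ring_c2_like):
        T = rf.transition_vector(ring_c6, ring_c2_like)
        assert rf.transition_dot(T, T) == pytest.approx(1.0)

    def test_disjoint_support_gives_zero(self):
        kw = dict(inner_beads=20, outer_beads=30)
        ref = rf.toy_calpha(rf.ToyRingSpec(**kw))
        a = rf.toy_calpha(rf.ToyRingSpec(**kw, angles_deg=(10, 0, 0, 0, 0, 0)))
        b = rf.toy_calpha(rf.ToyRingSpec(**kw, angles_deg=(0, 0, 0, 10, 0, 0)))
        Ta = rf.transition_vector_in_frame(ref, a, ref, "r", "a", "r")
        Tb = rf.transition_vector_in_frame(ref, b, ref, "r", "b", "r")
        assert abs(rf.transition_dot(Ta, Tb)) < 0.05

    def test_frame_mismatch_rejected(self, ring_c6, ring_c2_like, ring_c3_like):
        T1 = rf.transition_vector(ring_c6, ring_c2_like, "C6", "C2")
        T2 = rf.transition_vector(ring_c3_like, ring_c2_like, "C3", "C2")
        with pytest.raises(ValueError, match="frames"):
            rf.transition_dot(T1, T2)

    def test_morph_endpoints_and_midpoint(self, ring_c6, ring_c2_like):
        frames = rf.linear_morph(ring_c6, ring_c2_like, 3)
        assert len(frames) == 3
        np.testing.assert_allclose(frames[0].positions, ring_c6.positions)
        np.testing.assert_allclose(
            frames[1].positions,
            0.5 * (frames[0].positions + frames[2].positions),
            atol=1e-9,
        )
        assert all(f.labels == frames[0].labels for f in frames)
        with pytest.raises(ValueError):
            rf.linear_morph(ring_c6, ring_c2_like, 1)
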