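"""TPS warping and deterministic-annealing point matching."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from morphostage.register import RigidTransform, apply_transform, register_rigid
from morphostage.surface import Surface
from morphostage.tpsrpm import (AnnealingSchedule, Correspondence, TPSWarp, fit_tps,
                                match_tps_rpm, reorder_by_correspondence, tps_warp_points)


def _permuted_copy(surface: Surface, rng, noise_frac: float = 0.0):
    """Relabelled (and optionally jittered) copy plus the truth mapping.

    Returns (copy, truth) with truth[i] = copy-vertex index corresponding
    to reference vertex i.
    """
    v = surface.vertices
    perm = rng.permutation(len(v))
    inverse = np.empty_like(perm)
    inverse[perm] = np.arange(len(perm))
    size = float(np.sqrt(np.mean(np.sum((v - v.mean(0)) ** 2, axis=1))))
    noisy = v[perm] + noise_frac * size * rng.normal(size=v.shape)
    return Surface(noisy, inverse[surface.faces], organ=surface.organ), inverse


class TestTPSWarp:
    def test_zero_weights_identity_affine_is_noop(self):
        pts = np.random.default_rng(0).normal(size=(20, 3))
        assert np.array_equal(tps_warp_points(TPSWarp.identity(), pts), pts)

    def test_affine_only_translation(self):
        warp = TPSWarp(np.hstack([np.eye(3), np.array([[1.0], [2.0], [3.0]])]),
                       np.zeros((0, 3)), np.zeros((0, 3)))
        pts = np.random.default_rng(1).normal(size=(15, 3))
        assert np.allclose(tps_warp_points(warp, pts), pts + [1.0, 2.0, 3.0])

    def test_exact_interpolation_matches_direct_linear_system(self):
        # oracle: the classic square TPS interpolation system solved directly
        rng = np.random.default_rng(2)
        src = rng.normal(size=(10, 3))
        dst = src + 0.3 * rng.normal(size=(10, 3))
        warp = fit_tps(src, dst, regularization=1e-13)
        assert np.abs(warp.transform(src) - dst).max() < 1e-6

        phi = -cdist(src, src)
        p = np.hstack([src, np.ones((10, 1))])
        system = np.block([[phi, p], [p.T, np.zeros((4, 4))]])
        sol = np.linalg.solve(system, np.vstack([dst, np.zeros((4, 3))]))
        oracle = TPSWarp(np.hstack([sol[10:13].T, sol[13][:, None]]), sol[:10], src)
        # both maps agree away from the data points too
        probes = rng.normal(size=(30, 3))
        assert np.allclose(warp.transform(probes), oracle.transform(probes), atol=1e-5)

    def test_side_conditions_hold(self):
        rng = np.random.default_rng(3)
        src = rng.normal(size=(25, 3))
        dst = src + 0.2 * rng.normal(size=(25, 3))
        warp = fit_tps(src, dst, regularization=0.01)
        assert warp.side_condition_residual() < 1e-8


class TestMatchTPSRPM:
    def test_mismatched_counts_rejected(self, organ_surface):
        shrunk = Surface(organ_surface.vertices[:-1], np.zeros((1, 3), dtype=int))
        with pytest.raises(ValueError, match="same vertex count"):
            match_tps_rpm(shrunk, organ_surface)

    def test_self_match_is_identity(self, organ_surface):
        corr, _ = match_tps_rpm(organ_surface, organ_surface)
        assert np.array_equal(corr.mapping, np.arange(organ_surface.n_vertices))
        assert corr.residual < 1e-6

    def test_permuted_noisy_self_match_recovers_95_percent(self, organ_surface):
        rng = np.random.default_rng(4)
        perm = rng.permutation(organ_surface.n_vertices)
        truth = np.empty_like(perm)
        truth[perm] = np.arange(len(perm))
        v = organ_surface.vertices
        # independent oracle: optimal assignment on the noise-free distances
        cost = cdist(v, v[perm])
        _, cols = linear_sum_assignment(cost)
        assert np.array_equal(cols, truth)
        size = float(np.sqrt(np.mean(np.sum((v - v.mean(0)) ** 2, axis=1))))
        inverse_faces = truth[organ_surface.faces]
        subject = Surface(v[perm] + 0.01 * size * rng.normal(size=v.shape),
                          inverse_faces, organ="liver")
        corr, _ = match_tps_rpm(subject, organ_surface)
        assert np.mean(corr.mapping == truth) >= 0.95

    def test_energy_never_increases_within_a_temperature(self, organ_surface):
        rng = np.random.default_rng(5)
        subject, _ = _permuted_copy(organ_surface, rng, noise_frac=0.01)
        schedule = AnnealingSchedule(track_energy=True, sinkhorn_iterations=30)
        corr, _ = match_tps_rpm(subject, organ_surface, schedule)
        energies = corr.energies
        assert len(energies) > 10
        for (outer_a, e_a), (outer_b, e_b) in zip(energies, energies[1:]):
            if outer_a == outer_b:
                assert e_b <= e_a + 1e-6 * abs(e_a)

    def test_bending_beats_rigid_alignment(self, organ_surface):
        rng = np.random.default_rng(6)
        v = organ_surface.vertices
        size = float(np.sqrt(np.mean(np.sum((v - v.mean(0)) ** 2, axis=1))))
        bent = v + 0.05 * size * np.sin(v[:, [2, 0, 1]] / 30.0)
        subject, truth = _permuted_copy(
            Surface(bent, organ_surface.faces, organ="liver"), rng)
        rigid = register_rigid(subject, organ_surface)
        corr, _ = match_tps_rpm(apply_transform(subject, rigid), organ_surface)
        # mean squared residual of the non-rigid match beats the rigid one
        assert corr.residual < rigid.residual ** 2
        assert np.mean(corr.mapping == truth) >= 0.95

    def test_equivariant_under_common_rigid_transform(self, organ_surface):
        rng = np.random.default_rng(7)
        subject, _ = _permuted_copy(organ_surface, rng, noise_frac=0.01)
        base, _ = match_tps_rpm(subject, organ_surface)
        from scipy.spatial.transform import Rotation

        common = RigidTransform(Rotation.from_rotvec([0.3, -0.2, 0.5]).as_matrix(),
                                np.array([40.0, -25.0, 10.0]))
        moved_corr, _ = match_tps_rpm(apply_transform(subject, common),
                                      apply_transform(organ_surface, common))
        assert np.mean(base.mapping == moved_corr.mapping) > 0.99

    def test_deterministic(self, organ_surface):
        rng = np.random.default_rng(8)
        subject, _ = _permuted_copy(organ_surface, rng, noise_frac=0.01)
        a, _ = match_tps_rpm(subject, organ_surface)
        b, _ = match_tps_rpm(subject, organ_surface)
        assert np.array_equal(a.mapping, b.mapping)


class TestReorder:
    def test_identity_correspondence_is_noop(self, organ_surface):
        corr = Correspondence.identity(organ_surface.n_vertices)
        out = reorder_by_correspondence(organ_surface, corr)
        assert np.array_equal(out.vertices, organ_surface.vertices)
        assert np.array_equal(out.faces, organ_surface.faces)

    def test_reorder_then_inverse_restores_input(self, organ_surface):
        rng = np.random.default_rng(9)
        n = organ_surface.n_vertices
        perm = rng.permutation(n)
        corr = Correspondence(perm, np.zeros(n, dtype=bool), 0.0)
        reordered = reorder_by_correspondence(organ_surface, corr)
        inverse = np.empty_like(perm)
        inverse[perm] = np.arange(n)
        back = reorder_by_correspondence(reordered, Correspondence(inverse,
                                                                   np.zeros(n, dtype=bool), 0.0))
        assert np.allclose(back.vertices, organ_surface.vertices)
        assert np.array_equal(back.faces, organ_surface.faces)

    def test_reorder_reduces_vertexwise_distance_to_reference(self, organ_surface):
        rng = np.random.default_rng(10)
        subject, _ = _permuted_copy(organ_surface, rng, noise_frac=0.01)
        corr, _ = match_tps_rpm(subject, organ_surface)
        before = np.linalg.norm(subject.vertices - organ_surface.vertices, axis=1)
        after = np.linalg.norm(reorder_by_correspondence(subject, corr).vertices
                               - organ_surface.vertices, axis=1)
        assert np.mean(after <= before) >= 0.90

    def test_incomplete_correspondence_rejected(self, organ_surface):
        n = organ_surface.n_vertices
        mask = np.zeros(n, dtype=bool)
        mask[0] = True
        corr = Correspondence(np.arange(n), mask, 0.0)
        with pytest.raises(ValueError, match="outlier"):
            reorder_by_correspondence(organ_surface, corr)

    def test_duplicate_mapping_rejected(self):
        with pytest.raises(ValueError, match="reuses"):
            Correspondence(np.array([0, 0, 1]), np.zeros(3, dtype=bool), 0.0)
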