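"""Shape vectors and the PCA shape model."""

import numpy as np
import pytest

from morphostage.ssm import (ModeCoefficients, ShapeVector, StatisticalShapeModel,
                             assemble_shape_vector, fit_ssm, shape_vector_to_surfaces)
from morphostage.surface import Surface


def _toy_surfaces(n_vertices=1000):
    rng = np.random.default_rng(0)
    faces = np.array([[0, 1, 2]])
    liver = Surface(rng.normal(size=(n_vertices, 3)), faces, organ="liver")
    spleen = Surface(rng.normal(size=(n_vertices, 3)), faces, organ="spleen")
    return liver, spleen


class TestShapeVectors:
    def test_single_organ_vector_length_3000(self):
        liver, _ = _toy_surfaces(1000)
        assert len(assemble_shape_vector(liver).values) == 3000

    def test_joint_vector_length_6000(self):
        liver, spleen = _toy_surfaces(1000)
        vec = assemble_shape_vector(liver, spleen)
        assert len(vec.values) == 6000
        assert vec.layout == "joint"
        # liver block first
        assert np.array_equal(vec.values[:3000], liver.vertices.ravel())

    def test_joint_requires_liver_and_spleen(self):
        liver, _ = _toy_surfaces(100)
        with pytest.raises(ValueError, match="liver and .*spleen"):
            assemble_shape_vector(liver, liver)

    def test_mismatched_vertex_counts_rejected(self):
        liver, _ = _toy_surfaces(100)
        _, spleen = _toy_surfaces(101)
        with pytest.raises(ValueError, match="mismatch"):
            assemble_shape_vector(liver, spleen)

    def test_vector_surface_roundtrip(self):
        liver, spleen = _toy_surfaces(50)
        vec = assemble_shape_vector(liver, spleen)
        l2, s2 = shape_vector_to_surfaces(vec, np.array([[0, 1, 2]]))
        back = assemble_shape_vector(l2, s2)
        assert np.array_equal(back.values, vec.values)


class TestFitSSM:
    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            StatisticalShapeModel(np.ones((1, 30)))

    def test_inconsistent_lengths_rejected(self):
        vecs = [ShapeVector(np.ones(30)), ShapeVector(np.ones(33))]
        with pytest.raises(ValueError):
            fit_ssm(vecs)

    def test_identical_vectors_give_zero_variance(self):
        x = np.tile(np.arange(30.0), (5, 1))
        res = fit_ssm(list(x))
        assert np.allclose(res.mean, x[0])
        assert np.all(res.eigenvalues < 1e-20)

    def test_two_sample_closed_form(self):
        m0 = np.linspace(0.0, 1.0, 30)
        d = np.zeros(30)
        d[4] = 3.0
        d[7] = -4.0  # |d| = 5
        res = fit_ssm([ShapeVector(m0 + d), ShapeVector(m0 - d)])
        assert np.allclose(res.mean, m0)
        assert res.n_modes == 1
        assert np.isclose(res.eigenvalues[0], 25.0)  # |d|^2 with the 1/N = 1/2 normalization
        assert np.allclose(np.abs(res.eigenshapes[0]), np.abs(d) / 5.0)

    def test_matches_bruteforce_covariance_eigendecomposition(self):
        # oracle: explicitly formed S = (1/N) sum (x-m)(x-m)^T
        rng = np.random.default_rng(11)
        x = rng.normal(size=(10, 30))
        res = fit_ssm(list(x))
        centered = x - x.mean(axis=0)
        s = centered.T @ centered / len(x)
        w = np.sort(np.linalg.eigvalsh(s))[::-1]
        assert np.allclose(res.eigenvalues, w[:res.n_modes], atol=1e-8)
        # eigenvectors agree up to sign
        _, vecs = np.linalg.eigh(s)
        vecs = vecs[:, ::-1]
        for j in range(res.n_modes):
            assert min(np.linalg.norm(res.eigenshapes[j] - vecs[:, j]),
                       np.linalg.norm(res.eigenshapes[j] + vecs[:, j])) < 1e-7

    def test_eigenshapes_orthonormal(self):
        rng = np.random.default_rng(12)
        res = fit_ssm(list(rng.normal(size=(8, 40))))
        gram = res.eigenshapes @ res.eigenshapes.T
        assert np.allclose(gram, np.eye(res.n_modes), atol=1e-8)

    def test_trace_conservation(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=(9, 25))
        res = fit_ssm(list(x))
        total = np.mean(np.sum((x - x.mean(axis=0)) ** 2, axis=1))
        assert np.isclose(res.eigenvalues.sum(), total, atol=1e-8)

    def test_repeated_fits_bit_identical(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=(7, 21))
        a = fit_ssm(list(x))
        b = fit_ssm(list(x))
        assert np.array_equal(a.eigenshapes, b.eigenshapes)
        assert np.array_equal(a.eigenvalues, b.eigenvalues)

    def test_at_most_n_minus_1_modes(self):
        rng = np.random.default_rng(15)
        res = fit_ssm(list(rng.normal(size=(6, 100))))
        assert res.n_modes <= 5


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(16)
    x = rng.normal(size=(10, 30))
    return fit_ssm(list(x)), x


class TestProjectReconstruct:
    def test_mean_projects_to_zero(self, fitted):
        res, _ = fitted
        assert np.allclose(res.project(res.mean).values, 0.0, atol=1e-10)

    def test_mode_displacement_recovers_coefficient(self, fitted):
        res, _ = fitted
        b = res.project(res.mean + 2.0 * res.eigenshapes[0]).values
        assert np.isclose(b[0], 2.0)
        assert np.allclose(b[1:], 0.0, atol=1e-10)

    def test_full_roundtrip_on_training_samples(self, fitted):
        res, x = fitted
        for xi in x:
            back = res.reconstruct(res.project(xi)).values
            assert np.linalg.norm(back - xi) / np.linalg.norm(xi) < 1e-6

    def test_zero_coefficients_give_mean(self, fitted):
        res, _ = fitted
        assert np.array_equal(res.reconstruct(np.zeros(res.n_modes)).values, res.mean)

    def test_layout_mismatch_rejected(self, fitted):
        res, _ = fitted
        with pytest.raises(ValueError, match="layout"):
            res.project(ShapeVector(np.zeros(30), "joint"))

    def test_too_many_coefficients_rejected(self, fitted):
        res, _ = fitted
        with pytest.raises(ValueError, match="more coefficients"):
            res.reconstruct(np.zeros(res.n_modes + 1))


class TestAVCR:
    def test_known_eigenvalues(self):
        res = fit_ssm([ShapeVector(np.zeros(12)), ShapeVector(np.ones(12))])
        res.eigenvalues = np.array([4.0, 3.0, 2.0, 1.0])
        assert np.isclose(res.avcr(2), 0.7)
        assert np.isclose(res.avcr(4), 1.0)

    def test_monotone_in_k(self):
        rng = np.random.default_rng(17)
        res = fit_ssm(list(rng.normal(size=(9, 20))))
        values = [res.avcr(k) for k in range(1, res.n_modes + 1)]
        assert np.all(np.diff(values) >= -1e-12)
        assert np.isclose(values[-1], 1.0)

    def test_zero_variance_rejected(self):
        res = fit_ssm([ShapeVector(np.ones(6)), ShapeVector(np.ones(6)), ShapeVector(np.ones(6))])
        res.eigenvalues = np.array([0.0])
        with pytest.raises(ValueError, match="zero"):
            res.avcr(1)

    def test_out_of_range_k_rejected(self):
        rng = np.random.default_rng(18)
        res = fit_ssm(list(rng.normal(size=(5, 12))))
        with pytest.raises(ValueError):
            res.avcr(res.n_modes + 1)


class TestSerialization:
    def test_save_load_roundtrip(self, tmp_path):
        rng = np.random.default_rng(19)
        res = fit_ssm(list(rng.normal(size=(6, 18))), reference_id="s001")
        path = tmp_path / "model.npz"
        res.save(path)
        from morphostage.ssm import ShapeModelResults

        back = ShapeModelResults.load(path)
        assert np.array_equal(back.mean, res.mean)
        assert np.array_equal(back.eigenshapes, res.eigenshapes)
        assert back.reference_id == "s001"
        assert back.layout == res.layout
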