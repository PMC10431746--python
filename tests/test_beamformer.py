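import numpy as np
import pytest

from sensomap.beamformer import (CovarianceMatrix, apply_inverse,
                                 compute_data_covariance, lcmv_weights,
                                 neural_activity_index,
                                 regularize_median_eig, source_power)
from sensomap.containers import EpochSet
from sensomap.forward import LeadField


def _epochs(data, sfreq=250.0):
    return EpochSet(data, sfreq, 0.0, "rest")


class TestCovariance:
    def test_white_noise_near_identity(self):
        rng = np.random.default_rng(0)
        ep = _epochs(rng.standard_normal((40, 8, 2000)))
        cov = compute_data_covariance(ep).matrix
        assert np.allclose(np.diag(cov), 1.0, atol=0.05)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 0.05

    def test_duplicated_channel_singular_block(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((5, 3, 500))
        x[:, 1] = x[:, 0]
        cov = compute_data_covariance(_epochs(x)).matrix
        assert np.linalg.matrix_rank(cov[:2][:, :2], tol=1e-10) == 1

    def test_single_active_channel_rank_one(self):
        rng = np.random.default_rng(2)
        x = np.zeros((4, 5, 300))
        x[:, 2] = rng.standard_normal((4, 300))
        cov = compute_data_covariance(_epochs(x)).matrix
        assert np.linalg.matrix_rank(cov, tol=1e-12) == 1

    def test_requires_two_epochs_and_window(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="2 epochs"):
            compute_data_covariance(
                _epochs(rng.standard_normal((1, 3, 100))))
        with pytest.raises(ValueError):
            compute_data_covariance(
                _epochs(rng.standard_normal((3, 3, 100))),
                window_ms=(5000.0, 6000.0))


class TestMedianEigRegularization:
    def test_known_spectrum(self):
        rng = np.random.default_rng(4)
        Q, _ = np.linalg.qr(rng.standard_normal((5, 5)))
        cov = CovarianceMatrix((Q * [1, 2, 3, 4, 5]) @ Q.T)
        out = regularize_median_eig(cov)
        w = np.sort(np.linalg.eigvalsh(out.matrix))
        assert np.allclose(w, [3, 3, 3, 4, 5])

    def test_equal_eigenvalues_identity(self):
        cov = CovarianceMatrix(2.5 * np.eye(6))
        out = regularize_median_eig(cov)
        assert np.allclose(out.matrix, cov.matrix)

    def test_eigenvectors_unchanged_and_no_decrease(self):
        rng = np.random.default_rng(5)
        A = rng.standard_normal((8, 8))
        cov = CovarianceMatrix(A @ A.T)
        w0, v0 = np.linalg.eigh(cov.matrix)
        out = regularize_median_eig(cov)
        w1 = np.linalg.eigvalsh(out.matrix)
        assert (w1 >= w0 - 1e-12).all()
        # same eigenvectors: out must diagonalize in v0
        d = v0.T @ out.matrix @ v0
        assert np.allclose(d, np.diag(np.diag(d)), atol=1e-10)

    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError, match="symmetric"):
            regularize_median_eig(
                CovarianceMatrix(np.array([[1.0, 2.0], [0.0, 1.0]])))


class TestLCMV:
    def test_identity_cov_closed_form(self):
        """With C = I the constrained weight is l / (l'l)."""
        rng = np.random.default_rng(6)
        free = rng.standard_normal((6, 1, 3))
        normal = np.array([[0.0, 0.6, 0.8]])
        lf = LeadField(free)
        lf.constrain(normal)
        l = lf.constrained[:, 0]
        cov = CovarianceMatrix(np.eye(6))
        for mode in ("weights", "leadfield"):
            w = lcmv_weights(lf, cov, normal, projection=mode).weights[0]
            assert np.isclose(w @ l, 1.0)
        w_lead = lcmv_weights(lf, cov, normal,
                              projection="leadfield").weights[0]
        assert np.allclose(w_lead, l / (l @ l))

    def test_scale_invariance(self, leadfield162, mesh162):
        rng = np.random.default_rng(7)
        A = rng.standard_normal((48, 48))
        cov = CovarianceMatrix(A @ A.T + 48 * np.eye(48))
        w1 = lcmv_weights(leadfield162, cov, mesh162.normals).weights
        cov5 = CovarianceMatrix(5.0 * cov.matrix)
        w2 = lcmv_weights(leadfield162, cov5, mesh162.normals).weights
        assert np.allclose(w1, w2, atol=1e-10)

    def test_unit_gain_both_projections(self, leadfield162, mesh162):
        rng = np.random.default_rng(8)
        A = rng.standard_normal((48, 48))
        cov = CovarianceMatrix(A @ A.T + 48 * np.eye(48))
        for mode in ("weights", "leadfield"):
            bw = lcmv_weights(leadfield162, cov, mesh162.normals,
                              projection=mode)
            gains = np.einsum("vc,cv->v", bw.weights,
                              leadfield162.constrained)
            ok = np.setdiff1d(np.arange(mesh162.n_vertices),
                              bw.bad_vertices)
            assert np.abs(gains[ok] - 1.0).max() < 1e-6

    def test_two_planted_dipoles_power_peaks(self, leadfield162, mesh162):
        """Output power (noise-normalized) peaks at both planted,
        well-separated sources."""
        rng = np.random.default_rng(9)
        cn = np.linalg.norm(leadfield162.constrained, axis=0)
        v1 = int(np.argmax(cn))
        d = mesh162.graph_distance(v1)
        cand = np.nonzero(d >= d.max() // 2)[0]
        v2 = int(cand[np.argmax(cn[cand])])
        n = 4000
        s1 = np.sin(2 * np.pi * 10 * np.arange(n) / 250.0)
        s2 = np.sin(2 * np.pi * 21 * np.arange(n) / 250.0 + 1.0)
        data = (np.outer(leadfield162.constrained[:, v1], s1)
                + np.outer(leadfield162.constrained[:, v2], s2))
        noise_sd = data.std() / 5
        data = data + rng.normal(0, noise_sd, data.shape)
        ep = EpochSet(data.reshape(48, 8, 500).transpose(1, 0, 2).copy(),
                      250.0, 0.0, "rest")
        cov = compute_data_covariance(ep)
        w = lcmv_weights(leadfield162, regularize_median_eig(cov),
                         mesh162.normals)
        nai = neural_activity_index(w, cov, noise_variance=noise_sd ** 2)
        top = np.argsort(-nai)
        d1 = mesh162.graph_distance(v1)
        d2 = mesh162.graph_distance(v2)
        # each true source has a top-5 vertex within one edge
        assert min(d1[t] for t in top[:5]) <= 1
        assert min(d2[t] for t in top[:5]) <= 1


class TestApplyInverse:
    def test_zero_in_zero_out_and_linearity(self, leadfield162, mesh162):
        cov = CovarianceMatrix(np.eye(48))
        w = lcmv_weights(leadfield162, cov, mesh162.normals)
        rng = np.random.default_rng(10)
        a = EpochSet(rng.standard_normal((3, 48, 100)), 250.0, 0.0, "rest")
        z = apply_inverse(w, a.copy_with(np.zeros_like(a.data)))
        assert not z.data.any()
        b = EpochSet(rng.standard_normal((3, 48, 100)), 250.0, 0.0, "rest")
        sab = apply_inverse(w, a.copy_with(a.data + b.data))
        assert np.allclose(sab.data,
                           apply_inverse(w, a).data
                           + apply_inverse(w, b).data)
        assert sab.kind == "source"

    def test_dimension_mismatch(self, leadfield162, mesh162):
        cov = CovarianceMatrix(np.eye(48))
        w = lcmv_weights(leadfield162, cov, mesh162.normals)
        bad = EpochSet(np.zeros((2, 30, 50)), 250.0, 0.0, "rest")
        with pytest.raises(ValueError, match="mismatch"):
            apply_inverse(w, bad)

    def test_reconstruction_correlates_with_planted_source(
            self, leadfield162, mesh162, strong_vertex):
        rng = np.random.default_rng(11)
        n = 5000
        src = np.sin(2 * np.pi * 9 * np.arange(n) / 250.0) * \
            (1 + 0.3 * rng.standard_normal(n))
        data = np.outer(leadfield162.constrained[:, strong_vertex], src)
        data += rng.normal(0, data.std() / 5, data.shape)
        ep = EpochSet(data.reshape(48, 10, 500).transpose(1, 0, 2).copy(),
                      250.0, 0.0, "rest")
        cov = compute_data_covariance(ep)
        w = lcmv_weights(leadfield162, regularize_median_eig(cov),
                         mesh162.normals)
        rec = apply_inverse(w, ep).data[:, strong_vertex, :].ravel()
        r = np.corrcoef(rec, src)[0, 1]
        assert abs(r) > 0.9


def test_source_power_matches_quadratic_form(leadfield162, mesh162):
    rng = np.random.default_rng(12)
    A = rng.standard_normal((48, 48))
    cov = CovarianceMatrix(A @ A.T + np.eye(48))
    w = lcmv_weights(leadfield162, cov, mesh162.normals)
    p = source_power(w, cov)
    manual = np.array([wv @ cov.matrix @ wv for wv in w.weights])
    assert np.allclose(p, manual)
    assert (p >= -1e-12).all()
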