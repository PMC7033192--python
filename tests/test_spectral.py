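"""Unit and property tests for the spectral core (TT-SVD, Graph DMD, exact DMD)."""

import numpy as np
import pytest

import graphdmd as g
from graphdmd.spectral import _retained_rank

from conftest import random_symmetric_tensor


class TestTTSVD:
    def test_separable_tensor_has_rank_one(self, rng):
        u, v, w = rng.normal(size=4), rng.normal(size=5), rng.normal(size=6)
        X = np.einsum("i,j,t->ijt", u, v, w)
        tt = g.tt_svd_order3(X, 1e-10)
        assert (tt.r1, tt.r2) == (1, 1)
        Xm = X.reshape(20, 6, order="F")
        assert np.linalg.norm(Xm - tt.matricized()) <= 1e-10 * np.linalg.norm(Xm)

    def test_reconstruction_and_orthonormality(self, rng):
        X = rng.normal(size=(4, 4, 6))
        tt = g.tt_svd_order3(X, 1e-12)
        Xm = X.reshape(16, 6, order="F")
        assert np.linalg.norm(Xm - tt.matricized()) <= 1e-9 * np.linalg.norm(Xm)
        assert np.max(np.abs(tt.M.T @ tt.M - np.eye(tt.r2))) < 1e-10
        assert np.max(np.abs(tt.N @ tt.N.T - np.eye(tt.r2))) < 1e-10
        assert np.all(np.diff(tt.sigma) <= 0) and np.all(tt.sigma > 0)

    def test_zero_tensor_is_degenerate(self):
        with pytest.raises(g.DegenerateInputError):
            g.tt_svd_order3(np.zeros((3, 3, 4)), 1e-8)

    def test_nonfinite_rejected(self):
        X = np.ones((3, 3, 4))
        X[0, 0, 0] = np.nan
        with pytest.raises(g.ValidationError):
            g.tt_svd_order3(X, 1e-8)

    def test_truncation_rank_monotone_in_eps(self, rng):
        X = rng.normal(size=(5, 5, 8))
        loose = g.tt_svd_order3(X, 1e-2)
        tight = g.tt_svd_order3(X, 1e-12)
        assert loose.r2 <= tight.r2

    def test_retained_rank_threshold_is_strict(self):
        s = np.array([1.0, 1e-3, 1e-9])
        assert _retained_rank(s, 1e-3) == 1  # sigma_k/sigma_1 must exceed eps
        assert _retained_rank(s, 1e-4) == 2


class TestGraphDMD:
    def test_constant_sequence_is_fixed_point(self, constant_snapshots):
        res = g.graph_dmd(constant_snapshots, eps=1e-5)
        assert res.n_modes == 1
        assert abs(res.eigenvalues[0] - 1.0) < 1e-8
        # mode * amplitude proportional to (here: equal to) the snapshot
        recon = (res.modes[:, :, 0] * res.amplitudes[0]).real
        A0 = constant_snapshots.values[:, :, 0]
        assert np.allclose(recon, A0, atol=1e-8)
        full = g.reconstruct(res, range(constant_snapshots.n_frames))
        assert g.vaf(constant_snapshots.values, full) == pytest.approx(1.0, abs=1e-8)

    def test_generator_frequency_recovery(self):
        spec = g.LinearGDSSpec(
            m=8,
            components=(g.GDSComponent(0.5), g.GDSComponent(1.2)),
            static_amplitude=1.0,
            dt=0.04,
            T=60,
            seed=11,
        )
        tensor, truth = g.generate_linear_gds(spec)
        res = g.graph_dmd(tensor, eps=1e-9)
        recovered = np.unique(np.round(res.frequencies_hz, 6))
        assert np.allclose(sorted(recovered), [0.0, 0.5, 1.2], atol=1e-3)
        assert np.allclose(np.abs(res.eigenvalues), 1.0, atol=1e-6)

    def test_generator_mode_amplitude_product_recovery(self):
        spec = g.LinearGDSSpec(
            m=6,
            components=(g.GDSComponent(0.8, amplitude=2.0, phase=0.3),),
            static_amplitude=None,
            dt=0.04,
            T=50,
            seed=5,
        )
        tensor, truth = g.generate_linear_gds(spec)
        res = g.graph_dmd(tensor, eps=1e-10)
        for gt in truth:
            j = int(np.argmin(np.abs(res.eigenvalues - gt.eigenvalue)))
            assert abs(res.eigenvalues[j] - gt.eigenvalue) < 1e-6
            rec = res.modes[:, :, j] * res.amplitudes[j]
            ref = gt.mode * gt.amplitude
            assert np.linalg.norm(rec - ref) <= 1e-4 * np.linalg.norm(ref)

    @pytest.mark.parametrize("m,T,seed", [(3, 8, 0), (4, 12, 1), (6, 20, 2)])
    def test_matches_exact_dmd_oracle(self, m, T, seed):
        """Both methods compress Y X^+ onto the column space of the
        matricised data, so their nonzero spectra coincide."""
        rng = np.random.default_rng(seed)
        snap = random_symmetric_tensor(rng, m, T)
        gr = g.graph_dmd(snap, eps=1e-12)
        ex = g.exact_dmd(snap.values.reshape(m * m, T, order="F"), 1e-12)
        nz = ex.eigenvalues[np.abs(ex.eigenvalues) > 1e-10]
        assert gr.n_modes == nz.size
        assert np.allclose(np.sort_complex(gr.eigenvalues), np.sort_complex(nz), atol=1e-6)

    def test_conjugate_closure_and_real_reconstruction(self, rng):
        snap = random_symmetric_tensor(rng, 5, 15)
        res = g.graph_dmd(snap, eps=1e-12)
        eigs = np.sort_complex(res.eigenvalues)
        assert np.allclose(np.sort_complex(np.conj(eigs)), eigs, atol=1e-6)
        recon = g.reconstruct(res, range(snap.n_frames))
        # Re() is taken inside reconstruct; check symmetry of the output instead
        assert np.max(np.abs(recon - recon.transpose(1, 0, 2))) < 1e-6

    def test_too_few_frames_rejected(self, rng):
        X = rng.normal(size=(3, 3, 2))
        with pytest.raises(g.ValidationError):
            g.SnapshotTensor(0.5 * (X + X.transpose(1, 0, 2)), dt=0.04)

    def test_zero_tensor_degenerate(self):
        snap_values = np.zeros((3, 3, 5))
        with pytest.raises(g.DegenerateInputError):
            g.graph_dmd(g.SnapshotTensor(snap_values, dt=0.1))


class TestExactDMD:
    def test_scalar_geometric_sequence(self):
        y = 2.0 ** np.arange(6)
        res = g.exact_dmd(y[None, :], 1e-12)
        assert res.eigenvalues.shape == (1,)
        assert res.eigenvalues[0] == pytest.approx(2.0)
        # mode x amplitude reproduces the initial value regardless of scaling
        assert (res.modes[0, 0] * res.amplitudes[0]).real == pytest.approx(1.0)

    def test_planar_rotation_spectrum(self):
        theta = 0.3
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        x = np.array([1.0, 0.0])
        cols = [x]
        for _ in range(10):
            cols.append(R @ cols[-1])
        res = g.exact_dmd(np.column_stack(cols), 1e-12)
        expected = np.sort_complex(np.array([np.exp(1j * theta), np.exp(-1j * theta)]))
        assert np.allclose(np.sort_complex(res.eigenvalues), expected, atol=1e-8)

    def test_zero_shifted_block_gives_zero_eigenvalue(self):
        D = np.zeros((3, 4))
        D[:, 0] = [1.0, 2.0, 3.0]
        res = g.exact_dmd(D, 1e-12)
        assert res.eigenvalues.shape == (1,)
        assert res.eigenvalues[0] == pytest.approx(0.0)
        assert np.all(res.modes == 0)  # zero-eigenvalue mode skipped

    def test_single_column_rejected(self):
        with pytest.raises(g.ValidationError):
            g.exact_dmd(np.ones((3, 1)), 1e-12)

    def test_integer_rank_truncation(self, rng):
        D = rng.normal(size=(6, 8))
        res = g.exact_dmd(D, 3)
        assert res.rank == 3 and res.eigenvalues.size == 3


class TestFrequencyMapping:
    @pytest.mark.parametrize(
        "lam,dt,freq,growth",
        [
            (1.0 + 0j, 0.04, 0.0, 0.0),
            (np.exp(2j * np.pi * 0.5 * 0.04), 0.04, 0.5, 0.0),
            (0.9 + 0j, 0.04, 0.0, np.log(0.9) / 0.04),
        ],
    )
    def test_known_eigenvalues(self, lam, dt, freq, growth):
        got_f, got_g = g.eigenvalue_to_frequency(lam, dt)
        assert got_f == pytest.approx(freq, abs=1e-12)
        assert got_g == pytest.approx(growth, abs=1e-12)

    def test_conjugates_share_frequency(self):
        lam = 0.95 * np.exp(0.7j)
        f1, _ = g.eigenvalue_to_frequency(lam, 0.04)
        f2, _ = g.eigenvalue_to_frequency(np.conj(lam), 0.04)
        assert f1 == pytest.approx(f2)

    def test_zero_eigenvalue_rejected(self):
        with pytest.raises(g.ValidationError):
            g.eigenvalue_to_frequency(0.0, 0.04)


class TestAmplitudesAndReconstruction:
    def test_self_projection(self, rng):
        A0 = rng.normal(size=(4, 4))
        b = g.compute_amplitudes(A0[:, :, None].astype(complex), A0)
        assert b[0] == pytest.approx(1.0)

    def test_orthonormal_modes_give_inner_products(self, rng):
        Q, _ = np.linalg.qr(rng.normal(size=(16, 3)))
        modes = Q.reshape(4, 4, 3, order="F").astype(complex)
        A0 = rng.normal(size=(4, 4))
        b = g.compute_amplitudes(modes, A0)
        expected = Q.T @ A0.reshape(16, order="F")
        assert np.allclose(b, expected, atol=1e-10)

    def test_zero_initial_value(self, rng):
        modes = rng.normal(size=(3, 3, 2)) + 1j * rng.normal(size=(3, 3, 2))
        assert np.allclose(g.compute_amplitudes(modes, np.zeros((3, 3))), 0.0)

    def test_empty_subset_reconstructs_zero(self, constant_snapshots):
        res = g.graph_dmd(constant_snapshots)
        out = g.reconstruct(res, [0, 1, 2], mode_subset=[])
        assert np.all(out == 0.0) and out.shape == (5, 5, 3)

    def test_noiseless_generator_reconstruction(self):
        spec = g.LinearGDSSpec(m=5, T=40, seed=2)
        tensor, _ = g.generate_linear_gds(spec)
        res = g.graph_dmd(tensor, eps=1e-10)
        recon = g.reconstruct(res, range(tensor.n_frames))
        err = np.linalg.norm(tensor.values - recon) / np.linalg.norm(tensor.values)
        assert err <= 1e-6

    def test_vaf_monotone_for_orthogonal_modes(self, rng):
        """Adding an orthogonal mode never decreases total VAF."""
        Q, _ = np.linalg.qr(rng.normal(size=(16, 3)))
        modes = Q.reshape(4, 4, 3, order="F").astype(complex)
        A = rng.normal(size=(4, 4, 1))
        res = g.GraphDMDResult(
            eigenvalues=np.ones(3, dtype=complex),
            modes=modes,
            amplitudes=g.compute_amplitudes(modes, A[:, :, 0]),
            frequencies_hz=np.zeros(3),
            growth_per_s=np.zeros(3),
            dt=0.04,
            r1=3,
            r2=3,
            eps=1e-12,
        )
        t = [0]  # amplitudes are fitted to frame 0: projection is orthogonal there
        vafs = [
            g.vaf(A, g.reconstruct(res, t, subset))
            for subset in ([0], [0, 1], [0, 1, 2])
        ]
        assert vafs[0] <= vafs[1] + 1e-12 <= vafs[2] + 2e-12


class TestVAF:
    def test_identities(self, rng):
        A = rng.normal(size=(3, 3, 4))
        assert g.vaf(A, A) == pytest.approx(1.0)
        assert g.vaf(A, np.zeros_like(A)) == pytest.approx(0.0)
        assert g.vaf(A, 2 * A) == pytest.approx(0.0)

    def test_zero_original_rejected(self):
        with pytest.raises(g.ValidationError):
            g.vaf(np.zeros((2, 2, 3)), np.zeros((2, 2, 3)))
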