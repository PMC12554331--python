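"""Reconstruction solvers: exact recovery, gradients, prox operators, probes."""

import numpy as np
import pytest

from latentmr.dictionary import build_subspace, match_latent
from latentmr.operators import forward_timeseries
from latentmr.phantom import (
    PhantomSpec,
    Region,
    make_coil_maps,
    make_phantom,
    simulate_acquisition,
)
from latentmr.recon import (
    ReconConfig,
    _epg_value_grads,
    llr_prox,
    recon_epg,
    recon_latent,
    recon_linear,
    wavelet_prox,
)
from latentmr.sequences import epg_cpmg


@pytest.fixture(scope="module")
def small_truth():
    spec = PhantomSpec(
        grid_shape=(32, 32),
        regions=(Region("ellipse", (0.5, 0.5), (0.42, 0.42), T2=90.0, pd=0.9),
                 Region("ellipse", (0.42, 0.45), (0.15, 0.13), T2=220.0,
                        pd=1.0 * np.exp(0.4j))),
        sequence="fse", echo_count=32)
    return make_phantom(spec, 0)


@pytest.fixture(scope="module")
def small_full_acq(small_truth):
    coils = make_coil_maps(4, (32, 32), 0)
    mask = np.ones((32, 32), dtype=bool)
    return simulate_acquisition(small_truth, coils, mask, 0.0, 0)


class TestReconLinear:
    def test_noiseless_full_sampling_exact_recovery(self, small_truth,
                                                    small_full_acq,
                                                    fse_dict_short):
        # phantom series lie exactly in the span of a basis containing its
        # two tissue time courses
        g = fse_dict_short.grid
        atoms = fse_dict_short.atoms[:, [np.searchsorted(g, 90.0),
                                         np.searchsorted(g, 220.0)]]
        from latentmr.dictionary import LinearSubspace
        sub = LinearSubspace(np.linalg.qr(atoms)[0])
        res = recon_linear(small_full_acq, sub,
                           ReconConfig(problem="linear", iterations=80))
        err = np.linalg.norm(res.series - small_truth.series) / \
            np.linalg.norm(small_truth.series)
        assert err < 1e-6

    def test_objective_monotone_after_transient(self, small_full_acq,
                                                fse_dict_short_raw):
        sub = build_subspace(fse_dict_short_raw, 3)
        res = recon_linear(small_full_acq, sub,
                           ReconConfig(problem="linear", iterations=60))
        obj = res.objective
        assert np.all(np.diff(obj[5:]) <= 1e-8 * obj[0])

    def test_rank_mismatch_rejected(self, small_full_acq):
        from latentmr.dictionary import LinearSubspace
        bad = LinearSubspace(np.linalg.qr(
            np.random.default_rng(0).normal(size=(16, 2)))[0])
        with pytest.raises(ValueError):
            recon_linear(small_full_acq, bad)


class TestReconLatent:
    def test_single_voxel_noiseless_recovery(self, fse_ae_short, fse_dict_short):
        nx = ny = 8
        beta0 = np.zeros((nx, ny, 1))
        m0 = np.zeros((nx, ny), dtype=complex)
        atom = fse_dict_short.atoms[:, 150]
        beta0[4, 4] = fse_ae_short.encode(atom)
        m0[4, 4] = 1.3 * np.exp(0.7j)
        coils = make_coil_maps(2, (nx, ny), 3)
        mask = np.ones((ny, 32), dtype=bool)
        x = m0[:, :, None] * fse_ae_short.decode(
            beta0.reshape(-1, 1)).reshape(nx, ny, 32)
        from latentmr.operators import AcquisitionData
        acq = AcquisitionData(y=forward_timeseries(x, coils, mask), mask=mask,
                              coil_maps=coils)
        res = recon_latent(acq, fse_ae_short,
                           ReconConfig(problem="latent", iterations=400,
                                       step_size=3e-2),
                           dictionary=fse_dict_short)
        err = np.linalg.norm(res.series[4, 4] - x[4, 4]) / np.linalg.norm(x[4, 4])
        assert err < 5e-3

    def test_converges_from_randomized_global_phase(self, fse_ae_short,
                                                    fse_dict_short, rng):
        # gauge property: a global phase on the data is absorbed by M0
        nx = ny = 8
        atom = fse_dict_short.atoms[:, 100]
        x = np.zeros((nx, ny, 32), dtype=complex)
        x[2, 5] = 0.8 * atom
        coils = make_coil_maps(2, (nx, ny), 1)
        mask = np.ones((ny, 32), dtype=bool)
        theta = rng.uniform(0, 2 * np.pi)
        from latentmr.operators import AcquisitionData
        acq = AcquisitionData(y=np.exp(1j * theta) *
                              forward_timeseries(x, coils, mask),
                              mask=mask, coil_maps=coils)
        res = recon_latent(acq, fse_ae_short,
                           ReconConfig(problem="latent", iterations=400,
                                       step_size=3e-2),
                           dictionary=fse_dict_short)
        rec = res.series[2, 5]
        ref = np.exp(1j * theta) * x[2, 5]
        assert np.linalg.norm(rec - ref) / np.linalg.norm(ref) < 5e-3
        dphi = np.angle(res.solution["m0"][2, 5] * np.exp(-1j * theta))
        assert abs(dphi) < 0.05

    def test_objective_trace_finite_and_decreasing_overall(self, fixture_acq,
                                                           fse_ae_short,
                                                           fse_dict_short):
        res = recon_latent(fixture_acq, fse_ae_short,
                           ReconConfig(problem="latent", iterations=60,
                                       step_size=3e-2),
                           dictionary=fse_dict_short)
        assert np.all(np.isfinite(res.objective))
        assert res.objective[-1] < res.objective[0]
        assert res.meta["dof_per_voxel"] == 3


class TestReconEPG:
    def test_stationary_at_truth_of_noiseless_data(self, small_truth,
                                                   small_full_acq):
        t2 = np.where(small_truth.T2_map > 0, small_truth.T2_map, 100.0)
        # M0 scaled for the normalized-shape convention of the EPG model
        shapes = epg_cpmg(32, 5.56, 160.0, 1000.0, t2.ravel())
        norms = np.linalg.norm(shapes, axis=0).reshape(t2.shape)
        m0 = small_truth.M0_map * norms
        res = recon_epg(small_full_acq, t2, m0,
                        ReconConfig(problem="epg", iterations=30))
        moved = np.linalg.norm(res.series - small_truth.series) / \
            np.linalg.norm(small_truth.series)
        assert moved < 1e-3
        np.testing.assert_allclose(
            res.solution["T2"][small_truth.support],
            t2[small_truth.support], rtol=2e-3)

    def test_t2_gradient_matches_finite_differences(self, small_truth,
                                                    small_full_acq, rng):
        nx = ny = 32
        t2 = rng.uniform(60, 300, size=(nx, ny))
        m0 = rng.normal(size=(nx, ny)) + 1j * rng.normal(size=(nx, ny))
        obj, g_t2, g_m0 = _epg_value_grads(t2, m0, small_full_acq, 32, 5.56,
                                           160.0, 1000.0)
        h = 1e-2
        # probe voxels inside the object: at background voxels the residual
        # is parallel to the normalized shape and dV/dT2 vanishes exactly
        sup = np.argwhere(small_truth.support)
        picks = sup[rng.choice(len(sup), size=5, replace=False)]
        for (i, j) in picks:
            dt = np.zeros_like(t2)
            dt[i, j] = h
            op = _epg_value_grads(t2 + dt, m0, small_full_acq, 32, 5.56,
                                  160.0, 1000.0)[0]
            om = _epg_value_grads(t2 - dt, m0, small_full_acq, 32, 5.56,
                                  160.0, 1000.0)[0]
            fd = (op - om) / (2 * h)
            # abs floor covers the eps*V/h cancellation noise of the oracle
            assert g_t2[i, j] == pytest.approx(fd, rel=1e-4, abs=1e-8 * obj * 1e-3)

    def test_out_of_bounds_init_clipped_with_warning(self, small_full_acq):
        t2 = np.full((32, 32), 6000.0)
        m0 = np.ones((32, 32), dtype=complex)
        with pytest.warns(UserWarning, match="clip"):
            recon_epg(small_full_acq, t2, m0,
                      ReconConfig(problem="epg", iterations=1))


class TestGradientProbe:
    def test_zero_at_truth_of_noiseless_data(self, small_truth, small_full_acq,
                                             fse_dict_short, fse_ae_short):
        support = small_truth.support
        t2 = np.where(support, small_truth.T2_map, 100.0)
        shapes = epg_cpmg(32, 5.56, 160.0, 1000.0, t2.ravel())
        norms = np.linalg.norm(shapes, axis=0).reshape(t2.shape)
        m0 = small_truth.M0_map * norms
        _, g_t2, g_m0 = _epg_value_grads(t2, m0, small_full_acq, 32, 5.56,
                                         160.0, 1000.0)
        scale = np.abs(m0).max()
        assert np.linalg.norm(g_t2) < 1e-6 * scale
        assert np.linalg.norm(g_m0) < 1e-6 * scale

    def test_wrong_t2_map_increases_gradient_norm(self, small_truth,
                                                  small_full_acq):
        support = small_truth.support
        t2 = np.where(support, small_truth.T2_map, 100.0)
        shapes = epg_cpmg(32, 5.56, 160.0, 1000.0, t2.ravel())
        norms = np.linalg.norm(shapes, axis=0).reshape(t2.shape)
        m0 = small_truth.M0_map * norms
        good = np.linalg.norm(_epg_value_grads(t2, m0, small_full_acq, 32,
                                               5.56, 160.0, 1000.0)[1])
        bad = np.linalg.norm(_epg_value_grads(t2 + 40.0, m0, small_full_acq,
                                              32, 5.56, 160.0, 1000.0)[1])
        assert bad > good * 10


class TestProx:
    def test_lambda_zero_is_identity(self, rng):
        x = rng.normal(size=(16, 16, 3)) + 1j * rng.normal(size=(16, 16, 3))
        np.testing.assert_array_equal(wavelet_prox(x, 0.0), x)
        np.testing.assert_array_equal(llr_prox(x, 0.0), x)

    def test_negative_lambda_rejected(self, rng):
        x = rng.normal(size=(16, 16, 2))
        with pytest.raises(ValueError):
            wavelet_prox(x, -1.0)
        with pytest.raises(ValueError):
            llr_prox(x, -1.0)

    def test_wavelet_prox_preserves_constant_image(self):
        x = np.full((32, 32), 3.0)
        out = wavelet_prox(x, 0.5)
        np.testing.assert_allclose(out, x, atol=1e-10)

    def test_llr_prox_matches_per_block_svd_oracle(self, rng):
        x = rng.normal(size=(16, 16, 5)) + 1j * rng.normal(size=(16, 16, 5))
        lam = 1.5
        out = llr_prox(x, lam, block=8)
        for i in range(0, 16, 8):
            for j in range(0, 16, 8):
                s_in = np.linalg.svd(x[i:i + 8, j:j + 8].reshape(64, 5),
                                     compute_uv=False)
                s_out = np.linalg.svd(out[i:i + 8, j:j + 8].reshape(64, 5),
                                      compute_uv=False)
                np.testing.assert_allclose(s_out, np.maximum(s_in - lam, 0.0),
                                           atol=1e-10)

    def test_llr_requires_divisible_blocks(self, rng):
        with pytest.raises(ValueError):
            llr_prox(rng.normal(size=(10, 10, 2)), 1.0, block=8)


class TestMatchedInitBridge:
    def test_latent_then_epg_changes_little(self, fixture_acq, fixture_truth,
                                            fse_ae_short, fse_dict_short):
        # reduced-iteration version of the bridge experiment: the EPG-model
        # refinement initialized from the matched latent solution stays close
        res_lat = recon_latent(fixture_acq, fse_ae_short,
                               ReconConfig(problem="latent", iterations=600,
                                           step_size=3e-2),
                               dictionary=fse_dict_short)
        t2 = match_latent(res_lat.solution["beta"], fse_dict_short,
                          fse_ae_short)
        res_epg = recon_epg(fixture_acq, t2, res_lat.solution["m0"],
                            ReconConfig(problem="epg", iterations=60))
        bridge = np.linalg.norm(res_epg.series - res_lat.series) / \
            np.linalg.norm(res_lat.series) * 100
        assert bridge < 2.5  # full-length runs in the acceptance test hit 1.3
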