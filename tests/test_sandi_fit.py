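"""Inversion tests: shell means, SNR, training, RF inversion, DKI."""

import numpy as np
import pytest
from scipy import stats as sps

from hippomicro.dki import fibonacci_sphere, fit_dki
from hippomicro.dwi import DwiVolume
from hippomicro.inversion import (
    add_rician_noise,
    build_training_set,
    estimate_snr,
    fit_sandi,
    spherical_mean_shells,
    train_inverter,
)
from hippomicro.sandi import AcquisitionProtocol, sphmean_stick
from hippomicro.synthetic import build_gradient_table


def _dwi_from_signals(shell_signals, protocol, shape=(2, 2, 2), s0=1.0):
    bvals, bvecs = build_gradient_table(protocol)
    data = np.zeros(shape + (len(bvals),))
    shell_of = {b: j for j, b in enumerate(protocol.shells)}
    for v, b in enumerate(bvals):
        data[..., v] = s0 if b == 0 else s0 * shell_signals[shell_of[b]]
    return DwiVolume(data=data, bvals=bvals, bvecs=bvecs)


class TestSphericalMeanShells:
    def test_constant_shell_over_b0(self, small_protocol):
        sig = np.linspace(0.9, 0.2, len(small_protocol.shells))
        dwi = _dwi_from_signals(sig, small_protocol, s0=4.0)
        shells, means = spherical_mean_shells(dwi)
        np.testing.assert_allclose(means[0, 0, 0], sig, atol=1e-12)

    def test_scale_invariance(self, small_protocol):
        sig = np.linspace(0.9, 0.2, len(small_protocol.shells))
        a = spherical_mean_shells(_dwi_from_signals(sig, small_protocol, s0=1.0))[1]
        b = spherical_mean_shells(_dwi_from_signals(sig, small_protocol, s0=250.0))[1]
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_stick_direction_sampling_error(self):
        """64 quasi-uniform directions approximate the analytic spherical
        mean of a stick to < 0.5%."""
        proto = AcquisitionProtocol(
            shells=(3.0,), directions_per_shell=(64,), delta_small=8.0,
            delta_big=19.0, b0_count=1,
        )
        bvals, bvecs = build_gradient_table(proto)
        d_in = 2.0
        fiber = np.array([0.3, -0.5, 0.81])
        fiber /= np.linalg.norm(fiber)
        data = np.ones((1, 1, 1, len(bvals)))
        for v, b in enumerate(bvals):
            if b > 0:
                data[..., v] = np.exp(-b * d_in * (bvecs[v] @ fiber) ** 2)
        dwi = DwiVolume(data=data, bvals=bvals, bvecs=bvecs)
        _, means = spherical_mean_shells(dwi)
        assert abs(means[0, 0, 0, 0] / sphmean_stick(3.0, d_in) - 1) < 0.005

    def test_missing_b0_raises(self, small_protocol):
        bvals, bvecs = build_gradient_table(small_protocol)
        keep = bvals > 0
        dwi = DwiVolume(
            data=np.ones((2, 2, 2, keep.sum())), bvals=bvals[keep], bvecs=bvecs[keep]
        )
        with pytest.raises(ValueError, match="b = 0"):
            spherical_mean_shells(dwi)

    def test_nonpositive_b0_masked(self, small_protocol):
        sig = np.linspace(0.9, 0.2, len(small_protocol.shells))
        dwi = _dwi_from_signals(sig, small_protocol)
        dwi.data[0, 0, 0, :] = 0.0
        _, means = spherical_mean_shells(dwi)
        assert np.all(np.isnan(means[0, 0, 0]))
        assert not np.any(np.isnan(means[1, 1, 1]))


class TestEstimateSnr:
    def test_definition(self):
        b0 = np.full((4, 4, 4, 3), 100.0)
        sigma = np.full((4, 4, 4), 2.0)
        snr = estimate_snr(b0, sigma)
        assert np.allclose(snr.map, 50.0)
        assert snr.median == pytest.approx(50.0)

    def test_variance_bookkeeping_under_upsampling(self):
        """Upsampling a block-constant σ² map leaves in-block SNR unchanged."""
        b0_lr = np.full((2, 2, 2), 80.0)
        sigma = np.array([[[1.0, 2.0], [3.0, 4.0]], [[5.0, 6.0], [7.0, 8.0]]])
        from hippomicro.supres import nearest_upsample

        b0_hr = nearest_upsample(b0_lr, 2)[..., None]
        snr = estimate_snr(b0_hr, sigma, upsample_factor=2)
        assert snr.map[0, 0, 0] == pytest.approx(80.0)
        assert snr.map[3, 3, 3] == pytest.approx(10.0)

    def test_zero_sigma_raises_with_count(self):
        b0 = np.ones((2, 2, 2, 1))
        sigma = np.ones((2, 2, 2))
        sigma[0, 0, 0] = 0.0
        with pytest.raises(ValueError, match="1 in-mask voxels"):
            estimate_snr(b0, sigma)

    def test_rician_simulation_recovers_nominal(self, rng):
        sigma0, s0 = 2.0, 100.0
        e1 = rng.normal(0, sigma0, (8, 8, 8, 10))
        e2 = rng.normal(0, sigma0, (8, 8, 8, 10))
        b0 = np.sqrt((s0 + e1) ** 2 + e2**2)
        snr = estimate_snr(b0, np.full((8, 8, 8), sigma0))
        assert abs(snr.median / (s0 / sigma0) - 1) < 0.10


class TestTrainingSet:
    def test_fraction_simplex_and_ranges(self, protocol):
        ts = build_training_set(2000, protocol, seed=5)
        fs, fn = ts.targets[:, 0], ts.targets[:, 1]
        assert np.all(fs + fn <= 1.0)
        assert np.all((ts.targets[:, 2] >= 1) & (ts.targets[:, 2] <= 12))
        assert np.all((ts.targets[:, 3:] >= 0.25) & (ts.targets[:, 3:] <= 3))

    def test_same_seed_bit_identical(self, protocol):
        a = build_training_set(500, protocol, snr=40, seed=9)
        b = build_training_set(500, protocol, snr=40, seed=9)
        assert np.array_equal(a.signals, b.signals)
        assert np.array_equal(a.targets, b.targets)

    def test_r_soma_marginal_uniform(self, protocol):
        ts = build_training_set(20_000, protocol, seed=6)
        stat = sps.kstest(ts.targets[:, 2], sps.uniform(1, 11).cdf)
        assert stat.pvalue > 0.01


@pytest.fixture(scope="module")
def trained(protocol):
    ts = build_training_set(10_000, protocol, seed=11)
    return ts, train_inverter(ts, n_trees=50)


class TestInverter:
    def test_deterministic_refit(self, protocol):
        ts = build_training_set(800, protocol, seed=3)
        m1 = train_inverter(ts, n_trees=10)
        m2 = train_inverter(ts, n_trees=10)
        probe = build_training_set(50, protocol, seed=4).signals
        for name in ("f_soma", "r_soma"):
            np.testing.assert_array_equal(
                m1.regressors[name].predict(probe), m2.regressors[name].predict(probe)
            )

    def test_in_sample_fit_quality(self, trained):
        ts, model = trained
        for j, name in enumerate(("f_soma", "f_neurite")):
            pred = model.regressors[name].predict(ts.signals)
            resid = pred - ts.targets[:, j]
            r2 = 1 - resid @ resid / np.sum(
                (ts.targets[:, j] - ts.targets[:, j].mean()) ** 2
            )
            assert r2 > 0.90

    def test_constant_target_raises(self, protocol):
        ts = build_training_set(100, protocol, seed=1)
        ts.targets[:, 0] = 0.5
        with pytest.raises(ValueError, match="constant"):
            train_inverter(ts, n_trees=5)

    def test_predictions_clipped_to_ranges(self, trained, rng):
        _, model = trained
        wild = rng.random((200, 8)) * 2.0  # signals far outside training manifold
        pred = model.predict(wild)
        assert np.all((pred["f_soma"] >= 0) & (pred["f_soma"] <= 1))
        assert np.all((pred["r_soma"] >= 1) & (pred["r_soma"] <= 12))
        assert np.all((pred["d_e"] >= 0.25) & (pred["d_e"] <= 3))

    def test_fit_sandi_constraints_and_masking(self, trained, protocol):
        ts, model = trained
        test = build_training_set(100, protocol, seed=77)
        shell_map = test.signals.reshape(4, 25, 1, 8)
        mask = np.ones((4, 25, 1), dtype=bool)
        mask[0, 0, 0] = False
        maps = fit_sandi(shell_map, model, mask=mask)
        assert np.isnan(maps["f_soma"][0, 0, 0])
        valid = ~np.isnan(maps["f_soma"])
        total = maps["f_soma"][valid] + maps["f_neurite"][valid] + maps["f_extra"][valid]
        np.testing.assert_allclose(total, 1.0, atol=1e-12)

    def test_shell_count_mismatch_raises(self, trained):
        _, model = trained
        with pytest.raises(ValueError, match="expected"):
            model.predict(np.ones((5, 3)))

    def test_fextra_monotonicity(self, trained, protocol):
        """Increasing true f_extra increases fitted f_extra on average."""
        _, model = trained
        fe_true = np.linspace(0.05, 0.85, 9)
        fitted = []
        for fe in fe_true:
            fs = (1 - fe) * 0.55
            fn = (1 - fe) * 0.45
            from hippomicro.sandi import sandi_signal_batch

            sig = sandi_signal_batch(
                np.full(20, fs), np.full(20, fn), np.full(20, 6.0),
                np.full(20, 2.0), np.linspace(0.8, 1.5, 20), protocol,
            )
            pred = model.predict(sig)
            fitted.append((1 - pred["f_soma"] - pred["f_neurite"]).mean())
        rho = sps.spearmanr(fe_true, fitted).statistic
        assert rho > 0.9


class TestDki:
    @staticmethod
    def _design(nd=30, shells=(0.8, 1.5, 2.4, 3.45)):
        bvals = np.concatenate([[0.0], np.repeat(shells, nd)])
        dirs = fibonacci_sphere(nd)
        bvecs = np.vstack([[0, 0, 0], np.tile(dirs, (len(shells), 1))])
        return bvals, bvecs

    def test_isotropic_monoexponential(self):
        bvals, bvecs = self._design()
        sig = np.exp(-bvals * 1.0)[None, None, None, :]
        m = fit_dki(sig, bvals, bvecs)
        assert abs(m.md.ravel()[0] - 1.0) < 1e-6
        assert abs(m.fa.ravel()[0]) < 1e-6
        assert abs(m.mk.ravel()[0]) < 1e-6

    def test_prolate_tensor_fa(self):
        bvals, bvecs = self._design()
        d = np.diag([2.0, 0.5, 0.5])
        sig = np.exp(-bvals * np.einsum("ij,jk,ik->i", bvecs, d, bvecs))
        m = fit_dki(sig[None, None, None, :], bvals, bvecs)
        md = 1.0
        fa_true = np.sqrt(1.5 * ((2 - md) ** 2 + 2 * (0.5 - md) ** 2)) / np.sqrt(
            4 + 2 * 0.25
        )
        assert abs(m.ad.ravel()[0] - 2.0) < 1e-6
        assert abs(m.rd.ravel()[0] - 0.5) < 1e-6
        assert abs(m.fa.ravel()[0] - fa_true) < 1e-6

    def test_gaussian_mixture_kurtosis_vs_1d_oracle(self):
        """Equal-fraction two-ball mixture: the 3D fit must agree with an
        independent 1-D WLS fit of ln S in b (same truncation bias), and the
        small-b analytic kurtosis 3·Var(D)/E[D]² bounds it from above."""
        bvals, bvecs = self._design()
        sig = 0.5 * np.exp(-bvals * 0.5) + 0.5 * np.exp(-bvals * 1.5)
        m = fit_dki(sig[None, None, None, :], bvals, bvecs)
        w = sig**2
        a = np.column_stack([np.ones_like(bvals), -bvals, bvals**2 / 6])
        coef = np.linalg.solve((a.T * w) @ a, (a.T * w) @ np.log(sig))
        k_oracle = coef[2] / coef[1] ** 2
        assert m.mk.ravel()[0] == pytest.approx(k_oracle, abs=1e-9)
        assert 0 < m.mk.ravel()[0] < 3 * 0.25 / 1.0  # truncation bias shrinks K

    def test_residuals_zero_for_model_space_signal(self):
        from hippomicro.dki import dki_design_matrix

        bvals, bvecs = self._design()
        rng = np.random.default_rng(8)
        d = np.diag([1.2, 0.9, 0.6])
        # pure tensor signal lies exactly in the kurtosis model space
        sig = np.exp(-bvals * np.einsum("ij,jk,ik->i", bvecs, d, bvecs))
        design = dki_design_matrix(bvals, bvecs)
        w = sig**2
        beta = np.linalg.solve((design.T * w) @ design, (design.T * w) @ np.log(sig))
        assert np.max(np.abs(design @ beta - np.log(sig))) < 1e-10

    def test_constraint_projection_activates(self, rng):
        """Noisy decaying signal whose naive fit has negative directional
        kurtosis: the constrained fit must satisfy every constraint."""
        bvals, bvecs = self._design()
        sig = np.exp(-bvals * 0.9)
        sig = sig * (1 + rng.normal(0, 0.06, sig.shape))
        sig = np.abs(sig) + 1e-6
        m = fit_dki(sig[None, None, None, :], bvals, bvecs, constrain=True)
        assert m.mk.ravel()[0] >= -1e-8
        m_un = fit_dki(sig[None, None, None, :], bvals, bvecs, constrain=False)
        # the unconstrained fit exists; summaries may differ
        assert np.isfinite(m_un.mk.ravel()[0])

    def test_input_validation(self):
        bvals, bvecs = self._design(nd=30, shells=(0.8,))
        with pytest.raises(ValueError, match="two non-zero shells"):
            fit_dki(np.ones((1, 1, 1, len(bvals))), bvals, bvecs)
        bvals, bvecs = self._design(nd=3)
        with pytest.raises(ValueError, match="15"):
            fit_dki(np.ones((1, 1, 1, len(bvals))), bvals, bvecs)


class TestClosedLoop:
    def test_noiseless_closed_loop_small(self, protocol):
        """Forward signals round-trip through the trained inverter: the
        held-out soma-fraction error is far below the prior spread (0.289
        for uniform [0,1] fractions) and predictions track the truth.  The
        residual error reflects the intrinsic sphere/stick+ball degeneracy
        of the spherical-mean model, not regressor capacity."""
        ts = build_training_set(8000, protocol, seed=21)
        model = train_inverter(ts, n_trees=40)
        test = build_training_set(800, protocol, seed=22)
        pred = model.predict(test.signals)
        fs = test.targets[:, 0]
        rmse = np.sqrt(np.mean((pred["f_soma"] - fs) ** 2))
        assert rmse < 0.2
        assert np.corrcoef(pred["f_soma"], fs)[0, 1] > 0.7

    def test_rician_training_noise_changes_signals(self, protocol, rng):
        ts = build_training_set(300, protocol, seed=2)
        noisy = add_rician_noise(ts.signals, 30.0, rng)
        assert noisy.shape == ts.signals.shape
        assert np.all(noisy >= 0)
        assert not np.allclose(noisy, ts.signals)
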