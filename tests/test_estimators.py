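"""WHAM estimators against closed forms and an independent Bennett oracle."""

import numpy as np
import pytest

from pumpsel import (
    CosineTerm,
    CrossEnergyMatrix,
    FreeEnergyResult,
    TorsionPMF,
    TorsionProfileModel,
    block_error,
    run_mc,
    umbrella_scan,
    wham_multistate,
    wham_umbrella,
)
from pumpsel.constants import KB, T_DEFAULT

BETA = 1.0 / (KB * T_DEFAULT)


from oracles import bennett_bar, gaussian_two_state_matrix


class TestMultistateWham:
    def test_identical_states_give_zero(self, rng):
        m, *_ = gaussian_two_state_matrix(3.0, 3.0, 400, rng)
        res = wham_multistate(m, T_DEFAULT)
        assert res.f[1] - res.f[0] == pytest.approx(0.0, abs=1e-9)
        assert res.f[0] == 0.0

    def test_two_harmonic_states_match_partition_functions(self, rng):
        """Δf → (k_BT/2) ln(k1/k0) from the Gaussian partition integrals."""
        k0, k1 = 2.0, 8.0
        m, *_ = gaussian_two_state_matrix(k0, k1, 20000, rng)
        res = wham_multistate(m, T_DEFAULT)
        expected = 0.5 * KB * T_DEFAULT * np.log(k1 / k0)
        assert res.f[1] == pytest.approx(expected, abs=0.02)

    def test_agrees_with_bennett_oracle(self, rng):
        k0, k1 = 2.0, 6.0
        m, x0, x1 = gaussian_two_state_matrix(k0, k1, 8000, rng)
        res = wham_multistate(m, T_DEFAULT)
        du_f = 0.5 * (k1 - k0) * x0 * x0
        du_r = 0.5 * (k0 - k1) * x1 * x1
        oracle = bennett_bar(du_f, du_r, BETA)
        assert res.f[1] == pytest.approx(oracle, abs=0.05)

    def test_deterministic_given_matrix(self, rng):
        m, *_ = gaussian_two_state_matrix(2.0, 5.0, 1000, rng)
        r1 = wham_multistate(m, T_DEFAULT)
        r2 = wham_multistate(m, T_DEFAULT)
        np.testing.assert_array_equal(r1.f, r2.f)

    def test_constant_offset_on_one_state_shifts_its_f(self, rng):
        """Adding c to state 1's column (everywhere) shifts f_1 by c."""
        m, *_ = gaussian_two_state_matrix(2.0, 5.0, 4000, rng)
        res0 = wham_multistate(m, T_DEFAULT)
        c = 3.21
        shifted = CrossEnergyMatrix(
            energies=m.energies + np.array([0.0, c])[None, :],
            origin=m.origin)
        res1 = wham_multistate(shifted, T_DEFAULT)
        assert res1.f[1] - res0.f[1] == pytest.approx(c, abs=1e-6)

    def test_state_relabeling_preserves_differences(self, rng):
        m, *_ = gaussian_two_state_matrix(2.0, 5.0, 4000, rng)
        res = wham_multistate(m, T_DEFAULT)
        swapped = CrossEnergyMatrix(energies=m.energies[:, ::-1],
                                    origin=1 - m.origin)
        res_sw = wham_multistate(swapped, T_DEFAULT)
        assert res_sw.f[1] == pytest.approx(-res.f[1], abs=1e-6)

    def test_nonfinite_entries_rejected(self):
        with pytest.raises(ValueError):
            CrossEnergyMatrix(energies=np.array([[0.0, np.inf]]),
                              origin=np.array([0]))

    def test_missing_state_frames_rejected(self, rng):
        m, *_ = gaussian_two_state_matrix(2.0, 5.0, 100, rng)
        bad = CrossEnergyMatrix(energies=m.energies,
                                origin=np.zeros(len(m.origin), int))
        with pytest.raises(ValueError, match="contribute"):
            wham_multistate(bad, T_DEFAULT)

    def test_ess_reflects_overlap(self, rng):
        good, *_ = gaussian_two_state_matrix(2.0, 2.2, 2000, rng)
        poor, *_ = gaussian_two_state_matrix(2.0, 200.0, 2000, rng)
        assert (wham_multistate(good, T_DEFAULT).ess.min()
                > wham_multistate(poor, T_DEFAULT).ess.min())


class TestUmbrellaWham:
    def test_flat_potential_gives_flat_pmf(self):
        model = TorsionProfileModel(torsion=(CosineTerm(0.0, 1, 0.0),))
        series = umbrella_scan(model, n_steps=3000, seed=8, thin=3)
        pmf = wham_umbrella(series, n_bins=72)
        assert pmf.values.min() == 0.0
        # deviations stay well under k_BT: pure sampling noise
        assert pmf.values.max() < 0.35
        assert np.sqrt(np.mean(pmf.values ** 2)) < 0.2

    def test_recovers_known_cosine_potential(self):
        """Generating potential K(1+cos χ) recovered within 0.1 kcal/mol RMS."""
        K = 1.2
        model = TorsionProfileModel(torsion=(CosineTerm(K, 1, 0.0),))
        series = umbrella_scan(model, n_steps=4000, seed=2, thin=4)
        pmf = wham_umbrella(series)
        truth = K * (1 + np.cos(np.radians(pmf.grid)))
        truth -= truth.min()
        rms = np.sqrt(np.mean((pmf.values - truth) ** 2))
        assert rms < 0.1

    def test_single_unbiased_window_equals_histogram(self):
        model = TorsionProfileModel(torsion=(CosineTerm(0.6, 2, 0.0),))
        series = run_mc(model, 60000, seed=13, thin=3)
        n_bins = 36
        # direct histogram oracle
        hist, edges = np.histogram(series.chi, bins=n_bins, range=(-180, 180))
        w_direct = -KB * T_DEFAULT * np.log(hist / hist.max())
        # WHAM with a single (numerically unbiased) window
        from pumpsel.sampling import UmbrellaWindowSpec
        soft = UmbrellaWindowSpec(center=0.0, k_bias=1e-12)
        series.meta["window"] = soft
        pmf = wham_umbrella([series], n_bins=n_bins)
        np.testing.assert_allclose(pmf.values, w_direct - w_direct.min(),
                                   atol=1e-6)

    def test_disjoint_windows_raise(self, triple_well):
        from pumpsel.sampling import UmbrellaWindowSpec
        windows = [UmbrellaWindowSpec(center=c, k_bias=400.0, index=i)
                   for i, c in enumerate((-150.0, 150.0))]
        series = umbrella_scan(triple_well, windows, n_steps=300, seed=3, thin=3)
        with pytest.raises(ValueError, match="empty bins"):
            wham_umbrella(series, n_bins=180)

    def test_pmf_interp_is_periodic(self):
        pmf = TorsionPMF(grid=np.arange(-180.0, 180.0, 2.0),
                         values=np.abs(np.arange(-180.0, 180.0, 2.0)) / 90.0)
        assert pmf.interp(-180.0) == pytest.approx(pmf.interp(180.0))


class TestBlockError:
    def test_constant_series_has_zero_error(self):
        err, est = block_error(np.full(100, 2.5), n_blocks=10)
        assert err == 0.0
        np.testing.assert_allclose(est, 2.5)

    def test_iid_gaussian_block_error_near_sigma_over_sqrt(self, rng):
        """For i.i.d. data the block-mean std ≈ σ/√(n/blocks)."""
        sigma, n, nb = 2.0, 10000, 10
        x = rng.normal(scale=sigma, size=n)
        err, _ = block_error(x, n_blocks=nb)
        expected = sigma / np.sqrt(n / nb)
        assert err == pytest.approx(expected, rel=0.6)

    def test_degenerate_partition_gives_per_frame_estimates(self):
        x = np.arange(5.0)
        err, est = block_error(x, n_blocks=5)
        np.testing.assert_array_equal(est, x)

    def test_fewer_frames_than_blocks_rejected(self):
        with pytest.raises(ValueError):
            block_error(np.arange(3.0), n_blocks=10)

    def test_custom_estimator_over_paired_arrays(self):
        a = np.arange(10.0)
        b = np.ones(10)
        err, est = block_error((a, b), n_blocks=2,
                               estimator=lambda x, y: float(np.mean(x * y)))
        np.testing.assert_allclose(est, [2.0, 7.0])


def test_free_energy_result_identity():
    r = FreeEnergyResult(scenario_id="s", dg_site=5.0, dg_bulk=18.34,
                         dg_trans_i=1.0, dg_trans_j=1.0, error=0.1)
    assert r.dg_trans == 0.0
    assert r.ddg == pytest.approx(5.0 - 18.34)
    with pytest.raises(ValueError):
        FreeEnergyResult(scenario_id="s", dg_site=0, dg_bulk=0, error=-1.0)
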