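import numpy as np
import pytest

import ggcbench as gb
from tests.conftest import parametric_ggc_pairwise


def random_stable_two_channel(rng, max_radius=0.85):
    """Rejection-sample a stable 2-channel MVAR(2) with random PD noise cov.

    The pole radius is capped so the spectrum's circular truncation error
    on a few-hundred-point grid stays far below the comparison tolerances.
    """
    while True:
        coeffs = rng.uniform(-0.6, 0.6, size=(2, 2, 2))
        a = rng.uniform(-0.5, 0.5, size=(2, 2))
        cov = a @ a.T + 0.5 * np.eye(2)
        try:
            model = gb.MVARModel(coeffs=coeffs, noise_cov=cov, sampling_rate=200.0)
        except ValueError:
            continue
        if model.companion_spectral_radius() <= max_radius:
            return model


class TestPairwise:
    def test_matches_parametric_oracle_on_analytic_spectrum(
        self, snr2_model, grid_400
    ):
        s = gb.analytic_spectral_matrix(snr2_model, grid_400)
        est = gb.pairwise_ggc_from_spectrum(s, tol=1e-11, max_iter=200)
        oracle = parametric_ggc_pairwise(snr2_model, grid_400)
        assert np.abs(est.values - oracle).max() < 1e-6

    def test_matches_independent_var_fit(self, snr2_model, grid_400):
        # statsmodels VAR fits on long realizations are a fully independent
        # estimation route: no multitaper, no spectral factorization; the
        # per-trial fits are averaged to shrink the sampling error
        from statsmodels.tsa.api import VAR

        x = gb.simulate_mvar(snr2_model, 100_000, 20, seed=21)
        coefs, covs = [], []
        for tr in range(x.n_trials):
            fit = VAR(x.data[:, :, tr]).fit(maxlags=2, trend="n")
            coefs.append(fit.coefs)
            covs.append(fit.sigma_u)
        fitted = gb.MVARModel(
            coeffs=np.mean(coefs, axis=0),
            noise_cov=np.mean(covs, axis=0),
            sampling_rate=200.0,
        )
        ours = gb.pairwise_ggc_from_spectrum(
            gb.analytic_spectral_matrix(snr2_model, grid_400)
        ).values[1, 0]
        theirs = parametric_ggc_pairwise(fitted, grid_400)[1, 0]
        assert abs(ours.max() - theirs.max()) / ours.max() < 0.02

    def test_correct_directionality_on_simulated_data(self, snr2_model):
        x = gb.simulate_mvar(snr2_model, 400, 100, seed=1)
        g = gb.pairwise_ggc(x, NW=4)
        band = (g.freqs >= 35) & (g.freqs <= 48)
        assert g.values[1, 0][band].max() > 0.3  # true direction 1 -> 2
        assert g.values[0, 1][band].max() < 0.05  # reverse near zero

    def test_nonnegative_up_to_numerics(self, chain_model):
        x = gb.simulate_mvar(chain_model, 400, 50, seed=2)
        g = gb.pairwise_ggc(x)
        assert g.values.min() > -1e-10

    def test_independent_channels_near_null(self):
        m = gb.MVARModel(coeffs=np.zeros((0, 3, 3)), noise_cov=np.eye(3),
                         sampling_rate=200.0)
        x = gb.simulate_mvar(m, 400, 100, seed=3, burn_in=0)
        g = gb.pairwise_ggc(x)
        off = ~np.eye(3, dtype=bool)
        # bias scale is 1/(n_trials * n_tapers) = 1/700
        assert np.percentile(g.values[off], 95) < 10 / 700

    def test_needs_two_channels(self):
        x = gb.TrialsArray(data=np.random.default_rng(0).standard_normal((64, 1, 2)),
                           sampling_rate=200.0)
        with pytest.raises(ValueError):
            gb.pairwise_ggc(x)


class TestConditional:
    def test_equals_pairwise_for_two_channels(self):
        rng = np.random.default_rng(99)
        grid = np.fft.rfftfreq(512, 1 / 200.0)
        for _ in range(20):
            model = random_stable_two_channel(rng)
            s = gb.analytic_spectral_matrix(model, grid)
            pair = gb.pairwise_ggc_from_spectrum(s, tol=1e-11, max_iter=200)
            cond = gb.conditional_ggc_from_spectrum(s, tol=1e-11, max_iter=200)
            assert np.abs(pair.values - cond.values).max() < 1e-6

    def test_chain_indirect_influence_suppressed(self, chain_model, grid_400):
        s = gb.analytic_spectral_matrix(chain_model, grid_400)
        cond = gb.conditional_ggc_from_spectrum(s, tol=1e-11, max_iter=200)
        pair = gb.pairwise_ggc_from_spectrum(s, tol=1e-11, max_iter=200)
        assert pair.values[2, 0].max() > 0.1  # pairwise sees the indirect path
        assert cond.values[2, 0].max() < 1e-8  # conditional removes it
        assert cond.values[1, 0].max() > 0.3 and cond.values[2, 1].max() > 0.3

    def test_chain_on_simulated_data(self, chain_model):
        x = gb.simulate_mvar(chain_model, 400, 100, seed=5)
        cond = gb.conditional_ggc(x)
        band_all = cond.values[:, :, 1:]
        assert cond.values[2, 0].mean() < 0.02
        assert cond.values[1, 0].max() > 0.3


class TestNetAndTimeReversal:
    def test_net_antisymmetry_exact(self, snr2_model):
        x = gb.simulate_mvar(snr2_model, 400, 20, seed=6)
        net = gb.net_ggc(gb.pairwise_ggc(x))
        assert np.array_equal(net.values, -net.values.transpose(1, 0, 2))
        assert net.testing == "net"

    def test_net_requires_untested_input(self, snr2_model):
        x = gb.simulate_mvar(snr2_model, 400, 10, seed=6)
        net = gb.net_ggc(gb.pairwise_ggc(x))
        with pytest.raises(ValueError):
            gb.net_ggc(net)

    def test_symmetric_bidirectional_model_nets_to_zero(self):
        coeffs = np.array(
            [[[0.5, 0.2], [0.2, 0.5]], [[-0.8, -0.1], [-0.1, -0.8]]]
        )
        model = gb.MVARModel(coeffs=coeffs, noise_cov=np.eye(2), sampling_rate=200.0)
        # the sharpest mode here has pole radius ~0.95, so the circular
        # truncation error of an n-point grid is ~0.95^(n/2): use n = 1024
        grid = np.fft.rfftfreq(1024, 1 / 200.0)
        s = gb.analytic_spectral_matrix(model, grid)
        net = gb.net_ggc(gb.pairwise_ggc_from_spectrum(s, tol=1e-11, max_iter=200))
        assert np.abs(net.values).max() < 1e-8

    def test_time_reverse_is_involution(self, snr2_model):
        x = gb.simulate_mvar(snr2_model, 100, 5, seed=7)
        assert np.array_equal(gb.time_reverse(gb.time_reverse(x)).data, x.data)

    def test_reversal_preserves_autocovariance(self, snr2_model):
        x = gb.simulate_mvar(snr2_model, 500, 3, seed=8)
        rev = gb.time_reverse(x)
        for lag in range(5):
            a = x.data[lag:, 0, 0] @ x.data[: 500 - lag, 0, 0]
            b = rev.data[lag:, 0, 0] @ rev.data[: 500 - lag, 0, 0]
            assert a == pytest.approx(b, rel=1e-12)

    def test_reversal_flips_dominant_direction(self, snr2_model, grid_400):
        s = gb.analytic_spectral_matrix(snr2_model, grid_400)
        s_rev = gb.SpectralMatrix(freqs=s.freqs, S=s.S.transpose(0, 2, 1).copy(),
                                  sampling_rate=200.0)
        g_rev = gb.pairwise_ggc_from_spectrum(s_rev)
        assert g_rev.values[0, 1].max() > 0.5  # 2 -> 1 dominates after reversal
        assert g_rev.values[1, 0].max() < g_rev.values[0, 1].max()


class TestTrGGC:
    def test_rectification_and_exclusive_direction(self, snr2_model):
        x = gb.simulate_mvar(snr2_model, 400, 50, seed=9)
        t = gb.tr_ggc(x)
        assert t.testing == "tr-difference"
        assert np.array_equal(t.values, np.maximum(t.raw_values, 0.0))
        both = (t.values[0, 1] > 0) & (t.values[1, 0] > 0)
        assert not both.any()

    def test_clean_data_keeps_true_direction_only(self, snr2_model):
        x = gb.simulate_mvar(snr2_model, 400, 100, seed=10)
        t = gb.tr_ggc(x)
        band = (t.freqs >= 38) & (t.freqs <= 42)
        assert t.values[1, 0][band].min() > 0.1
        assert np.all(t.values[0, 1][band] == 0.0)

    def test_data_and_spectrum_routes_agree(self, snr2_model):
        x = gb.simulate_mvar(snr2_model, 400, 30, seed=11)
        a = gb.tr_ggc(x)
        b = gb.tr_ggc_from_spectrum(gb.multitaper_csd(x))
        assert np.abs(a.values - b.values).max() < 1e-9

    def test_independent_channels_null(self):
        m = gb.MVARModel(coeffs=np.zeros((0, 2, 2)), noise_cov=np.eye(2),
                         sampling_rate=200.0)
        x = gb.simulate_mvar(m, 400, 100, seed=12, burn_in=0)
        t = gb.tr_ggc(x)
        assert np.abs(t.values).max() < 0.02

    def test_unknown_variant_listed(self, snr2_model):
        x = gb.simulate_mvar(snr2_model, 400, 5, seed=13)
        with pytest.raises(ValueError, match="difference"):
            gb.tr_ggc(x, variant="ratio")

    def test_conditional_flag(self, chain_model):
        x = gb.simulate_mvar(chain_model, 400, 50, seed=14)
        t = gb.tr_ggc(x, conditional=True)
        assert t.variant == "conditional"
        band = (t.freqs >= 35) & (t.freqs <= 48)
        assert t.values[1, 0][band].max() > 0.1
        assert t.values[2, 0][band].mean() < 0.02


def test_csv_export(tmp_path, snr2_model):
    import pandas as pd

    x = gb.simulate_mvar(snr2_model, 400, 10, seed=15)
    t = gb.tr_ggc(x)
    path = tmp_path / "ggc.csv"
    t.to_csv(path)
    df = pd.read_csv(path)
    assert set(df.columns) == {
        "frequency", "receiver", "sender", "value", "raw_value", "variant", "testing"
    }
    assert set(df.testing) == {"tr-difference"}
    got = df[(df.receiver == 2) & (df.sender == 1)].value.values
    assert np.allclose(got, t.values[1, 0])
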