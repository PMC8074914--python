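"""State-space model: simulation, fitting, bands, departures."""

import numpy as np
import pytest

from alloctrace import statespace as ss
from conftest import make_panel


class TestSpecValidation:
    def test_needs_multiple_chains(self):
        with pytest.raises(ValueError, match="chains"):
            ss.StateSpaceSpec(chains=1)

    def test_per_time_deviation_sds_unsupported(self):
        with pytest.raises(NotImplementedError):
            ss.StateSpaceSpec(deviation_sd_mode="per_time")

    def test_positive_noise_required(self):
        with pytest.raises(ValueError):
            ss.StateSpaceSpec(obs_noise_sd=0.0)


class TestSimulatePanel:
    def test_zero_process_is_identically_zero(self):
        feats = np.array([[1.0, -1.0], [-1.0, 1.0]])
        x = ss.simulate_panel(
            feats, np.array([0, 0]),
            {"a": np.zeros(101), "b": np.zeros(101)},
            np.random.default_rng(0), obs_noise_sd=0.0, eta_sds=(0.0, 0.0),
            delta_sd=0.0,
        )
        np.testing.assert_array_equal(x, 0.0)

    def test_first_bin_exactly_zero(self):
        x, *_ = make_panel(0, "smooth")
        np.testing.assert_array_equal(x[:, 0], 0.0)

    def test_series_must_start_at_zero(self):
        feats = np.ones((2, 2))
        bad = {"a": np.full(101, 0.1), "b": np.zeros(101)}
        with pytest.raises(ValueError, match="exactly 0"):
            ss.simulate_panel(feats, np.array([0, 0]), bad, np.random.default_rng(0))


class TestFitValidation:
    def test_wrong_bin_count_rejected(self):
        x = np.zeros((4, 50))
        with pytest.raises(ValueError, match="101"):
            ss.fit_statespace(x, np.zeros(4, int), np.zeros((4, 2)))

    def test_non_standardized_features_rejected(self):
        x, pidx, feats, _ = make_panel(1, "null")
        with pytest.raises(ss.NonStandardizedFeaturesError):
            ss.fit_statespace(x, pidx, feats * 3.0)

    def test_nonzero_first_bin_rejected(self):
        x, pidx, feats, _ = make_panel(1, "null")
        x = x.copy()
        x[:, 0] = 0.2
        with pytest.raises(ValueError, match="origin"):
            ss.fit_statespace(x, pidx, feats)


class TestRecovery:
    def test_truth_inside_pointwise_bands(self, recovery_fit):
        ct, true = recovery_fit
        for name, series in true.items():
            hdi = ct.pointwise[name]
            coverage = np.mean((series >= hdi[:, 0]) & (series <= hdi[:, 1]))
            assert coverage >= 0.9

    def test_first_bin_coefficients_exactly_zero(self, recovery_fit):
        ct, _ = recovery_fit
        for name in ct.coef_names:
            np.testing.assert_array_equal(ct.draws[name][:, 0], 0.0)

    def test_converged_with_rhat_below_threshold(self, recovery_fit):
        ct, _ = recovery_fit
        assert ct.converged
        assert all(v < 1.1 for v in ct.rhat.values())

    def test_pointwise_nested_in_simultaneous(self, recovery_fit):
        ct, _ = recovery_fit
        for name in ct.coef_names:
            pw, sm = ct.pointwise[name], ct.simultaneous[name]
            assert np.all(sm[:, 0] <= pw[:, 0] + 1e-12)
            assert np.all(sm[:, 1] >= pw[:, 1] - 1e-12)

    def test_random_walk_mu_mode_recovers_series(self):
        """The selectable random-walk intercept dynamics also recover a
        known smooth coefficient series."""
        rng = np.random.default_rng(31)
        raw = rng.normal(size=(16, 2))
        fp = (raw - raw.mean(0)) / raw.std(0)
        pidx = np.repeat(np.arange(10), 16)
        feats = np.tile(fp, (10, 1))
        u = np.linspace(0, 1, 101)
        true = {"beta_min": 0.12 * u**1.2, "beta_var": 0.04 * u**2}
        x = ss.simulate_panel(feats, pidx, true, rng, mu_dynamics="random_walk",
                              delta_sd=0.01)
        ct = ss.fit_statespace(
            x, pidx, feats,
            ss.StateSpaceSpec(seed=31, mu_dynamics="random_walk",
                              walkers=16, warmup=200, draws=200, n_state_draws=400),
        )
        for name, series in true.items():
            hdi = ct.pointwise[name]
            assert np.mean((series >= hdi[:, 0]) & (series <= hdi[:, 1])) >= 0.9
        assert set(ct.participant_means) == {"beta_min", "beta_var"}

    def test_trial_order_permutation_leaves_likelihood_invariant(self):
        x, pidx, feats, _ = make_panel(3, "smooth", n_part=4, n_prob=8)
        spec = ss.StateSpaceSpec()
        m1 = ss._MarginalModel(x, pidx, feats, spec)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(x))
        m2 = ss._MarginalModel(x[perm], pidx[perm], feats[perm], spec)
        theta = np.log([0.02, 0.03, 0.03, 0.02, 0.02])
        assert m1.log_post(theta)[0] == pytest.approx(m2.log_post(theta)[0], rel=1e-9)

    def test_feature_rescaling_absorbed_by_standardization(self):
        rng = np.random.default_rng(4)
        raw = rng.normal(size=(12, 2))
        z1 = (raw - raw.mean(0)) / raw.std(0)
        scaled = raw * np.array([37.0, 0.004])
        z2 = (scaled - scaled.mean(0)) / scaled.std(0)
        np.testing.assert_allclose(z1, z2, atol=1e-12)


class TestWithTotal:
    def test_adds_exactly_one_series_and_null_total_covers_zero(self):
        rng = np.random.default_rng(21)
        n_part, n_prob = 10, 16
        raw = rng.normal(size=(n_prob, 3))
        fp = (raw - raw.mean(0)) / raw.std(0)
        pidx = np.repeat(np.arange(n_part), n_prob)
        feats = np.tile(fp, (n_part, 1))
        u = np.linspace(0, 1, 101)
        true = {"beta_min": 0.1 * u, "beta_var": 0.03 * u, "beta_total": 0.0 * u}
        x = ss.simulate_panel(feats, pidx, true, rng, eta_sds=(0.03, 0.03, 0.03))
        spec = ss.StateSpaceSpec(seed=21, walkers=16, warmup=150, draws=150,
                                 n_state_draws=300)
        ct = ss.fit_statespace_with_total(x, pidx, feats, spec)
        assert ct.coef_names == ["beta_min", "beta_var", "beta_total"]
        assert set(ct.draws) == {"beta_min", "beta_var", "beta_total"}
        hdi = ct.pointwise["beta_total"]
        cover0 = np.mean((hdi[:, 0] <= 0.0) & (0.0 <= hdi[:, 1]))
        assert cover0 >= 0.85


class TestBands:
    def test_degenerate_draws_give_point_interval(self):
        hdi = ss.pointwise_hdi(np.full(500, 1.3))
        np.testing.assert_array_equal(hdi, [1.3, 1.3])

    def test_standard_normal_hdi_matches_known_quantiles(self):
        rng = np.random.default_rng(0)
        hdi = ss.pointwise_hdi(rng.standard_normal(100_000))
        assert hdi[0] == pytest.approx(-1.96, abs=0.05)
        assert hdi[1] == pytest.approx(1.96, abs=0.05)

    def test_symmetric_unimodal_hdi_close_to_equal_tailed(self):
        rng = np.random.default_rng(1)
        d = rng.standard_normal(50_000) * 2.0 + 1.0
        hdi = ss.pointwise_hdi(d)
        et = np.quantile(d, [0.025, 0.975])
        np.testing.assert_allclose(hdi, et, atol=0.1)

    def test_single_time_point_band_equals_pointwise(self):
        rng = np.random.default_rng(2)
        d = rng.standard_normal((2000, 1))
        np.testing.assert_allclose(ss.simultaneous_band(d), ss.pointwise_hdi(d))

    def test_band_wider_than_pointwise_for_independent_bins(self):
        rng = np.random.default_rng(3)
        d = rng.standard_normal((4000, 101))
        pw = ss.pointwise_hdi(d)
        sm = ss.simultaneous_band(d)
        assert np.all(sm[:, 0] < pw[:, 0])
        assert np.all(sm[:, 1] > pw[:, 1])

    def test_simultaneous_band_joint_coverage(self):
        """Band built from one sample of random-walk series achieves ~95%
        joint coverage on independent replicates of the same process."""
        rng = np.random.default_rng(4)
        steps = rng.normal(size=(4000, 101)) * 0.05
        draws = np.cumsum(steps, axis=1)
        band = ss.simultaneous_band(draws)
        new = np.cumsum(rng.normal(size=(500, 101)) * 0.05, axis=1)
        inside = np.all((new >= band[:, 0]) & (new <= band[:, 1]), axis=1)
        assert inside.mean() >= 0.95 - 0.03


class TestDepartures:
    def _ct(self, draws_min, draws_var):
        names = ["beta_min", "beta_var"]
        draws = {"beta_min": draws_min, "beta_var": draws_var}
        return ss.CoefficientTrajectories(
            t=np.arange(1, 102), coef_names=names, draws=draws,
            pointwise={n: ss.pointwise_hdi(draws[n]) for n in names},
            simultaneous={n: ss.simultaneous_band(draws[n]) for n in names},
            hyper_names=[], hyper_draws=np.zeros((2, 1, 1)),
            delta_draws=np.zeros((1, 1)),
            participant_means={}, rhat={}, converged=True,
            log_posts=np.zeros(1), spec=ss.StateSpaceSpec(),
        )

    def test_departure_at_first_excluding_bin(self):
        rng = np.random.default_rng(5)
        m = np.zeros(101)
        m[29:] = 1.0                      # bins 30..101 shifted away from zero
        dmin = m + 0.05 * rng.standard_normal((3000, 101))
        dvar = 0.05 * rng.standard_normal((3000, 101))
        dmin[:, 0] = dvar[:, 0] = 0.0
        rep = ss.departure_times(self._ct(dmin, dvar))
        assert rep.departure["beta_min"] == 30
        assert rep.sign_at_departure["beta_min"] == 1
        assert rep.departure["beta_var"] is None
        assert rep.min_exceeds_var[29:].all()
        assert not rep.min_exceeds_var[0]

    def test_all_covering_means_no_departure(self):
        rng = np.random.default_rng(6)
        d = 0.1 * rng.standard_normal((2000, 101))
        d[:, 0] = 0.0
        rep = ss.departure_times(self._ct(d, d.copy()))
        assert rep.departure["beta_min"] is None
        assert rep.sign_at_departure["beta_min"] is None
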