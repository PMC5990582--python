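import numpy as np
import pytest
from scipy.special import ndtri
from scipy.stats import kstest

from igtbayes import (
    MCMCConfig,
    PVLDeltaParams,
    fit_hierarchical_group,
    gelman_rubin,
    generate_group_dataset,
    to_natural,
    to_probit,
)
from igtbayes.igt_task import GroupDataset


class TestProbitTransforms:
    def test_midpoints_map_to_zero(self):
        pp = to_probit(PVLDeltaParams(A=0.5, w=2.5, a=0.5, c=2.5))
        assert np.allclose(pp.as_array(), 0.0, atol=1e-12)

    def test_quantile_value(self):
        # unit value 0.975 -> probit ~ 1.95996 (standard normal quantile)
        pp = to_probit(PVLDeltaParams(A=0.975, w=1.0, a=0.5, c=1.0))
        assert pp.A == pytest.approx(ndtri(0.975), abs=1e-10)
        assert pp.A == pytest.approx(1.95996, abs=1e-4)

    def test_roundtrip_identity_1000_vectors(self, rng):
        for _ in range(1000):
            params = PVLDeltaParams(
                rng.uniform(0.01, 0.99), rng.uniform(0.05, 4.95),
                rng.uniform(0.01, 0.99), rng.uniform(0.05, 4.95),
            )
            back = to_natural(to_probit(params))
            assert np.allclose(back.as_array(), params.as_array(), atol=1e-10)

    def test_boundary_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            pp = to_probit(PVLDeltaParams(A=0.0, w=5.0, a=0.5, c=2.5))
        assert np.all(np.isfinite(pp.as_array()))
        nat = to_natural(pp)
        assert 0.0 < nat.A < 1.0


class TestGelmanRubin:
    def test_iid_chains_converged(self, rng):
        chains = rng.standard_normal((4, 1000))
        assert gelman_rubin(chains) < 1.05

    def test_shifted_chain_flagged(self, rng):
        chains = rng.standard_normal((4, 1000))
        chains[0] += 10.0
        assert gelman_rubin(chains) > 1.1

    def test_constant_chains_undefined(self):
        assert np.isnan(gelman_rubin(np.ones((3, 100))))

    def test_lower_bound(self, rng):
        # split R-hat is bounded below by sqrt((n-1)/n), n = split length
        for _ in range(20):
            chains = rng.standard_normal((3, 50))
            assert gelman_rubin(chains) >= np.sqrt(24 / 25) - 1e-12

    def test_matches_arviz_split_rhat(self, rng):
        arviz = pytest.importorskip("arviz")
        chains = np.cumsum(rng.standard_normal((3, 400)), axis=1) * 0.05
        ours = gelman_rubin(chains)
        theirs = float(arviz.rhat(arviz.convert_to_dataset(chains)).x)
        # arviz uses rank-normalized split R-hat; agreement is approximate
        assert ours == pytest.approx(theirs, rel=0.05)

    def test_needs_two_chains(self, rng):
        with pytest.raises(ValueError):
            gelman_rubin(rng.standard_normal((1, 100)))


class TestMCMCConfig:
    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="chains"):
            MCMCConfig(n_chains=1, seed=1)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_retained=0, seed=1)


@pytest.fixture(scope="module")
def prior_only_fit():
    ds, _ = generate_group_dataset([0.0] * 4, [0.3] * 4, 8, 5, seed=2)
    cfg = MCMCConfig(n_chains=3, n_burnin=300, n_retained=3000, seed=17,
                     prior_only=True)
    return fit_hierarchical_group(ds, cfg, store_individuals=False)


class TestPriorCalibration:
    """With the likelihood switched off the posterior must equal the prior:
    mu ~ N(0, 1), sigma ~ Uniform(0, 1.5)."""

    def test_mu_moments(self, prior_only_fit):
        for p in "Awac":
            x = prior_only_fit.stacked(f"mu_{p}")
            assert abs(x.mean()) < 0.12
            assert abs(x.std() - 1.0) < 0.12

    def test_sigma_moments(self, prior_only_fit):
        for p in "Awac":
            x = prior_only_fit.stacked(f"sigma_{p}")
            assert abs(x.mean() - 0.75) < 0.08
            assert abs(x.std() - 1.5 / np.sqrt(12)) < 0.06

    def test_sigma_uniform_ks(self, prior_only_fit):
        # thinned to reduce autocorrelation before the distributional check
        x = prior_only_fit.stacked("sigma_A")[::10]
        stat = kstest(x, "uniform", args=(0, 1.5)).statistic
        assert stat < 0.08

    def test_mu_normal_ks(self, prior_only_fit):
        x = prior_only_fit.stacked("mu_c")[::10]
        stat = kstest(x, "norm").statistic
        assert stat < 0.08


class TestFitHierarchicalGroup:
    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            fit_hierarchical_group(GroupDataset([], "empty"),
                                   MCMCConfig(seed=1))

    def test_small_fit_shapes_and_summary(self):
        ds, _ = generate_group_dataset([0.0] * 4, [0.2] * 4, 5, 30, seed=4)
        cfg = MCMCConfig(n_chains=2, n_burnin=200, n_retained=300, seed=5,
                         rhat_threshold=10.0)  # smoke run, no strict R-hat
        fit = fit_hierarchical_group(ds, cfg)
        assert fit.draws.shape == (2, 300, 8 + 4 * 5)
        summ = fit.summary()
        assert set(["mean", "sd", "q2.5", "q97.5", "rhat"]) <= set(summ.columns)
        means = fit.individual_posterior_means()
        assert len(means) == 5
        for m in means:
            assert 0 <= m.A <= 1 and 0 <= m.w <= 5

    def test_recovery_small(self):
        # truth should be covered by the 95% intervals for most parameters
        mu_true = np.array([0.3, -0.4, 0.0, 0.5])
        ds, _ = generate_group_dataset(mu_true, [0.2] * 4, 12, 80, seed=8)
        cfg = MCMCConfig(n_chains=3, n_burnin=800, n_retained=1200, seed=9)
        fit = fit_hierarchical_group(ds, cfg, store_individuals=False)
        covered = 0
        for j, p in enumerate("Awac"):
            x = fit.stacked(f"mu_{p}")
            lo, hi = np.quantile(x, [0.025, 0.975])
            covered += lo <= mu_true[j] <= hi
        assert covered >= 3

    def test_posterior_sd_shrinks_with_more_trials(self):
        cfg = MCMCConfig(n_chains=2, n_burnin=600, n_retained=800, seed=21,
                         rhat_threshold=10.0)
        sds = {}
        for n_trials in (50, 200):
            ds, _ = generate_group_dataset([0.0] * 4, [0.2] * 4, 10, n_trials,
                                           seed=33)
            fit = fit_hierarchical_group(ds, cfg, store_individuals=False)
            sds[n_trials] = fit.stacked("mu_c").std()
        assert sds[200] <= sds[50]

    def test_seed_determinism(self):
        ds, _ = generate_group_dataset([0.0] * 4, [0.2] * 4, 4, 20, seed=6)
        cfg = MCMCConfig(n_chains=2, n_burnin=100, n_retained=200, seed=7,
                         rhat_threshold=10.0)
        a = fit_hierarchical_group(ds, cfg)
        b = fit_hierarchical_group(ds, cfg)
        assert np.array_equal(a.draws, b.draws)

    def test_nonconvergence_warns(self):
        ds, _ = generate_group_dataset([0.0] * 4, [0.2] * 4, 4, 20, seed=6)
        cfg = MCMCConfig(n_chains=2, n_burnin=0, n_retained=40, seed=7)
        with pytest.warns(UserWarning, match="R-hat"):
            fit = fit_hierarchical_group(ds, cfg)
        assert not fit.converged

    def test_export_roundtrip(self, tmp_path):
        ds, _ = generate_group_dataset([0.0] * 4, [0.2] * 4, 3, 10, seed=6)
        cfg = MCMCConfig(n_chains=2, n_burnin=50, n_retained=100, seed=7,
                         rhat_threshold=10.0)
        fit = fit_hierarchical_group(ds, cfg)
        fit.to_csv(tmp_path / "draws.csv")
        fit.to_json_summary(tmp_path / "summary.json")
        import json

        import pandas as pd

        tidy = pd.read_csv(tmp_path / "draws.csv")
        assert set(tidy.columns) == {"chain", "iteration", "parameter", "value"}
        assert len(tidy) == 2 * 100 * len(fit.names)
        payload = json.loads((tmp_path / "summary.json").read_text())
        assert "mu_A" in payload["parameters"]
        assert payload["metadata"]["seed"] == 7
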