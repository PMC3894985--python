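import dataclasses
import math

import numpy as np
import pytest

import rotabayes as rb
from rotabayes.hblm import (
    McmcConfig,
    PriorSpec,
    beta_full_conditional,
    gibbs_fit,
    rhat,
    variance_full_conditional,
)
from rotabayes.preprocess import ModelDesign


def plain_design(X, y, names=None):
    X = np.asarray(X, dtype=float)
    return ModelDesign(
        model_id=0,
        response=np.asarray(y, dtype=float),
        response_name="y",
        fixed_names=names or [f"b{j}" for j in range(X.shape[1])],
        fixed_matrix=X,
        field_index=None,
        year_index=None,
    )


class TestBetaFullConditional:
    def test_intercept_only_conjugate_closed_form(self):
        d = plain_design(np.ones((4, 1)), [1.0, 1.0, 1.0, 1.0])
        mean, cov = beta_full_conditional(d, None, None, 1.0, PriorSpec())
        assert mean[0] == pytest.approx(4.0 / (4.0 + 1e-4))
        assert cov[0, 0] == pytest.approx(1.0 / (4.0 + 1e-4))

    def test_zero_response_gives_zero_mean(self):
        rng = np.random.default_rng(0)
        d = plain_design(rng.normal(size=(12, 3)), np.zeros(12))
        mean, _ = beta_full_conditional(d, None, None, 2.0, PriorSpec())
        assert np.all(mean == 0.0)

    def test_flat_prior_limit_is_least_squares(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        d = plain_design(X, y)
        mean, _ = beta_full_conditional(d, None, None, 1.3, PriorSpec(beta_sd=1e8))
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(mean, ols, atol=1e-6)

    def test_nonpositive_sigma2_rejected(self):
        d = plain_design(np.ones((3, 1)), [0.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            beta_full_conditional(d, None, None, 0.0, PriorSpec())


class TestVarianceFullConditional:
    def test_two_unit_residuals(self):
        sh, sc = variance_full_conditional(np.array([1.0, -1.0]), PriorSpec())
        assert (sh, sc) == pytest.approx((1.001, 1.001))

    def test_ten_zeros(self):
        sh, sc = variance_full_conditional(np.zeros(10), PriorSpec())
        assert (sh, sc) == pytest.approx((5.001, 0.001))

    def test_quadratic_scaling(self):
        r = np.array([0.5, -2.0, 1.5])
        _, sc1 = variance_full_conditional(r, PriorSpec())
        _, sc2 = variance_full_conditional(2 * r, PriorSpec())
        assert sc2 - 0.001 == pytest.approx(4 * (sc1 - 0.001))


def small_mixed_design(seed=0, n=90, J=18, T=5, p=3):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
    fi = rng.integers(0, J, size=n)
    yi = rng.integers(0, T, size=n)
    # relabel to dense codes in case a level went unused
    fl, fi = np.unique(fi, return_inverse=True)
    yl, yi = np.unique(yi, return_inverse=True)
    u = rng.normal(0, 2.0, size=len(fl))
    v = rng.normal(0, 1.0, size=len(yl))
    beta = np.array([1.0, -2.0, 0.5][:p])
    y = X @ beta + u[fi] + v[yi] + rng.normal(0, 1.0, size=n)
    return ModelDesign(
        model_id=0,
        response=y,
        response_name="y",
        fixed_names=["intercept"] + [f"x{j}" for j in range(1, p)],
        fixed_matrix=X,
        field_index=fi,
        year_index=yi,
        field_levels=list(fl),
        year_levels=list(yl),
    )


class TestGibbsFit:
    def test_bit_identical_under_fixed_seed(self):
        d = small_mixed_design()
        cfg = McmcConfig(n_chains=2, n_iter=200, n_burn=100, master_seed=5)
        a = gibbs_fit(d, PriorSpec(), cfg)
        b = gibbs_fit(d, PriorSpec(), cfg)
        assert np.array_equal(a.beta, b.beta)
        assert np.array_equal(a.sigma2, b.sigma2)
        assert np.array_equal(a.u, b.u)

    def test_sequential_kernel_also_deterministic(self):
        d = small_mixed_design()
        cfg = McmcConfig(
            n_chains=2, n_iter=200, n_burn=100, master_seed=5,
            joint_effects=False, collapse_variances=False,
        )
        a = gibbs_fit(d, PriorSpec(), cfg)
        b = gibbs_fit(d, PriorSpec(), cfg)
        assert np.array_equal(a.beta, b.beta)

    def test_variance_draws_strictly_positive(self):
        d = small_mixed_design(seed=3)
        s = gibbs_fit(d, PriorSpec(), McmcConfig(n_chains=2, n_iter=400, n_burn=100, master_seed=1))
        assert np.all(s.sigma2 > 0)
        assert np.all(s.sigma2_field > 0)
        assert np.all(s.sigma2_year > 0)

    def test_zero_response_centres_beta_at_zero(self):
        rng = np.random.default_rng(2)
        d = plain_design(np.column_stack([np.ones(40), rng.normal(size=(40, 2))]), np.zeros(40))
        s = gibbs_fit(d, PriorSpec(), McmcConfig(n_chains=2, n_iter=2000, n_burn=500, master_seed=3),
                      fixed_sigma2=1.0)
        means = s.beta.reshape(-1, 3).mean(axis=0)
        # draws are iid from the exact posterior here; 4 MC sd margin
        mc_sd = s.beta.reshape(-1, 3).std(axis=0) / math.sqrt(3000)
        assert np.all(np.abs(means) < 4 * mc_sd + 1e-12)

    def test_blocked_and_sequential_kernels_share_a_posterior(self):
        """The blocked (joint + collapsed-variance) kernel and the plain
        conjugate cycle must agree on the posterior they sample."""
        d = small_mixed_design(seed=4, n=120, J=15, T=5)
        blocked = gibbs_fit(
            d, PriorSpec(), McmcConfig(n_chains=3, n_iter=4000, n_burn=1000, master_seed=11)
        )
        plain = gibbs_fit(
            d,
            PriorSpec(),
            McmcConfig(
                n_chains=3, n_iter=4000, n_burn=1000, master_seed=12,
                joint_effects=False, collapse_variances=False,
            ),
        )
        for name in ("intercept", "x1", "x2", "sigma2", "sigma2_field", "sigma2_year"):
            a, b = blocked.pooled(name), plain.pooled(name)
            # the few-level variance posteriors are heavy-tailed, so
            # compare quantiles, scaled by the central 80% spread
            qa = np.quantile(a, [0.1, 0.5, 0.9])
            qb = np.quantile(b, [0.1, 0.5, 0.9])
            scale = max(qa[2] - qa[0], 1e-9)
            assert np.all(np.abs(qa - qb) < 0.2 * scale), (name, qa, qb)

    def test_permutation_of_rows_leaves_fit_distributionally_stable(self):
        d = small_mixed_design(seed=6)
        rng = np.random.default_rng(0)
        perm = rng.permutation(d.n_obs)
        d2 = ModelDesign(
            model_id=0,
            response=d.response[perm],
            response_name="y",
            fixed_names=d.fixed_names,
            fixed_matrix=d.fixed_matrix[perm],
            field_index=d.field_index[perm],
            year_index=d.year_index[perm],
            field_levels=d.field_levels,
            year_levels=d.year_levels,
        )
        cfg = McmcConfig(n_chains=2, n_iter=3000, n_burn=1000, master_seed=9)
        a = gibbs_fit(d, PriorSpec(), cfg)
        b = gibbs_fit(d2, PriorSpec(), cfg)
        for name in ("intercept", "x1"):
            assert np.mean(a.pooled(name)) == pytest.approx(
                np.mean(b.pooled(name)), abs=0.12 * np.std(a.pooled(name))
            )

    def test_collinear_columns_named_in_error(self):
        X = np.ones((10, 2))  # duplicated intercept
        d = plain_design(X, np.arange(10.0), names=["intercept", "copy"])
        with pytest.raises(ValueError, match="copy"):
            beta_full_conditional(d, None, None, 1.0, PriorSpec(beta_sd=1e12))


class TestRhat:
    def test_two_chain_separation_formula(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=100)
        base = (base - base.mean()) / base.std(ddof=1)  # exact mean 0, sd 1
        chains = np.stack([base, base + 10.0])
        # W = 1, B = 100 * var([0, 10]) = 5000 -> sqrt(0.99 + 50)
        assert rhat(chains) == pytest.approx(math.sqrt(50.99), rel=1e-9)

    def test_same_distribution_chains_near_one(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(size=(2, 10_000))
        assert rhat(chains) < 1.05

    def test_exact_copies_give_sqrt_nminus1_over_n(self):
        rng = np.random.default_rng(2)
        c = rng.normal(size=500)
        assert rhat(np.stack([c, c])) == pytest.approx(math.sqrt(499 / 500))

    def test_zero_within_chain_variance_is_undefined(self):
        assert math.isnan(rhat(np.ones((2, 50))))

    def test_input_validation(self):
        with pytest.raises(ValueError):
            rhat(np.ones((1, 50)))


def test_posterior_samples_save_round_trip(tmp_path):
    d = small_mixed_design(seed=8)
    s = gibbs_fit(d, PriorSpec(), McmcConfig(n_chains=2, n_iter=120, n_burn=60, master_seed=2))
    s.save(tmp_path)
    import json

    import pandas as pd

    draws = pd.read_csv(tmp_path / "draws.csv")
    assert len(draws) == 2 * 60
    assert "intercept" in draws.columns and "sigma2_field" in draws.columns
    meta = json.loads((tmp_path / "meta.json").read_text())
    assert meta["config"]["master_seed"] == 2
    assert set(meta["rhat"]) == set(s.parameter_names())
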