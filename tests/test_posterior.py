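import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from rotabayes.hblm import PosteriorSamples
from rotabayes.posterior import (
    contrast_table,
    crop_contrasts,
    hpdi,
    percent_change,
    sign_probability,
    summarize,
)


def brute_force_hpdi(draws, mass):
    """Exhaustive minimal-width window search (the oracle)."""
    s = sorted(float(x) for x in draws)
    n = len(s)
    m = min(n, math.ceil(mass * n))
    best = None
    for i in range(n - m + 1):
        w = s[i + m - 1] - s[i]
        if best is None or w < best[0]:  # strict < keeps the leftmost tie
            best = (w, s[i], s[i + m - 1])
    return best[1], best[2]


class TestHpdi:
    def test_uniform_grid_takes_leftmost_window(self):
        assert hpdi(np.arange(1, 101), 0.95) == (1.0, 95.0)

    def test_outlier_excluded(self):
        assert hpdi([0, 1, 2, 3, 100], 0.8) == (0.0, 3.0)

    def test_constant_draws_zero_width(self):
        assert hpdi([4.2] * 10, 0.95) == (4.2, 4.2)

    def test_full_mass_is_min_max(self):
        x = [3.0, -1.0, 7.5, 0.0]
        assert hpdi(x, 1.0) == (-1.0, 7.5)

    @pytest.mark.parametrize("mass", [0.0, -0.1, 1.5])
    def test_invalid_mass_rejected(self, mass):
        with pytest.raises(ValueError):
            hpdi([1.0, 2.0, 3.0], mass)

    @given(
        st.lists(
            st.one_of(
                st.floats(-50, 50, allow_nan=False),
                st.integers(-3, 3).map(float),  # forces ties
            ),
            min_size=5,
            max_size=200,
        ),
        st.sampled_from([0.5, 0.8, 0.9, 0.95, 0.99]),
    )
    def test_matches_brute_force_oracle(self, draws, mass):
        assert hpdi(draws, mass) == brute_force_hpdi(draws, mass)

    def test_invariant_to_draw_order(self):
        rng = np.random.default_rng(0)
        x = rng.standard_exponential(500)
        assert hpdi(x) == hpdi(rng.permutation(x))

    def test_agrees_with_arviz_on_continuous_draws(self):
        arviz = pytest.importorskip("arviz")
        rng = np.random.default_rng(1)
        x = rng.normal(size=4000)
        lo, hi = hpdi(x, 0.95)
        # arviz rounds the window size differently, so agreement is to
        # the draw spacing, not exact
        ref = arviz.hdi(x, hdi_prob=0.95)
        assert lo == pytest.approx(float(ref[0]), abs=0.02)
        assert hi == pytest.approx(float(ref[1]), abs=0.02)


class TestSignProbability:
    def test_all_negative(self):
        assert sign_probability([-1.0, -0.5, -3.0]) == 1.0

    def test_symmetric_draws(self):
        assert sign_probability([-2.0, 2.0, -1.0, 1.0]) == 0.5

    def test_counting(self):
        draws = np.concatenate([-np.ones(934), np.ones(66)])
        assert sign_probability(draws) == pytest.approx(0.934)

    def test_zero_counts_as_nonnegative(self):
        assert sign_probability([0.0, -1.0]) == 0.5

    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=50))
    def test_complement_identity(self, draws):
        x = np.asarray(draws)
        assert sign_probability(x) + np.mean(x >= 0) == pytest.approx(1.0)


def fabricate_samples(named_draws, n_chains=3):
    """PosteriorSamples with given pooled draws split over chains."""
    names = list(named_draws)
    S = len(next(iter(named_draws.values()))) // n_chains
    beta = np.stack(
        [np.column_stack([named_draws[n][c * S : (c + 1) * S] for n in names]) for c in range(n_chains)]
    )
    return PosteriorSamples(
        beta=beta, beta_names=names, sigma2=np.ones((n_chains, S))
    )


class TestCropContrasts:
    def test_degenerate_constant_draws(self):
        s = fabricate_samples({"prior_tomatoes": np.full(300, 7.0)})
        from rotabayes.preprocess import ModelDesign

        d = ModelDesign(
            model_id=1, response=np.ones(1), response_name="y",
            fixed_names=["prior_tomatoes"], fixed_matrix=np.ones((1, 1)),
            field_index=None, year_index=None,
        )
        (c,) = crop_contrasts(s, d)
        assert (c.post_mean, c.hpdi_low, c.hpdi_high, c.prob_negative) == (7.0, 7.0, 7.0, 0.0)

    def test_standard_normal_draws_summary(self):
        rng = np.random.default_rng(3)
        s = fabricate_samples({"prior_garlic": rng.normal(size=30_000)})
        from rotabayes.preprocess import ModelDesign

        d = ModelDesign(
            model_id=1, response=np.ones(1), response_name="y",
            fixed_names=["prior_garlic"], fixed_matrix=np.ones((1, 1)),
            field_index=None, year_index=None,
        )
        (c,) = crop_contrasts(s, d)
        assert c.post_mean == pytest.approx(0.0, abs=0.03)
        assert c.prob_negative == pytest.approx(0.5, abs=0.02)
        assert not c.excludes_zero

    def test_reference_contrast_is_exact_zero(self):
        s = fabricate_samples({"prior_wheat": np.full(30, 1.0)})
        from rotabayes.preprocess import ModelDesign

        d = ModelDesign(
            model_id=1, response=np.ones(1), response_name="y",
            fixed_names=["prior_wheat"], fixed_matrix=np.ones((1, 1)),
            field_index=None, year_index=None,
        )
        ref = crop_contrasts(s, d, include_reference=True)[0]
        assert ref.label == "cotton vs cotton"
        assert (ref.post_mean, ref.hpdi_low, ref.hpdi_high) == (0.0, 0.0, 0.0)

    def test_dropped_crop_marked_unavailable(self, fitted_model1):
        report = fitted_model1
        unavailable = [s for s in report.summaries if not s.available]
        # the small fixture drops some rare crops; their rows are flagged
        for s in unavailable:
            assert math.isnan(s.post_mean)
        table = contrast_table(report.summaries)
        assert (~table["available"]).sum() == len(unavailable)

    def test_chain_order_invariance(self):
        rng = np.random.default_rng(5)
        draws = rng.normal(size=3000)
        s1 = fabricate_samples({"prior_corn": draws})
        s2 = PosteriorSamples(
            beta=s1.beta[::-1].copy(), beta_names=s1.beta_names, sigma2=s1.sigma2
        )
        a = summarize("c", s1.pooled("prior_corn"))
        b = summarize("c", s2.pooled("prior_corn"))
        # identical up to float summation order
        assert a.post_mean == pytest.approx(b.post_mean, rel=1e-12)
        assert (a.hpdi_low, a.hpdi_high, a.prob_negative) == (
            b.hpdi_low, b.hpdi_high, b.prob_negative,
        )


class TestPercentChange:
    def test_exact_arithmetic(self):
        draws = np.full(100, -24.0)
        pct, summ = percent_change(draws, baseline=1200.0)
        assert np.all(pct == -2.0)
        assert summ.post_mean == -2.0

    def test_symmetric_draws_have_zero_mean_percent(self):
        draws = np.concatenate([np.arange(-50, 0), np.arange(1, 51)])
        _, summ = percent_change(draws, baseline=500.0)
        assert summ.post_mean == pytest.approx(0.0, abs=1e-12)

    def test_hpdi_commutes_with_positive_scaling(self):
        rng = np.random.default_rng(7)
        draws = rng.standard_gamma(2.0, size=2000) - 1.0
        lo, hi = hpdi(draws, 0.95)
        _, summ = percent_change(draws, baseline=800.0)
        assert summ.hpdi_low == pytest.approx(lo * 100 / 800.0)
        assert summ.hpdi_high == pytest.approx(hi * 100 / 800.0)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            percent_change(np.ones(5), baseline=0.0)
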