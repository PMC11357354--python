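"""Mixture fitting, bimodality index, dispersion, categorization."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flimhet.heterogeneity import (
    MixtureFit,
    bimodality_index,
    categorize,
    compute_sample_metrics,
    dispersion,
    fit_two_gaussian,
)


def _grid_search_loglik(x, n_mu=24, n_sigma=16, n_p=9):
    """Dense grid-search oracle for the common-variance mixture likelihood."""
    lo, hi = x.min(), x.max()
    mus = np.linspace(lo, hi, n_mu)
    sigmas = np.linspace(0.05 * x.std(), 1.5 * x.std() + 1e-9, n_sigma)
    ps = np.linspace(0.1, 0.9, n_p)
    best = -np.inf
    for mu1, mu2 in itertools.combinations_with_replacement(mus, 2):
        d1 = (x[:, None] - mu1) ** 2
        d2 = (x[:, None] - mu2) ** 2
        for s in sigmas:
            logn1 = -0.5 * d1[:, 0] / s**2 - np.log(s)
            logn2 = -0.5 * d2[:, 0] / s**2 - np.log(s)
            for p in ps:
                m = np.maximum(logn1 + np.log(p), logn2 + np.log(1 - p))
                ll = (
                    m
                    + np.log(
                        np.exp(logn1 + np.log(p) - m) + np.exp(logn2 + np.log(1 - p) - m)
                    )
                ).sum() - 0.5 * len(x) * np.log(2 * np.pi)
                best = max(best, ll)
    return best


class TestFitTwoGaussian:
    def test_recovers_balanced_mixture(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(70, 2, 100), rng.normal(80, 2, 100)])
        f = fit_two_gaussian(x, seed=0)
        assert f.mu1 == pytest.approx(70, abs=0.5)
        assert f.mu2 == pytest.approx(80, abs=0.5)
        assert f.pi1 == pytest.approx(0.5, abs=0.1)
        assert f.converged

    def test_unimodal_null_rarely_crosses_bimodality_cutoff(self):
        """On pure-Gaussian samples the fitted mixture splits the tails, but
        the resulting BI stays below the 1.1 cutoff."""
        below = 0
        n_seeds = 50
        for s in range(n_seeds):
            rng = np.random.default_rng(20_000 + s)
            f = fit_two_gaussian(100 + rng.normal(0, 1, 500), seed=s)
            below += bimodality_index(f) < 1.1
        assert below >= 0.95 * n_seeds

    def test_loglik_dominates_single_gaussian(self):
        rng = np.random.default_rng(3)
        x = rng.normal(5, 1.3, 80)
        f = fit_two_gaussian(x, seed=0)
        single = (
            -0.5 * len(x) * np.log(2 * np.pi)
            - len(x) * np.log(x.std())
            - 0.5 * len(x)
        )
        assert f.log_likelihood >= single - 1e-6

    def test_matches_grid_search_oracle_small_n(self):
        """EM's optimum is never worse than a dense grid search at n <= 12."""
        for seed, gen in [
            (0, lambda r: r.normal(0, 1, 8)),
            (1, lambda r: np.concatenate([r.normal(0, 0.5, 6), r.normal(4, 0.5, 6)])),
            (2, lambda r: r.uniform(0, 10, 10)),
        ]:
            x = gen(np.random.default_rng(seed))
            f = fit_two_gaussian(x, seed=seed)
            assert f.log_likelihood >= _grid_search_loglik(x) - 1e-6

    def test_matches_sklearn_tied_mixture(self):
        """Independent cross-check: sklearn's tied-covariance EM finds the
        same optimum on well-separated data."""
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(70, 2, 90), rng.normal(80, 2, 110)])
        f = fit_two_gaussian(x, seed=0)
        gm = GaussianMixture(
            n_components=2, covariance_type="tied", n_init=5, random_state=0,
            tol=1e-8, max_iter=500,
        ).fit(x[:, None])
        sk_ll = gm.score(x[:, None]) * len(x)
        assert f.log_likelihood == pytest.approx(sk_ll, abs=0.01)
        mus = sorted(gm.means_.ravel())
        assert f.mu1 == pytest.approx(mus[0], abs=0.05)
        assert f.mu2 == pytest.approx(mus[1], abs=0.05)

    def test_seed_determinism(self):
        x = np.random.default_rng(9).normal(0, 1, 50)
        f1 = fit_two_gaussian(x, seed=4)
        f2 = fit_two_gaussian(x, seed=4)
        assert (f1.mu1, f1.mu2, f1.sigma, f1.pi1) == (f2.mu1, f2.mu2, f2.sigma, f2.pi1)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            fit_two_gaussian([1.0, 2.0, 3.0])

    def test_zero_variance_is_degenerate_with_floor(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            f = fit_two_gaussian(np.full(10, 7.0))
        assert f.degenerate and f.sigma_at_floor
        assert bimodality_index(f) == 0.0

    def test_unequal_variance_variant(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(70, 1, 100), rng.normal(80, 4, 100)])
        f = fit_two_gaussian(x, seed=0, equal_variance=False)
        assert f.sigma1 < f.sigma2
        assert f.sigma == pytest.approx(np.sqrt(f.sigma1 * f.sigma2), rel=1e-9)


class TestBimodalityIndex:
    def test_zero_separation_gives_zero(self):
        f = MixtureFit(mu1=5.0, mu2=5.0, sigma=1.0, pi1=0.5, n=100,
                       log_likelihood=0.0, converged=True, n_restarts_used=1)
        assert bimodality_index(f) == 0.0

    def test_closed_form_balanced_two_sigma_separation(self):
        # sqrt(0.25) * 2 = 1: the canonical reference point of the index
        f = MixtureFit(mu1=0.0, mu2=2.0, sigma=1.0, pi1=0.5, n=100,
                       log_likelihood=0.0, converged=True, n_restarts_used=1)
        assert bimodality_index(f) == pytest.approx(1.0, abs=1e-12)

    def test_em_estimate_near_truth_for_balanced_mixture(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(70, 2, 100), rng.normal(80, 2, 100)])
        bi = bimodality_index(fit_two_gaussian(x, seed=0))
        assert bi == pytest.approx(2.5, abs=0.3)  # formula at true parameters

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(70, 2, 80), rng.normal(80, 2, 80)])
        b1 = bimodality_index(fit_two_gaussian(x, seed=0))
        b2 = bimodality_index(fit_two_gaussian(3.7 * x, seed=0))
        assert b2 == pytest.approx(b1, rel=1e-6)

    def test_monotone_in_separation(self):
        """For balanced mixtures BI grows with the mode separation."""
        bis = []
        for delta in (2.0, 4.0, 6.0, 8.0):
            vals = []
            for s in range(5):
                rng = np.random.default_rng(100 * s + int(delta))
                x = np.concatenate(
                    [rng.normal(70, 2, 100), rng.normal(70 + delta, 2, 100)]
                )
                vals.append(bimodality_index(fit_two_gaussian(x, seed=s)))
            bis.append(np.median(vals))
        assert all(a < b for a, b in zip(bis, bis[1:]))


def _iqr_sorted_oracle(values):
    """Textbook linear-interpolation quantile on the sorted data."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)

    def q(p):
        h = (n - 1) * p
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return x[lo] + (h - lo) * (x[hi] - x[lo])

    return q(0.75) - q(0.25)


class TestDispersion:
    def test_constant_vector_is_zero(self):
        assert dispersion([5.0] * 8) == 0.0

    def test_hand_computed_example(self):
        # Q1 = 1.75, Q3 = 3.25 under linear interpolation
        assert dispersion([1, 2, 3, 4]) == pytest.approx(1.5, abs=1e-12)

    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=40),
           st.floats(-1e3, 1e3))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_shift_invariance_and_oracle(self, values, c):
        d = dispersion(values)
        assert d >= 0
        assert dispersion([v + c for v in values]) == pytest.approx(d, abs=1e-6)
        assert d == pytest.approx(_iqr_sorted_oracle(values), abs=1e-9)

    def test_alternative_quantile_rules(self):
        x = [1, 2, 3, 4]
        assert dispersion(x, method="midpoint") == pytest.approx(2.0)
        assert dispersion(x, method="nearest") == pytest.approx(1.0)


class TestCategorize:
    @pytest.mark.parametrize(
        "bi, expected",
        [
            (1.25, "bimodal"),  # a published highly heterogeneous sample
            (0.24, "homogeneous"),  # the one published homogeneous sample
            (1.1, "bimodal"),  # inclusive cutoff
            (1.0999, "intermediate"),
            (0.5, "intermediate"),
            (0.4999, "homogeneous"),
            (0.0, "homogeneous"),
        ],
    )
    def test_band_edges(self, bi, expected):
        assert categorize(bi) == expected

    def test_negative_bi_rejected(self):
        with pytest.raises(ValueError):
            categorize(-0.1)


class TestComputeSampleMetrics:
    def test_metrics_fields_and_category(self):
        rng = np.random.default_rng(0)
        values = {
            "a1": np.concatenate([rng.normal(70, 2, 75), rng.normal(80, 2, 75)]),
            "tau_m": rng.normal(0.9, 0.1, 150),
            "tau2": rng.normal(2.5, 0.25, 150),
        }
        m = compute_sample_metrics("s1", values, seed=0)
        assert m.n_cells == 150
        assert m.BI_a1 >= 1.1 and m.category == "bimodal"
        assert m.D_a1 > m.D_tau_m  # percent scale vs ns scale
        assert m.D_tau2 == pytest.approx(1.349 * 0.25, rel=0.25)
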