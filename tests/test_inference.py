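"""Posterior evaluation, optimization and sampling machinery."""

import math

import numpy as np
import pytest
from scipy import stats

from rtktraffic.inference import (AMConfig, ExperimentSet,
                                  TraffickingPosterior, adaptive_metropolis,
                                  estimate_sigmas, gelman_rubin, lhs_starts,
                                  multistart_minimize, pattern_search)
from rtktraffic.priors import PriorSpec, PriorSet, default_prior_set
from rtktraffic.synthetic_data import (make_experiment_set, scenario_preset)


def _dataset(rng=None, sigma=0.1, n_ep=4, n_tc=3):
    """Small random-but-fixed dataset for likelihood tests."""
    rng = rng or np.random.default_rng(99)
    times = np.array([5.0, 20.0, 45.0, 75.0, 90.0])
    return ExperimentSet(
        endpoint_lysate=rng.uniform(1e5, 3e5, n_ep),
        endpoint_supernatant=rng.uniform(1e3, 5e3, n_ep),
        timecourse_times=times,
        timecourse_total=rng.uniform(0.5, 1.0, (times.size, n_tc)),
        timecourse_internal=rng.uniform(0.05, 0.3, (times.size, n_tc)),
        sigma={k: sigma for k in ("endpoint_lysate", "endpoint_supernatant",
                                  "timecourse_total", "timecourse_internal")},
    )


def _flat_priors():
    params = {n: PriorSpec(kind="uniform", bounds=(-6.0, 0.0))
              for n in ("k_deg", "k_end", "k_rec", "k_shed")}
    params["P_syn"] = PriorSpec(kind="uniform", bounds=(0.0, 5.0))
    return PriorSet(params=params, surface_fraction=None)


class TestLikelihood:
    def test_perfect_predictions_count_observations(self):
        """With y = yhat and sigma = 1 every observation contributes
        -log(1) - log(2 pi)/2 = -0.9189."""
        ds = _dataset(sigma=1.0)
        # explicit initial conditions in theta, so predictions do not
        # feed back through the data means
        theta = np.array([2.5, -2.0, -2.5, -2.2, -3.5, 1.0, 0.1, 0.9])
        post = TraffickingPosterior(ds, _flat_priors(), init_mode="sampled")
        pred = post.predict(theta)
        ds.endpoint_lysate = np.full(3, pred["endpoint_lysate"])
        ds.endpoint_supernatant = np.full(3, pred["endpoint_supernatant"])
        ds.supernatant_censored = np.zeros(3, bool)
        ds.timecourse_total = np.tile(pred["timecourse_total"][:, None], (1, 2))
        ds.timecourse_internal = np.tile(pred["timecourse_internal"][:, None],
                                         (1, 2))
        post2 = TraffickingPosterior(ds, _flat_priors(), init_mode="sampled")
        # rt0_ref changed with the data, so rescale the ratio coordinate
        theta2 = theta.copy()
        theta2[5] = theta[5] * post.data.rt0_ref / post2.data.rt0_ref
        n_obs = 3 + 3 + 2 * 5 + 2 * 5
        assert post2.log_likelihood(theta2) == pytest.approx(
            n_obs * -0.9189385, abs=1e-4)

    def test_matches_independent_gaussian_sum(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            ds = _dataset(rng, sigma=float(rng.uniform(0.05, 0.4)))
            post = TraffickingPosterior(ds, _flat_priors(), init_mode="fixed")
            theta = np.concatenate([[rng.uniform(1, 4)],
                                    rng.uniform(-4, -1, 4)])
            pred = post.predict(theta)
            expect = 0.0
            s = ds.sigma["endpoint_lysate"]
            expect += stats.norm.logpdf(
                np.log10(ds.endpoint_lysate),
                math.log10(pred["endpoint_lysate"]), s).sum()
            expect += stats.norm.logpdf(
                np.log10(ds.endpoint_supernatant),
                math.log10(pred["endpoint_supernatant"]),
                ds.sigma["endpoint_supernatant"]).sum()
            for key in ("timecourse_total", "timecourse_internal"):
                yh = pred[key]
                for k in range(5):
                    expect += stats.norm.logpdf(
                        np.log10(getattr(ds, key)[k]), np.log10(yh[k]),
                        ds.sigma[key]).sum()
            assert post.log_likelihood(theta) == pytest.approx(expect,
                                                               abs=1e-10)

    def test_censored_below_lloq_contributes_nothing(self):
        ds = _dataset()
        ds.lloq_endpoint = 1e9   # prediction guaranteed below
        ds.supernatant_censored = np.ones(ds.endpoint_supernatant.size, bool)
        post = TraffickingPosterior(ds, _flat_priors(), init_mode="fixed")
        theta = np.array([2.5, -2.0, -2.5, -2.2, -3.5])
        ds2 = _dataset()
        ds2.supernatant_censored = np.ones(ds2.endpoint_supernatant.size, bool)
        ds2.lloq_endpoint = float("nan")
        post2 = TraffickingPosterior(ds2, _flat_priors(), init_mode="fixed")
        assert post.log_likelihood(theta) == pytest.approx(
            post2.log_likelihood(theta))

    def test_censored_above_lloq_penalized(self):
        ds = _dataset()
        ds.supernatant_censored = np.ones(ds.endpoint_supernatant.size, bool)
        theta = np.array([2.5, -2.0, -2.5, -2.2, -3.5])
        post = TraffickingPosterior(ds, _flat_priors(), init_mode="fixed")
        pred = post.predict(theta)
        ds.lloq_endpoint = pred["endpoint_supernatant"] / 10.0
        post = TraffickingPosterior(ds, _flat_priors(), init_mode="fixed")
        sig = ds.sigma["endpoint_supernatant"]
        penalty = -0.5 * (1.0 / sig) ** 2 * ds.endpoint_supernatant.size
        base = post.log_likelihood(theta)
        ds.supernatant_censored = np.zeros(ds.endpoint_supernatant.size, bool)
        ds_unc = _dataset()
        # penalty equals -(log10 yhat - log10 LLOQ)^2 / (2 sigma^2) per flag
        post_nocen = TraffickingPosterior(
            ExperimentSet(endpoint_lysate=ds.endpoint_lysate,
                          endpoint_supernatant=ds.endpoint_supernatant,
                          timecourse_times=ds.timecourse_times,
                          timecourse_total=ds.timecourse_total,
                          timecourse_internal=ds.timecourse_internal,
                          sigma=ds.sigma), _flat_priors(), init_mode="fixed")
        diff = base - post_nocen.log_likelihood(theta)
        # censored part replaced the Gaussian terms by the one-sided penalty
        s = ds.sigma["endpoint_supernatant"]
        gauss_terms = stats.norm.logpdf(
            np.log10(ds.endpoint_supernatant),
            math.log10(pred["endpoint_supernatant"]), s).sum()
        assert diff == pytest.approx(penalty - gauss_terms, abs=1e-8)

    def test_posterior_adds_prior_and_propagates_inf(self):
        ds = _dataset()
        post = TraffickingPosterior(ds, _flat_priors(), init_mode="fixed")
        theta = np.array([2.5, -2.0, -2.5, -2.2, -3.5])
        assert post(theta) == pytest.approx(post.log_likelihood(theta))
        assert post(np.array([9.0, -2, -2, -2, -3])) == -math.inf

    def test_sigma_estimation_median_of_replicate_groups(self):
        sc = scenario_preset("control", seed=1)
        sets = [make_experiment_set(sc, r) for r in ("rtkA_axl", "rtkB_met")]
        sig = estimate_sigmas(sets)
        for et, truth in sc.sigmas.items():
            assert sig[et] == pytest.approx(truth, rel=0.5)


class TestLHS:
    def test_one_point_per_bin_1d(self):
        pts = lhs_starts(4, np.array([[0.0, 4.0]]), seed=0).ravel()
        assert sorted(int(p) for p in pts) == [0, 1, 2, 3]

    def test_marginal_stratification_5d(self):
        bounds = np.array([[-6.0, 0.0]] * 4 + [[0.0, 5.0]])
        pts = lhs_starts(100, bounds, seed=3)
        for j in range(5):
            lo, hi = bounds[j]
            bins = np.floor((pts[:, j] - lo) / (hi - lo) * 100).astype(int)
            assert sorted(bins) == list(range(100))

    def test_seeded_reproducibility(self):
        b = np.array([[0.0, 1.0]] * 3)
        assert np.array_equal(lhs_starts(10, b, seed=5),
                              lhs_starts(10, b, seed=5))

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            lhs_starts(5, np.array([[1.0, 0.0]]))


class TestPatternSearch:
    def test_quadratic_minimum(self):
        x, f, conv = pattern_search(lambda v: (v[0] + 3.0) ** 2,
                                    np.array([0.0]),
                                    np.array([[-6.0, 0.0]]))
        assert conv and abs(x[0] + 3.0) < 1e-5

    def test_monotone_objective_hits_boundary(self):
        x, _, _ = pattern_search(lambda v: float(v[0]), np.array([-1.0]),
                                 np.array([[-6.0, 0.0]]))
        assert x[0] == pytest.approx(-6.0, abs=1e-5)

    def test_multistart_finds_deeper_basin(self):
        # two basins: shallow at +2, deep at -2
        def f(v):
            x = v[0]
            return float(min((x - 2) ** 2 + 1.0, (x + 2) ** 2))
        grid = np.linspace(-6, 6, 20001)
        oracle = grid[np.argmin([f([g]) for g in grid])]
        starts = lhs_starts(8, np.array([[-6.0, 6.0]]), seed=2)
        x, _ = multistart_minimize(f, starts, np.array([[-6.0, 6.0]]))
        # oracle resolution is the grid spacing (6e-4)
        assert x[0] == pytest.approx(oracle, abs=1e-3)
        assert x[0] == pytest.approx(-2.0, abs=1e-4)


class TestAdaptiveMetropolis:
    def test_pre_onset_proposals_use_fixed_covariance(self):
        """On a flat target every proposal is accepted, so pre-onset
        increments are exactly N(0, C0 I) draws."""
        cfg = AMConfig(n_iter=4000, burn_in=1, t0=10000, seed=2, n_chains=2)
        ch = adaptive_metropolis(lambda x: 0.0, np.zeros(3), cfg)
        incs = np.diff(ch.chains, axis=1).reshape(-1, 3)
        C = np.cov(incs.T)
        assert np.allclose(np.diag(C), 0.01, rtol=0.15)
        off = C - np.diag(np.diag(C))
        assert np.max(np.abs(off)) < 0.002

    def test_seeded_chains_bit_identical(self):
        lp = lambda x: -0.5 * float(x @ x)
        cfg = AMConfig(n_iter=2000, burn_in=500, seed=11, n_chains=2)
        a = adaptive_metropolis(lp, np.ones(4), cfg)
        b = adaptive_metropolis(lp, np.ones(4), cfg)
        assert np.array_equal(a.chains, b.chains)
        assert np.array_equal(a.accepted, b.accepted)

    def test_acceptance_rate_reasonable_on_gaussian(self):
        lp = lambda x: -0.5 * float(x @ x)
        cfg = AMConfig(n_iter=8000, burn_in=2000, seed=3)
        ch = adaptive_metropolis(lp, np.full(3, 0.5), cfg)
        assert 0.1 < ch.acceptance_rate < 0.6


class TestGelmanRubin:
    def test_identical_chains(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(100, 2))
        r = gelman_rubin(np.stack([x, x]))
        assert np.allclose(r, math.sqrt(99 / 100), atol=1e-12)

    def test_stationary_chains_near_one(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(size=(4, 2000, 3))
        assert np.all(gelman_rubin(chains) < 1.1)

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.0, 0.01, size=(500, 1))
        b = rng.normal(5.0, 0.01, size=(500, 1))
        assert gelman_rubin(np.stack([a, b]))[0] > 10

    def test_zero_variance_undefined(self):
        chains = np.zeros((2, 50, 1))
        assert np.isnan(gelman_rubin(chains)[0])


class TestSelfConsistency:
    def test_noiseless_map_recovers_truth(self):
        """The two-stage fit on noiseless control data lands on the
        generating parameters for the identifiable rates."""
        from rtktraffic.inference import fit_condition
        from rtktraffic.pipeline import build_condition_priors
        sc = scenario_preset(
            "control", seed=0,
            sigmas={k: 0.0 for k in ("endpoint_lysate", "endpoint_supernatant",
                                     "timecourse_total", "timecourse_internal")})
        sig = {k: 0.05 for k in ("endpoint_lysate", "endpoint_supernatant",
                                 "timecourse_total", "timecourse_internal")}
        ds = make_experiment_set(sc, "rtkA_axl", sigmas=sig)
        priors = build_condition_priors(ds, seed=1)
        res = fit_condition(ds, priors,
                            AMConfig(n_iter=10000, burn_in=2000, seed=5),
                            n_starts=24, max_poll_iter=300)
        p = sc.params_for("rtkA_axl")
        truth = np.log10([p.P_syn, p.k_deg, p.k_end, p.k_rec, p.k_shed])
        err = res.chains.map_estimate()[:5] - truth
        for j in (0, 1, 2, 4):  # P_syn, k_deg, k_end, k_shed
            assert abs(err[j]) < 0.05

    def test_doubling_identical_replicates_keeps_map(self):
        sc = scenario_preset(
            "control", seed=0,
            sigmas={k: 0.0 for k in ("endpoint_lysate", "endpoint_supernatant",
                                     "timecourse_total", "timecourse_internal")})
        sig = {k: 0.1 for k in ("endpoint_lysate", "endpoint_supernatant",
                                "timecourse_total", "timecourse_internal")}
        small = make_experiment_set(sc, "rtkB_met", sigmas=sig)
        doubled = ExperimentSet(
            endpoint_lysate=np.tile(small.endpoint_lysate, 2),
            endpoint_supernatant=np.tile(small.endpoint_supernatant, 2),
            timecourse_times=small.timecourse_times,
            timecourse_total=np.tile(small.timecourse_total, (1, 2)),
            timecourse_internal=np.tile(small.timecourse_internal, (1, 2)),
            sigma=sig)
        start = np.array([2.5, -2.0, -2.5, -2.2, -3.0])
        pa = TraffickingPosterior(small, _flat_priors(), init_mode="fixed")
        pb = TraffickingPosterior(doubled, _flat_priors(), init_mode="fixed")
        xa, _, _ = pattern_search(lambda x: -pa(x), start, pa.bounds[:5],
                                  max_iter=200)
        xb, _, _ = pattern_search(lambda x: -pb(x), start, pb.bounds[:5],
                                  max_iter=200)
        assert np.allclose(xa, xb)
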