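"""Joint Bayesian inference over end-point and pulse-chase data.

One receptor / treatment / cell-line condition is fit at a time.  The
unknowns are the five kinetic parameters on the log10 scale, optionally
joined by three nuisance initial conditions (end-point initial lysate and
the time-course initial internal/total label).  The posterior combines

* a Gaussian likelihood on log10-transformed observations, with one
  frozen noise sd per experiment type (end-point lysate / supernatant,
  time-course total / internal);
* the kinetic priors (log10-normal or uniform per parameter);
* a truncated-normal prior on the model-implied steady-state surface
  fraction and on the initial conditions.

Sampling follows a two-stage scheme: a multi-start derivative-free
pattern search from latin-hypercube start sites locates the presumed
global optimum, then a Haario-style adaptive Metropolis sampler (4 chains
seeded around the optimum at 5% CV) draws the posterior.  Convergence is
checked with the Gelman–Rubin potential scale reduction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc

from .model_core import (CompartmentState, RateParams, simulate_full,
                         simulate_pulse_chase, steady_surface_fraction)
from .priors import PARAM_NAMES, PriorSet, DEFAULT_BOUNDS

__all__ = [
    "ExperimentSet",
    "AMConfig",
    "PosteriorChains",
    "TraffickingPosterior",
    "FitResult",
    "log_likelihood",
    "log_posterior",
    "lhs_starts",
    "pattern_search",
    "adaptive_metropolis",
    "gelman_rubin",
    "fit_condition",
    "estimate_sigmas",
]

_LOG2PI_HALF = 0.5 * math.log(2.0 * math.pi)

EXPERIMENT_TYPES = ("endpoint_lysate", "endpoint_supernatant",
                    "timecourse_total", "timecourse_internal")


@dataclass
class ExperimentSet:
    """Replicated observations for one receptor/treatment/cell line.

    End-point values are molecules/cell after 24 h (``endpoint_dt`` min);
    time-course values are pulse-chase label in units normalized to the
    mean total signal at the first time point.  ``sigma`` maps experiment
    type to the frozen log10-scale noise sd.  ``lloq_endpoint`` is the
    censoring threshold on the end-point supernatant in molecules/cell
    over the end-point window (NaN when nothing is censored).
    """

    endpoint_lysate: np.ndarray
    endpoint_supernatant: np.ndarray
    timecourse_times: np.ndarray
    timecourse_total: np.ndarray      # (n_times, n_replicates)
    timecourse_internal: np.ndarray   # (n_times, n_replicates)
    sigma: dict
    endpoint_dt: float = 1440.0
    rt0_ref: float = float("nan")     # prior mean for initial lysate
    lloq_endpoint: float = float("nan")
    supernatant_censored: np.ndarray | None = None
    rtk: str = ""
    treatment: str = ""
    cell_line: str = ""

    def __post_init__(self) -> None:
        self.endpoint_lysate = np.asarray(self.endpoint_lysate, float)
        self.endpoint_supernatant = np.asarray(self.endpoint_supernatant, float)
        self.timecourse_times = np.asarray(self.timecourse_times, float)
        self.timecourse_total = np.atleast_2d(np.asarray(self.timecourse_total, float))
        self.timecourse_internal = np.atleast_2d(
            np.asarray(self.timecourse_internal, float))
        if np.any(np.diff(self.timecourse_times) <= 0):
            raise ValueError("time points must be sorted and distinct")
        for et in EXPERIMENT_TYPES:
            if not self.sigma.get(et, 0.0) > 0:
                raise ValueError(f"sigma for {et} must be > 0")
        if self.supernatant_censored is None:
            self.supernatant_censored = np.zeros(
                self.endpoint_supernatant.shape, dtype=bool)
        else:
            self.supernatant_censored = np.asarray(self.supernatant_censored,
                                                   dtype=bool)
        if math.isnan(self.rt0_ref):
            self.rt0_ref = float(np.mean(self.endpoint_lysate))

    @property
    def tc_total_t0_mean(self) -> float:
        return float(np.mean(self.timecourse_total[0]))

    @property
    def tc_internal_t0_mean(self) -> float:
        return float(np.mean(self.timecourse_internal[0]))


@dataclass(frozen=True)
class AMConfig:
    """Adaptive-Metropolis settings (defaults follow the published run,
    with chain length configurable for scaled-down studies)."""

    C0: float = 0.01          # initial proposal covariance scale (C0 * I)
    t0: int = 100             # adaptation onset, steps
    s_d: float = 0.2          # covariance scaling term
    eps: float = 1e-20        # regularization added to the empirical cov
    n_iter: int = 100000
    n_chains: int = 4
    burn_in: int = 20000
    start_cv: float = 0.05    # start-site coefficient of variation
    beta: float = 0.05        # post-onset probability of the fixed kernel
    target_accept: float = 0.234  # Robbins-Monro scale-adaptation target
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.burn_in < self.n_iter):
            raise ValueError("need 0 < burn_in < n_iter")
        for name in ("C0", "t0", "s_d", "eps", "start_cv"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class PosteriorChains:
    """Sampled log10-parameter chains with bookkeeping."""

    chains: np.ndarray        # (n_chains, n_iter, dim)
    log_post: np.ndarray      # (n_chains, n_iter)
    accepted: np.ndarray      # (n_chains, n_iter) bool
    burn_in: int
    param_names: tuple

    @property
    def n_chains(self) -> int:
        return self.chains.shape[0]

    @property
    def acceptance_rate(self) -> float:
        return float(self.accepted[:, self.burn_in:].mean())

    def posterior_samples(self) -> np.ndarray:
        """Post-burn-in samples pooled over chains, (n, dim)."""
        return self.chains[:, self.burn_in:, :].reshape(-1, self.chains.shape[2])

    def map_estimate(self) -> np.ndarray:
        flat = np.argmax(self.log_post)
        c, i = np.unravel_index(flat, self.log_post.shape)
        return self.chains[c, i].copy()

    def summary(self) -> dict:
        S = self.posterior_samples()
        rhat = gelman_rubin(self.chains[:, self.burn_in:, :])
        return {
            "mean": dict(zip(self.param_names, np.mean(S, axis=0))),
            "sd": dict(zip(self.param_names, np.std(S, axis=0, ddof=1))),
            "map": dict(zip(self.param_names, self.map_estimate())),
            "rhat": dict(zip(self.param_names, rhat)),
            "acceptance_rate": self.acceptance_rate,
        }


def estimate_sigmas(datasets: list) -> dict:
    """Per-experiment-type noise sd: the sd of log10 values within each
    replicate group, medianed over all conditions (and time points).

    ``datasets`` is a list of :class:`ExperimentSet` carrying raw
    replicate values (their ``sigma`` dicts are ignored).
    """
    groups = {et: [] for et in EXPERIMENT_TYPES}
    for ds in datasets:
        for name, arr in (("endpoint_lysate", ds.endpoint_lysate),
                          ("endpoint_supernatant", ds.endpoint_supernatant)):
            vals = arr[arr > 0]
            if vals.size > 1:
                groups[name].append(np.std(np.log10(vals), ddof=1))
        for name, mat in (("timecourse_total", ds.timecourse_total),
                          ("timecourse_internal", ds.timecourse_internal)):
            for row in mat:
                vals = row[row > 0]
                if vals.size > 1:
                    groups[name].append(np.std(np.log10(vals), ddof=1))
    out = {}
    for et, sds in groups.items():
        if not sds:
            raise ValueError(f"no replicate groups available for {et}")
        out[et] = float(np.median(sds))
    return out


class TraffickingPosterior:
    """Callable posterior over one condition's trafficking parameters.

    ``init_mode='sampled'`` (default) appends three nuisance coordinates
    to the five log10 kinetic parameters: the end-point initial lysate as
    a ratio to its prior mean, and the time-course initial internal and
    total label (normalized units).  ``init_mode='fixed'`` pins all three
    at the data means, leaving a 5-dimensional problem.
    """

    def __init__(self, data: ExperimentSet, priors: PriorSet,
                 init_mode: str = "sampled"):
        if init_mode not in ("sampled", "fixed"):
            raise ValueError("init_mode must be 'sampled' or 'fixed'")
        self.data = data
        self.priors = priors
        self.init_mode = init_mode
        names = list(PARAM_NAMES)
        lo = [DEFAULT_BOUNDS[n][0] for n in PARAM_NAMES]
        hi = [DEFAULT_BOUNDS[n][1] for n in PARAM_NAMES]
        for j, n in enumerate(PARAM_NAMES):
            b = priors.params[n].bounds
            if np.isfinite(b[0]):
                lo[j] = max(lo[j], b[0])
            if np.isfinite(b[1]):
                hi[j] = min(hi[j], b[1])
        if init_mode == "sampled":
            names += ["rt0_ratio", "ri0_tc", "rt0_tc"]
            lo += [0.05, 0.0, 0.05]
            hi += [20.0, 5.0, 5.0]
        self.param_names = tuple(names)
        self.bounds = np.column_stack([lo, hi])
        self.dim = len(names)

    # -- pieces ---------------------------------------------------------
    def _unpack(self, theta: np.ndarray):
        params = RateParams.from_log10(theta[:5])
        if self.init_mode == "sampled":
            rt0 = float(theta[5]) * self.data.rt0_ref
            ri0_tc = float(theta[6])
            rt0_tc = float(theta[7])
        else:
            rt0 = self.data.rt0_ref
            ri0_tc = self.data.tc_internal_t0_mean
            rt0_tc = self.data.tc_total_t0_mean
        return params, rt0, ri0_tc, rt0_tc

    def predict(self, theta: np.ndarray) -> dict:
        """Model predictions for every experiment type at this theta."""
        params, rt0, ri0_tc, rt0_tc = self._unpack(theta)
        fs = steady_surface_fraction(params)
        init = CompartmentState(r_s=rt0 * fs, r_i=rt0 * (1.0 - fs), r_f=0.0)
        ep = simulate_full(params, init, [self.data.endpoint_dt])
        rs0_tc = rt0_tc - ri0_tc
        if rs0_tc < 0:
            raise ValueError("time-course initial total below internal")
        tc_init = CompartmentState(r_s=rs0_tc, r_i=ri0_tc, r_f=0.0)
        tc = simulate_pulse_chase(params, tc_init, self.data.timecourse_times)
        return {
            "endpoint_lysate": float(ep.r_t[0]),
            "endpoint_supernatant": float(ep.r_f[0]),
            "timecourse_total": tc.r_t,
            "timecourse_internal": tc.r_i,
        }

    def log_likelihood(self, theta: np.ndarray) -> float:
        theta = np.asarray(theta, float)
        try:
            pred = self.predict(theta)
        except ValueError:
            return -math.inf
        d, total = self.data, 0.0

        def _gauss(yhat: float, y_log10: np.ndarray, sig: float) -> float:
            if yhat <= 0 or not math.isfinite(yhat):
                return -math.inf
            z = (math.log10(yhat) - y_log10) / sig
            return float(np.sum(-0.5 * z * z) -
                         y_log10.size * (math.log(sig) + _LOG2PI_HALF))

        total += _gauss(pred["endpoint_lysate"],
                        np.log10(d.endpoint_lysate),
                        d.sigma["endpoint_lysate"])
        if total == -math.inf:
            return total

        # supernatant: censored replicates contribute only when the model
        # predicts a quantifiable signal
        cen = d.supernatant_censored
        sig = d.sigma["endpoint_supernatant"]
        yhat = pred["endpoint_supernatant"]
        obs = d.endpoint_supernatant[~cen]
        if obs.size:
            total += _gauss(yhat, np.log10(obs), sig)
            if total == -math.inf:
                return total
        n_cen = int(np.sum(cen))
        if n_cen and math.isfinite(d.lloq_endpoint):
            if yhat > d.lloq_endpoint:
                z = (math.log10(yhat) - math.log10(d.lloq_endpoint)) / sig
                total += -0.5 * z * z * n_cen

        for key in ("timecourse_total", "timecourse_internal"):
            sig = d.sigma[key]
            Y = getattr(d, key)
            yh = pred[key]
            for k in range(Y.shape[0]):
                row = Y[k]
                if yh[k] <= 0 or not math.isfinite(yh[k]):
                    return -math.inf
                z = (math.log10(yh[k]) - np.log10(row)) / sig
                total += float(np.sum(-0.5 * z * z) -
                               row.size * (math.log(sig) + _LOG2PI_HALF))
        return total

    def log_prior(self, theta: np.ndarray) -> float:
        theta = np.asarray(theta, float)
        lo, hi = self.bounds[:, 0], self.bounds[:, 1]
        if np.any(theta < lo) or np.any(theta > hi):
            return -math.inf
        total = self.priors.kinetic_logpdf(theta[:5])
        if total == -math.inf:
            return total
        if self.priors.surface_fraction is not None:
            params = RateParams.from_log10(theta[:5])
            total += self.priors.surface_fraction.logpdf(
                steady_surface_fraction(params))
        if self.init_mode == "sampled":
            if theta[7] < theta[6]:
                return -math.inf
            if self.priors.rt0_endpoint is not None:
                total += self.priors.rt0_endpoint.logpdf(
                    float(theta[5]) * self.data.rt0_ref)
            if self.priors.ri0_timecourse is not None:
                total += self.priors.ri0_timecourse.logpdf(float(theta[6]))
            if self.priors.rt0_timecourse is not None:
                total += self.priors.rt0_timecourse.logpdf(float(theta[7]))
        return total

    def __call__(self, theta: np.ndarray) -> float:
        lp = self.log_prior(theta)
        if lp == -math.inf:
            return lp
        return lp + self.log_likelihood(theta)

    def start_vector(self) -> np.ndarray:
        """Data-informed centre used to complete LHS starts for the
        nuisance coordinates."""
        if self.init_mode == "fixed":
            return np.zeros(0)
        return np.array([1.0, max(self.data.tc_internal_t0_mean, 1e-3),
                         max(self.data.tc_total_t0_mean, 1e-2)])


def log_likelihood(theta, data: ExperimentSet, priors: PriorSet | None = None,
                   init_mode: str = "fixed") -> float:
    """Functional wrapper: likelihood of ``theta`` under one condition."""
    from .priors import default_prior_set
    post = TraffickingPosterior(data, priors or default_prior_set(),
                                init_mode=init_mode)
    return post.log_likelihood(np.asarray(theta, float))


def log_posterior(theta, data: ExperimentSet, priors: PriorSet,
                  init_mode: str = "fixed") -> float:
    post = TraffickingPosterior(data, priors, init_mode=init_mode)
    return post(np.asarray(theta, float))


def lhs_starts(n: int, bounds: np.ndarray, seed: int = 0) -> np.ndarray:
    """Latin-hypercube start sites: each dimension stratified into ``n``
    equal bins with exactly one point per bin."""
    bounds = np.asarray(bounds, float)
    if n < 1:
        raise ValueError("need n >= 1 start sites")
    if bounds.ndim != 2 or bounds.shape[1] != 2 or np.any(
            bounds[:, 0] >= bounds[:, 1]):
        raise ValueError("bounds must be (dim, 2) with lo < hi")
    sampler = qmc.LatinHypercube(d=bounds.shape[0], seed=seed)
    unit = sampler.random(n)
    return qmc.scale(unit, bounds[:, 0], bounds[:, 1])


def pattern_search(objective, start, bounds, *, mesh0: float = 0.1,
                   mesh_tol: float = 1e-6, max_iter: int = 2000):
    """Generalized pattern search with coordinate polling.

    Polls +/- mesh * range(dim) along each coordinate; expands the mesh
    x2 on success, contracts x0.5 on failure; stops when the mesh falls
    below ``mesh_tol`` or the iteration cap is reached.

    Returns ``(theta_star, f_star, converged)``.
    """
    bounds = np.asarray(bounds, float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo
    x = np.clip(np.asarray(start, float), lo, hi)
    f = float(objective(x))
    if not math.isfinite(f):
        raise ValueError("objective must be finite at the start point")
    mesh = mesh0
    d = x.size
    for _ in range(max_iter):
        if mesh < mesh_tol:
            return x, f, True
        improved = False
        for j in range(d):
            for sign in (1.0, -1.0):
                cand = x.copy()
                cand[j] = min(max(cand[j] + sign * mesh * span[j], lo[j]), hi[j])
                if cand[j] == x[j]:
                    continue
                fc = float(objective(cand))
                if fc < f:
                    x, f, improved = cand, fc, True
                    break
            if improved:
                break
        mesh = mesh * 2.0 if improved else mesh * 0.5
        if improved:
            mesh = min(mesh, 1.0)
    return x, f, mesh < mesh_tol


def multistart_minimize(objective, starts: np.ndarray, bounds, **kwargs):
    """Pattern search from every start; the minimum wins, first-found
    start breaking ties."""
    best_x, best_f = None, math.inf
    for s in np.asarray(starts, float):
        try:
            x, fv, _ = pattern_search(objective, s, bounds, **kwargs)
        except ValueError:
            continue
        if fv < best_f:
            best_x, best_f = x, fv
    if best_x is None:
        raise RuntimeError("objective was infinite at every start site")
    return best_x, best_f


def adaptive_metropolis(log_post, start, cfg: AMConfig,
                        rng: np.random.Generator | None = None,
                        param_names: tuple | None = None) -> PosteriorChains:
    """Haario-style adaptive Metropolis, multi-chain.

    Proposals are N(theta_t, C0*I) for the first ``t0`` steps, then
    N(theta_t, s_d * (Cov(theta_0..t-1) + eps*I)) with the empirical
    covariance maintained recursively.  Chains start from N(start,
    (start_cv*|start|)^2) draws.  Two safeguards keep the adaptation out
    of known failure modes: if the adapted covariance is not positive
    definite the initial C0*I proposal is used for that step, and after
    onset a small fraction ``beta`` of proposals always come from the
    fixed C0*I kernel (the standard mixture safeguard), so a chain whose
    history-based covariance is momentarily too large or too small can
    still move.  A diminishing Robbins-Monro adaptation of a global
    proposal scale (targeting ``target_accept``) corrects the overall
    step size when the history-based covariance is badly calibrated,
    e.g. right after a long uphill approach to the mode.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    start = np.asarray(start, float)
    d = start.size
    names = param_names or tuple(f"theta_{i}" for i in range(d))
    chains = np.empty((cfg.n_chains, cfg.n_iter, d))
    logps = np.empty((cfg.n_chains, cfg.n_iter))
    accepted = np.zeros((cfg.n_chains, cfg.n_iter), dtype=bool)
    L0 = math.sqrt(cfg.C0) * np.eye(d)

    for c in range(cfg.n_chains):
        theta, lp = None, -math.inf
        for _ in range(100):
            cand = rng.normal(start, cfg.start_cv * np.abs(start))
            lpc = float(log_post(cand))
            if math.isfinite(lpc):
                theta, lp = cand, lpc
                break
        if theta is None:
            theta, lp = start.copy(), float(log_post(start))
            if not math.isfinite(lp):
                raise ValueError("log posterior infinite at the start site")
        mean = theta.copy()
        M2 = np.zeros((d, d))
        count = 1
        n_since_accept = 0
        log_scale = 0.0
        for t in range(cfg.n_iter):
            if count <= cfg.t0:
                L = L0
                adapting = False
            else:
                adapting = True
                if rng.random() < cfg.beta:
                    L = math.exp(0.5 * log_scale) * L0
                else:
                    cov = cfg.s_d * (M2 / (count - 1) + cfg.eps * np.eye(d))
                    try:
                        L = math.exp(0.5 * log_scale) * np.linalg.cholesky(cov)
                    except np.linalg.LinAlgError:
                        L = math.exp(0.5 * log_scale) * L0
            prop = theta + L @ rng.standard_normal(d)
            lpp = float(log_post(prop))
            alpha = math.exp(min(0.0, lpp - lp))
            if adapting:
                gamma = (count - cfg.t0) ** -0.6
                log_scale += gamma * (alpha - cfg.target_accept)
                log_scale = min(max(log_scale, -30.0), 30.0)
            if lpp - lp > math.log(rng.random() + 1e-300):
                theta, lp = prop, lpp
                accepted[c, t] = True
                n_since_accept = 0
            else:
                n_since_accept += 1
            chains[c, t] = theta
            logps[c, t] = lp
            # recursive covariance update with the realized chain state
            count += 1
            delta = theta - mean
            mean += delta / count
            M2 += np.outer(delta, theta - mean)
        if n_since_accept > 5000:
            import warnings
            warnings.warn(f"chain {c}: no acceptance over the last "
                          f"{n_since_accept} steps", stacklevel=2)
    return PosteriorChains(chains=chains, log_post=logps, accepted=accepted,
                           burn_in=cfg.burn_in, param_names=names)


def gelman_rubin(chains: np.ndarray) -> np.ndarray:
    """Potential scale reduction per parameter.

    ``chains`` is (n_chains, n_samples, dim).  R-hat = sqrt((((n-1)/n) W
    + B/n) / W) with W the mean within-chain variance and B the
    between-chain variance of the chain means (times n).
    """
    X = np.asarray(chains, float)
    if X.ndim != 3 or X.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    m, n, d = X.shape
    chain_means = X.mean(axis=1)            # (m, d)
    W = X.var(axis=1, ddof=1).mean(axis=0)  # (d,)
    B = n * chain_means.var(axis=0, ddof=1)
    out = np.full(d, np.nan)
    ok = W > 0
    out[ok] = np.sqrt(((n - 1) / n * W[ok] + B[ok] / n) / W[ok])
    return out


@dataclass
class FitResult:
    """Everything downstream stages need from one condition's fit."""

    posterior: TraffickingPosterior
    chains: PosteriorChains
    global_optimum: np.ndarray
    optimum_value: float
    rhat: np.ndarray

    @property
    def converged(self) -> bool:
        return bool(np.all(self.rhat[np.isfinite(self.rhat)] < 1.1))

    def kinetic_samples(self) -> np.ndarray:
        """Post-burn-in log10 kinetic parameter samples, (n, 5)."""
        return self.chains.posterior_samples()[:, :5]

    def summary(self) -> dict:
        s = self.chains.summary()
        s["neg_log_posterior_optimum"] = self.optimum_value
        s["converged"] = self.converged
        return s


def fit_condition(data: ExperimentSet, priors: PriorSet, cfg: AMConfig,
                  n_starts: int = 100, init_mode: str = "sampled",
                  mesh_tol: float = 1e-6, max_poll_iter: int = 400) -> FitResult:
    """Full two-stage fit of one condition.

    Latin-hypercube starts -> pattern search on -log posterior from every
    start -> adaptive Metropolis chains seeded around the winner.
    """
    post = TraffickingPosterior(data, priors, init_mode=init_mode)
    rng = np.random.default_rng(cfg.seed)

    kin_bounds = post.bounds[:5]
    starts_kin = lhs_starts(n_starts, kin_bounds, seed=cfg.seed)
    extra = post.start_vector()
    if extra.size:
        starts = np.hstack([starts_kin,
                            np.tile(extra, (n_starts, 1))])
    else:
        starts = starts_kin

    def objective(x):
        v = post(x)
        return math.inf if v == -math.inf else -v

    opt, fval = multistart_minimize(objective, starts, post.bounds,
                                    mesh_tol=mesh_tol, max_iter=max_poll_iter)
    chains = adaptive_metropolis(post, opt, cfg, rng=rng,
                                 param_names=post.param_names)
    rhat = gelman_rubin(chains.chains[:, cfg.burn_in:, :])
    return FitResult(posterior=post, chains=chains, global_optimum=opt,
                     optimum_value=fval, rhat=rhat)
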