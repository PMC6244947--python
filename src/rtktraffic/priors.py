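"""Prior distributions for the trafficking parameters.

Three families are used:

* literature-anchored log-normal priors (normal on log10 values) for
  P_syn, k_deg, k_end and k_rec — wide, reflecting how poorly published
  rates transfer across receptors and cell contexts;
* a data-derived shedding prior: assuming surface levels are roughly
  constant over the end-point experiment, k_shed ~ r_f / (r_t f_s dt),
  and a Monte-Carlo draw over the replicate-level uncertainty of r_f,
  r_t and the surface fraction f_s turns the end-point measurements into
  a log10-normal prior;
* a censored variant for analytes whose supernatant signal never clears
  the assay LLOQ: the hourly shedding flux is taken Uniform(1, LLOQ)
  molecules cell^-1 h^-1 and the implied log10 k_shed range becomes a
  uniform prior.

After the control condition is fit, treatment fits reuse the control
posterior as their prior with the standard deviation doubled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

__all__ = [
    "PriorSpec",
    "PriorSet",
    "ShedPriorInputs",
    "estimate_kshed_prior",
    "censored_kshed_prior",
    "log_prior",
    "update_treatment_priors",
    "default_prior_set",
]

_LOG2PI_HALF = 0.5 * math.log(2.0 * math.pi)

PARAM_NAMES = ("P_syn", "k_deg", "k_end", "k_rec", "k_shed")

#: literature anchors for the log10 prior means; sigma_p = 2 decades
DEFAULT_ANCHORS = {"P_syn": 2.0, "k_deg": -2.0, "k_end": -2.0, "k_rec": -2.0}
DEFAULT_SIGMA = 2.0

#: hard optimization bounds on log10 parameters
DEFAULT_BOUNDS = {"P_syn": (0.0, 5.0), "k_deg": (-6.0, 0.0),
                  "k_end": (-6.0, 0.0), "k_rec": (-6.0, 0.0),
                  "k_shed": (-6.0, 0.0)}


@dataclass(frozen=True)
class PriorSpec:
    """One parameter's prior.

    kind 'lognormal10': normal density on the log10 value with mean ``mu``
    and sd ``sigma``.  kind 'uniform': flat between ``bounds`` (log10
    space for kinetic parameters).  kind 'truncnormal': normal(mu, sigma)
    truncated to ``bounds`` on the natural scale.
    """

    kind: str
    mu: float = float("nan")
    sigma: float = float("nan")
    bounds: tuple[float, float] = (-math.inf, math.inf)

    def __post_init__(self) -> None:
        if self.kind not in ("lognormal10", "uniform", "truncnormal"):
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if self.kind in ("lognormal10", "truncnormal") and not self.sigma > 0:
            raise ValueError("sigma must be > 0 for normal-family priors")
        if self.kind == "uniform" and not self.bounds[0] < self.bounds[1]:
            raise ValueError("uniform prior needs bounds[0] < bounds[1]")

    def logpdf(self, value: float) -> float:
        lo, hi = self.bounds
        if value < lo or value > hi:
            return -math.inf
        if self.kind == "lognormal10":
            z = (value - self.mu) / self.sigma
            return -0.5 * z * z - math.log(self.sigma) - _LOG2PI_HALF
        if self.kind == "uniform":
            return 0.0
        # truncated normal, closed form (kept off scipy for speed in the
        # MCMC hot path; cross-checked against scipy.stats.truncnorm)
        z = (value - self.mu) / self.sigma
        a = -math.inf if lo == -math.inf else (lo - self.mu) / self.sigma
        b = math.inf if hi == math.inf else (hi - self.mu) / self.sigma
        cdf_b = 1.0 if b == math.inf else 0.5 * (1.0 + math.erf(b / math.sqrt(2)))
        cdf_a = 0.0 if a == -math.inf else 0.5 * (1.0 + math.erf(a / math.sqrt(2)))
        mass = cdf_b - cdf_a
        if mass <= 0.0:
            return -math.inf
        return (-0.5 * z * z - math.log(self.sigma) - _LOG2PI_HALF
                - math.log(mass))

    def to_dict(self) -> dict:
        return {"kind": self.kind, "mu": self.mu, "sigma": self.sigma,
                "bounds": list(self.bounds)}

    @staticmethod
    def from_dict(d: dict) -> "PriorSpec":
        return PriorSpec(kind=d["kind"], mu=d.get("mu", float("nan")),
                         sigma=d.get("sigma", float("nan")),
                         bounds=tuple(d.get("bounds", (-math.inf, math.inf))))


@dataclass(frozen=True)
class PriorSet:
    """Priors for the five kinetic parameters (log10 space) plus the
    nonparametric pieces: a truncated-normal prior on the model's
    steady-state surface fraction and on the initial conditions."""

    params: dict  # name -> PriorSpec, log10 space
    surface_fraction: PriorSpec | None = field(default_factory=lambda: PriorSpec(
        kind="truncnormal", mu=0.85, sigma=0.1, bounds=(0.0, 1.0)))
    # end-point initial lysate r_t,0 prior, natural scale (molecules/cell)
    rt0_endpoint: PriorSpec | None = None
    # time-course initial conditions, normalized label units
    ri0_timecourse: PriorSpec | None = None
    rt0_timecourse: PriorSpec | None = None

    def kinetic_logpdf(self, theta_log10: np.ndarray) -> float:
        total = 0.0
        for name, value in zip(PARAM_NAMES, theta_log10):
            total += self.params[name].logpdf(float(value))
            if total == -math.inf:
                return -math.inf
        return total

    def to_dict(self) -> dict:
        out = {"params": {k: v.to_dict() for k, v in self.params.items()},
               "surface_fraction": (self.surface_fraction.to_dict()
                                    if self.surface_fraction else None)}
        for key in ("rt0_endpoint", "ri0_timecourse", "rt0_timecourse"):
            spec = getattr(self, key)
            out[key] = spec.to_dict() if spec is not None else None
        return out

    @staticmethod
    def from_dict(d: dict) -> "PriorSet":
        sf = d.get("surface_fraction")
        kw = {"params": {k: PriorSpec.from_dict(v)
                         for k, v in d["params"].items()},
              "surface_fraction": PriorSpec.from_dict(sf) if sf else None}
        for key in ("rt0_endpoint", "ri0_timecourse", "rt0_timecourse"):
            v = d.get(key)
            kw[key] = PriorSpec.from_dict(v) if v else None
        return PriorSet(**kw)


@dataclass(frozen=True)
class ShedPriorInputs:
    """Replicate summaries feeding the Monte-Carlo shedding prior."""

    r_f_mean: float
    r_f_sd: float
    r_t_mean: float
    r_t_sd: float
    dt_min: float = 1440.0
    fs_mean: float = 0.85
    fs_sd: float = 0.1
    fs_bounds: tuple[float, float] = (0.0, 1.0)
    n_iter: int = 10000
    lloq: float = float("nan")  # molecules cell^-1 h^-1

    def __post_init__(self) -> None:
        if self.dt_min <= 0:
            raise ValueError("dt_min must be > 0")
        if self.n_iter < 1000:
            raise ValueError("n_iter must be >= 1000")
        if self.r_t_mean <= 0:
            raise ValueError("r_t mean must be > 0")


def _draw_fs(inp: ShedPriorInputs, rng: np.random.Generator, n: int) -> np.ndarray:
    if inp.fs_sd == 0:
        return np.full(n, inp.fs_mean)
    lo, hi = inp.fs_bounds
    a = (lo - inp.fs_mean) / inp.fs_sd
    b = (hi - inp.fs_mean) / inp.fs_sd
    return stats.truncnorm.rvs(a, b, loc=inp.fs_mean, scale=inp.fs_sd,
                               size=n, random_state=rng)


def estimate_kshed_prior(inp: ShedPriorInputs, seed: int = 0) -> PriorSpec:
    """Monte-Carlo shedding prior from end-point replicate statistics.

    Draws f_s (truncated normal), r_f and r_t (normal) ``n_iter`` times,
    forms k_shed = r_f / (r_t f_s dt) per draw, and summarizes the valid
    (positive, finite) draws as a normal prior on log10 k_shed.
    """
    rng = np.random.default_rng(seed)
    fs = _draw_fs(inp, rng, inp.n_iter)
    rf = rng.normal(inp.r_f_mean, inp.r_f_sd, size=inp.n_iter)
    rt = rng.normal(inp.r_t_mean, inp.r_t_sd, size=inp.n_iter)
    k = rf / (rt * fs * inp.dt_min)
    k = k[np.isfinite(k) & (k > 0)]
    if k.size == 0:
        raise ValueError("all Monte-Carlo k_shed draws were non-positive")
    logk = np.log10(k)
    sigma = float(np.std(logk, ddof=1)) if k.size > 1 else 0.0
    return PriorSpec(kind="lognormal10", mu=float(np.mean(logk)),
                     sigma=max(sigma, 1e-12))


def censored_kshed_prior(inp: ShedPriorInputs, seed: int = 0) -> PriorSpec:
    """Uniform shedding prior for analytes below the assay LLOQ.

    The hourly flux is drawn Uniform(1, LLOQ) molecules cell^-1 h^-1 and
    converted via k_shed = flux / (60 r_t f_s); the min/max sampled
    log10 k_shed become the uniform prior bounds.
    """
    if not inp.lloq > 1:
        raise ValueError("LLOQ must exceed 1 molecule cell^-1 h^-1")
    rng = np.random.default_rng(seed)
    fs = _draw_fs(inp, rng, inp.n_iter)
    rt = (np.full(inp.n_iter, inp.r_t_mean) if inp.r_t_sd == 0
          else rng.normal(inp.r_t_mean, inp.r_t_sd, size=inp.n_iter))
    flux = rng.uniform(1.0, inp.lloq, size=inp.n_iter)
    k = flux / (60.0 * rt * fs)
    k = k[np.isfinite(k) & (k > 0)]
    if k.size == 0:
        raise ValueError("all censored-prior draws were non-positive")
    logk = np.log10(k)
    return PriorSpec(kind="uniform", bounds=(float(logk.min()), float(logk.max())))


def log_prior(theta_log10: np.ndarray, priors: PriorSet) -> float:
    """Joint log-prior of the five kinetic parameters (log10 space)."""
    return priors.kinetic_logpdf(np.asarray(theta_log10, float))


def update_treatment_priors(priors: PriorSet, posterior_samples: np.ndarray,
                            converged: bool = True) -> PriorSet:
    """Build treatment priors from a control posterior.

    Per kinetic parameter, the prior mean becomes the posterior mean of
    the log10 samples and the prior sd twice the posterior sd; uniform
    priors keep their bounds.  ``posterior_samples`` is (n_samples, 5) in
    log10 space (post burn-in, chains pooled).

    An unconverged control posterior is allowed through with a warning —
    downstream summaries flag it.
    """
    if not converged:
        import warnings
        warnings.warn("control chains not converged; treatment priors may "
                      "be unreliable", stacklevel=2)
    S = np.asarray(posterior_samples, float)
    if S.ndim != 2 or S.shape[1] != len(PARAM_NAMES):
        raise ValueError("posterior_samples must be (n, 5) log10 vectors")
    new = {}
    for j, name in enumerate(PARAM_NAMES):
        old = priors.params[name]
        if old.kind == "uniform":
            new[name] = old
            continue
        sd = float(np.std(S[:, j], ddof=1))
        if sd <= 0:
            raise ValueError(f"degenerate control posterior for {name}: sd=0")
        new[name] = PriorSpec(kind="lognormal10", mu=float(np.mean(S[:, j])),
                              sigma=2.0 * sd, bounds=old.bounds)
    return replace(priors, params=new)


def default_prior_set(kshed_prior: PriorSpec | None = None,
                      sigma_p: float = DEFAULT_SIGMA,
                      rt0_mean: float | None = None,
                      rt0_sd: float | None = None,
                      tc_ri0_mean: float = 0.0,
                      tc_rt0_mean: float = 1.0,
                      tc_ic_sd: float = 10.0) -> PriorSet:
    """Literature-anchored prior set.

    ``kshed_prior`` usually comes from :func:`estimate_kshed_prior` or
    :func:`censored_kshed_prior`; a wide default is used when absent.
    Time-course initial-condition priors centre on the first observed
    time point with a deliberately loose sd (normalized units).
    """
    params = {}
    for name in ("P_syn", "k_deg", "k_end", "k_rec"):
        params[name] = PriorSpec(kind="lognormal10", mu=DEFAULT_ANCHORS[name],
                                 sigma=sigma_p, bounds=DEFAULT_BOUNDS[name])
    params["k_shed"] = kshed_prior if kshed_prior is not None else PriorSpec(
        kind="lognormal10", mu=-4.0, sigma=sigma_p,
        bounds=DEFAULT_BOUNDS["k_shed"])
    kw = {}
    if rt0_mean is not None:
        kw["rt0_endpoint"] = PriorSpec(
            kind="truncnormal", mu=rt0_mean,
            sigma=rt0_sd if rt0_sd else 0.1 * rt0_mean,
            bounds=(0.0, math.inf))
    kw["ri0_timecourse"] = PriorSpec(kind="truncnormal", mu=tc_ri0_mean,
                                     sigma=tc_ic_sd, bounds=(0.0, math.inf))
    kw["rt0_timecourse"] = PriorSpec(kind="truncnormal", mu=tc_rt0_mean,
                                     sigma=tc_ic_sd, bounds=(0.0, math.inf))
    return PriorSet(params=params, **kw)
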