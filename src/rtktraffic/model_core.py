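"""Three-compartment receptor trafficking model.

Receptors live on the cell surface (``r_s``), in an internal pool
(``r_i``, lumping endosomes/lysosomes/nucleus), or as shed ectodomain
free in the medium (``r_f``).  Mass-action fluxes connect them:

.. math::

    dr_i/dt &= k_{end} r_s - (k_{rec} + k_{deg}) r_i \\
    dr_s/dt &= P_{syn} + k_{rec} r_i - (k_{end} + k_{shed}) r_s \\
    dr_f/dt &= k_{shed} r_s

``P_syn`` (molecules cell^-1 min^-1) is net synthesis delivered to the
surface; the four first-order rates are in min^-1.  The system is linear,
so trajectories are computed in closed form (eigen-decomposition of the
2x2 ``(r_i, r_s)`` block, with a matrix-exponential fallback for
degenerate spectra) — exact, deterministic, and fast enough to sit inside
an MCMC likelihood.

A pulse-chase variant drops the synthesis term: only receptor labelled at
t=0 is followed, and newly made protein is invisible to the label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm

__all__ = [
    "RateParams",
    "CompartmentState",
    "Trajectory",
    "NoSteadyStateError",
    "simulate_full",
    "simulate_pulse_chase",
    "steady_state",
    "derived_observables",
]

# discriminants below this (relative) size route through the expm fallback
_DEGENERATE_TOL = 1e-12


@dataclass(frozen=True)
class RateParams:
    """The five kinetic unknowns of one receptor under one condition.

    Attributes
    ----------
    P_syn : synthesis flux, molecules cell^-1 min^-1
    k_deg : degradation of the internal pool, min^-1
    k_end : endocytosis (surface -> internal), min^-1
    k_rec : recycling (internal -> surface), min^-1
    k_shed : ectodomain shedding (surface -> medium), min^-1
    """

    P_syn: float
    k_deg: float
    k_end: float
    k_rec: float
    k_shed: float

    def __post_init__(self) -> None:
        for name in ("P_syn", "k_deg", "k_end", "k_rec", "k_shed"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.P_syn, self.k_deg, self.k_end, self.k_rec, self.k_shed])

    def log10(self) -> np.ndarray:
        """log10 of all five values; requires strict positivity."""
        a = self.as_array()
        if np.any(a <= 0):
            raise ValueError("log10 representation requires all rates > 0")
        return np.log10(a)

    @staticmethod
    def from_log10(vec: Sequence[float]) -> "RateParams":
        p, kd, ke, kr, ks = (10.0 ** float(v) for v in vec)
        return RateParams(P_syn=p, k_deg=kd, k_end=ke, k_rec=kr, k_shed=ks)

    def replace(self, **kwargs: float) -> "RateParams":
        d = dict(P_syn=self.P_syn, k_deg=self.k_deg, k_end=self.k_end,
                 k_rec=self.k_rec, k_shed=self.k_shed)
        d.update(kwargs)
        return RateParams(**d)


@dataclass(frozen=True)
class CompartmentState:
    """Amounts in each compartment at one time point (molecules/cell or
    normalized label units)."""

    r_s: float
    r_i: float
    r_f: float = 0.0

    def __post_init__(self) -> None:
        for name in ("r_s", "r_i", "r_f"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    @property
    def r_t(self) -> float:
        """Total cell-associated receptor (lysate proxy)."""
        return self.r_s + self.r_i


@dataclass(frozen=True)
class Trajectory:
    """Solution of the trafficking system on a time grid (minutes)."""

    times: np.ndarray
    r_s: np.ndarray
    r_i: np.ndarray
    r_f: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.r_s) == len(self.r_i) == len(self.r_f) == n):
            raise ValueError("trajectory arrays must share one length")

    @property
    def r_t(self) -> np.ndarray:
        return self.r_s + self.r_i

    def state_at(self, idx: int) -> CompartmentState:
        return CompartmentState(r_s=max(self.r_s[idx], 0.0),
                                r_i=max(self.r_i[idx], 0.0),
                                r_f=max(self.r_f[idx], 0.0))

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: columns time_min, r_s, r_i, r_f, r_t."""
        return pd.DataFrame({
            "time_min": self.times, "r_s": self.r_s, "r_i": self.r_i,
            "r_f": self.r_f, "r_t": self.r_t,
        })


class NoSteadyStateError(ValueError):
    """Raised when the cellular pool has no finite fixed point."""


def _check_times(times: np.ndarray) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if t[0] < 0 or np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing with times[0] >= 0")
    return t


def _phi(lam: float, t: np.ndarray) -> np.ndarray:
    """Integral of exp(lam*s) over [0, t]."""
    if lam == 0.0:
        return t.copy()
    return np.expm1(lam * t) / lam


def _solve_linear(params: RateParams, init: CompartmentState,
                  times: np.ndarray, synthesis: bool) -> Trajectory:
    """Exact solution of the (r_i, r_s) block plus quadrature for r_f."""
    kd, ke, kr, ks = params.k_deg, params.k_end, params.k_rec, params.k_shed
    psyn = params.P_syn if synthesis else 0.0

    # x = (r_i, r_s); dx/dt = A x + b
    a11, a12 = -(kr + kd), ke
    a21, a22 = kr, -(ke + ks)
    tr, det = a11 + a22, a11 * a22 - a12 * a21
    disc = tr * tr - 4.0 * det  # = (a11-a22)^2 + 4 ke kr >= 0
    scale = max(abs(a11), abs(a12), abs(a21), abs(a22), 1e-300)

    if disc < _DEGENERATE_TOL * scale * scale or (det == 0.0 and psyn != 0.0):
        return _solve_expm(params, init, times, psyn)

    sq = math.sqrt(max(disc, 0.0))
    l1, l2 = 0.5 * (tr + sq), 0.5 * (tr - sq)

    # particular (fixed-point) solution; for psyn == 0 it is the origin
    if psyn == 0.0:
        xp_i = xp_s = 0.0
    else:
        # x_p = -A^{-1} b with b = (0, psyn)
        xp_i = a12 * psyn / det
        xp_s = -a11 * psyn / det

    yi0, ys0 = init.r_i - xp_i, init.r_s - xp_s

    # eigenvectors via (A - l I) v = 0; components chosen to avoid the
    # cancellation-prone row when a12 or a21 vanish
    def _eigvec(lam: float) -> tuple[float, float]:
        if abs(a12) >= abs(a21):
            return (a12, lam - a11) if abs(a12) > 0 or lam != a11 else (1.0, 0.0)
        return (lam - a22, a21)

    v1i, v1s = _eigvec(l1)
    v2i, v2s = _eigvec(l2)
    den = v1i * v2s - v2i * v1s
    if abs(den) < 1e-300:
        return _solve_expm(params, init, times, psyn)
    c1 = (yi0 * v2s - ys0 * v2i) / den
    c2 = (ys0 * v1i - yi0 * v1s) / den

    e1, e2 = np.exp(l1 * times), np.exp(l2 * times)
    r_i = c1 * v1i * e1 + c2 * v2i * e2 + xp_i
    r_s = c1 * v1s * e1 + c2 * v2s * e2 + xp_s
    int_rs = c1 * v1s * _phi(l1, times) + c2 * v2s * _phi(l2, times) + xp_s * times
    r_f = init.r_f + ks * int_rs
    return Trajectory(times=times, r_s=r_s, r_i=r_i, r_f=r_f)


def _solve_expm(params: RateParams, init: CompartmentState,
                times: np.ndarray, psyn: float) -> Trajectory:
    """Augmented matrix exponential; exact also for defective spectra."""
    kd, ke, kr, ks = params.k_deg, params.k_end, params.k_rec, params.k_shed
    # state (r_i, r_s, r_f, 1)
    M = np.array([
        [-(kr + kd), ke, 0.0, 0.0],
        [kr, -(ke + ks), 0.0, psyn],
        [0.0, ks, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.0],
    ])
    x0 = np.array([init.r_i, init.r_s, init.r_f, 1.0])
    out = np.empty((len(times), 4))
    for j, t in enumerate(times):
        out[j] = expm(M * t) @ x0
    return Trajectory(times=times, r_s=out[:, 1], r_i=out[:, 0], r_f=out[:, 2])


def simulate_full(params: RateParams, init: CompartmentState,
                  times: Sequence[float]) -> Trajectory:
    """Simulate the full (synthesizing) system from ``init`` at ``times``."""
    return _solve_linear(params, init, _check_times(np.asarray(times, float)),
                         synthesis=True)


def simulate_pulse_chase(params: RateParams, init: CompartmentState,
                         times: Sequence[float]) -> Trajectory:
    """Simulate the biotin-labelled pool: synthesis does not add label, so
    the homogeneous system is solved and total label r_t is non-increasing."""
    return _solve_linear(params, init, _check_times(np.asarray(times, float)),
                         synthesis=False)


def drain_rate(params: RateParams) -> float:
    """Net first-order loss rate from the cellular (r_s + r_i) pool at the
    fixed point; positive iff a finite steady state exists."""
    kd, ke, kr, ks = params.k_deg, params.k_end, params.k_rec, params.k_shed
    if kr + kd == 0.0:
        # internal pool only accumulates; finite only if nothing enters it
        return ks if ke == 0.0 else 0.0
    return ke + ks - ke * kr / (kr + kd)


def steady_state(params: RateParams) -> CompartmentState:
    """Fixed point of the cellular pools.

    r_f has no fixed point (the medium pool only grows); the returned r_f
    is the steady shedding rate k_shed * r_s* in molecules cell^-1 min^-1.
    """
    if params.P_syn <= 0:
        raise NoSteadyStateError("steady state requires P_syn > 0")
    d = drain_rate(params)
    if d <= 0:
        raise NoSteadyStateError(
            "no finite steady state: net drain from the cellular pool is "
            f"{d:g} min^-1 (must be > 0)")
    r_s = params.P_syn / d
    kd, ke, kr = params.k_deg, params.k_end, params.k_rec
    r_i = ke * r_s / (kr + kd) if (kr + kd) > 0 else 0.0
    return CompartmentState(r_s=r_s, r_i=r_i, r_f=params.k_shed * r_s)


def steady_surface_fraction(params: RateParams) -> float:
    """Surface fraction f_s = r_s*/(r_s* + r_i*) at the fixed point.

    Depends only on k_end/(k_rec + k_deg), so it is defined even when
    P_syn = 0 (take a unit surface pool).
    """
    kd, ke, kr = params.k_deg, params.k_end, params.k_rec
    if kr + kd == 0.0:
        return 1.0 if ke == 0.0 else 0.0
    ratio = ke / (kr + kd)  # r_i*/r_s*
    return 1.0 / (1.0 + ratio)


def derived_observables(traj: Trajectory) -> pd.DataFrame:
    """Per-time observables used for comparison with measurements:
    lysate proxy r_t, supernatant proxy r_f, percent shed r_f/r_t and
    surface fraction r_s/r_t."""
    r_t = traj.r_t
    if np.any(r_t <= 0):
        raise ValueError("percent shed undefined: r_t must be > 0 at all "
                         "queried times")
    return pd.DataFrame({
        "time_min": traj.times,
        "r_t": r_t,
        "r_f": traj.r_f,
        "percent_shed": traj.r_f / r_t,
        "surface_fraction": traj.r_s / r_t,
    })
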