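"""Absolute receptor quantification from bead-ELISA readouts.

Raw median-fluorescence readouts (MFU) are mapped to analyte mass through
a five-parameter logistic (5PL) standard curve fit to recombinant-protein
standards, then converted to molecules/cell using the total-protein
content of the lysate and a per-cell protein estimate (300 pg/cell).
The assay's lower limit of quantitation (LLOQ) is the lowest standard
that clears a 5x-background rule and back-fits to within 20% of its true
concentration.  A per-batch control offset aligns in-experiment medians
to the absolute reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "StandardCurve",
    "QuantContext",
    "FitFailure",
    "fit_5pl",
    "invert_5pl",
    "mass_to_molecules",
    "compute_lloq",
    "apply_control_offset",
]

AVOGADRO = 6.022e23  # mol^-1
_PG_PER_G = 1e12


class FitFailure(RuntimeError):
    """Standard-curve regression failed to converge or is degenerate."""


def five_pl(x: np.ndarray, a: float, d: float, c: float, b: float, g: float) -> np.ndarray:
    """y = d + (a - d) / (1 + (x/c)^b)^g  with a the low-dose asymptote."""
    return d + (a - d) / (1.0 + (x / c) ** b) ** g


@dataclass
class StandardCurve:
    """A fitted 5PL calibration curve plus the raw standards behind it.

    ``concentration_grid`` holds the standard concentrations (pg, strictly
    increasing), ``readouts`` the replicate MFU per standard (2-D,
    standards x replicates), ``background`` the blank-well MFU.
    """

    a: float
    d: float
    c: float
    b: float
    g: float
    concentration_grid: np.ndarray
    readouts: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.zeros(0))
    residual_norm: float = float("nan")

    def __post_init__(self) -> None:
        self.concentration_grid = np.asarray(self.concentration_grid, float)
        self.readouts = np.atleast_2d(np.asarray(self.readouts, float))
        self.background = np.asarray(self.background, float)
        if self.c <= 0:
            raise ValueError("inflection concentration c must be > 0")
        if np.any(self.concentration_grid <= 0) or np.any(
                np.diff(self.concentration_grid) <= 0):
            raise ValueError("concentration_grid must be positive and increasing")
        if not np.all(np.isfinite(self.readouts)):
            raise ValueError("readouts must be finite")

    def predict(self, conc: np.ndarray) -> np.ndarray:
        return five_pl(np.asarray(conc, float), self.a, self.d, self.c, self.b, self.g)


@dataclass(frozen=True)
class QuantContext:
    """Everything needed to turn an analyte mass into molecules/cell."""

    m_r: float            # analyte mass in the well, pg
    dil: float            # inverse of the measured fraction of the sample
    c_prot: float         # lysate total protein concentration, pg/uL
    MW_RTK: float         # standard molecular weight, g/mol
    v_lys: float          # lysate volume, uL
    prot_cell: float = 300.0  # protein per cell, pg/cell
    n_avg: float = AVOGADRO

    def __post_init__(self) -> None:
        for name in ("dil", "c_prot", "MW_RTK", "v_lys", "prot_cell", "n_avg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.m_r < 0:
            raise ValueError("m_r must be >= 0")


def _initial_guesses(x: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    a0, d0 = float(y[0]), float(y[-1])
    c0 = float(np.exp(np.mean(np.log(x))))
    base = np.array([a0, d0, c0, 1.0 if d0 >= a0 else -1.0, 1.0])
    yield base
    for _ in range(10):
        jitter = rng.normal(1.0, 0.3, size=5)
        cand = base * jitter
        cand[2] = abs(cand[2]) or c0
        cand[4] = abs(cand[4]) or 1.0
        yield cand


def fit_5pl(concentration_grid, readouts, background=(), seed: int = 0) -> StandardCurve:
    """Least-squares 5PL fit with jittered multi-start.

    Parameters
    ----------
    concentration_grid : standard concentrations (pg), >= 6 points
    readouts : MFU, shape (n_standards,) or (n_standards, n_replicates)
    background : blank-well MFU (kept on the curve for LLOQ rules)
    """
    x = np.asarray(concentration_grid, float)
    Y = np.atleast_2d(np.asarray(readouts, float).T).T
    if Y.ndim == 1:
        Y = Y[:, None]
    if x.size < 6:
        raise ValueError("need >= 6 standard points spanning the dynamic range")
    y = Y.mean(axis=1)
    if np.ptp(y) == 0:
        raise FitFailure("constant readouts: 5PL fit is degenerate")

    rng = np.random.default_rng(seed)
    best, best_res = None, math.inf
    for p0 in _initial_guesses(x, y, rng):
        try:
            popt, _ = curve_fit(
                five_pl, x, y, p0=p0, maxfev=20000,
                bounds=([-np.inf, -np.inf, 1e-12, -np.inf, 1e-6],
                        [np.inf, np.inf, np.inf, np.inf, np.inf]))
        except (RuntimeError, ValueError):
            continue
        res = float(np.linalg.norm(five_pl(x, *popt) - y))
        if res < best_res:
            best, best_res = popt, res
    if best is None:
        raise FitFailure("5PL regression did not converge from any start")
    a, d, c, b, g = (float(v) for v in best)
    return StandardCurve(a=a, d=d, c=c, b=b, g=g, concentration_grid=x,
                         readouts=Y, background=np.asarray(background, float),
                         residual_norm=best_res)


def invert_5pl(curve: StandardCurve, mfu: float) -> float:
    """Analytic inverse of the 5PL: concentration (pg) for a readout.

    Readouts outside the open interval between the asymptotes are censored
    (returns ``nan``).
    """
    lo, hi = min(curve.a, curve.d), max(curve.a, curve.d)
    if not (lo < mfu < hi):
        return float("nan")
    ratio = (curve.a - curve.d) / (mfu - curve.d)
    inner = ratio ** (1.0 / curve.g) - 1.0
    if inner <= 0:
        return float("nan")
    return float(curve.c * inner ** (1.0 / curve.b))


def mass_to_molecules(ctx: QuantContext) -> float:
    """Convert analyte mass to receptors per cell.

    r = m_r * dil * prot_cell * N_A / (c_prot * MW * v_lys), with the pg
    masses converted to grams so the mole count is correct.  The lysate's
    total protein c_prot * v_lys divided by prot_cell counts the cells the
    well represents.
    """
    grams = ctx.m_r / _PG_PER_G
    molecules = grams / ctx.MW_RTK * ctx.n_avg
    cells = (ctx.c_prot * ctx.v_lys) / ctx.prot_cell
    return molecules * ctx.dil / cells


def compute_lloq(curve: StandardCurve, *, to_rate=None) -> float:
    """Lowest quantifiable standard concentration.

    A standard qualifies if (1) its mean readout exceeds 5x the mean
    background and (2) its back-fit concentration is within 20% of truth.
    Returns the lowest qualifying concentration (pg), or passes it through
    ``to_rate`` (e.g. a molecules cell^-1 h^-1 conversion) when given.
    """
    if curve.background.size == 0:
        raise ValueError("background wells required for LLOQ determination")
    bg = float(np.mean(curve.background))
    means = curve.readouts.mean(axis=1)
    order = np.argsort(curve.concentration_grid)
    for idx in order:
        conc = float(curve.concentration_grid[idx])
        if not means[idx] > 5.0 * bg:
            continue
        back = invert_5pl(curve, float(means[idx]))
        if not math.isfinite(back):
            continue
        if abs(back - conc) <= 0.20 * conc:
            return float(to_rate(conc)) if to_rate is not None else conc
    raise FitFailure("assay not quantitative: no standard passes the "
                     "5x-background and 20% back-fit rules")


def apply_control_offset(values: np.ndarray, control_median: float,
                         reference_absolute: float) -> np.ndarray:
    """Scale a batch by reference/control fold change.

    Aligns every measurement in the batch (all treatments) so the
    in-experiment control median lands on the absolute reference value.
    Not idempotent — the pipeline applies it exactly once per batch.
    """
    if control_median <= 0:
        raise ValueError("control median must be > 0")
    return np.asarray(values, float) * (reference_absolute / control_median)
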