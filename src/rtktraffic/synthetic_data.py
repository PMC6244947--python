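"""Ground-truth-parameterized synthetic studies.

Emulates the study design the pipeline expects so every stage can be
exercised (and parameter recovery scored) without any measured data:

* four receptor analogs with trafficking rates in physiologically
  plausible regimes — abundances of 1e5–1e6 molecules/cell, roughly
  0.4–4% of lysate shed per hour, a surface fraction near 0.85;
* treatment presets as multiplicative effects on the control rates,
  mirroring the qualitative direction of EGF stimulation (endocytosis
  up), a metalloprotease inhibitor (shedding down), Mek inhibition
  (synthesis up, degradation and endocytosis down for two receptors) and
  Erk inhibition (synthesis up only);
* 24-h end-point lysate/supernatant replicates (n = 12) and pulse-chase
  time-course total/internal replicates (n = 18 per time point) at 5,
  20, 45, 75, 90 min, normalized to the mean total label at the first
  time point;
* log-normal measurement noise (normal on log10 values) with one sd per
  experiment type, matching the likelihood's assumption, plus an
  optional misspecified raw-additive mode for robustness checks;
* below-LLOQ censoring of end-point supernatant values;
* 5PL standard curves with background wells for the quantification
  stage.

Everything is a pure function of (Scenario, seed).
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import ExperimentSet
from .model_core import (CompartmentState, RateParams, simulate_full,
                         simulate_pulse_chase, steady_state,
                         steady_surface_fraction)
from .quantify import five_pl

__all__ = ["Scenario", "generate_endpoint", "generate_timecourse",
           "generate_standard_curve", "make_study", "scenario_preset"]

TIME_POINTS = (5.0, 20.0, 45.0, 75.0, 90.0)

#: control kinetics per receptor analog.  Rates give a steady-state
#: surface fraction of 0.85 (k_end/(k_rec+k_deg) = 3/17) except the
#: met-like analog, which turns over faster; P_syn sets abundances at
#: the 1e5–1e6 molecules/cell scale.  k_shed spans sub-LLOQ (her2-like)
#: to ~4%/h (met-like).
CONTROL_PARAMS = {
    "rtkA_axl": RateParams(P_syn=500.0, k_deg=0.010, k_end=0.0030,
                           k_rec=0.0070, k_shed=3.0e-4),
    "rtkB_met": RateParams(P_syn=800.0, k_deg=0.020, k_end=0.0080,
                           k_rec=0.0060, k_shed=1.0e-3),
    "rtkC_egfr": RateParams(P_syn=300.0, k_deg=0.008, k_end=0.0025,
                            k_rec=0.0060, k_shed=2.0e-4),
    "rtkD_her2": RateParams(P_syn=60.0, k_deg=0.012, k_end=0.0030,
                            k_rec=0.0070, k_shed=2.0e-6),
}

#: treatment presets: rtk -> {param -> multiplicative effect}; "*" keys
#: apply to every receptor.
TREATMENT_EFFECTS = {
    "control": {},
    "egf_like": {"rtkC_egfr": {"k_end": 3.0}, "rtkD_her2": {"k_end": 3.0}},
    "batimastat_like": {"*": {"k_shed": 0.2}},
    "mek_like": {"rtkA_axl": {"P_syn": 2.5, "k_deg": 0.6, "k_end": 0.7},
                 "rtkD_her2": {"P_syn": 2.5, "k_deg": 0.6, "k_end": 0.7}},
    "erk_tki_like": {"rtkA_axl": {"P_syn": 2.0}, "rtkD_her2": {"P_syn": 2.0}},
}

DEFAULT_SIGMAS = {
    "endpoint_lysate": 0.10,
    "endpoint_supernatant": 0.15,
    "timecourse_total": 0.05,
    "timecourse_internal": 0.08,
}


@dataclass(frozen=True)
class Scenario:
    """One synthetic study: receptors, treatments, noise and design."""

    name: str
    control_params: dict = field(default_factory=lambda: dict(CONTROL_PARAMS))
    effects: dict = field(default_factory=dict)  # rtk -> {param -> factor}
    sigmas: dict = field(default_factory=lambda: dict(DEFAULT_SIGMAS))
    n_endpoint: int = 12
    n_timecourse: int = 18
    time_points: tuple = TIME_POINTS
    endpoint_dt: float = 1440.0
    lloq_rate: float = 89.0     # molecules cell^-1 h^-1
    noise_mode: str = "lognormal"  # or "additive" (misspecified)
    seed: int = 0

    def __post_init__(self) -> None:
        for eff in self.effects.values():
            for f in eff.values():
                if f <= 0:
                    raise ValueError("treatment effects must be > 0")
        if self.noise_mode not in ("lognormal", "additive"):
            raise ValueError("noise_mode must be 'lognormal' or 'additive'")

    @property
    def lloq_endpoint(self) -> float:
        """Censoring threshold in molecules/cell over the end-point window."""
        return self.lloq_rate * self.endpoint_dt / 60.0

    def params_for(self, rtk: str) -> RateParams:
        base = self.control_params[rtk]
        eff = dict(self.effects.get("*", {}))
        eff.update(self.effects.get(rtk, {}))
        if not eff:
            return base
        return base.replace(**{k: getattr(base, k) * v for k, v in eff.items()})


def scenario_preset(treatment: str, seed: int = 0, **overrides) -> Scenario:
    """Build a preset scenario ('control', 'egf_like', 'batimastat_like',
    'mek_like', 'erk_tki_like')."""
    if treatment not in TREATMENT_EFFECTS:
        raise KeyError(f"unknown preset {treatment!r}; choose from "
                       f"{sorted(TREATMENT_EFFECTS)}")
    return Scenario(name=treatment, effects=dict(TREATMENT_EFFECTS[treatment]),
                    seed=seed, **overrides)


def _rng_for(sc: Scenario, rtk: str, treatment: str, stage: str) -> np.random.Generator:
    rtk_i = sorted(sc.control_params).index(rtk)
    stage_i = {"endpoint": 0, "timecourse": 1, "curve": 2}[stage]
    treat_i = zlib.crc32(treatment.encode()) % (2 ** 16)
    return np.random.default_rng(
        np.random.SeedSequence([sc.seed, rtk_i, stage_i, treat_i]))


def _noisy(truth: float, sd: float, n: int, rng: np.random.Generator,
           mode: str) -> np.ndarray:
    if sd == 0 or truth == 0:
        return np.full(n, truth)
    if mode == "lognormal":
        return 10.0 ** (math.log10(truth) + rng.normal(0.0, sd, n))
    # misspecified: additive normal with matched CV
    cv = math.sqrt(10.0 ** (sd * sd * math.log(10.0)) - 1.0)
    return np.clip(rng.normal(truth, cv * truth, n), 1e-12, None)


def endpoint_truth(sc: Scenario, rtk: str) -> tuple[float, float]:
    """Noise-free 24-h lysate and supernatant under treatment kinetics.

    Cells start at the *control* steady state (treatment begins at t=0)
    and evolve under the treated parameters for the end-point window.
    """
    control = sc.control_params[rtk]
    treated = sc.params_for(rtk)
    ss = steady_state(control)
    init = CompartmentState(r_s=ss.r_s, r_i=ss.r_i, r_f=0.0)
    traj = simulate_full(treated, init, [sc.endpoint_dt])
    return float(traj.r_t[0]), float(traj.r_f[0])


def timecourse_truth(sc: Scenario, rtk: str) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free pulse-chase total/internal label, pre-normalization.

    The label starts on the surface pool only (surface biotinylation,
    unit label); the absolute label scale cancels after normalization to
    the first time point, so only the kinetics matter.
    """
    treated = sc.params_for(rtk)
    init = CompartmentState(r_s=1.0, r_i=0.0, r_f=0.0)
    traj = simulate_pulse_chase(treated, init, np.asarray(sc.time_points))
    return traj.r_t, traj.r_i


def generate_endpoint(sc: Scenario, rtk: str, treatment: str | None = None):
    """Replicated 24-h end-point measurements (molecules/cell).

    Returns ``(lysate, supernatant, censored)`` arrays of length
    ``n_endpoint``; ``censored`` flags supernatant replicates whose
    noise-free truth sits below the LLOQ (their recorded values are the
    threshold itself, as a real assay would report).
    """
    treatment = treatment or sc.name
    rng = _rng_for(sc, rtk, treatment, "endpoint")
    rt, rf = endpoint_truth(sc, rtk)
    lys = _noisy(rt, sc.sigmas["endpoint_lysate"], sc.n_endpoint, rng,
                 sc.noise_mode)
    sup = _noisy(rf, sc.sigmas["endpoint_supernatant"], sc.n_endpoint, rng,
                 sc.noise_mode)
    censored = sup < sc.lloq_endpoint
    sup = np.where(censored, sc.lloq_endpoint, sup)
    return lys, sup, censored


def generate_timecourse(sc: Scenario, rtk: str, treatment: str | None = None):
    """Replicated pulse-chase measurements, normalized to the mean total
    label at the first time point.

    Returns ``(times, total, internal)`` with the value arrays shaped
    (n_times, n_timecourse).
    """
    treatment = treatment or sc.name
    rng = _rng_for(sc, rtk, treatment, "timecourse")
    rt, ri = timecourse_truth(sc, rtk)
    n, nt = sc.n_timecourse, len(sc.time_points)
    total = np.empty((nt, n))
    internal = np.empty((nt, n))
    for k in range(nt):
        total[k] = _noisy(float(rt[k]), sc.sigmas["timecourse_total"], n,
                          rng, sc.noise_mode)
        internal[k] = _noisy(float(ri[k]), sc.sigmas["timecourse_internal"],
                             n, rng, sc.noise_mode)
    norm = total[0].mean()
    return np.asarray(sc.time_points), total / norm, internal / norm


def generate_standard_curve(a: float, d: float, c: float, b: float, g: float,
                            concentrations, noise_sd: float = 0.0,
                            n_background: int = 8, background_level: float = 30.0,
                            seed: int = 0):
    """Synthetic 5PL calibration data.

    Returns a tidy DataFrame with columns analyte, concentration_pg, mfu,
    is_background (background rows carry concentration 0).
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(concentrations, float)
    y = five_pl(x, a, d, c, b, g)
    if noise_sd > 0:
        y = y * (1.0 + rng.normal(0.0, noise_sd, y.size))
    bg = np.full(n_background, background_level)
    if noise_sd > 0:
        bg = bg * (1.0 + rng.normal(0.0, noise_sd, n_background))
    rows = [{"analyte": "standard", "concentration_pg": xv, "mfu": yv,
             "is_background": False} for xv, yv in zip(x, y)]
    rows += [{"analyte": "standard", "concentration_pg": 0.0, "mfu": bv,
              "is_background": True} for bv in bg]
    return pd.DataFrame(rows)


def make_experiment_set(sc: Scenario, rtk: str, sigmas: dict | None = None,
                        treatment: str | None = None) -> ExperimentSet:
    """Bundle one receptor/treatment into the inference container."""
    treatment = treatment or sc.name
    lys, sup, cen = generate_endpoint(sc, rtk, treatment)
    times, total, internal = generate_timecourse(sc, rtk, treatment)
    # noiseless scenarios still need a positive likelihood scale
    sigma = {k: max(v, 1e-6) for k, v in (sigmas or sc.sigmas).items()}
    return ExperimentSet(
        endpoint_lysate=lys, endpoint_supernatant=sup,
        timecourse_times=times, timecourse_total=total,
        timecourse_internal=internal,
        sigma=sigma,
        endpoint_dt=sc.endpoint_dt,
        lloq_endpoint=sc.lloq_endpoint,
        supernatant_censored=cen,
        rtk=rtk, treatment=treatment, cell_line="synthetic")


def make_study(sc: Scenario, rtks: list | None = None) -> dict:
    """Full dataset bundle for one scenario.

    Returns ``{"datasets": {rtk: ExperimentSet}, "manifest": {...}}``
    where the manifest records the ground-truth parameters and noise-free
    observables for recovery scoring.
    """
    rtks = rtks or sorted(sc.control_params)
    datasets, manifest = {}, {"scenario": sc.name, "seed": sc.seed, "rtks": {}}
    for rtk in rtks:
        datasets[rtk] = make_experiment_set(sc, rtk)
        truth = sc.params_for(rtk)
        rt, rf = endpoint_truth(sc, rtk)
        manifest["rtks"][rtk] = {
            "params": {"P_syn": truth.P_syn, "k_deg": truth.k_deg,
                       "k_end": truth.k_end, "k_rec": truth.k_rec,
                       "k_shed": truth.k_shed},
            "log10_params": list(truth.log10()),
            "endpoint_lysate_truth": rt,
            "endpoint_supernatant_truth": rf,
            "surface_fraction": steady_surface_fraction(truth),
        }
    return {"datasets": datasets, "manifest": manifest}


def write_study(bundle: dict, out_dir) -> None:
    """Write the CSV dialects plus the ground-truth manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ep_rows, tc_rows = [], []
    for rtk, ds in bundle["datasets"].items():
        for r, (ly, su, ce) in enumerate(zip(ds.endpoint_lysate,
                                             ds.endpoint_supernatant,
                                             ds.supernatant_censored)):
            ep_rows.append({"cell_line": ds.cell_line, "treatment": ds.treatment,
                            "rtk": rtk, "compartment": "lysate",
                            "replicate": r, "value": ly, "censored": False})
            ep_rows.append({"cell_line": ds.cell_line, "treatment": ds.treatment,
                            "rtk": rtk, "compartment": "supernatant",
                            "replicate": r, "value": su, "censored": bool(ce)})
        for k, t in enumerate(ds.timecourse_times):
            for r in range(ds.timecourse_total.shape[1]):
                tc_rows.append({"cell_line": ds.cell_line,
                                "treatment": ds.treatment, "rtk": rtk,
                                "time_min": t, "replicate": r,
                                "total": ds.timecourse_total[k, r],
                                "internal": ds.timecourse_internal[k, r]})
    pd.DataFrame(ep_rows).to_csv(out / "endpoint.csv", index=False)
    pd.DataFrame(tc_rows).to_csv(out / "timecourse.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle["manifest"], fh, indent=2)
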