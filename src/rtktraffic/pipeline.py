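"""End-to-end orchestration: simulate -> priors -> fit -> predict -> pca.

A :class:`PipelineConfig` (YAML-serializable) fixes the scenario, the
receptors, the sampler settings and one global seed; every stochastic
stage derives its own seed deterministically from it, so a config + seed
pair reproduces the run bit for bit.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .inference import (AMConfig, ExperimentSet, estimate_sigmas,
                        fit_condition)
from .predict import (overlap_fraction, posterior_mean_params,
                      resample_envelope, single_param_substitution)
from .priors import (PriorSet, ShedPriorInputs, censored_kshed_prior,
                     default_prior_set, estimate_kshed_prior,
                     update_treatment_priors, PARAM_NAMES)
from .reprogramming_pca import build_matrix, run_pca, zscore_by_cellline
from .synthetic_data import (Scenario, make_experiment_set, scenario_preset,
                             write_study, make_study)

log = logging.getLogger("rtktraffic")

__all__ = ["PipelineConfig", "run_pipeline", "validate_tables",
           "build_condition_priors"]


@dataclass
class PipelineConfig:
    """Settings for one synthetic-study pipeline run."""

    scenario: str = "mek_like"
    rtks: tuple = ("rtkA_axl", "rtkB_met")
    out_dir: str = "results/pipeline"
    seed: int = 0
    n_starts: int = 24
    n_iter: int = 8000
    burn_in: int = 2000
    n_chains: int = 4
    overlap_cut: float = 0.25
    resample_fraction: float = 0.10
    init_mode: str = "sampled"
    max_poll_iter: int = 200

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in PipelineConfig.__dataclass_fields__}
        extra = set(raw) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        if "rtks" in raw:
            raw["rtks"] = tuple(raw["rtks"])
        return PipelineConfig(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["rtks"] = list(d["rtks"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)


def build_condition_priors(control_ds: ExperimentSet, seed: int) -> PriorSet:
    """Data-derived k_shed prior + literature anchors for one receptor."""
    sup = control_ds.endpoint_supernatant
    cen = control_ds.supernatant_censored
    lys = control_ds.endpoint_lysate
    inp = ShedPriorInputs(
        r_f_mean=float(np.mean(sup)), r_f_sd=float(np.std(sup, ddof=1)),
        r_t_mean=float(np.mean(lys)), r_t_sd=float(np.std(lys, ddof=1)),
        dt_min=control_ds.endpoint_dt,
        lloq=control_ds.lloq_endpoint * 60.0 / control_ds.endpoint_dt)
    if np.mean(cen) > 0.5:
        kshed = censored_kshed_prior(inp, seed=seed)
    else:
        kshed = estimate_kshed_prior(inp, seed=seed)
    return default_prior_set(
        kshed_prior=kshed,
        rt0_mean=float(np.mean(lys)), rt0_sd=float(np.std(lys, ddof=1)),
        tc_ri0_mean=control_ds.tc_internal_t0_mean,
        tc_rt0_mean=control_ds.tc_total_t0_mean)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; write artifacts and a run manifest.

    Returns the manifest dict (also written as ``run_manifest.json``).
    """
    t_start = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")

    control_only = cfg.scenario == "control"
    treatments = ["control"] if control_only else ["control", cfg.scenario]

    # --- simulate -----------------------------------------------------
    scenarios = {tr: scenario_preset(tr, seed=cfg.seed) for tr in treatments}
    raw = {(tr, r): make_experiment_set(scenarios[tr], r)
           for tr in treatments for r in cfg.rtks}
    sigmas = estimate_sigmas(list(raw.values()))
    datasets = {k: make_experiment_set(scenarios[k[0]], k[1], sigmas=sigmas)
                for k in raw}
    for tr in treatments:
        write_study(make_study(scenarios[tr], rtks=list(cfg.rtks)),
                    out / "data" / tr)
    log.info("simulated %d conditions; sigmas=%s", len(datasets), sigmas)

    # --- fit ----------------------------------------------------------
    am = dict(n_iter=cfg.n_iter, burn_in=cfg.burn_in, n_chains=cfg.n_chains)
    fits, summaries = {}, {}
    prior_sets = {}
    for i, r in enumerate(cfg.rtks):
        priors = build_condition_priors(datasets[("control", r)], seed=cfg.seed + 17 * i)
        prior_sets[("control", r)] = priors
        fit = fit_condition(datasets[("control", r)], priors,
                            AMConfig(seed=cfg.seed + 1000 + i, **am),
                            n_starts=cfg.n_starts, init_mode=cfg.init_mode,
                            max_poll_iter=cfg.max_poll_iter)
        fits[("synthetic", "control", r)] = fit
        summaries[f"control/{r}"] = fit.summary()
        for tr in treatments[1:]:
            tpriors = update_treatment_priors(priors, fit.kinetic_samples(),
                                              converged=fit.converged)
            prior_sets[(tr, r)] = tpriors
            tfit = fit_condition(datasets[(tr, r)], tpriors,
                                 AMConfig(seed=cfg.seed + 2000 + i, **am),
                                 n_starts=cfg.n_starts, init_mode=cfg.init_mode,
                                 max_poll_iter=cfg.max_poll_iter)
            fits[("synthetic", tr, r)] = tfit
            summaries[f"{tr}/{r}"] = tfit.summary()
    _write_fits(fits, out / "fits")

    # --- predict ------------------------------------------------------
    attribution_frames, overlap_rows = [], []
    if not control_only:
        tr = cfg.scenario
        for r in cfg.rtks:
            ctrl = fits[("synthetic", "control", r)]
            trt = fits[("synthetic", tr, r)]
            rt0 = ctrl.posterior.data.rt0_ref
            attr = single_param_substitution(
                posterior_mean_params(ctrl.kinetic_samples()),
                posterior_mean_params(trt.kinetic_samples()), rt0)
            attribution_frames.append(attr.to_frame(rtk=r, treatment=tr))
            for j, p in enumerate(PARAM_NAMES):
                ov = overlap_fraction(ctrl.kinetic_samples()[:, j],
                                      trt.kinetic_samples()[:, j],
                                      seed=cfg.seed + 31 * j)
                overlap_rows.append({"rtk": r, "treatment": tr,
                                     "parameter": p, "overlap": ov})
        pd.concat(attribution_frames).to_csv(out / "attribution.csv",
                                             index=False)
        pd.DataFrame(overlap_rows).to_csv(out / "overlap.csv", index=False)
        env = resample_envelope(
            fits[("synthetic", tr, cfg.rtks[0])].posterior,
            fits[("synthetic", tr, cfg.rtks[0])].chains,
            fraction=cfg.resample_fraction, seed=cfg.seed + 7)
        with open(out / "envelope.json", "w") as fh:
            json.dump({k: {"min": np.asarray(v["min"]).tolist(),
                           "max": np.asarray(v["max"]).tolist()}
                       for k, v in env.items()}, fh, indent=2)
    else:
        log.info("control-only run: predict and pca stages skipped")

    # --- pca ----------------------------------------------------------
    pca_out = {}
    if not control_only:
        for mode in ("param_means", "fold_change"):
            M = build_matrix(fits, mode=mode, overlap_cut=cfg.overlap_cut,
                             fraction=cfg.resample_fraction, seed=cfg.seed)
            Z = zscore_by_cellline(M)
            scores, loadings, evr = run_pca(Z)
            scores.to_csv(out / f"pca_{mode}_scores.csv")
            loadings.to_csv(out / f"pca_{mode}_loadings.csv")
            pca_out[mode] = {"explained_variance_ratio": evr.tolist()}

    manifest = {
        "config": {**asdict(cfg), "rtks": list(cfg.rtks)},
        "sigmas": sigmas,
        "fit_summaries": summaries,
        "rhat_table": {k: v["rhat"] for k, v in summaries.items()},
        "pca": pca_out,
        "runtime_s": round(time.time() - t_start, 2),
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest


def _write_fits(fits: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for (cl, tr, r), fit in fits.items():
        S = fit.chains.posterior_samples()
        df = pd.DataFrame(S, columns=list(fit.chains.param_names))
        df.to_csv(out / f"{cl}_{tr}_{r}_samples.csv", index=False)
        summary = fit.summary()
        summary["rt0_ref"] = fit.posterior.data.rt0_ref
        summary["condition"] = {"cell_line": cl, "treatment": tr, "rtk": r}
        with open(out / f"{cl}_{tr}_{r}_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)


ENDPOINT_COLUMNS = {"cell_line", "treatment", "rtk", "compartment",
                    "replicate", "value"}
TIMECOURSE_COLUMNS = {"cell_line", "treatment", "rtk", "time_min",
                      "replicate", "total", "internal"}
CURVE_COLUMNS = {"analyte", "concentration_pg", "mfu", "is_background"}


def validate_tables(paths: dict) -> list:
    """Validate the CSV dialects; returns a list of diagnostics (empty
    when everything is well-formed).  Columns are header-keyed, so order
    never matters."""
    diags = []
    for kind, path in paths.items():
        p = Path(path)
        if not p.exists():
            diags.append(f"{kind}: file not found: {p}")
            continue
        df = pd.read_csv(p)
        if kind == "endpoint":
            missing = ENDPOINT_COLUMNS - set(df.columns)
            if missing:
                diags.append(f"endpoint: missing columns {sorted(missing)}")
                continue
            bad = ~df["compartment"].isin(["lysate", "supernatant"])
            if bad.any():
                diags.append("endpoint: compartment must be lysate|supernatant")
            if (df["value"] < 0).any():
                diags.append("endpoint: negative measurement values")
        elif kind == "timecourse":
            missing = TIMECOURSE_COLUMNS - set(df.columns)
            if missing:
                diags.append(f"timecourse: missing columns {sorted(missing)}")
                continue
            for (_, _, r), grp in df.groupby(["cell_line", "treatment", "rtk"]):
                t = np.sort(grp["time_min"].unique())
                if np.any(np.diff(t) <= 0):
                    diags.append(f"timecourse: non-monotone time grid for {r}")
            if (df[["total", "internal"]] < 0).to_numpy().any():
                diags.append("timecourse: negative signal values")
        elif kind == "standard_curve":
            missing = CURVE_COLUMNS - set(df.columns)
            if missing:
                diags.append(f"standard_curve: missing columns {sorted(missing)}")
                continue
            stds = df[~df["is_background"]]
            if (stds["concentration_pg"] <= 0).any():
                diags.append("standard_curve: non-positive standard "
                             "concentration")
        else:
            diags.append(f"unknown table kind {kind!r}")
    return diags
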