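"""Readers for the pipeline's CSV dialects."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .inference import ExperimentSet

__all__ = ["read_study_dir"]

# placeholder sigmas; callers re-estimate via inference.estimate_sigmas
_UNIT_SIGMA = {"endpoint_lysate": 1.0, "endpoint_supernatant": 1.0,
               "timecourse_total": 1.0, "timecourse_internal": 1.0}


def read_study_dir(path, lloq_endpoint: float = float("nan")) -> dict:
    """Read ``endpoint.csv`` + ``timecourse.csv`` written by
    :func:`rtktraffic.synthetic_data.write_study`.

    Returns ``{(treatment, rtk): ExperimentSet}`` with unit sigmas (the
    caller estimates and assigns real noise scales).
    """
    p = Path(path)
    ep = pd.read_csv(p / "endpoint.csv")
    tc = pd.read_csv(p / "timecourse.csv")
    out = {}
    for (tr, rtk), grp in ep.groupby(["treatment", "rtk"]):
        lys = grp[grp["compartment"] == "lysate"].sort_values("replicate")
        sup = grp[grp["compartment"] == "supernatant"].sort_values("replicate")
        tgrp = tc[(tc["treatment"] == tr) & (tc["rtk"] == rtk)]
        times = np.sort(tgrp["time_min"].unique())
        piv_t = tgrp.pivot_table(index="time_min", columns="replicate",
                                 values="total").loc[times]
        piv_i = tgrp.pivot_table(index="time_min", columns="replicate",
                                 values="internal").loc[times]
        cen = (sup["censored"].to_numpy(dtype=bool)
               if "censored" in sup.columns else None)
        out[(tr, rtk)] = ExperimentSet(
            endpoint_lysate=lys["value"].to_numpy(float),
            endpoint_supernatant=sup["value"].to_numpy(float),
            timecourse_times=times,
            timecourse_total=piv_t.to_numpy(float),
            timecourse_internal=piv_i.to_numpy(float),
            sigma=dict(_UNIT_SIGMA),
            supernatant_censored=cen,
            lloq_endpoint=lloq_endpoint,
            rtk=str(rtk), treatment=str(tr),
            cell_line=str(grp["cell_line"].iloc[0]))
    return out
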