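"""Generate the synthetic study bundles used by the downstream steps.

Writes control and Mek-inhibitor-like datasets (two receptor analogs,
n = 12 end-point and n = 18 time-course replicates) plus their
ground-truth manifests under results/data/.
"""

import sys
from pathlib import Path

from rtktraffic.synthetic_data import make_study, scenario_preset, write_study

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results/data")


def main() -> None:
    for treatment in ("control", "mek_like"):
        sc = scenario_preset(treatment, seed=SEED)
        bundle = make_study(sc, rtks=["rtkA_axl", "rtkB_met"])
        write_study(bundle, OUT / treatment)
        for rtk, info in bundle["manifest"]["rtks"].items():
            print(f"{treatment:>10s} {rtk:>9s}: lysate truth "
                  f"{info['endpoint_lysate_truth']:9.0f} molecules/cell, "
                  f"shed truth {info['endpoint_supernatant_truth']:8.0f}")
    print(f"wrote studies (seed {SEED}) to {OUT}/")


if __name__ == "__main__":
    main()
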