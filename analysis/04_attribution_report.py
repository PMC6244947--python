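"""Summarize mechanistic attribution from the fitted pipeline.

Reads results/pipeline/attribution.csv and overlap.csv (written by
03_fit_conditions.py) and reports, per receptor, which trafficking
parameter's substitution explains most of the predicted lysate change
and which parameter posteriors actually separated from control.
"""

import math
from pathlib import Path

import pandas as pd

IN = Path("results/pipeline")


def main() -> None:
    attr = pd.read_csv(IN / "attribution.csv")
    over = pd.read_csv(IN / "overlap.csv")
    for rtk, grp in attr[attr["parameter"] != "all"].groupby("rtk"):
        grp = grp.assign(effect=grp["fold_change"].map(
            lambda f: abs(math.log(f))))
        top = grp.sort_values("effect", ascending=False).iloc[0]
        full = attr[(attr["rtk"] == rtk) &
                    (attr["parameter"] == "all")]["fold_change"].iloc[0]
        print(f"{rtk}: full-substitution lysate fold change {full:.2f}; "
              f"dominant single parameter {top['parameter']} "
              f"(fold change {top['fold_change']:.2f})")
    moved = over[over["overlap"] <= 0.25]
    print(f"parameters separated from control (overlap <= 25%): "
          f"{len(moved)}/{len(over)}")
    for _, row in moved.iterrows():
        print(f"  {row['rtk']} {row['parameter']}: overlap {row['overlap']:.3f}")


if __name__ == "__main__":
    main()
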