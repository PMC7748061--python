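"""Aggregate saved program outputs into the scenario summary tables.

Reads the per-stage summaries written by 03_run_ps_programs.py and
04_run_gs_programs.py and emits the three scenario tables — annual genetic
gain per strategy x correlation (with the across-replicate SD of the final
genetic response), year-25 gain and genetic variance at F5-F8, and the
selection-accuracy table — plus the F5 genetic-variance trajectory and a
within-cycle variance profile.  All outputs land in results/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import wheatsim as ws
from wheatsim import reporting

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    frames = []
    for name in ("ps_stage_stats.csv", "gs_stage_stats.csv"):
        path = OUT / name
        if path.exists():
            frames.append(pd.read_csv(path))
        else:
            print(f"note: {path} not found (run the 03/04 scripts first)")
    if not frames:
        sys.exit("no stage statistics found under results/")
    df = pd.concat(frames, ignore_index=True)

    tables = reporting.aggregate_tables(df)
    for name, tab in tables.items():
        tab.to_csv(OUT / f"{name}.csv", index=False)
        print(f"--- {name} ---")
        print(tab.to_string(index=False))

    reporting.variance_at_stage(df).to_csv(
        OUT / "variance_trajectory.csv", index=False)
    # one completed example cycle per strategy (started year 9, F1 in year
    # 10 through F8 in year 17)
    try:
        reporting.within_cycle_variance(df, 9).to_csv(
            OUT / "within_cycle_variance.csv", index=False)
    except reporting.MissingYearsError:
        pass
    print(f"wrote trajectory tables under {OUT}/")


if __name__ == "__main__":
    main()
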