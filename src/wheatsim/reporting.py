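"""Summary statistics of simulated breeding programs.

All reported quantities are pure functions of the per-year, per-stage
summaries logged by the scheme engine: annual genetic gain (the OLS slope
of the yearly mean F8 breeding value for the goal trait on year, averaged
over replicates), the genetic-variance trajectory at F5, within-cycle
variance profiles, and accuracy tables, aggregated into analogues of the
published scenario tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class MissingYearsError(ValueError):
    pass


def _stats_frame(output) -> pd.DataFrame:
    """Accept a ProgramOutput, a DataFrame, or a list of outputs."""
    if isinstance(output, pd.DataFrame):
        return output
    if isinstance(output, (list, tuple)):
        return pd.concat([_stats_frame(o) for o in output], ignore_index=True)
    return output.stage_stats


@dataclass
class GainEstimate:
    """Annual genetic gain in base genetic-SD units per year."""

    delta_g: float
    standard_error: float
    per_replicate: np.ndarray
    stage: str = "F8"
    trait: str = "AYT"
    window: tuple = (9, 25)


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    return float((xc @ (y - y.mean())) / (xc @ xc))


def annual_genetic_gain(output, stage: str = "F8", trait: str = "AYT",
                        window: tuple[int, int] = (9, 25)) -> GainEstimate:
    """Per-replicate OLS slope of mean stage TBV on year, then averaged.

    The regression uses one point per year (the cohort mean TBV of the
    stage) over the window years inclusive; the standard error is the
    between-replicate SE of the slopes (missing when only one replicate).
    """
    df = _stats_frame(output)
    lo, hi = window
    sub = df[(df["stage"] == stage) & (df["year"] >= lo) & (df["year"] <= hi)]
    slopes = []
    for _, rep in sub.groupby(["strategy", "corr_pyt_ayt", "replicate"]):
        years = rep["year"].to_numpy()
        if np.unique(years).size != hi - lo + 1:
            raise MissingYearsError(
                f"stage {stage} does not cover years {lo}..{hi}")
        slopes.append(_ols_slope(years, rep[f"mean_{trait}"].to_numpy()))
    slopes = np.array(slopes)
    se = (slopes.std(ddof=1) / np.sqrt(slopes.size)
          if slopes.size > 1 else float("nan"))
    return GainEstimate(delta_g=float(slopes.mean()), standard_error=se,
                        per_replicate=slopes, stage=stage, trait=trait,
                        window=window)


def cumulative_gain(output, stage: str = "F8", trait: str = "AYT",
                    window: tuple[int, int] = (9, 25)) -> float:
    """Fitted TBV advance of a stage over the comparison window.

    Under the linear-response assumption of the comparison protocol, the
    cumulative gain is the per-replicate OLS slope of the stage's yearly
    mean TBV on year multiplied by the window length, averaged over
    replicates.  (The raw endpoint difference is a noisy estimator for the
    five-line F8 product cohorts; the fitted advance uses every window
    year.)
    """
    est = annual_genetic_gain(output, stage=stage, trait=trait, window=window)
    return float(est.delta_g * (window[1] - window[0]))


def variance_at_stage(output, stage: str = "F5",
                      trait: str = "AYT") -> pd.DataFrame:
    """Per-year genetic variance at a stage, averaged over replicates.

    The variance is the sample variance of the stage cohort's TBVs for the
    trait in each year (computed by the scheme engine at evaluation time).
    """
    df = _stats_frame(output)
    sub = df[df["stage"] == stage]
    if sub.empty:
        raise ValueError(f"no rows for stage {stage}")
    col = f"var_{trait}"
    out = (sub.groupby(["strategy", "corr_pyt_ayt", "year"])[col]
           .agg(["mean", "sem", "count"]).reset_index())
    return out.rename(columns={"mean": "variance", "sem": "se",
                               "count": "n_replicates"})


def within_cycle_variance(output, cycle_start_year: int,
                          trait: str = "AYT") -> pd.DataFrame:
    """TBV variance at each generation F1..F8 of one breeding cycle.

    A cycle started in year ``c`` is evaluated at F1 in year ``c + 1`` and
    at F8 in year ``c + 8``; an incomplete cycle raises.
    """
    df = _stats_frame(output)
    sub = df[df["cycle"] == cycle_start_year]
    gens = [f"F{g}" for g in range(1, 9)]
    have = set(sub["stage"])
    if not all(g in have for g in gens):
        raise MissingYearsError(
            f"cycle {cycle_start_year} incomplete: stages {sorted(have)}")
    col = f"var_{trait}"
    out = (sub[sub["stage"].isin(gens)]
           .groupby(["strategy", "corr_pyt_ayt", "stage"])[col]
           .agg(["mean", "sem"]).reset_index()
           .rename(columns={"mean": "variance", "sem": "se"}))
    out["generation_order"] = out["stage"].str[1].astype(int)
    return out.sort_values(["strategy", "corr_pyt_ayt", "generation_order"],
                           ignore_index=True)


def accuracy_table(output, stages=("F6", "F7", "F8"),
                   window: tuple[int, int] = (9, 25)) -> pd.DataFrame:
    """Mean (SE) selection accuracy per strategy x generation.

    Accuracy is the Pearson correlation, recorded at each decision point,
    between the stage's selection criterion (plot mean under PS, GEBV under
    GS) and true breeding values for the goal trait over the candidate set;
    the F8 value carries the F7-decision criterion restricted to the five
    survivors.  Degenerate candidate sets (NaN accuracies) are skipped.
    """
    df = _stats_frame(output)
    lo, hi = window
    sub = df[(df["stage"].isin(stages)) & (df["year"] >= lo)
             & (df["year"] <= hi) & df["accuracy"].notna()]
    out = (sub.groupby(["strategy", "corr_pyt_ayt", "stage"])["accuracy"]
           .agg(["mean", "sem", "count"]).reset_index())
    return out.rename(columns={"mean": "accuracy", "sem": "se",
                               "count": "n_points"})


def aggregate_tables(outputs, window: tuple[int, int] = (9, 25)) -> dict:
    """Scenario-grid summary tables.

    Returns a dict of DataFrames:

    * ``table1_gain`` — annual genetic gain (mean and between-replicate SE)
      per strategy x correlation level, plus the across-replicate SD of the
      cumulative year-25 F8 gain (the "SD of genetic response");
    * ``table2_year25`` — mean TBV (gain) and genetic variance for AYT at
      F5..F8 in the final year, per scenario;
    * ``table3_accuracy`` — mean accuracy per strategy x generation.
    """
    df = _stats_frame(outputs)
    final_year = int(df["year"].max())

    rows = []
    for (strat, corr), grp in df.groupby(["strategy", "corr_pyt_ayt"]):
        est = annual_genetic_gain(grp, window=window)
        f8 = grp[(grp["stage"] == "F8") & (grp["year"] == final_year)]
        sd_response = (f8.groupby("replicate")["mean_AYT"].mean().std(ddof=1)
                       if f8["replicate"].nunique() > 1 else float("nan"))
        rows.append(dict(strategy=strat, corr_pyt_ayt=corr,
                         delta_g=est.delta_g, se=est.standard_error,
                         n_replicates=est.per_replicate.size,
                         sd_response=sd_response))
    table1 = pd.DataFrame(rows)

    last = df[df["year"] == final_year]
    gens = last[last["stage"].isin(["F5", "F6", "F7", "F8"])]
    table2 = (gens.groupby(["strategy", "corr_pyt_ayt", "stage"])
              [["mean_AYT", "var_AYT"]]
              .agg(["mean", "sem"]))
    table2.columns = ["_".join(c) for c in table2.columns]
    table2 = table2.reset_index().rename(columns={
        "mean_AYT_mean": "gain", "mean_AYT_sem": "gain_se",
        "var_AYT_mean": "variance", "var_AYT_sem": "variance_se"})

    table3 = accuracy_table(df, window=window)
    return {"table1_gain": table1, "table2_year25": table2,
            "table3_accuracy": table3}
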