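#!/usr/bin/env python
"""Estimate APP production rates by the grid-multistart compartmental fit
and test for a dose effect with the pre-treatment lumbar concentration as
covariate.

Each subject's SILK curve and early (0-15 h, post-11am) lumbar Abeta40
concentrations are fitted at every grid combination of the structural
unknowns; production estimates within the 20% residual band are averaged.
Because the generator records each subject's true production rate, the
script also reports the recovery error — the check real data cannot give.
"""

import argparse
from pathlib import Path

from silkstudy.gridfit import GridConfig, OptimizerSettings
from silkstudy.pipeline import grid_fit_tables, load_study


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--study", default="results/study")
    ap.add_argument("--out", default="results")
    ap.add_argument("--grid", choices=["default", "test"], default="test",
                    help="'default' runs the full 128-combination grid")
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    study = load_study(args.study)
    grid = GridConfig() if args.grid == "default" else GridConfig.test_preset()
    opt = OptimizerSettings(maxiter=300, n_restarts=1, xatol=1e-3)
    summaries, records, dose_resp = grid_fit_tables(study, grid, opt)
    summaries.to_csv(out / "subject_fits.csv", index=False)
    records.to_csv(out / "fit_records.csv", index=False)
    dose_resp.to_csv(out / "dose_response.csv", index=False)

    print(f"grid: {grid.n_combinations} optimizations per subject, "
          f"{len(summaries)} subjects")
    by_arm = summaries.groupby("arm")["r_app"].agg(["median", "count"])
    print("\naveraged R_APP by arm [nmol/h]:")
    print(by_arm.round(3).to_string())

    if len(study.truth):
        merged = summaries.merge(
            study.truth[["subject_id", "true_r_app"]], on="subject_id")
        err = (merged.r_app - merged.true_r_app).abs() / merged.true_r_app
        print(f"\nrecovery vs simulated truth: median |rel err| "
              f"{100 * err.median():.1f}% (max {100 * err.max():.0f}%)")

    print("\ndose-response ANCOVA (baseline-adjusted contrasts vs placebo):")
    print(dose_resp.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
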