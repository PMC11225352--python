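#!/usr/bin/env python
"""Noncompartmental PK of the study drug and its N1/N8 metabolites.

Computes per-subject AUC(0-24), Cmax/Tmax, terminal lambda_z/t1/2 and the
dose-normalized Cl/F and Vz/F, summarizes each arm as geometric mean (%GCV)
with median (min-max) for Tmax, and reports plasma-CSF exposure rank
correlations.
"""

import argparse
from pathlib import Path

from silkstudy.nca import plasma_csf_correlation
from silkstudy.pipeline import load_study, nca_tables


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--study", default="results/study")
    ap.add_argument("--out", default="results")
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    study = load_study(args.study)
    per_subject, summary = nca_tables(study)
    per_subject.to_csv(out / "nca_subjects.csv", index=False)
    summary.to_csv(out / "nca_summary.csv", index=False)

    print(f"{len(per_subject)} subject x analyte x matrix NCA records")
    gm = summary[summary["parameter"] == "auc_0_24"]
    print("\nAUC(0-24) geometric mean (%GCV) by arm/analyte/matrix:")
    print(gm.round(2).to_string(index=False))

    pairs = per_subject[["subject_id", "analyte", "matrix", "auc_0_24"]]
    try:
        rho = plasma_csf_correlation(pairs)
        rho.to_csv(out / "plasma_csf_correlation.csv", index=False)
        print("\nplasma vs CSF exposure (Spearman):")
        print(rho.round(3).to_string(index=False))
    except ValueError as exc:
        print(f"\nplasma-CSF correlation unavailable: {exc}")


if __name__ == "__main__":
    main()
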