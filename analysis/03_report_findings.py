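"""Report the cohort findings from the pipeline tables.

Reads results/tables/ and prints the three observations the analysis is
built around: (1) on-treatment changes in GTV, D and f; (2) the weak
voxel-wise SUV-vs-IVIM correlations; (3) which pre-treatment metrics and
PRM sub-volumes associate with the relative tumor-volume change.

Run after 02_run_pipeline.py:  python analysis/03_report_findings.py
"""

from pathlib import Path

import pandas as pd

TABLES = Path("results/tables")


def load(name: str) -> pd.DataFrame:
    return pd.read_csv(TABLES / name, sep="\t", comment="#")


def main() -> None:
    paired = load("paired_tests.tsv").set_index("variable")
    vox = load("voxelwise_correlations.tsv").set_index("metric")
    assoc = load("table2_associations.tsv").set_index("variable")

    print("1) pre- vs on-treatment (Wilcoxon signed-rank):")
    for var, label in (("GTV_cc", "tumor volume"), ("D", "IVIM D"),
                       ("f", "IVIM f"), ("Dstar", "IVIM D*")):
        row = paired.loc[var]
        direction = "increased" if row["median_change"] > 0 else "decreased"
        sig = "significantly " if row["significant"] else "not significantly "
        print(f"   {label:13s} {sig}{direction} (p = {row['p_value']:.2g})")

    print("\n2) voxel-wise SUV vs IVIM inside the GTV (mean +/- SD over patients):")
    for m, label in (("r_SUV_D", "SUV vs D"), ("r_SUV_f", "SUV vs f")):
        row = vox.loc[m]
        print(f"   {label}: r = {row['mean']:+.2f} +/- {row['sd']:.2f}")

    print("\n3) associations of delta-GTV with pre-treatment metrics (Spearman):")
    for var in ("GTV_cc", "D", "PRM_SUVhi_Dlo", "PRM_SUVlo_Dhi", "PRM_SUVlo_fhi",
                "PRM_Dhi_fhi", "PRM_Dlo_flo"):
        row = assoc.loc[var]
        star = " *" if row["significant"] else ""
        print(f"   {var:16s} r = {row['spearman_r']:+.2f} "
              f"(p = {row['p_value']:.2g}){star}")
    print("\n   (* significant at two-sided alpha = 0.05; delta-GTV is "
          "100*(on-pre)/pre, shrinkage negative)")


if __name__ == "__main__":
    main()
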