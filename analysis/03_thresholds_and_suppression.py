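#!/usr/bin/env python
"""Thermal-threshold dispersion and noxious-heat suppression analysis.

Compares the dispersion of 80%-of-peak thermal thresholds between Dys and
BF per layer (two-sample Ansari-Bradley) and the fraction of units whose
noxious-heat S/N fell below 1 (suppression) between regions (2x2
chi-square).  Writes results/stats/tests.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from noxtact import ansari_bradley, chi_square_2x2, suppressed_fraction
from noxtact.stats import results_table

parser = argparse.ArgumentParser()
parser.add_argument("--metrics", type=Path,
                    default=Path("results/metrics/unit_metrics.csv"))
parser.add_argument("--out", type=Path, default=Path("results/stats"))
args = parser.parse_args()

metrics = pd.read_csv(args.metrics)
results, names = [], []
for layer in sorted(metrics["layer"].unique()):
    sub = metrics[metrics["layer"] == layer]
    dys = sub.loc[(sub.region == "Dys") & sub.threshold_c.notna(), "threshold_c"]
    bf = sub.loc[(sub.region == "BF") & sub.threshold_c.notna(), "threshold_c"]
    if len(dys) >= 2 and len(bf) >= 2:
        results.append(ansari_bradley(dys, bf))
        names.append(f"threshold_dispersion_{layer}")

for region in ("Dys", "BF"):
    frac = suppressed_fraction(metrics.loc[metrics.region == region, "sn_nox"])
    print(f"{region}: {100 * frac:.1f}% of units suppressed (S/N < 1)")

agg = metrics.assign(supp=metrics.sn_nox < 1).groupby("region")["supp"] \
             .agg(["sum", "count"])
table = [[int(agg.loc["BF", "sum"]), int(agg.loc["BF", "count"] - agg.loc["BF", "sum"])],
         [int(agg.loc["Dys", "sum"]), int(agg.loc["Dys", "count"] - agg.loc["Dys", "sum"])]]
results.append(chi_square_2x2(table))
names.append("suppressed_BF_vs_Dys")

tbl = results_table(results)
tbl.insert(0, "comparison", names)
args.out.mkdir(parents=True, exist_ok=True)
tbl.to_csv(args.out / "tests.csv", index=False)
print(tbl[["comparison", "method", "statistic", "p_value"]].to_string(index=False))
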