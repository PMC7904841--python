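#!/usr/bin/env python
"""Rapid-test vs ELISA agreement.

For each fluid: Spearman rank correlation with its strength label, the OLS
slope of ELISA on QBT with 95% CI, and a Bland-Altman analysis restricted to
the clinically relevant range (pair means <= 12,000 ng/ml).  Writes the
per-fluid reports and plot-ready pair tables under results/.
"""

import argparse
import json
from pathlib import Path

from ptacal.agreement import agreement_report
from ptacal.cohort import read_cohort_csv


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
    ap.add_argument("--ba-restriction", type=float, default=12000.0)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    df = read_cohort_csv(args.cohort)
    args.results.mkdir(parents=True, exist_ok=True)
    for fluid in ("serum", "saliva"):
        rep = agreement_report(df[f"{fluid}_qbt"], df[f"{fluid}_elisa"],
                               fluid=fluid, ba_restriction=args.ba_restriction)
        (args.results / f"agreement_{fluid}.json").write_text(
            json.dumps(rep.to_dict(), indent=2, sort_keys=True) + "\n")
        pairs = df[[f"{fluid}_qbt", f"{fluid}_elisa"]].dropna()
        pairs.columns = ["qbt", "elisa"]
        pairs.assign(mean=(pairs.qbt + pairs.elisa) / 2,
                     diff=pairs.qbt - pairs.elisa).to_csv(
            args.results / f"agreement_{fluid}_pairs.csv", index=False)
        print(f"{fluid}: n={rep.n_pairs}, r_sp={rep.r_sp:.3f} ({rep.r_class}), "
              f"slope={rep.slope:.3f} CI ({rep.slope_ci95[0]:.3f}, {rep.slope_ci95[1]:.3f}); "
              f"Bland-Altman bias={rep.ba.bias:.0f} ng/ml "
              f"[{rep.ba.limits[0]:.0f}, {rep.ba.limits[1]:.0f}] "
              f"on {rep.ba.n_pairs} pairs ({rep.ba.n_excluded} above restriction)")


if __name__ == "__main__":
    main()
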