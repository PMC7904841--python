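#!/usr/bin/env python
"""Marker ROC analysis and cutoff derivation.

Per-group mean +/- SEM of the rapid-test channel with Mann-Whitney
comparisons against controls, then the PTA-vs-controls ROC per fluid with the
Youden-optimal cutoff.  Writes ROC point tables and a summary JSON under
results/.
"""

import argparse
import json
from pathlib import Path

from ptacal.cohort import read_cohort_csv
from ptacal.pipeline import marker_group_summaries, marker_roc


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
    ap.add_argument("--negative-class", choices=["controls", "all"], default="controls")
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    df = read_cohort_csv(args.cohort)
    args.results.mkdir(parents=True, exist_ok=True)
    summary = {}
    for fluid in ("serum", "saliva"):
        groups = marker_group_summaries(df, f"{fluid}_qbt")
        pta, ctrl = groups["pta"], groups["control"]
        print(f"{fluid}: PTA {pta.mean:.0f} +/- {pta.sem:.0f} ng/ml vs "
              f"control {ctrl.mean:.0f} +/- {ctrl.sem:.0f} ng/ml "
              f"(U={pta.u_stat:.0f}, p={pta.p_two_sided:.2g})")
        roc = marker_roc(df, f"{fluid}_qbt", args.negative_class)
        roc.points_frame().to_csv(args.results / f"roc_{fluid}_points.csv", index=False)
        print(f"  ROC ({args.negative_class}): cutoff={roc.cutoff:.0f} ng/ml, "
              f"sens={roc.cutoff_sens:.3f}, spec={roc.cutoff_spec:.3f}, "
              f"AUC={roc.auc:.3f} ({roc.auc_class})")
        summary[fluid] = {
            "group_summaries": {g: {"n": s.n, "mean": s.mean, "sem": s.sem,
                                    "u_stat": s.u_stat, "p_two_sided": s.p_two_sided}
                                for g, s in groups.items()},
            "roc": roc.to_dict(),
        }
    (args.results / "roc_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")


if __name__ == "__main__":
    main()
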