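#!/usr/bin/env python
"""Adjusted PTA score analysis.

Scores every subject (one point per symptom, one point per fluid with
calprotectin strictly above its cutoff), summarises scores per group with
Mann-Whitney comparisons against the PTA group, derives the score-level ROC
cutoff, and evaluates the integer clinical rule.  Writes the per-patient
score table and a summary JSON under results/.
"""

import argparse
import json
from pathlib import Path

from ptacal.cohort import read_cohort_csv, records_from_frame
from ptacal.score import ScoreConfig, clinical_cutoff, score_cohort


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
    ap.add_argument("--serum-cutoff", type=float, default=2940.0)
    ap.add_argument("--saliva-cutoff", type=float, default=5310.0)
    ap.add_argument("--negative-class", choices=["controls", "all"], default="controls")
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    records = records_from_frame(read_cohort_csv(args.cohort))
    cfg = ScoreConfig(serum_cutoff=args.serum_cutoff, saliva_cutoff=args.saliva_cutoff)
    res = score_cohort(records, cfg, negative_class=args.negative_class)

    args.results.mkdir(parents=True, exist_ok=True)
    res.score_table().to_csv(args.results / "score_table.csv", index=False)

    for g in ("pta", "peritonsillitis", "acute_tonsillitis", "control"):
        if g not in res.group_summaries:
            continue
        s = res.group_summaries[g]
        vs = "" if s.p_two_sided is None else f" (vs PTA: p={s.p_two_sided:.3g})"
        print(f"{g}: mean score {s.mean:.1f} +/- {s.sem:.1f} (n={s.n}){vs}")
    print(f"score ROC ({res.negative_class}): statistical cutoff {res.roc.cutoff:.1f} points "
          f"(sens={res.roc.cutoff_sens:.3f}, spec={res.roc.cutoff_spec:.3f}, "
          f"AUC={res.roc.auc:.3f}) -> clinical cutoff {clinical_cutoff(res.roc.cutoff)} points")
    c = res.confusion
    print(f"at the configured clinical cutoff ({res.clinical_cutoff} points): "
          f"sens={c.sensitivity:.3f}, spec={c.specificity:.3f} "
          f"(tp={c.tp}, fp={c.fp}, tn={c.tn}, fn={c.fn})")

    summary = {
        "clinical_cutoff": res.clinical_cutoff,
        "roc": res.roc.to_dict(),
        "confusion": {"tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn,
                      "sensitivity": c.sensitivity, "specificity": c.specificity},
        "group_summaries": {g: {"n": s.n, "mean": s.mean, "sem": s.sem,
                                "u_stat": s.u_stat, "p_two_sided": s.p_two_sided}
                            for g, s in res.group_summaries.items()},
    }
    (args.results / "score_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")


if __name__ == "__main__":
    main()
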