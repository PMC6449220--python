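#!/usr/bin/env python
"""Score the inference tables against the hidden truth under all four keys.

Classifies every data set x component slot as correct / miss / false alarm
/ flip, summarises each method under the planned key and the two
alternative keys (emphasis also affecting ease, or also affecting
non-decision time) plus the no-ndt key, and reports pairwise method
agreement.
"""

import argparse
from pathlib import Path

import pandas as pd

import rtvalid as rv
from rtvalid.io import read_inference_table

RESULTS = Path(__file__).resolve().parents[1] / "results"
KEYS = ("planned", "alt1_caution_ease", "alt2_caution_ndt", "planned_no_ndt")


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--truth", type=Path, default=RESULTS / "datasets" / "truth_hidden.csv")
    ap.add_argument("--outdir", type=Path, default=RESULTS)
    ap.add_argument(
        "--inferences", type=Path, nargs="+",
        default=[RESULTS / "inferences_estimate.csv", RESULTS / "inferences_heuristic.csv"],
    )
    args = ap.parse_args()

    truth = (
        pd.read_csv(args.truth, dtype=str)
        .astype({"dataset": int})
        .set_index("dataset")[["ease", "caution", "biasR", "ndt"]]
    )
    tables = {p.stem.replace("inferences_", ""): read_inference_table(p) for p in args.inferences}

    rows = []
    for key in KEYS:
        t = rv.build_truth(truth, key)
        for name, tab in tables.items():
            s = rv.summarize_scores(tab, t)
            disp = s.display()
            rows.append({"key": key, "method": name, "n_slots": s.n_slots, **disp})
            print(
                f"{key:18s} {name:10s}: correct {disp['correct']:.2f}  "
                f"miss {disp['miss']:.2f}  FA {disp['false_alarm']:.2f}  "
                f"flip {disp['flip']:.2f}  ({s.n_slots} slots)"
            )
    pd.DataFrame(rows).to_csv(args.outdir / "score_summary.csv", index=False)

    agree = rv.agreement_matrix(tables)
    agree.to_csv(args.outdir / "method_agreement.csv")
    print("\npairwise agreement (proportion of identical inferences):")
    print(agree.round(3).to_string())
    print(f"\nwrote score_summary.csv and method_agreement.csv to {args.outdir}")


if __name__ == "__main__":
    main()
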