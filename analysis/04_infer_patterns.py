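#!/usr/bin/env python
"""Infer the manipulated components of every data set, two ways.

Estimate-based: paired t-tests on per-participant EZ2 (or ML) parameter
estimates.  Heuristic: accuracy / RT-quantile / criterion cutoff rules on
the raw trials.  Writes one inference table per procedure in the
submission format: rows = data sets, columns = ease, caution, biasR, ndt.
"""

import argparse
from pathlib import Path

import pandas as pd

import rtvalid as rv
from rtvalid.inference import inference_table
from rtvalid.io import read_trial_table, write_inference_table

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--fits", type=Path, default=RESULTS / "fits_ez2.csv")
    ap.add_argument("--datadir", type=Path, default=RESULTS / "datasets")
    ap.add_argument("--outdir", type=Path, default=RESULTS)
    args = ap.parse_args()

    fits = pd.read_csv(args.fits)
    cfg = rv.InferenceConfig()
    est, heur = {}, {}
    for path in sorted(args.datadir.glob("dataset_*.csv")):
        df = read_trial_table(path)
        ds = int(df["dataset"].iloc[0])
        f = fits[fits.dataset == ds]
        fa = f[f.condition == "A"].set_index("participant")
        fb = f[f.condition == "B"].set_index("participant")
        est[ds] = rv.infer_pattern_estimate_based(fa, fb, cfg)
        heur[ds] = rv.infer_pattern_heuristic(
            df[df.condition == "A"], df[df.condition == "B"], cfg
        )
    for name, pats in (("estimate", est), ("heuristic", heur)):
        tab = inference_table(pats)
        write_inference_table(tab, args.outdir / f"inferences_{name}.csv")
        print(f"{name}-based inferences:")
        print(tab.to_string())
    print(f"wrote inference tables to {args.outdir}")


if __name__ == "__main__":
    main()
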