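#!/usr/bin/env python
"""Relabel the session and assemble the 14 blinded two-condition data sets.

Applies the favoured-side-reads-right recoding, samples each condition
from its source cells, shuffles participant ids, flips A/B for half the
data sets, and writes one blinded CSV per data set plus the hidden truth
table (kept separate so the data carry no trace of the design).
"""

import argparse
from pathlib import Path

import pandas as pd

import rtvalid as rv
from rtvalid.io import write_pseudo_experiments

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--session", type=Path, default=RESULTS / "session_trials.csv")
    ap.add_argument("--outdir", type=Path, default=RESULTS / "datasets")
    args = ap.parse_args()

    sess = pd.read_csv(args.session)
    sess["correct"] = sess["correct"].astype(bool)
    sess["timed_out"] = sess["timed_out"].astype(bool)
    relabelled = rv.relabel_trials(sess)
    experiments = rv.construct_pseudo_experiments(relabelled, rng_seed=args.seed + 2)
    paths = write_pseudo_experiments(experiments, args.outdir)
    print(f"wrote {len(paths)} blinded data sets to {args.outdir}")
    for e in experiments:
        na, nb = len(e.trials_A), len(e.trials_B)
        print(
            f"  data set {e.id:2d}: {na} + {nb} trials; truth "
            f"{''.join(e.truth.as_tuple()).replace('0', '-')}"
            f"{' (A/B flipped)' if e.flipped else ''}"
        )


if __name__ == "__main__":
    main()
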