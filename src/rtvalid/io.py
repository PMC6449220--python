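"""Delimited-text interchange for trial tables, fits and inference tables.

Pseudo-experiments are written the way the blinded study distributed them:
one CSV per data set with columns (dataset, participant, condition,
stimulus, response, rt, correct), plus a separate hidden truth file so the
data carry no trace of the manipulations.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .pseudo import COMPONENTS, PseudoExperiment

DATASET_COLUMNS = ["dataset", "participant", "condition", "stimulus", "response", "rt", "correct"]


def write_pseudo_experiments(
    experiments: list[PseudoExperiment], outdir: str | Path, truth_name: str = "truth_hidden.csv"
) -> list[Path]:
    """One blinded CSV per data set plus a hidden truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    truth_rows = []
    for e in experiments:
        df = pd.concat([e.trials_A, e.trials_B], ignore_index=True)
        df["dataset"] = e.id
        df["correct"] = df["correct"].astype(int)
        path = outdir / f"dataset_{e.id:02d}.csv"
        df[DATASET_COLUMNS].to_csv(path, index=False)
        paths.append(path)
        truth_rows.append(
            {
                "dataset": e.id,
                **dict(zip(COMPONENTS, e.truth.as_tuple())),
                "cell_A": e.provenance[0].describe(),
                "cell_B": e.provenance[1].describe(),
            }
        )
    pd.DataFrame(truth_rows).to_csv(outdir / truth_name, index=False)
    return paths


def read_trial_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "correct" in df.columns:
        df["correct"] = df["correct"].astype(bool)
    if "timed_out" not in df.columns:
        df["timed_out"] = False
    return df


def write_fit_table(fits: pd.DataFrame, path: str | Path) -> None:
    fits.to_csv(path)


def write_inference_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path)


def read_inference_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str).astype({"dataset": int}).set_index("dataset")
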