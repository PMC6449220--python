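"""The 14 canonical two-condition pseudo-experiments.

A pseudo-experiment pairs two pools of trials (conditions A and B) drawn
from cells of the factorial design so that the conditions differ in a known
direction on each of three manipulable components: ease of processing,
response caution, and rightward response bias (non-decision time is never
manipulated).  Up to a global swap of the condition labels there are
(3^3 + 1)/2 = 14 distinct direction patterns, and each is realised by the
cell pair with no bias manipulation where possible and the largest expected
error count (hard over easy, speed over accuracy) otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

COMPONENTS = ("ease", "caution", "biasR", "ndt")
LABELS = ("A", "0", "B")


@dataclass(frozen=True)
class ManipulationPattern:
    """Which condition holds the higher value on each component ('0' = tie)."""

    ease: str = "0"
    caution: str = "0"
    biasR: str = "0"
    ndt: str = "0"

    def __post_init__(self) -> None:
        for c in COMPONENTS:
            if getattr(self, c) not in LABELS:
                raise ValueError(f"{c} must be one of {LABELS}")

    def swapped(self) -> "ManipulationPattern":
        """The same pattern with condition labels A and B exchanged."""
        sw = {"A": "B", "B": "A", "0": "0"}
        return ManipulationPattern(*(sw[getattr(self, c)] for c in COMPONENTS))

    def as_tuple(self) -> tuple[str, str, str, str]:
        return tuple(getattr(self, c) for c in COMPONENTS)


# Canonical representative of each equivalence class, in study order.
_CANONICAL: list[tuple[str, str, str]] = [
    ("0", "0", "0"),
    ("B", "0", "0"),
    ("0", "B", "0"),
    ("0", "0", "B"),
    ("B", "B", "0"),
    ("B", "0", "B"),
    ("0", "B", "B"),
    ("A", "B", "0"),
    ("A", "0", "B"),
    ("0", "A", "B"),
    ("A", "B", "B"),
    ("B", "A", "B"),
    ("B", "B", "A"),
    ("B", "B", "B"),
]


def enumerate_patterns() -> list[ManipulationPattern]:
    """All direction patterns over (ease, caution, biasR), one per class.

    Enumerates the 27 assignments of {A, 0, B}, collapses them into
    equivalence classes under the global A/B swap, and returns the classes
    in canonical study order (data sets 1-14), each represented by its
    canonical labeling.  ndt is '0' throughout: it was never manipulated.
    """
    classes = set()
    for combo in itertools.product(LABELS, repeat=3):
        p = ManipulationPattern(*combo)
        q = p.swapped()
        classes.add(max(p.as_tuple()[:3], q.as_tuple()[:3]))
    canon = [ManipulationPattern(*c) for c in _CANONICAL]
    found = {
        max(p.as_tuple()[:3], p.swapped().as_tuple()[:3]) for p in canon
    }
    if len(canon) != len(classes) or found != classes:
        raise AssertionError("canonical pattern list does not cover the swap classes")
    return canon


@dataclass(frozen=True)
class SourceCell:
    """Emphasis/difficulty/bias provenance of one condition (bias is boolean:
    after relabeling, every biased block favours 'R')."""

    difficulty: str
    emphasis: str
    biased: bool

    def describe(self) -> str:
        return f"{self.difficulty}, {self.emphasis}, {'bias' if self.biased else 'no bias'}"


# data set id -> (cell for condition A, cell for condition B)
SOURCE_CELLS: dict[int, tuple[SourceCell, SourceCell]] = {
    1: (SourceCell("hard", "speed", False), SourceCell("hard", "speed", False)),
    2: (SourceCell("hard", "speed", False), SourceCell("easy", "speed", False)),
    3: (SourceCell("hard", "speed", False), SourceCell("hard", "accuracy", False)),
    4: (SourceCell("hard", "speed", False), SourceCell("hard", "speed", True)),
    5: (SourceCell("hard", "speed", False), SourceCell("easy", "accuracy", False)),
    6: (SourceCell("hard", "speed", False), SourceCell("easy", "speed", True)),
    7: (SourceCell("hard", "speed", False), SourceCell("hard", "accuracy", True)),
    8: (SourceCell("easy", "speed", False), SourceCell("hard", "accuracy", False)),
    9: (SourceCell("easy", "speed", False), SourceCell("hard", "speed", True)),
    10: (SourceCell("hard", "accuracy", False), SourceCell("hard", "speed", True)),
    11: (SourceCell("easy", "speed", False), SourceCell("hard", "accuracy", True)),
    12: (SourceCell("hard", "accuracy", False), SourceCell("easy", "speed", True)),
    13: (SourceCell("hard", "speed", True), SourceCell("easy", "accuracy", False)),
    14: (SourceCell("hard", "speed", False), SourceCell("easy", "accuracy", True)),
}


def pattern_from_cells(cell_a: SourceCell, cell_b: SourceCell) -> ManipulationPattern:
    """Direction pattern implied by a pair of source cells."""

    def direction(val_a, val_b, order) -> str:
        if order.index(val_a) > order.index(val_b):
            return "A"
        if order.index(val_a) < order.index(val_b):
            return "B"
        return "0"

    return ManipulationPattern(
        ease=direction(cell_a.difficulty, cell_b.difficulty, ["hard", "easy"]),
        caution=direction(cell_a.emphasis, cell_b.emphasis, ["speed", "accuracy"]),
        biasR=direction(cell_a.biased, cell_b.biased, [False, True]),
        ndt="0",
    )


class InsufficientTrialsError(RuntimeError):
    pass


@dataclass(frozen=True)
class PseudoExperiment:
    id: int
    trials_A: pd.DataFrame
    trials_B: pd.DataFrame
    truth: ManipulationPattern
    provenance: tuple[SourceCell, SourceCell]
    flipped: bool

    def condition(self, label: str) -> pd.DataFrame:
        return self.trials_A if label == "A" else self.trials_B


def _cell_pool(t: pd.DataFrame, cell: SourceCell) -> pd.DataFrame:
    mask = (
        (t["difficulty"] == cell.difficulty)
        & (t["emphasis"] == cell.emphasis)
        & ((t["bias"] != "none") == cell.biased)
    )
    return t[mask]


def construct_pseudo_experiments(
    t: pd.DataFrame,
    rng_seed: int = 0,
    n_per_participant: int = 312,
    dataset_ids: list[int] | None = None,
) -> list[PseudoExperiment]:
    """Assemble the (up to) 14 two-condition data sets from a relabelled
    session table.

    For every data set, each condition samples ``n_per_participant`` trials
    per participant without replacement from all blocks of its source cell
    (data set 1 instead splits its single cell's pool into two disjoint
    halves).  Participant ids are shuffled per data set and the A/B order is
    flipped for half of the data sets; the stored truth pattern always
    describes the data as delivered.
    """
    ids = dataset_ids if dataset_ids is not None else list(SOURCE_CELLS)
    participants = np.sort(t["participant"].unique())
    out = []
    for ds in ids:
        cell_a, cell_b = SOURCE_CELLS[ds]
        rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed) & 0x7FFFFFFF, 3, ds]))
        cond_frames: dict[str, list[pd.DataFrame]] = {"A": [], "B": []}
        for pid in participants:
            tp = t[t["participant"] == pid]
            if ds == 1:
                pool = _cell_pool(tp, cell_a)
                idx = rng.permutation(pool.index.to_numpy())
                half = len(idx) // 2
                cond_frames["A"].append(pool.loc[idx[:half]])
                cond_frames["B"].append(pool.loc[idx[half : 2 * half]])
            else:
                for label, cell in (("A", cell_a), ("B", cell_b)):
                    pool = _cell_pool(tp, cell)
                    if len(pool) < n_per_participant:
                        raise InsufficientTrialsError(
                            f"data set {ds}, participant {pid}: cell "
                            f"({cell.describe()}) holds {len(pool)} trials, "
                            f"need {n_per_participant}"
                        )
                    take = rng.choice(pool.index.to_numpy(), n_per_participant, replace=False)
                    cond_frames[label].append(pool.loc[np.sort(take)])

        truth = pattern_from_cells(cell_a, cell_b)
        # shuffle participant ids within the data set
        perm = rng.permutation(len(participants))
        remap = dict(zip(participants, perm))
        flipped = ds % 2 == 0
        conds = {}
        for label in ("A", "B"):
            df = pd.concat(cond_frames[label], ignore_index=True)
            df["participant"] = df["participant"].map(remap)
            conds[label] = df
        if flipped:
            conds = {"A": conds["B"], "B": conds["A"]}
            truth = truth.swapped()
            provenance = (cell_b, cell_a)
        else:
            provenance = (cell_a, cell_b)
        for label in ("A", "B"):
            conds[label] = conds[label].assign(condition=label)
        out.append(
            PseudoExperiment(
                id=ds,
                trials_A=conds["A"],
                trials_B=conds["B"],
                truth=truth,
                provenance=provenance,
                flipped=flipped,
            )
        )
    return out


def truth_table(experiments: list[PseudoExperiment]) -> pd.DataFrame:
    """One row per data set, columns = components, values in {A, 0, B}."""
    return pd.DataFrame(
        [{"dataset": e.id, **dict(zip(COMPONENTS, e.truth.as_tuple()))} for e in experiments]
    ).set_index("dataset")
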