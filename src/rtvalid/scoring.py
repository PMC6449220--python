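"""Scoring inference tables against the truth under alternative keys.

The planned key assumes strict selective influence.  Two alternative keys
encode plausible violations reported in the literature: emphasis
manipulations may also affect ease (alternative 1) or non-decision time
(alternative 2); both modify the truth only where caution was manipulated.
A post-hoc key simply drops the non-decision-time column.  Every slot
(data set x component) is classified as correct, miss, false alarm, or
flip, and methods are compared by the proportion of identical inferences.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .pseudo import COMPONENTS

KEY_NAMES = ("planned", "alt1_caution_ease", "alt2_caution_ndt", "planned_no_ndt")
OUTCOMES = ("correct", "miss", "false_alarm", "flip")


@dataclass(frozen=True)
class ScoringKey:
    name: str

    def __post_init__(self) -> None:
        if self.name not in KEY_NAMES:
            raise ValueError(f"key must be one of {KEY_NAMES}")


def build_truth(patterns: pd.DataFrame, key: ScoringKey | str) -> pd.DataFrame:
    """Re-express a truth table (rows = data sets, columns = components)
    under a scoring key.

    planned: unchanged.  alt1: wherever caution was manipulated, ease is
    assumed manipulated in the same direction; data sets whose original
    ease and caution truths point in opposite directions cannot be rescored
    and are dropped.  alt2: same coupling, into ndt.  planned_no_ndt: the
    ndt column is removed.
    """
    if isinstance(key, str):
        key = ScoringKey(key)
    t = patterns.copy()
    if key.name == "planned":
        return t
    if key.name == "planned_no_ndt":
        return t.drop(columns="ndt")
    manip = t["caution"] != "0"
    if key.name == "alt1_caution_ease":
        opposed = manip & (t["ease"] != "0") & (t["ease"] != t["caution"])
        t = t[~opposed].copy()
        t.loc[t["caution"] != "0", "ease"] = t["caution"]
        return t
    # alt2_caution_ndt
    t.loc[manip, "ndt"] = t.loc[manip, "caution"]
    return t


def classify_slot(truth: str, inferred: str) -> str:
    """correct / miss / false_alarm / flip for one data set x component slot."""
    for lab in (truth, inferred):
        if lab not in ("A", "0", "B"):
            raise ValueError(f"labels must be in {{A, 0, B}}, got {lab!r}")
    if truth == inferred:
        return "correct"
    if truth != "0" and inferred == "0":
        return "miss"
    if truth == "0":
        return "false_alarm"
    return "flip"


@dataclass(frozen=True)
class ScoreSummary:
    n_slots: int
    counts: dict[str, int]

    @property
    def proportions(self) -> dict[str, float]:
        return {k: v / self.n_slots for k, v in self.counts.items()}

    def display(self, decimals: int = 2) -> dict[str, float]:
        """Proportions rounded half-up for tabulation."""
        q = Decimal(10) ** -decimals
        return {
            k: float(Decimal(repr(v)).quantize(q, rounding=ROUND_HALF_UP))
            for k, v in self.proportions.items()
        }


def score_slots(inferences: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Outcome of every slot shared by the inference and truth tables."""
    cols = [c for c in truth.columns if c in COMPONENTS]
    common = truth.index.intersection(inferences.index)
    if len(common) != len(truth.index):
        missing = set(truth.index) - set(common)
        raise ValueError(f"inference table lacks data sets {sorted(missing)}")
    rows = []
    for ds in truth.index:
        for comp in cols:
            rows.append(
                {
                    "dataset": ds,
                    "component": comp,
                    "truth": truth.loc[ds, comp],
                    "inferred": inferences.loc[ds, comp],
                    "outcome": classify_slot(truth.loc[ds, comp], inferences.loc[ds, comp]),
                }
            )
    return pd.DataFrame(rows)


def summarize_scores(inferences: pd.DataFrame, truth: pd.DataFrame) -> ScoreSummary:
    """Counts and proportions of each outcome over all truth-table slots."""
    slots = score_slots(inferences, truth)
    counts = {o: int((slots["outcome"] == o).sum()) for o in OUTCOMES}
    return ScoreSummary(n_slots=len(slots), counts=counts)


def agreement_matrix(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Pairwise proportion of identical {A, 0, B} entries across methods.

    All tables must cover the same data sets and components; the diagonal
    is 1 by construction and the matrix is symmetric.
    """
    names = list(tables)
    if len(names) < 2:
        raise ValueError("need at least two methods")
    ref = tables[names[0]]
    flat = {}
    for name, tab in tables.items():
        if not (tab.index.equals(ref.index) and list(tab.columns) == list(ref.columns)):
            tab = tab.loc[ref.index, ref.columns]
        flat[name] = tab.to_numpy().ravel()
    n = len(flat[names[0]])
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            prop = float(np.mean(flat[a] == flat[b]))
            out.loc[a, b] = out.loc[b, a] = prop
    return out
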