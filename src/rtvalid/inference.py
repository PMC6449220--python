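"""Turning per-condition fits or raw summaries into a manipulation pattern.

Two procedure families mirror what analysts actually do with this kind of
data: an estimate-based procedure (paired hypothesis tests on
individual-participant parameter estimates, the modal choice in practice)
and a heuristic procedure working directly from accuracy, RT quantiles and
the signal-detection criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pseudo import COMPONENTS, ManipulationPattern

DIFFUSION_COMPONENT_MAP = {"ease": "v", "caution": "a", "biasR": "zr", "ndt": "ter"}
LBA_COMPONENT_MAP = {"ease": "v_delta", "caution": "b", "biasR": "start_bias", "ndt": "t0"}


@dataclass(frozen=True)
class InferenceConfig:
    alpha: float = 0.05
    component_map: dict[str, str] = field(default_factory=lambda: dict(DIFFUSION_COMPONENT_MAP))
    # heuristic cutoffs
    accuracy_cutoff: float = 0.05  # the classic 5 %-accuracy rule for ease
    rt_quantile_cutoff: float = 0.050  # s, on the .9 (caution) and .1 (ndt) quantiles
    criterion_cutoff: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if min(self.accuracy_cutoff, self.rt_quantile_cutoff, self.criterion_cutoff) < 0:
            raise ValueError("heuristic cutoffs must be >= 0")


def infer_pattern_estimate_based(
    fits_A: pd.DataFrame, fits_B: pd.DataFrame, cfg: InferenceConfig = InferenceConfig()
) -> ManipulationPattern:
    """Paired two-sided t-tests on mapped parameters across participants.

    Per component: test the paired difference of the mapped parameter; if
    p < alpha, label the condition with the higher mean ('A' or 'B'),
    otherwise '0'.  No correction across the four components.
    """
    common = fits_A.index.intersection(fits_B.index)
    if len(common) < 3:
        raise ValueError(f"need >= 3 paired participants, have {len(common)}")
    labels = {}
    for comp in COMPONENTS:
        col = cfg.component_map[comp]
        if col not in fits_A.columns or col not in fits_B.columns:
            labels[comp] = "0"
            continue
        xa = fits_A.loc[common, col].to_numpy(float)
        xb = fits_B.loc[common, col].to_numpy(float)
        diff = xa - xb
        if np.allclose(diff, 0.0):
            labels[comp] = "0"
            continue
        res = stats.ttest_rel(xa, xb)
        if res.pvalue < cfg.alpha:
            labels[comp] = "A" if diff.mean() > 0 else "B"
        else:
            labels[comp] = "0"
    return ManipulationPattern(**labels)


@dataclass(frozen=True)
class SDTRates:
    H: float  # P(respond 'L' | stimulus 'L'), edge-corrected
    FA: float  # P(respond 'L' | stimulus 'R'), edge-corrected


def sdt_criterion(rates: SDTRates) -> float:
    """Signal-detection criterion C = (z(H) + z(FA)) / 2.

    ``z`` is the standard-normal quantile function; positive C means a bias
    toward responding 'left'.
    """
    if not (0.0 < rates.H < 1.0 and 0.0 < rates.FA < 1.0):
        raise ValueError("H and FA must be edge-corrected into (0, 1)")
    return float(0.5 * (stats.norm.ppf(rates.H) + stats.norm.ppf(rates.FA)))


def sdt_rates_from_trials(trials: pd.DataFrame) -> SDTRates:
    """Hit / false-alarm rates for 'L' responses, 1/(2n) edge correction."""
    from .estimation import edge_correct, filter_trials

    t = filter_trials(trials)
    out = {}
    for stim in ("L", "R"):
        grp = t[t["stimulus"] == stim]
        if len(grp) == 0:
            raise ValueError(f"no scoreable trials with stimulus {stim!r}")
        out[stim] = edge_correct(float((grp["response"] == "L").mean()), len(grp))
    return SDTRates(H=out["L"], FA=out["R"])


def _pooled_stats(trials: pd.DataFrame) -> dict[str, float]:
    from .estimation import filter_trials

    t = filter_trials(trials)
    d = {
        "accuracy": float(t["correct"].mean()),
        "rt_q10": float(t["rt"].quantile(0.1)),
        "rt_q90": float(t["rt"].quantile(0.9)),
        "criterion": sdt_criterion(sdt_rates_from_trials(trials)),
    }
    for resp in ("L", "R"):
        grp = t[t["response"] == resp]
        d[f"rt_q10_{resp}"] = float(grp["rt"].quantile(0.1)) if len(grp) else np.nan
    return d


def infer_pattern_heuristic(
    trials_A: pd.DataFrame, trials_B: pd.DataFrame, cfg: InferenceConfig = InferenceConfig()
) -> ManipulationPattern:
    """Summary-statistic rules, one per component.

    ease: accuracy differs by more than the 5 % cutoff (RT direction is not
    consulted, matching the classic rule).
    caution: the slower condition (by the .9 RT quantile, beyond cutoff) is
    also the more accurate one.
    biasR: criterion difference beyond cutoff; the condition with the lower
    (more rightward) criterion gets the label.
    ndt: the .1 RT quantile shifts beyond cutoff in the same direction for
    both response classes (a common shift of the whole distribution).
    """
    if len(trials_A) == 0 or len(trials_B) == 0:
        raise ValueError("both conditions must contain trials")
    sa, sb = _pooled_stats(trials_A), _pooled_stats(trials_B)
    labels = {c: "0" for c in COMPONENTS}

    d_acc = sa["accuracy"] - sb["accuracy"]
    if abs(d_acc) > cfg.accuracy_cutoff:
        labels["ease"] = "A" if d_acc > 0 else "B"

    d_q90 = sa["rt_q90"] - sb["rt_q90"]
    if abs(d_q90) > cfg.rt_quantile_cutoff and d_acc * d_q90 > 0:
        # slower and more accurate -> more cautious
        labels["caution"] = "A" if d_q90 > 0 else "B"

    d_c = sa["criterion"] - sb["criterion"]
    if abs(d_c) > cfg.criterion_cutoff:
        labels["biasR"] = "B" if d_c > 0 else "A"

    shifts = [
        sa[f"rt_q10_{r}"] - sb[f"rt_q10_{r}"]
        for r in ("L", "R")
        if np.isfinite(sa[f"rt_q10_{r}"]) and np.isfinite(sb[f"rt_q10_{r}"])
    ]
    if len(shifts) == 2 and all(abs(s) > cfg.rt_quantile_cutoff for s in shifts):
        if shifts[0] > 0 and shifts[1] > 0:
            labels["ndt"] = "A"
        elif shifts[0] < 0 and shifts[1] < 0:
            labels["ndt"] = "B"
    return ManipulationPattern(**labels)


def inference_table(patterns: dict[int, ManipulationPattern]) -> pd.DataFrame:
    """Rows = data sets, columns = components, values in {A, 0, B}."""
    return pd.DataFrame(
        [{"dataset": ds, **dict(zip(COMPONENTS, p.as_tuple()))} for ds, p in sorted(patterns.items())]
    ).set_index("dataset")
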