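"""Synthetic factorial two-choice session.

Emulates the behavioural study the pipeline validates against: 20
participants run 18 main blocks of 156 trials of a left/right motion
discrimination.  Speed/accuracy emphasis and stimulus base-rate bias vary
across blocks following a fixed schedule; difficulty (easy/hard) is mixed
50/50 within every block; responses are censored at a 3 s deadline.

Each design cell maps onto diffusion parameters by selective influence:
easy stimuli raise the drift rate, accuracy emphasis raises the boundary
separation, and a base-rate bias both shifts the start point toward the
favoured side and sets that side's stimulus rate to 2/3.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .diffusion import _draw_trial_params, euler_fpt_batch, sample_fpt_inverse_cdf
from .params import DiffusionParams

EMPHASIS_SCHEDULE = (
    "sp ac sp sp ac ac sp sp ac ac sp sp ac ac sp sp ac sp".split()
)
BIAS_SCHEDULE = (
    "none none none left left none none right right none "
    "none left left none none right right none".split()
)
N_TRIALS_PER_BLOCK = 156
N_PARTICIPANTS = 20
DEADLINE = 3.0

DIFFICULTIES = ("easy", "hard")
EMPHASES = ("speed", "accuracy")
BIASES = ("left", "none", "right")
_EMPH_CODE = {"sp": "speed", "ac": "accuracy"}


@dataclass(frozen=True)
class DesignCell:
    """One cell of the 2 (difficulty) x 2 (emphasis) x 3 (bias) design."""

    difficulty: str
    emphasis: str
    bias: str

    def __post_init__(self) -> None:
        if self.difficulty not in DIFFICULTIES:
            raise ValueError(f"difficulty must be one of {DIFFICULTIES}")
        if self.emphasis not in EMPHASES:
            raise ValueError(f"emphasis must be one of {EMPHASES}")
        if self.bias not in BIASES:
            raise ValueError(f"bias must be one of {BIASES}")


@dataclass(frozen=True)
class BlockSpec:
    index: int
    emphasis: str
    bias: str
    n_trials: int = N_TRIALS_PER_BLOCK


def default_schedule() -> list[BlockSpec]:
    """The 18-block schedule: each emphasis x bias cell occurs four times in
    blocks 2-17, and blocks 1 and 18 add two extra speed/no-bias blocks."""
    return [
        BlockSpec(i + 1, _EMPH_CODE[e], b)
        for i, (e, b) in enumerate(zip(EMPHASIS_SCHEDULE, BIAS_SCHEDULE))
    ]


@dataclass(frozen=True)
class EffectSizes:
    """Manipulation effect sizes on the diffusion parameters (s = 1 scale).

    With the default base parameters (v=1, a=1, zr=0.5, ter=0.3 s) these
    yield hard/easy drift 1.0/2.0, speed/accuracy boundary 1.0/2.0 and a
    start point of 0.55 toward the favoured side -- behaviour in the
    accuracy and median-RT ranges the reference study reports.
    """

    easy_v_factor: float = 2.0
    accuracy_a_factor: float = 2.0
    bias_zr_shift: float = 0.05
    biased_stim_rate: float = 2.0 / 3.0


DEFAULT_BASE = DiffusionParams(v=1.0, a=1.0, zr=0.5, ter=0.3, s=1.0)


@dataclass(frozen=True)
class ParticipantSpread:
    """Between-participant heterogeneity: coefficients of variation of the
    log-normally perturbed positive parameters and the SD of the
    logit-normally perturbed start point."""

    cv_v: float = 0.1
    cv_a: float = 0.1
    cv_ter: float = 0.1
    sd_logit_zr: float = 0.1


def participant_population(
    n_participants: int,
    base: DiffusionParams = DEFAULT_BASE,
    spread: ParticipantSpread = ParticipantSpread(),
    rng_seed: int = 0,
) -> list[DiffusionParams]:
    """Draw per-participant baseline parameters around ``base``.

    Positive parameters get mean-preserving log-normal multipliers with the
    configured coefficient of variation; ``zr`` is perturbed on the logit
    scale.  Zero spread returns ``n_participants`` copies of ``base``.
    """
    if n_participants < 1:
        raise ValueError("need at least one participant")
    rng = np.random.default_rng(rng_seed)

    def lognorm_mult(cv: float, size: int) -> np.ndarray:
        if cv == 0.0:
            return np.ones(size)
        sigma = np.sqrt(np.log1p(cv**2))
        return np.exp(rng.normal(-sigma**2 / 2.0, sigma, size))

    mv = lognorm_mult(spread.cv_v, n_participants)
    ma = lognorm_mult(spread.cv_a, n_participants)
    mt = lognorm_mult(spread.cv_ter, n_participants)
    logit_zr = np.log(base.zr / (1.0 - base.zr)) + (
        rng.normal(0.0, spread.sd_logit_zr, n_participants)
        if spread.sd_logit_zr > 0
        else np.zeros(n_participants)
    )
    zr = 1.0 / (1.0 + np.exp(-logit_zr))
    return [
        replace(base, v=base.v * mv[i], a=base.a * ma[i], ter=base.ter * mt[i], zr=float(zr[i]))
        for i in range(n_participants)
    ]


def map_cell_to_params(
    base: DiffusionParams, cell: DesignCell, effects: EffectSizes = EffectSizes()
) -> DiffusionParams:
    """Apply the selective-influence mapping of a design cell to ``base``.

    The reference cell (hard, speed, none) returns ``base`` unchanged; easy
    stimuli scale ``v``, accuracy emphasis scales ``a``, and a bias shifts
    ``zr`` toward the favoured side.  The stimulus base rate is handled by
    the session simulator, not here.
    """
    p = base
    if cell.difficulty == "easy":
        p = replace(p, v=p.v * effects.easy_v_factor)
    if cell.emphasis == "accuracy":
        p = replace(p, a=p.a * effects.accuracy_a_factor)
    if cell.bias == "right":
        p = replace(p, zr=p.zr + effects.bias_zr_shift)
    elif cell.bias == "left":
        p = replace(p, zr=p.zr - effects.bias_zr_shift)
    return p


def _child_rng(rng_seed: int, *key: int) -> np.random.Generator:
    """Deterministic substream (e.g. one per participant) of the master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(rng_seed) & 0x7FFFFFFF, *key]))


def simulate_factorial_session(
    schedule: list[BlockSpec] | None = None,
    participants: list[DiffusionParams] | None = None,
    rng_seed: int = 0,
    effects: EffectSizes = EffectSizes(),
    deadline: float = DEADLINE,
    dt: float = 1e-4,
    sampler: str = "auto",
) -> pd.DataFrame:
    """Simulate the full factorial session for all participants.

    Returns a tidy trial table with columns participant, block, emphasis,
    bias, difficulty, trial (0-based within block), stimulus, response, rt,
    timed_out, correct.

    ``sampler='auto'`` draws choices and RTs from the exact first-passage
    law (inverse-CDF) whenever a participant follows the simple model, and
    falls back to Euler-Maruyama integration (step ``dt``) when
    trial-to-trial variability makes trials non-identically distributed
    within a cell; 'euler' forces the latter everywhere.
    """
    if sampler not in ("auto", "euler", "cdf"):
        raise ValueError("sampler must be 'auto', 'euler' or 'cdf'")
    if schedule is None:
        schedule = default_schedule()
    if participants is None:
        participants = participant_population(N_PARTICIPANTS, rng_seed=_child_rng(rng_seed, 0))

    frames = []
    for pid, base in enumerate(participants):
        rng = _child_rng(rng_seed, 1, pid)
        cols = {
            k: []
            for k in ("block", "emphasis", "bias", "difficulty", "trial", "stimulus")
        }
        for blk in schedule:
            n = blk.n_trials
            # 50/50 easy-hard, randomly intermixed
            difficulty = np.array(["easy"] * (n // 2) + ["hard"] * (n - n // 2))
            rng.shuffle(difficulty)
            if blk.bias == "none":
                p_right = 0.5
            elif blk.bias == "right":
                p_right = effects.biased_stim_rate
            else:
                p_right = 1.0 - effects.biased_stim_rate
            stimulus = np.where(rng.random(n) < p_right, "R", "L")

            cols["block"].append(np.full(n, blk.index))
            cols["emphasis"].append(np.full(n, blk.emphasis, dtype=object))
            cols["bias"].append(np.full(n, blk.bias, dtype=object))
            cols["difficulty"].append(difficulty)
            cols["trial"].append(np.arange(n))
            cols["stimulus"].append(stimulus)

        flat = {k: np.concatenate(c) for k, c in cols.items()}
        n_tot = len(flat["stimulus"])
        rt = np.empty(n_tot)
        up = np.zeros(n_tot, dtype=bool)
        tout = np.zeros(n_tot, dtype=bool)
        use_cdf = sampler == "cdf" or (sampler == "auto" and base.is_simple)
        if use_cdf:
            for diff in DIFFICULTIES:
                for emph in EMPHASES:
                    for bias in BIASES:
                        p = map_cell_to_params(base, DesignCell(diff, emph, bias), effects)
                        cell_mask = (
                            (flat["difficulty"] == diff)
                            & (flat["emphasis"] == emph)
                            & (flat["bias"] == bias)
                        )
                        for stim in ("L", "R"):
                            mask = cell_mask & (flat["stimulus"] == stim)
                            m = int(mask.sum())
                            if m == 0:
                                continue
                            r, u, to = sample_fpt_inverse_cdf(p, stim, m, deadline, rng)
                            rt[mask], up[mask], tout[mask] = r, u, to
        else:
            v = np.empty(n_tot)
            a = np.empty(n_tot)
            zr = np.empty(n_tot)
            ter = np.empty(n_tot)
            for diff in DIFFICULTIES:
                for emph in EMPHASES:
                    for bias in BIASES:
                        p = map_cell_to_params(base, DesignCell(diff, emph, bias), effects)
                        mask = (
                            (flat["difficulty"] == diff)
                            & (flat["emphasis"] == emph)
                            & (flat["bias"] == bias)
                        )
                        m = int(mask.sum())
                        if m == 0:
                            continue
                        vt, zt, tt = _draw_trial_params(p, m, rng)
                        v[mask], zr[mask], ter[mask] = vt, zt, tt
                        a[mask] = p.a
            v = np.where(flat["stimulus"] == "R", v, -v)
            rt, up, tout = euler_fpt_batch(v, a, zr, ter, base.s, deadline, dt, rng)
        frames.append(
            pd.DataFrame(
                {
                    "participant": pid,
                    **flat,
                    "response": np.where(up, "R", "L"),
                    "rt": rt,
                    "timed_out": tout,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out["correct"] = (out["stimulus"] == out["response"]) & ~out["timed_out"]
    return out


def relabel_trials(t: pd.DataFrame) -> pd.DataFrame:
    """Recode left/right so the favoured option always reads 'R'.

    In biased blocks, stimulus and response labels are swapped wherever the
    favoured side is 'left'.  In no-bias blocks, both labels are flipped for
    the even-indexed half of the trials, averaging out any natural side
    preference.  RT, timed-out status and correctness are untouched.
    """
    for col in ("bias", "stimulus", "response", "trial"):
        if col not in t.columns:
            raise ValueError(f"trial table lacks required column {col!r}")
    out = t.copy()
    swap = {"L": "R", "R": "L"}
    flip = (out["bias"] == "left") | ((out["bias"] == "none") & (out["trial"] % 2 == 0))
    out.loc[flip, "stimulus"] = out.loc[flip, "stimulus"].map(swap)
    out.loc[flip, "response"] = out.loc[flip, "response"].map(swap)
    if "correct" in out.columns:
        out["correct"] = (out["stimulus"] == out["response"]) & ~out["timed_out"]
    return out


def block_descriptives(t: pd.DataFrame) -> pd.DataFrame:
    """Accuracy and RT quantiles (.1/.5/.9) per block, pooled over participants."""
    ok = t[~t["timed_out"]]
    g = ok.groupby("block")
    return pd.DataFrame(
        {
            "accuracy": g["correct"].mean(),
            "rt_q10": g["rt"].quantile(0.1),
            "rt_q50": g["rt"].quantile(0.5),
            "rt_q90": g["rt"].quantile(0.9),
            "emphasis": g["emphasis"].first(),
            "bias": g["bias"].first(),
        }
    )
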