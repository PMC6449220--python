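"""Linear ballistic accumulator: defective densities and simulation.

Each response side has an independent accumulator that starts at a point
drawn uniformly from ``[0, A]``, rises with a normally distributed slope
(no within-trial noise), and triggers its response on reaching its
threshold.  The winning accumulator's density times the survivor function
of the loser gives the defective density of that response.  Because slopes
may be negative, a trial can have no finishing accumulator; that mass,
``P(both drifts < 0)``, is what keeps the two defective densities from
integrating to one.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr

_SQRT2PI = 2.5066282746310002

from .params import LBAParams, ParameterError


def _phi(x):
    """Standard normal pdf (vectorised, minimal overhead)."""
    return np.exp(-0.5 * np.square(x)) / _SQRT2PI


def _acc_pdf(t: np.ndarray, b: float, A: float, v: float, s: float) -> np.ndarray:
    """Density of a single accumulator's finishing time (untruncated drifts)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tt = t[pos]
    if A == 0.0:
        out[pos] = (b / (s * tt**2)) * _phi((b / tt - v) / s)
        return out
    d1 = (b - A - tt * v) / (tt * s)
    d2 = (b - tt * v) / (tt * s)
    out[pos] = (-v * ndtr(d1) + s * _phi(d1) + v * ndtr(d2) - s * _phi(d2)) / A
    return np.maximum(out, 0.0)


def _acc_cdf(t: np.ndarray, b: float, A: float, v: float, s: float) -> np.ndarray:
    """CDF of a single accumulator's finishing time (untruncated drifts)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tt = t[pos]
    if A == 0.0:
        out[pos] = ndtr((v - b / tt) / s)
        return out
    d1 = (b - A - tt * v) / (tt * s)
    d2 = (b - tt * v) / (tt * s)
    out[pos] = (
        1.0
        + ((b - A - tt * v) / A) * ndtr(d1)
        - ((b - tt * v) / A) * ndtr(d2)
        + (tt * s / A) * (_phi(d1) - _phi(d2))
    )
    return np.clip(out, 0.0, 1.0)


def lba_defective_density(
    t: float | np.ndarray,
    p: LBAParams,
    which: str = "match",
    stim: str = "R",
) -> np.ndarray | float:
    """Defective density that the ``match``/``mismatch`` accumulator wins at ``t``.

    ``t`` is the observed response time; the race runs over ``t - t0`` and
    the density vanishes for ``t <= t0``.  With ``start_bias != 0`` the two
    accumulators carry side-specific thresholds, so the stimulus side
    matters; with the default unbiased parameters it does not.
    """
    if which not in ("match", "mismatch"):
        raise ParameterError(f"which must be 'match' or 'mismatch', got {which!r}")
    if stim not in ("L", "R"):
        raise ParameterError(f"stim must be 'L' or 'R', got {stim!r}")
    scalar = np.isscalar(t)
    tau = np.atleast_1d(np.asarray(t, dtype=float)) - p.t0

    b_match = p.threshold(stim == "R")
    b_mis = p.threshold(stim != "R")
    if which == "match":
        win = (b_match, p.v_c)
        lose = (b_mis, p.v_e)
    else:
        win = (b_mis, p.v_e)
        lose = (b_match, p.v_c)
    out = _acc_pdf(tau, win[0], p.A, win[1], p.sdrift) * (
        1.0 - _acc_cdf(tau, lose[0], p.A, lose[1], p.sdrift)
    )
    return float(out[0]) if scalar else out


def lba_response_density(
    t: float | np.ndarray, p: LBAParams, response: str, stim: str
) -> np.ndarray | float:
    """Defective density of responding ``response`` at time ``t`` given ``stim``."""
    which = "match" if response == stim else "mismatch"
    return lba_defective_density(t, p, which=which, stim=stim)


def prob_no_response(p: LBAParams) -> float:
    """P(both sampled drifts are negative): mass missing from the two densities."""
    return float(ndtr(-p.v_c / p.sdrift) * ndtr(-p.v_e / p.sdrift))


def simulate_lba(
    p: LBAParams,
    stim: str,
    n: int,
    deadline: float = 3.0,
    rng_seed: int = 0,
    negative_drift: str = "resample",
):
    """Simulate ``n`` LBA trials; returns a DataFrame (response, rt, timed_out).

    Trials on which both sampled drifts are non-positive never finish; by
    default they are redrawn (the number of redraws is recorded in
    ``df.attrs['n_resampled']``), or censored at the deadline with
    ``negative_drift='censor'``.
    """
    import pandas as pd

    if stim not in ("L", "R"):
        raise ParameterError(f"stim must be 'L' or 'R', got {stim!r}")
    if n < 1:
        raise ParameterError("need n >= 1 trials")
    if negative_drift not in ("resample", "censor"):
        raise ParameterError("negative_drift must be 'resample' or 'censor'")
    rng = np.random.default_rng(rng_seed)

    v_R = p.v_c if stim == "R" else p.v_e
    v_L = p.v_e if stim == "R" else p.v_c
    b_R, b_L = p.threshold(True), p.threshold(False)

    d_R = rng.normal(v_R, p.sdrift, size=n)
    d_L = rng.normal(v_L, p.sdrift, size=n)
    n_resampled = 0
    if negative_drift == "resample":
        stuck = (d_R <= 0) & (d_L <= 0)
        while stuck.any():
            n_resampled += int(stuck.sum())
            d_R[stuck] = rng.normal(v_R, p.sdrift, size=int(stuck.sum()))
            d_L[stuck] = rng.normal(v_L, p.sdrift, size=int(stuck.sum()))
            stuck = (d_R <= 0) & (d_L <= 0)
    u_R = rng.uniform(0.0, p.A, size=n) if p.A > 0 else np.zeros(n)
    u_L = rng.uniform(0.0, p.A, size=n) if p.A > 0 else np.zeros(n)

    with np.errstate(divide="ignore"):
        t_R = np.where(d_R > 0, (b_R - u_R) / d_R, np.inf)
        t_L = np.where(d_L > 0, (b_L - u_L) / d_L, np.inf)
    t_win = np.minimum(t_R, t_L)
    resp = np.where(t_R <= t_L, "R", "L")
    rt = p.t0 + t_win
    timed_out = rt > deadline
    rt = np.where(timed_out, deadline, rt)
    df = pd.DataFrame({"response": resp, "rt": rt, "timed_out": timed_out})
    df.attrs["n_resampled"] = n_resampled
    return df
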