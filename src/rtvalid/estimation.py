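"""Parameter estimation: EZ / EZ2 moment methods and maximum likelihood.

All estimators share one outlier rule, applied before anything else: trials
faster than 0.18 s and trials censored at the deadline are dropped.

EZ inverts the closed-form forward map of the unbiased simple diffusion --
accuracy, plus mean and variance of correct-response RTs -- into (v, a,
ter); the inversion is algebraically exact, so forward moments of any
parameter set round-trip to machine precision.  EZ2 generalises this to a
biased start point by solving the moment equations per stimulus side
(response proportion, RT mean and RT variance for each side) numerically.

Maximum likelihood fits the simple diffusion (via the series first-passage
density) or the LBA (via its closed-form defective density) per participant
and condition, with a derivative-free simplex started from moment-based
initial values and refreshed from jittered restarts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize

from . import diffusion as dfu
from . import lba as lbam
from .params import DiffusionParams, LBAParams

MIN_RT = 0.18  # fastest plausible genuine response (s)


def filter_trials(trials: pd.DataFrame, min_rt: float = MIN_RT) -> pd.DataFrame:
    """Outlier rule shared by every estimator: drop censored and sub-``min_rt`` trials."""
    keep = (~trials["timed_out"]) & (trials["rt"] >= min_rt)
    return trials[keep]


def edge_correct(p: float, n: int) -> float:
    """Pull a proportion of 0 or 1 in by 1/(2n) so logits stay finite."""
    if p <= 0.0:
        return 1.0 / (2 * n)
    if p >= 1.0:
        return 1.0 - 1.0 / (2 * n)
    return p


@dataclass(frozen=True)
class SideMoments:
    n: int
    p_r: float  # P(respond 'R' | this stimulus side), edge-corrected
    mrt: float  # mean RT, all responses to this side
    vrt: float  # RT variance (ddof=1), all responses to this side


@dataclass(frozen=True)
class EZMoments:
    n: int
    pc: float  # proportion correct, edge-corrected
    mrt: float  # mean RT of correct responses
    vrt: float  # variance of correct-response RTs
    by_stim: dict[str, SideMoments] = field(default_factory=dict)


def compute_ez_moments(trials: pd.DataFrame, min_rt: float = MIN_RT) -> EZMoments:
    """Accuracy and correct-RT moments, plus per-stimulus-side moments for EZ2.

    ``Pc`` is edge-corrected at 0 and 1 by 1/(2n); an exact 0.5 is nudged by
    1/(2n) in the direction implied by the relative speed of correct versus
    error responses (correct faster implies above-chance drift).
    """
    t = filter_trials(trials, min_rt)
    n = len(t)
    if n == 0 or t["correct"].sum() == 0:
        raise ValueError("need at least one correct, scoreable trial")
    pc = float(t["correct"].mean())
    if pc == 0.5:
        mc = t.loc[t["correct"], "rt"].mean()
        me = t.loc[~t["correct"], "rt"].mean()
        pc += (1.0 if mc <= me else -1.0) / (2 * n)
    pc = edge_correct(pc, n)
    rt_c = t.loc[t["correct"], "rt"]
    mrt = float(rt_c.mean())
    vrt = float(rt_c.var(ddof=1)) if len(rt_c) > 1 else float("nan")

    by_stim = {}
    if "stimulus" in t.columns:
        for side, grp in t.groupby("stimulus"):
            ns = len(grp)
            pr = edge_correct(float((grp["response"] == "R").mean()), ns)
            by_stim[side] = SideMoments(
                n=ns,
                p_r=pr,
                mrt=float(grp["rt"].mean()),
                vrt=float(grp["rt"].var(ddof=1)) if ns > 1 else float("nan"),
            )
    return EZMoments(n=n, pc=pc, mrt=mrt, vrt=vrt, by_stim=by_stim)


# ---------------------------------------------------------------- EZ ---


def ez_forward_moments(v: float, a: float, ter: float, s: float = 1.0):
    """(Pc, MRT, VRT) predicted by the unbiased simple diffusion."""
    p = DiffusionParams(v=v, a=a, zr=0.5, ter=ter, s=s)
    pc = dfu.boundary_hit_probability(p, "upper")
    mrt = dfu.fpt_mean(p) + ter
    vrt = dfu.fpt_variance(p)
    return pc, mrt, vrt


def ez_point_estimates(m: EZMoments, s: float = 1.0) -> tuple[float, float, float]:
    """Closed-form EZ inversion of (Pc, MRT, VRT) into (v, a, ter)."""
    pc, mrt, vrt = m.pc, m.mrt, m.vrt
    if not vrt > 0:
        raise ValueError(f"RT variance must be positive, got {vrt}")
    if pc in (0.0, 0.5, 1.0):
        raise ValueError("Pc must be edge-corrected away from {0, 0.5, 1}")
    L = np.log(pc / (1.0 - pc))
    x = L * (L * pc**2 - L * pc + pc - 0.5) / vrt
    v = np.sign(pc - 0.5) * s * x**0.25
    a = s**2 * L / v
    y = np.exp(-v * a / s**2)
    mdt = (a / (2.0 * v)) * (1.0 - y) / (1.0 + y)
    return float(v), float(a), float(mrt - mdt)


# --------------------------------------------------------------- EZ2 ---


def ez2_forward_moments(
    v: float, a: float, zr: float, ter: float, s: float = 1.0
) -> dict[str, tuple[float, float, float]]:
    """Per-stimulus-side (P(resp R), MRT, VRT) under the biased simple diffusion."""
    out = {}
    for side, drift in (("R", v), ("L", -v)):
        p = DiffusionParams(v=drift, a=a, zr=zr, ter=ter, s=s)
        out[side] = (
            dfu.boundary_hit_probability(p, "upper"),
            dfu.fpt_mean(p) + ter,
            dfu.fpt_variance(p),
        )
    return out


@dataclass(frozen=True)
class EZ2Result:
    v: float
    a: float
    zr: float
    ter: float
    converged: bool
    cost: float


def ez2_point_estimates(m: EZMoments, s: float = 1.0) -> EZ2Result:
    """Numeric solution of the per-side moment equations for (v, a, zr, ter).

    Minimises squared residuals between observed and predicted response
    proportions (on the logit scale), RT means and RT standard deviations
    for both stimulus sides; started from the EZ solution with zr = 0.5.
    Reduces to the EZ estimates (with zr = 0.5) for side-symmetric moments.
    """
    if set(m.by_stim) != {"L", "R"}:
        raise ValueError("EZ2 requires moments for both stimulus sides")

    obs = []
    for side in ("R", "L"):
        sm = m.by_stim[side]
        obs.append((np.log(sm.p_r / (1 - sm.p_r)), sm.mrt, np.sqrt(sm.vrt)))

    def residuals(theta):
        v, log_a, logit_zr, ter = theta
        a = np.exp(log_a)
        zr = 1.0 / (1.0 + np.exp(-logit_zr))
        pred = ez2_forward_moments(v, a, zr, ter, s)
        res = []
        for (lo, mo, so), side in zip(obs, ("R", "L")):
            pr, mrt, vrt = pred[side]
            pr = min(max(pr, 1e-12), 1 - 1e-12)
            res += [
                0.2 * (np.log(pr / (1 - pr)) - lo),
                mrt - mo,
                np.sqrt(max(vrt, 1e-12)) - so,
            ]
        return np.asarray(res)

    try:
        v0, a0, t0 = ez_point_estimates(m, s)
    except ValueError:
        v0, a0, t0 = 1.0, 1.0 * s, max(m.mrt - 0.2, 0.05)
    best = None
    for jit in (0.0, 0.15, -0.15):
        x0 = np.array([v0 * (1 + jit), np.log(a0) + jit, 0.0, t0 * (1 + 0.5 * jit)])
        sol = least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < 1e-16:
            break
    v, log_a, logit_zr, ter = best.x
    return EZ2Result(
        v=float(v),
        a=float(np.exp(log_a)),
        zr=float(1.0 / (1.0 + np.exp(-logit_zr))),
        ter=float(ter),
        converged=bool(best.success),
        cost=float(best.cost),
    )


# ---------------------------------------------------------- ML fits ---


@dataclass(frozen=True)
class FitConfig:
    min_trials: int = 40
    n_starts: int = 5
    seed: int = 0
    min_rt: float = MIN_RT
    max_iter: int = 600
    start_jitter: float = 0.12


@dataclass(frozen=True)
class FitResult:
    params: DiffusionParams | LBAParams
    loglik: float
    converged: bool
    n_used: int
    n_excluded: int
    method: str


def _prep(trials: pd.DataFrame, cfg: FitConfig):
    t = filter_trials(trials, cfg.min_rt)
    if len(t) < cfg.min_trials:
        raise ValueError(f"only {len(t)} scoreable trials, need {cfg.min_trials}")
    rt = t["rt"].to_numpy(float)
    resp_r = (t["response"] == "R").to_numpy()
    stim_r = (t["stimulus"] == "R").to_numpy()
    return rt, resp_r, stim_r, len(t), len(trials) - len(t)


def _diffusion_nll(theta, rt, resp_r, stim_r, min_rt, s):
    v = theta[0]
    a = np.exp(theta[1])
    zr = 1.0 / (1.0 + np.exp(-theta[2]))
    ter = min_rt * 0.999 / (1.0 + np.exp(-theta[3]))
    if abs(v) > 20 or a > 20 * s or a < 1e-3:
        return 1e10
    ll = 0.0
    for sr in (True, False):
        drift = v if sr else -v
        p = DiffusionParams(v=drift, a=a, zr=zr, ter=ter, s=s)
        for ru in (True, False):
            mask = (stim_r == sr) & (resp_r == ru)
            if not mask.any():
                continue
            d = dfu.wiener_fpt_density(rt[mask], p, "upper" if ru else "lower")
            ll += float(np.sum(np.log(np.maximum(d, 1e-300))))
    return -ll


def fit_ml_simple_diffusion(
    trials: pd.DataFrame, cfg: FitConfig = FitConfig(), s: float = 1.0
) -> FitResult:
    """Maximum-likelihood fit of (v, a, zr, ter) for the simple diffusion.

    Multi-start Nelder-Mead on a transformed space (log boundary, logit
    start point, logistic-bounded ter below the fastest retained RT),
    initialised from the EZ2 moment solution.
    """
    rt, resp_r, stim_r, n_used, n_exc = _prep(trials, cfg)
    fastest = float(rt.min())
    rng = np.random.default_rng(cfg.seed)

    m = compute_ez_moments(trials, cfg.min_rt)
    try:
        init = ez2_point_estimates(m, s)
        v0, a0, zr0, t0 = init.v, init.a, init.zr, init.ter
    except ValueError:
        v0, a0, t0 = ez_point_estimates(m, s)
        zr0 = 0.5
    t0 = min(max(t0, 0.02), fastest * 0.95)
    x0 = np.array(
        [v0, np.log(a0), np.log(zr0 / (1 - zr0)), np.log(t0 / (fastest * 0.999 - t0))]
    )

    best = None
    for k in range(cfg.n_starts):
        start = x0 if k == 0 else x0 + rng.normal(0.0, cfg.start_jitter, 4)
        sol = minimize(
            _diffusion_nll,
            start,
            args=(rt, resp_r, stim_r, fastest, s),
            method="Nelder-Mead",
            options={"maxiter": cfg.max_iter, "xatol": 1e-6, "fatol": 1e-8},
        )
        if best is None or sol.fun < best.fun:
            best = sol
    th = best.x
    params = DiffusionParams(
        v=float(th[0]),
        a=float(np.exp(th[1])),
        zr=float(1.0 / (1.0 + np.exp(-th[2]))),
        ter=float(fastest * 0.999 / (1.0 + np.exp(-th[3]))),
        s=s,
    )
    return FitResult(params, -float(best.fun), bool(np.isfinite(best.fun)), n_used, n_exc, "ml_diffusion")


def _lba_nll(theta, rt, resp_r, stim_r, min_rt, estimate_bias):
    b = np.exp(theta[0])
    A = b / (1.0 + np.exp(-theta[1]))
    vc = theta[2]
    ve = theta[3]
    t0 = min_rt * 0.999 / (1.0 + np.exp(-theta[4]))
    bias = np.tanh(theta[5]) * (b - A) * 0.99 if estimate_bias else 0.0  # theta has 5 entries otherwise
    if b > 50 or abs(vc) > 20 or abs(ve) > 20:
        return 1e10
    try:
        p = LBAParams(b=b, A=A, v_c=vc, v_e=ve, sdrift=1.0, t0=t0, start_bias=bias)
    except ValueError:
        return 1e10
    ll = 0.0
    for sr in (True, False):
        stim = "R" if sr else "L"
        for ru in (True, False):
            mask = (stim_r == sr) & (resp_r == ru)
            if not mask.any():
                continue
            d = lbam.lba_response_density(rt[mask], p, "R" if ru else "L", stim)
            ll += float(np.sum(np.log(np.maximum(d, 1e-300))))
    return -ll


def fit_ml_lba(
    trials: pd.DataFrame, cfg: FitConfig = FitConfig(), estimate_bias: bool = False
) -> FitResult:
    """Maximum-likelihood LBA fit of (b, A, v_c, v_e, t0), ``sdrift`` fixed at 1.

    ``estimate_bias=True`` additionally frees the side-specific threshold
    offset.  Multi-start Nelder-Mead from summary-statistic initial values.
    """
    rt, resp_r, stim_r, n_used, n_exc = _prep(trials, cfg)
    fastest = float(rt.min())
    rng = np.random.default_rng(cfg.seed)

    pc = float(np.mean(resp_r == stim_r))
    t0_0 = 0.7 * fastest
    mdt = max(float(rt.mean()) - t0_0, 0.05)
    b0, A0 = 1.0, 0.5
    vc0 = (b0 - A0 / 2) / mdt
    ve0 = vc0 - 2.0 * (pc - 0.5) * vc0
    x0 = np.array([np.log(b0), 0.0, vc0, max(ve0, 0.1), np.log(t0_0 / (fastest * 0.999 - t0_0))])
    if estimate_bias:
        x0 = np.append(x0, 0.0)

    best = None
    for k in range(cfg.n_starts):
        start = x0.copy() if k == 0 else x0 + rng.normal(0.0, 2.5 * cfg.start_jitter, x0.size)
        sol = minimize(
            _lba_nll,
            start,
            args=(rt, resp_r, stim_r, fastest, estimate_bias),
            method="Nelder-Mead",
            options={"maxiter": 2 * cfg.max_iter, "xatol": 1e-6, "fatol": 1e-8},
        )
        if best is None or sol.fun < best.fun:
            best = sol
    th = best.x
    b = float(np.exp(th[0]))
    A = float(b / (1.0 + np.exp(-th[1])))
    bias = float(np.tanh(th[5]) * (b - A) * 0.99) if estimate_bias else 0.0

    params = LBAParams(
        b=b,
        A=A,
        v_c=float(th[2]),
        v_e=float(th[3]),
        sdrift=1.0,
        t0=float(fastest * 0.999 / (1.0 + np.exp(-th[4]))),
        start_bias=bias,
    )
    return FitResult(params, -float(best.fun), bool(np.isfinite(best.fun)), n_used, n_exc, "ml_lba")


def fit_condition_table(
    trials: pd.DataFrame,
    method: str = "ez2",
    cfg: FitConfig = FitConfig(),
    s: float = 1.0,
) -> pd.DataFrame:
    """Fit every participant of one condition; one row per participant.

    ``method`` is 'ez', 'ez2', 'ml_diffusion' or 'ml_lba'.  Diffusion rows
    carry columns (v, a, zr, ter); LBA rows (b, A, v_c, v_e, t0,
    start_bias, v_delta).
    """
    rows = []
    for pid, grp in trials.groupby("participant"):
        if method == "ez":
            v, a, ter = ez_point_estimates(compute_ez_moments(grp, cfg.min_rt), s)
            rows.append({"participant": pid, "v": v, "a": a, "zr": 0.5, "ter": ter, "converged": True})
        elif method == "ez2":
            r = ez2_point_estimates(compute_ez_moments(grp, cfg.min_rt), s)
            rows.append(
                {"participant": pid, "v": r.v, "a": r.a, "zr": r.zr, "ter": r.ter, "converged": r.converged}
            )
        elif method == "ml_diffusion":
            r = fit_ml_simple_diffusion(grp, cfg, s)
            p = r.params
            rows.append(
                {"participant": pid, "v": p.v, "a": p.a, "zr": p.zr, "ter": p.ter,
                 "loglik": r.loglik, "converged": r.converged}
            )
        elif method == "ml_lba":
            r = fit_ml_lba(grp, cfg)
            p = r.params
            rows.append(
                {"participant": pid, "b": p.b, "A": p.A, "v_c": p.v_c, "v_e": p.v_e,
                 "t0": p.t0, "start_bias": p.start_bias, "v_delta": p.v_c - p.v_e,
                 "loglik": r.loglik, "converged": r.converged}
            )
        else:
            raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame(rows).set_index("participant").sort_index()
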