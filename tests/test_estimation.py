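"""EZ/EZ2 moment estimators and maximum-likelihood fits."""

import numpy as np
import pandas as pd
import pytest

import rtvalid as rv
from conftest import two_sided_cdf_trials
from rtvalid.estimation import (
    EZMoments,
    FitConfig,
    SideMoments,
    _diffusion_nll,
    compute_ez_moments,
    ez2_forward_moments,
    ez2_point_estimates,
    ez_forward_moments,
    ez_point_estimates,
    filter_trials,
)


def _trials(rts, correct, stim=None, resp=None):
    n = len(rts)
    df = pd.DataFrame(
        {
            "rt": rts,
            "correct": correct,
            "timed_out": [False] * n,
            "stimulus": stim if stim is not None else ["R"] * n,
        }
    )
    df["response"] = resp if resp is not None else np.where(df["correct"], df["stimulus"], "L")
    return df


def _moments_from_params(v, a, zr, ter, n=10**6):
    fm = ez2_forward_moments(v, a, zr, ter)
    by = {s: SideMoments(n=n, p_r=fm[s][0], mrt=fm[s][1], vrt=fm[s][2]) for s in ("L", "R")}
    pc, mrt, vrt = ez_forward_moments(v, a, ter)
    return EZMoments(n=n, pc=pc, mrt=mrt, vrt=vrt, by_stim=by)


class TestMoments:
    def test_hand_arithmetic_toy_set(self):
        m = compute_ez_moments(_trials([0.4, 0.5, 0.6], [True] * 3))
        assert m.pc == 1 - 1 / 6  # all correct at n=3, edge-corrected
        assert np.isclose(m.mrt, 0.5)
        assert np.isclose(m.vrt, 0.01)

    def test_edge_correction_at_perfect_accuracy(self):
        m = compute_ez_moments(_trials([0.5] * 100, [True] * 100))
        assert m.pc == 1 - 1 / 200

    def test_chance_accuracy_nudged_toward_rt_implied_sign(self):
        # correct responses faster than errors -> nudged above 0.5
        rts = [0.4] * 50 + [0.8] * 50
        m = compute_ez_moments(_trials(rts, [True] * 50 + [False] * 50))
        assert m.pc == 0.5 + 1 / 200

    def test_invariant_to_trial_order(self):
        rng = np.random.default_rng(0)
        rts = rng.uniform(0.3, 1.0, 200)
        ok = rng.random(200) < 0.8
        t1 = _trials(rts, ok)
        t2 = t1.sample(frac=1.0, random_state=1).reset_index(drop=True)
        m1, m2 = compute_ez_moments(t1), compute_ez_moments(t2)
        assert m1.pc == m2.pc and np.isclose(m1.mrt, m2.mrt) and np.isclose(m1.vrt, m2.vrt)

    def test_outlier_rule_drops_fast_and_censored(self):
        df = _trials([0.1, 0.5, 3.0], [True] * 3)
        df.loc[2, "timed_out"] = True
        assert len(filter_trials(df)) == 1


class TestEZ:
    @pytest.mark.parametrize("v,a,ter", [(1.0, 2.0, 0.3), (2.0, 1.0, 0.3)])
    def test_analytic_round_trip(self, v, a, ter):
        pc, mrt, vrt = ez_forward_moments(v, a, ter)
        m = EZMoments(n=10**6, pc=pc, mrt=mrt, vrt=vrt)
        vh, ah, th = ez_point_estimates(m)
        assert max(abs(vh - v), abs(ah - a), abs(th - ter)) < 1e-8

    def test_round_trip_grid(self):
        """Forward->inverse identity over a grid spanning Pc in (0.55, 0.99)."""
        worst = 0.0
        count = 0
        for v in np.linspace(0.3, 3.0, 10):
            for a in np.linspace(0.5, 2.8, 10):
                pc, mrt, vrt = ez_forward_moments(v, a, 0.3)
                if not 0.55 < pc < 0.99:
                    continue
                count += 1
                vh, ah, th = ez_point_estimates(EZMoments(10**6, pc, mrt, vrt))
                worst = max(worst, abs(vh - v), abs(ah - a), abs(th - 0.3))
        assert count >= 50
        assert worst < 1e-8

    def test_simulation_consistency(self):
        """EZ estimates agree with generating values within Monte-Carlo error."""
        v, a, ter = 1.5, 1.5, 0.3
        p = rv.DiffusionParams(v=v, a=a, zr=0.5, ter=ter)
        rng = np.random.default_rng(77)
        reps = [
            ez_point_estimates(compute_ez_moments(two_sided_cdf_trials(p, 10000, rng)))
            for _ in range(6)
        ]
        est = np.array(reps)
        for j, truth in enumerate((v, a, ter)):
            se = est[:, j].std(ddof=1) / np.sqrt(len(reps))
            assert abs(est[:, j].mean() - truth) < max(3 * se, 5e-3)

    def test_consistency_bias_shrinks_with_n(self):
        p = rv.DiffusionParams(v=1.2, a=1.4, zr=0.5, ter=0.3)
        rng = np.random.default_rng(99)
        med_err = []
        for n in (250, 1000, 4000):
            errs = [
                abs(
                    ez_point_estimates(compute_ez_moments(two_sided_cdf_trials(p, n // 2, rng)))[0]
                    - p.v
                )
                for _ in range(100)
            ]
            med_err.append(np.median(errs))
        assert med_err[0] > med_err[1] > med_err[2]

    def test_degenerate_moments_raise(self):
        with pytest.raises(ValueError):
            ez_point_estimates(EZMoments(100, 0.8, 0.5, -0.1))
        with pytest.raises(ValueError):
            ez_point_estimates(EZMoments(100, 0.5, 0.5, 0.1))


class TestEZ2:
    def test_side_symmetric_moments_give_half_start(self):
        r = ez2_point_estimates(_moments_from_params(1.0, 1.0, 0.5, 0.3))
        assert abs(r.zr - 0.5) < 1e-6

    def test_recovers_biased_start_from_forward_moments(self):
        r = ez2_point_estimates(_moments_from_params(1.0, 1.2, 0.6, 0.3))
        assert abs(r.zr - 0.6) < 1e-6

    def test_full_round_trip(self):
        r = ez2_point_estimates(_moments_from_params(1.0, 2.0, 0.55, 0.3))
        assert (
            abs(r.v - 1.0) < 1e-6
            and abs(r.a - 2.0) < 1e-6
            and abs(r.zr - 0.55) < 1e-6
            and abs(r.ter - 0.3) < 1e-6
        )
        assert r.converged

    def test_requires_both_sides(self):
        m = EZMoments(100, 0.8, 0.5, 0.01, by_stim={"R": SideMoments(100, 0.8, 0.5, 0.01)})
        with pytest.raises(ValueError):
            ez2_point_estimates(m)

    def test_simulation_consistency_with_bias(self):
        p = rv.DiffusionParams(v=1.0, a=1.0, zr=0.55, ter=0.3)
        rng = np.random.default_rng(4)
        est = np.array(
            [
                [
                    getattr(ez2_point_estimates(compute_ez_moments(two_sided_cdf_trials(p, 8000, rng))), f)
                    for f in ("v", "a", "zr", "ter")
                ]
                for _ in range(6)
            ]
        )
        for j, truth in enumerate((1.0, 1.0, 0.55, 0.3)):
            se = est[:, j].std(ddof=1) / np.sqrt(6)
            assert abs(est[:, j].mean() - truth) < max(3 * se, 5e-3)


class TestMLDiffusion:
    def test_likelihood_peaks_at_truth_not_perturbation(self):
        p = rv.DiffusionParams(v=1.0, a=1.5, zr=0.5, ter=0.3)
        tr = two_sided_cdf_trials(p, 4000, np.random.default_rng(8))
        t = filter_trials(tr)
        args = (
            t["rt"].to_numpy(),
            (t["response"] == "R").to_numpy(),
            (t["stimulus"] == "R").to_numpy(),
            float(t["rt"].min()),
            1.0,
        )

        def theta(v, a, zr, ter, fastest):
            return np.array(
                [v, np.log(a), np.log(zr / (1 - zr)), np.log(ter / (fastest * 0.999 - ter))]
            )

        nll_true = _diffusion_nll(theta(1.0, 1.5, 0.5, 0.3, args[3]), *args)
        nll_pert = _diffusion_nll(theta(2.0, 1.5, 0.5, 0.3, args[3]), *args)
        assert nll_true < nll_pert

    def test_deterministic_given_seed_and_data(self):
        p = rv.DiffusionParams(v=1.2, a=1.2, zr=0.5, ter=0.3)
        tr = two_sided_cdf_trials(p, 300, np.random.default_rng(2))
        f1 = rv.fit_ml_simple_diffusion(tr, FitConfig(seed=3))
        f2 = rv.fit_ml_simple_diffusion(tr, FitConfig(seed=3))
        assert f1.params == f2.params and f1.loglik == f2.loglik

    def test_parameter_recovery_median_bias(self):
        """Median absolute bias < 10% of truth for v, a, ter at n = 1000."""
        p = rv.DiffusionParams(v=1.2, a=1.5, zr=0.55, ter=0.3)
        rng = np.random.default_rng(31)
        est = []
        for _ in range(12):
            tr = two_sided_cdf_trials(p, 500, rng)
            fp = rv.fit_ml_simple_diffusion(tr, FitConfig(n_starts=3)).params
            est.append([fp.v, fp.a, fp.ter])
        est = np.array(est)
        for j, truth in enumerate((p.v, p.a, p.ter)):
            assert np.median(np.abs(est[:, j] - truth)) < 0.10 * truth

    def test_consistency_bias_shrinks_with_n(self):
        """ML error decreases across n = 250, 1000, 4000 (median over reps)."""
        p = rv.DiffusionParams(v=1.2, a=1.4, zr=0.5, ter=0.3)
        rng = np.random.default_rng(6)
        meds = []
        for n in (250, 1000, 4000):
            errs = []
            for _ in range(16):
                fp = rv.fit_ml_simple_diffusion(
                    two_sided_cdf_trials(p, n // 2, rng), FitConfig(n_starts=2)
                ).params
                errs.append(
                    abs(fp.v - p.v) / p.v + abs(fp.a - p.a) / p.a + abs(fp.ter - p.ter) / p.ter
                )
            meds.append(np.median(errs))
        assert meds[0] > meds[1] > meds[2]

    def test_min_trials_enforced(self):
        p = rv.DiffusionParams(v=1.0, a=1.0)
        tr = two_sided_cdf_trials(p, 5, np.random.default_rng(0))
        with pytest.raises(ValueError):
            rv.fit_ml_simple_diffusion(tr, FitConfig(min_trials=40))


class TestMLLBA:
    def test_parameter_recovery_median_bias(self):
        """Median absolute bias < 15% for b, A, v_c, v_e, t0 at n = 1000.

        Uses a regime with a wide start range relative to threshold, where
        the start-point parameter is identifiable at this sample size.
        """
        p = rv.LBAParams(b=1.0, A=0.8, v_c=2.5, v_e=1.0, sdrift=1.0, t0=0.3)
        est = []
        for r in range(8):
            frames = []
            for k, stim in enumerate(("L", "R")):
                df = rv.simulate_lba(p, stim, 500, rng_seed=1000 + 2 * r + k)
                df["stimulus"] = stim
                frames.append(df)
            tr = pd.concat(frames, ignore_index=True)
            tr["correct"] = tr.response == tr.stimulus
            fp = rv.fit_ml_lba(tr, FitConfig(n_starts=3)).params
            est.append([fp.b, fp.A, fp.v_c, fp.v_e, fp.t0])
        est = np.array(est)
        for j, truth in enumerate((p.b, p.A, p.v_c, p.v_e, p.t0)):
            assert np.median(np.abs(est[:, j] - truth)) < 0.15 * truth

    def test_truth_beats_swapped_drifts(self):
        from rtvalid.estimation import _lba_nll

        p = rv.LBAParams(b=1.2, A=0.6, v_c=2.5, v_e=1.0, sdrift=1.0, t0=0.25)
        frames = []
        for k, stim in enumerate(("L", "R")):
            df = rv.simulate_lba(p, stim, 2000, rng_seed=50 + k)
            df["stimulus"] = stim
            frames.append(df)
        tr = pd.concat(frames, ignore_index=True)
        tr["correct"] = tr.response == tr.stimulus
        t = filter_trials(tr)
        args = (
            t["rt"].to_numpy(),
            (t["response"] == "R").to_numpy(),
            (t["stimulus"] == "R").to_numpy(),
            float(t["rt"].min()),
            False,
        )

        def theta(b, A, vc, ve, t0, fastest):
            return np.array(
                [np.log(b), np.log(A / (b - A)), vc, ve, np.log(t0 / (fastest * 0.999 - t0)), 0.0]
            )

        assert _lba_nll(theta(1.2, 0.6, 2.5, 1.0, 0.25, args[3]), *args) < _lba_nll(
            theta(1.2, 0.6, 1.0, 2.5, 0.25, args[3]), *args
        )

    def test_deterministic_given_seed_and_data(self):
        p = rv.LBAParams(b=1.0, A=0.5, v_c=2.0, v_e=0.8, sdrift=1.0, t0=0.2)
        df = rv.simulate_lba(p, "R", 300, rng_seed=1)
        df["stimulus"] = "R"
        df["correct"] = df.response == "R"
        f1 = rv.fit_ml_lba(df, FitConfig(seed=9, n_starts=2))
        f2 = rv.fit_ml_lba(df, FitConfig(seed=9, n_starts=2))
        assert f1.params == f2.params


class TestInvariances:
    def test_estimators_invariant_to_trial_order_and_relabeling(self, relabelled_session):
        """EZ2 fits don't change under row shuffling; relabeling a no-bias
        block leaves accuracy-based moments identical."""
        sub = relabelled_session.query("participant == 0 and emphasis == 'speed' and bias == 'none' and difficulty == 'hard'")
        m1 = compute_ez_moments(sub)
        m2 = compute_ez_moments(sub.sample(frac=1.0, random_state=0))
        assert m1.pc == m2.pc and np.isclose(m1.vrt, m2.vrt)
        r1 = ez2_point_estimates(m1)
        r2 = ez2_point_estimates(m2)
        assert np.isclose(r1.v, r2.v) and np.isclose(r1.zr, r2.zr)
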