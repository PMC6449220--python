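"""End-to-end study driver: session -> pseudo-experiments -> fits -> scores.

Convenience wrappers used by the analysis scripts, the acceptance checks
and the recovery studies; every step is just a call into the underlying
modules.
"""

from __future__ import annotations

from dataclasses import dataclass

from .estimation import FitConfig, fit_condition_table
from .experiment import (
    DEFAULT_BASE,
    EffectSizes,
    ParticipantSpread,
    participant_population,
    relabel_trials,
    simulate_factorial_session,
)
from .inference import (
    InferenceConfig,
    infer_pattern_estimate_based,
    infer_pattern_heuristic,
    inference_table,
)
from .params import DiffusionParams
from .pseudo import construct_pseudo_experiments, truth_table
from .scoring import ScoreSummary, build_truth, summarize_scores


@dataclass(frozen=True)
class StudyConfig:
    n_participants: int = 20
    base: DiffusionParams = DEFAULT_BASE
    spread: ParticipantSpread = ParticipantSpread()
    effects: EffectSizes = EffectSizes()
    n_per_participant: int = 312
    dt: float = 1e-4
    fit_method: str = "ez2"
    fit_config: FitConfig = FitConfig()
    inference: InferenceConfig = InferenceConfig()
    dataset_ids: tuple[int, ...] | None = None


def run_study(seed: int, cfg: StudyConfig = StudyConfig()) -> dict:
    """Simulate one complete blinded study and analyse it two ways.

    Returns a dict with the session table, the pseudo-experiments, the
    truth table, per-method inference tables ('estimate' and 'heuristic')
    and fitted parameter tables.
    """
    participants = participant_population(
        cfg.n_participants, cfg.base, cfg.spread, rng_seed=seed * 7919 + 1
    )
    session = simulate_factorial_session(
        participants=participants, rng_seed=seed, effects=cfg.effects, dt=cfg.dt
    )
    session = relabel_trials(session)
    experiments = construct_pseudo_experiments(
        session,
        rng_seed=seed * 104729 + 2,
        n_per_participant=cfg.n_per_participant,
        dataset_ids=list(cfg.dataset_ids) if cfg.dataset_ids else None,
    )
    truth = truth_table(experiments)

    est_patterns, heur_patterns, fits = {}, {}, {}
    for e in experiments:
        fa = fit_condition_table(e.trials_A, cfg.fit_method, cfg.fit_config)
        fb = fit_condition_table(e.trials_B, cfg.fit_method, cfg.fit_config)
        fits[e.id] = {"A": fa, "B": fb}
        est_patterns[e.id] = infer_pattern_estimate_based(fa, fb, cfg.inference)
        heur_patterns[e.id] = infer_pattern_heuristic(e.trials_A, e.trials_B, cfg.inference)

    return {
        "session": session,
        "experiments": experiments,
        "truth": truth,
        "inferences": {
            "estimate": inference_table(est_patterns),
            "heuristic": inference_table(heur_patterns),
        },
        "fits": fits,
    }


def score_study(result: dict, key: str = "planned") -> dict[str, ScoreSummary]:
    """ScoreSummary per method under one scoring key."""
    truth = build_truth(result["truth"], key)
    return {
        name: summarize_scores(tab, truth) for name, tab in result["inferences"].items()
    }
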