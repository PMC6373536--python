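"""Synthetic approach-avoidance experiments with Wiener-process responses.

Emulates a joystick classification task: 2 (expression: angry/happy) x
2 (required response: push/pull) x 2 (face gender) within participants,
participant gender between. Each participant completes 16 practice trials
and two 128-trial main blocks with opposite response mappings. Choices and
reaction times come from a two-boundary diffusion process with
condition-specific drift, boundary and non-decision time; a small fraction
of contaminant trials with out-of-range RTs exercises the downstream
filters; BIS/BAS questionnaire totals are drawn from gender-specific
truncated normals calibrated so the *truncated* means hit their targets.
"""

from __future__ import annotations

from itertools import product
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .types import (
    EXPRESSIONS,
    GENDERS,
    MAPPINGS,
    PARTICIPANT_COLUMNS,
    RESPONSES,
    TRIAL_COLUMNS,
    DiffusionParams,
    ScenarioConfig,
)
from .wiener import simulate_first_passage

__all__ = [
    "FACE_IDENTITIES",
    "generate_design",
    "default_scenario",
    "generate_dataset",
    "required_response_for",
    "SyntheticDataset",
]

#: Eight face identities, four per face gender.
FACE_IDENTITIES = {
    "male": ("JJ", "WF", "GS", "PE"),
    "female": ("MO", "MF", "NR", "CC"),
}

_MAIN_REPS = 8  # per stimulus per main block -> 128 trials
_PRACTICE_REPS = 1  # per stimulus -> 16 trials


def required_response_for(expression: str, mapping: str) -> str:
    """The correct joystick response under a response mapping."""
    if mapping == "push-angry/pull-happy":
        return "push" if expression == "angry" else "pull"
    if mapping == "push-happy/pull-angry":
        return "push" if expression == "happy" else "pull"
    raise ValueError(f"unknown mapping {mapping!r}")


def _stimulus_table() -> pd.DataFrame:
    rows = [
        {"stimulus_id": f"{ident}-{expr}", "expression": expr, "face_gender": fg}
        for fg, idents in FACE_IDENTITIES.items()
        for ident in idents
        for expr in EXPRESSIONS
    ]
    return pd.DataFrame(rows)


def generate_design(n_participants_per_gender: int, seed: int) -> pd.DataFrame:
    """Build trial skeletons (no responses or RTs yet) for a full experiment.

    Per participant: a 16-trial practice block (one presentation of each
    stimulus, under the first main block's mapping) followed by two
    128-trial main blocks (8 presentations of each of the 16 stimuli) with
    opposite response mappings; block order is randomised per participant,
    trial order within block is randomised.
    """
    if n_participants_per_gender < 1:
        raise ValueError("n_participants_per_gender must be >= 1")
    rng = np.random.default_rng(seed)
    stimuli = _stimulus_table()
    blocks = []
    for gender in GENDERS:
        prefix = gender[0].upper()
        for i in range(n_participants_per_gender):
            pid = f"{prefix}{i + 1:02d}"
            first = int(rng.integers(2))  # which mapping comes first
            mappings = (MAPPINGS[first], MAPPINGS[1 - first])
            for block, mapping, reps in (
                ("practice", mappings[0], _PRACTICE_REPS),
                ("main1", mappings[0], _MAIN_REPS),
                ("main2", mappings[1], _MAIN_REPS),
            ):
                trials = stimuli.loc[np.repeat(stimuli.index, reps)].reset_index(
                    drop=True
                )
                trials = trials.iloc[rng.permutation(len(trials))].reset_index(
                    drop=True
                )
                trials.insert(0, "participant_id", pid)
                trials.insert(1, "participant_gender", gender)
                trials.insert(2, "block", block)
                trials.insert(3, "mapping", mapping)
                trials.insert(4, "trial_index", np.arange(1, len(trials) + 1))
                trials["required_response"] = [
                    required_response_for(e, mapping) for e in trials["expression"]
                ]
                blocks.append(trials)
    design = pd.concat(blocks, ignore_index=True)
    return design[
        [c for c in TRIAL_COLUMNS if c not in ("observed_response", "rt_ms", "correct")]
    ]


def default_scenario(n_per_gender: int = 32, seed: int = 0) -> ScenarioConfig:
    """Ground-truth scenario mirroring the study's reported effect pattern.

    Female participants carry the full structure: a compatible-mapping
    drift advantage (push-angry and pull-happy faster evidence
    accumulation), shorter non-decision times for angry/push and for
    angry-male and happy-female faces, and wider boundaries for angry-male
    (and, smaller, happy-female) faces. Male participants carry only a
    happy > angry drift difference; their boundary and non-decision
    parameters are flat across conditions.
    """
    female_v = {
        ("angry", "push"): 2.16,
        ("angry", "pull"): 1.85,
        ("happy", "push"): 2.12,
        ("happy", "pull"): 2.31,
    }
    male_v = {"angry": 1.95, "happy": 2.15}
    truth: dict[tuple[str, str, str, str], DiffusionParams] = {}
    for expr, resp, fg in product(EXPRESSIONS, RESPONSES, GENDERS):
        # female participants
        a = 1.20
        if (expr, fg) == ("angry", "male"):
            a = 1.26
        elif (expr, fg) == ("happy", "female"):
            a = 1.25
        ter = 0.30
        if (expr, resp) == ("angry", "push"):
            ter -= 0.015
        if (expr, fg) in (("angry", "male"), ("happy", "female")):
            ter -= 0.020
        truth[("female", expr, resp, fg)] = DiffusionParams(
            v=female_v[(expr, resp)], a=a, ter=ter
        )
        truth[("male", expr, resp, fg)] = DiffusionParams(
            v=male_v[expr], a=1.20, ter=0.30
        )
    return ScenarioConfig(n_per_gender=n_per_gender, truth=truth, seed=seed)


def _solve_truncnorm_loc(target_mean: float, sd: float, lo: float, hi: float) -> float:
    """Parent-normal location whose [lo, hi]-truncated mean equals the target."""

    def truncated_mean(mu: float) -> float:
        alpha, beta = (lo - mu) / sd, (hi - mu) / sd
        return stats.truncnorm.mean(alpha, beta, loc=mu, scale=sd)

    return optimize.brentq(
        lambda mu: truncated_mean(mu) - target_mean, lo - 2 * sd, hi + 2 * sd, xtol=1e-10
    )


def _draw_truncnorm(
    rng: np.random.Generator, n: int, target_mean: float, sd: float, lo: float, hi: float
) -> np.ndarray:
    mu = _solve_truncnorm_loc(target_mean, sd, lo, hi)
    alpha, beta = (lo - mu) / sd, (hi - mu) / sd
    return stats.truncnorm.rvs(alpha, beta, loc=mu, scale=sd, size=n, random_state=rng)


#: BAS subscale ranges under 0-3 item scoring: Drive (4 items), Fun Seeking
#: (4 items), Reward Responsiveness (5 items); total range [0, 39].
_BAS_SUBSCALES = {"bas_drive": (4, 12.0), "bas_fun": (4, 12.0), "bas_reward": (5, 15.0)}
_BIS_RANGE = (7.0, 28.0)


def draw_bisbas(
    gender: str, n: int, scenario: ScenarioConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Gender-specific BIS/BAS questionnaire totals for ``n`` participants."""
    bis_mean, bis_sd = scenario.bis[gender]
    bas_mean, bas_sd = scenario.bas[gender]
    out = {"bis": _draw_truncnorm(rng, n, bis_mean, bis_sd, *_BIS_RANGE)}
    n_items_total = sum(k for k, _ in _BAS_SUBSCALES.values())
    sub_sd = bas_sd / np.sqrt(len(_BAS_SUBSCALES))
    for name, (n_items, hi) in _BAS_SUBSCALES.items():
        out[name] = _draw_truncnorm(
            rng, n, bas_mean * n_items / n_items_total, sub_sd, 0.0, hi
        )
    df = pd.DataFrame(out)
    df["bas"] = df[list(_BAS_SUBSCALES)].sum(axis=1)
    return df


class SyntheticDataset(NamedTuple):
    """Trials, participant profiles, and per-participant generating parameters."""

    trials: pd.DataFrame
    participants: pd.DataFrame
    participant_params: pd.DataFrame


def generate_dataset(scenario: ScenarioConfig) -> SyntheticDataset:
    """Simulate a complete experiment under a ground-truth scenario.

    Every trial's choice and RT comes from the participant's
    condition-specific diffusion parameters (condition mean + shared
    participant intercept + condition jitter); the diffusion process
    hitting the wrong boundary is the only source of response errors.
    A ``contaminant_rate`` fraction of trials then has its RT replaced
    by a uniform draw outside the 200-2500 ms analysis window.
    """
    scenario.validate()
    ss = np.random.SeedSequence(scenario.seed)
    rng_design, rng_params, rng_sim, rng_contam, rng_bisbas = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    design = generate_design(
        scenario.n_per_gender, int(rng_design.integers(2**31 - 1))
    )

    conditions = list(product(EXPRESSIONS, RESPONSES, GENDERS))
    profiles, param_rows = [], []
    for gender in GENDERS:
        bisbas = draw_bisbas(gender, scenario.n_per_gender, scenario, rng_bisbas)
        bis_mean, bis_sd = scenario.bis[gender]
        for i in range(scenario.n_per_gender):
            pid = f"{gender[0].upper()}{i + 1:02d}"
            row = {"participant_id": pid, "participant_gender": gender}
            row.update({k: float(bisbas.iloc[i][k]) for k in bisbas.columns})
            profiles.append(row)
            u_v = rng_params.normal(0.0, scenario.sd_v)
            u_a = rng_params.normal(0.0, scenario.sd_a)
            u_ter = rng_params.normal(0.0, scenario.sd_ter)
            bis_z2 = (row["bis"] - bis_mean) / (2.0 * bis_sd)
            for expr, resp, fg in conditions:
                mean = scenario.truth[(gender, expr, resp, fg)]
                v = mean.v + u_v + rng_params.normal(0.0, scenario.jitter_v)
                a = mean.a + u_a + rng_params.normal(0.0, scenario.jitter_a)
                ter = mean.ter + u_ter + rng_params.normal(0.0, scenario.jitter_ter)
                if gender == "female" and (expr, resp) == ("happy", "pull"):
                    ter += scenario.bis_ter_coupling * bis_z2
                param_rows.append(
                    {
                        "participant_id": pid,
                        "participant_gender": gender,
                        "expression": expr,
                        "required_response": resp,
                        "face_gender": fg,
                        "v": max(v, 0.05),
                        "a": max(a, 0.3),
                        "ter": max(ter, 0.02),
                    }
                )
    participants = pd.DataFrame(profiles)[PARTICIPANT_COLUMNS]
    participant_params = pd.DataFrame(param_rows)

    # attach per-trial generating parameters and simulate all trials at once
    trials = design.merge(
        participant_params.drop(columns="participant_gender"),
        on=["participant_id", "expression", "required_response", "face_gender"],
        how="left",
        validate="many_to_one",
    )
    rt_s, hit_upper = simulate_first_passage(
        trials["v"].to_numpy(),
        trials["a"].to_numpy(),
        trials["ter"].to_numpy(),
        s=1.0,
        rng=rng_sim,
        dt=scenario.dt,
    )
    other = {"push": "pull", "pull": "push"}
    required = trials["required_response"].to_numpy()
    trials["observed_response"] = np.where(
        hit_upper, required, [other[r] for r in required]
    )
    trials["rt_ms"] = rt_s * 1000.0

    if scenario.contaminant_rate > 0:
        contam = rng_contam.random(len(trials)) < scenario.contaminant_rate
        fast = rng_contam.random(len(trials)) < 0.5
        lo_f, hi_f = scenario.contaminant_fast_ms
        lo_s, hi_s = scenario.contaminant_slow_ms
        rt = trials["rt_ms"].to_numpy()
        rt[contam & fast] = rng_contam.uniform(lo_f, hi_f, int((contam & fast).sum()))
        rt[contam & ~fast] = rng_contam.uniform(lo_s, hi_s, int((contam & ~fast).sum()))
        trials["rt_ms"] = rt

    trials["correct"] = trials["observed_response"] == trials["required_response"]
    trials = trials[TRIAL_COLUMNS]
    return SyntheticDataset(trials, participants, participant_params)
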