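"""Synthetic cohort generator.

Produces complete trial tables with the statistical structure the
analysis pipeline assumes, so every downstream stage can be exercised and
validated without animal data: restless reward-probability walks, a
latent explore/exploit(-side) chain from the constrained HMM, choices
consistent with that chain (exploit states emit their side; explore
choices come from an RLCK policy or a fair coin), Bernoulli rewards from
the walk, and touch coordinates / response latencies whose dispersion
depends on state, sex and the previous trial's outcome.

Touch model: truncated bivariate Gaussians centred on the chosen
aperture. Exploit touches are tighter; explore touches are wider and
mean-shifted toward the screen midline (emulating deliberative,
centre-proximal responding). Dispersion scales up in males, shrinks after
a rewarded trial, and carries mouse-level lognormal heterogeneity so that
sex contrasts are honest between-animal comparisons. Latencies are
lognormal, faster in exploit states and in females. Default effect
magnitudes are stated in :mod:`docs/methods`; they are fixed study
conditions, not tuning knobs.

Ground truth (latent states, per-mouse agent parameters, generator
config) is returned alongside the trials for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hmm import HMMParams, sample_states
from .rlck import AgentParams
from .screen import (
    APERTURE_CENTER,
    APERTURE_ORIGIN,
    APERTURE_SIZE_PX,
    CENTER_X_PX,
    MM_PER_PX,
)
from .task import WalkParams, simulate_walk

__all__ = [
    "TouchGenParams",
    "CohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "make_fixture",
]

SIDES = ("left", "right")


@dataclass(frozen=True)
class TouchGenParams:
    """Generative touch/latency model; distances in mm, times in seconds."""

    exploit_sd_mm: float = 2.5
    explore_sd_mm: float = 5.0
    explore_center_shift_mm: float = 8.0  # explore mean moved toward midline
    male_dispersion_mult: float = 1.3
    post_reward_mult: float = 0.8
    mouse_dispersion_cv: float = 0.10  # lognormal sigma of per-mouse scaling
    rt_median_explore_s: float = 2.0
    rt_median_exploit_s: float = 1.4
    rt_sigma: float = 0.4
    male_rt_mult: float = 1.25
    mouse_rt_cv: float = 0.10

    def __post_init__(self) -> None:
        if min(self.exploit_sd_mm, self.explore_sd_mm) <= 0:
            raise ValueError("dispersions must be > 0")
        if min(self.male_dispersion_mult, self.post_reward_mult,
               self.male_rt_mult) <= 0:
            raise ValueError("multipliers must be > 0")


@dataclass(frozen=True)
class CohortConfig:
    """Study-design conditions for one synthetic cohort."""

    n_per_sex: int = 16
    n_sessions: int = 8
    n_trials: int = 300
    walk: WalkParams = field(default_factory=WalkParams)
    hmm: HMMParams = field(default_factory=lambda: HMMParams(0.9, 0.7))
    touch: TouchGenParams = field(default_factory=TouchGenParams)
    explore_policy: str = "uniform"  # or "rlck"
    # per-sex agent-parameter distributions (mean, sd); alpha higher in F
    alpha_by_sex: dict = field(
        default_factory=lambda: {"F": (0.65, 0.10), "M": (0.50, 0.10)}
    )
    beta_mean_sd: tuple = (4.0, 1.0)
    bias_mean_sd: tuple = (0.0, 0.3)
    kappa_mean_sd: tuple = (0.5, 0.3)

    def __post_init__(self) -> None:
        if min(self.n_per_sex, self.n_sessions, self.n_trials) < 1:
            raise ValueError("all cohort counts must be >= 1")
        if self.explore_policy not in ("rlck", "uniform"):
            raise ValueError("explore_policy must be 'rlck' or 'uniform'")


@dataclass
class SyntheticCohort:
    trials: pd.DataFrame  # with true_state / true_state_side columns
    agents: pd.DataFrame  # per-mouse generating AgentParams + multipliers
    config: CohortConfig

    @property
    def truth(self) -> pd.DataFrame:
        return self.trials[
            ["mouse_id", "session", "trial", "true_state", "true_state_side"]
        ]


def _truncate(vals: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return np.clip(vals, lo, hi)


def _draw_agent(cfg: CohortConfig, sex: str, rng) -> AgentParams:
    am, asd = cfg.alpha_by_sex[sex]
    return AgentParams(
        alpha=float(np.clip(rng.normal(am, asd), 0.05, 0.95)),
        beta=float(np.clip(rng.normal(*cfg.beta_mean_sd), 0.5, 15.0)),
        bias=float(rng.normal(*cfg.bias_mean_sd)),
        kappa=float(rng.normal(*cfg.kappa_mean_sd)),
    )


def _session_trials(
    mouse_id: str,
    sex: str,
    session: int,
    agent: AgentParams,
    disp_mult: float,
    rt_mult: float,
    cfg: CohortConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    tp = cfg.touch
    n = cfg.n_trials
    walk = simulate_walk(cfg.walk, rng)
    states = sample_states(cfg.hmm, n, rng)
    p_arm = np.column_stack([walk.p_left, walk.p_right])

    choices = np.empty(n, dtype=np.int64)
    rewards = np.empty(n, dtype=np.int64)
    u_choice = rng.random(n)
    u_reward = rng.random(n)
    ql = qr = 0.5
    cl = cr = 0.0
    for t in range(n):
        s = states[t]
        if s == 1:
            c = 0
        elif s == 2:
            c = 1
        elif cfg.explore_policy == "uniform":
            c = 0 if u_choice[t] < 0.5 else 1
        else:
            z = agent.beta * (ql - qr) + agent.bias + agent.kappa * (cl - cr)
            c = 0 if u_choice[t] < 1.0 / (1.0 + np.exp(-z)) else 1
        r = 1 if u_reward[t] < p_arm[t, c] else 0
        choices[t] = c
        rewards[t] = r
        a = agent.alpha
        if c == 0:
            ql += a * (r - ql)
            cl += a * (1.0 - cl)
            cr -= a * cr
        else:
            qr += a * (r - qr)
            cr += a * (1.0 - cr)
            cl -= a * cl

    sides = np.where(choices == 0, "left", "right")
    explore = states == 0
    prev_reward = np.concatenate([[0], rewards[:-1]])

    sd_mm = np.where(explore, tp.explore_sd_mm, tp.exploit_sd_mm) * disp_mult
    if sex == "M":
        sd_mm = sd_mm * tp.male_dispersion_mult
    sd_mm = sd_mm * np.where(prev_reward == 1, tp.post_reward_mult, 1.0)
    sd_px = sd_mm / MM_PER_PX

    mean_x = np.array([APERTURE_CENTER[s][0] for s in sides])
    mean_y = np.array([APERTURE_CENTER[s][1] for s in sides])
    shift_px = tp.explore_center_shift_mm / MM_PER_PX
    toward_mid = np.sign(CENTER_X_PX - mean_x)
    mean_x = mean_x + np.where(explore, toward_mid * shift_px, 0.0)

    x = rng.normal(mean_x, sd_px)
    y = rng.normal(mean_y, sd_px)
    for i, s in enumerate(sides):  # truncate to the aperture mask
        x0, y0 = APERTURE_ORIGIN[s]
        x[i] = min(max(x[i], x0), x0 + APERTURE_SIZE_PX - 1)
        y[i] = min(max(y[i], y0), y0 + APERTURE_SIZE_PX - 1)

    rt_median = np.where(
        explore, tp.rt_median_explore_s, tp.rt_median_exploit_s
    ) * rt_mult
    if sex == "M":
        rt_median = rt_median * tp.male_rt_mult
    rt = np.exp(rng.normal(np.log(rt_median), tp.rt_sigma))

    state_names = np.array(["explore", "exploit-left", "exploit-right"])
    return pd.DataFrame(
        {
            "mouse_id": mouse_id,
            "sex": sex,
            "session": session,
            "trial": np.arange(n),
            "side": sides,
            "x": x,
            "y": y,
            "reward": rewards,
            "rt": rt,
            "true_state": np.where(explore, "explore", "exploit"),
            "true_state_side": state_names[states],
        }
    )


def generate_cohort(
    config: CohortConfig = CohortConfig(), seed: int = 0
) -> SyntheticCohort:
    """Generate a full cohort; fully reproducible from the seed."""
    root = np.random.SeedSequence(seed)
    mouse_seeds = root.spawn(2 * config.n_per_sex)
    trials, agents = [], []
    idx = 0
    for sex in ("F", "M"):
        for j in range(config.n_per_sex):
            rng = np.random.default_rng(mouse_seeds[idx])
            idx += 1
            mouse_id = f"{sex}{j + 1:02d}"
            agent = _draw_agent(config, sex, rng)
            disp_mult = float(
                np.exp(rng.normal(0.0, config.touch.mouse_dispersion_cv))
            )
            rt_mult = float(np.exp(rng.normal(0.0, config.touch.mouse_rt_cv)))
            agents.append(
                {
                    "mouse_id": mouse_id,
                    "sex": sex,
                    "alpha": agent.alpha,
                    "beta": agent.beta,
                    "bias": agent.bias,
                    "kappa": agent.kappa,
                    "dispersion_mult": disp_mult,
                    "rt_mult": rt_mult,
                }
            )
            for session in range(config.n_sessions):
                trials.append(
                    _session_trials(
                        mouse_id, sex, session, agent, disp_mult, rt_mult,
                        config, rng,
                    )
                )
    df = pd.concat(trials, ignore_index=True)
    return SyntheticCohort(
        trials=df, agents=pd.DataFrame(agents), config=config
    )


def make_fixture(kind: str) -> pd.DataFrame:
    """Deterministic micro-datasets shared across module tests.

    Kinds: ``worked_example`` (one touch at x = 34), ``side_switch_6``
    (six same-state trials, one side transition at trial 4),
    ``all_exploit`` (ten exploit-left trials), ``alternating``
    (20 strictly alternating choices).
    """
    base = dict(mouse_id="m1", sex="F", session=0, reward=0, rt=1.0)
    if kind == "worked_example":
        rows = [dict(base, trial=0, side="left", x=34, y=208, state="explore")]
    elif kind == "side_switch_6":
        sides = ["left", "left", "left", "right", "right", "right"]
        rows = [
            dict(
                base,
                trial=i,
                side=s,
                x=160.0 + 5 * i if s == "left" else 640.0 + 5 * i,
                y=300.0 + 3 * i,
                state="explore",
            )
            for i, s in enumerate(sides)
        ]
    elif kind == "all_exploit":
        rows = [
            dict(
                base,
                trial=i,
                side="left",
                x=150.0 + 4 * i,
                y=290.0 + (i % 3) * 6,
                state="exploit",
                reward=i % 2,
            )
            for i in range(10)
        ]
    elif kind == "alternating":
        rows = [
            dict(
                base,
                trial=i,
                side="left" if i % 2 == 0 else "right",
                x=160.0 if i % 2 == 0 else 640.0,
                y=300.0,
                state="explore",
            )
            for i in range(20)
        ]
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return pd.DataFrame(rows)
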