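"""Two-arm restless bandit task simulator.

Each session presents two spatially distinct choice apertures ("arms").
Every arm carries a reward probability that drifts independently over
trials: on each trial there is a ``step_prob`` chance that an arm's
probability moves up or down by ``step_size`` (direction equiprobable),
bounded to ``[p_min, p_max]`` so the contingency never becomes
deterministic. Defaults follow the task as run with mice: 300-trial
sessions, 10% step chance, 10% step size, bounds 20% and 90%.

Boundary handling: the task definition bounds the walk but does not say
whether a step that would cross a bound is clamped to the bound or
reflected back. The default here is ``"reflect"`` — an outward step
bounces back by its overshoot (0.9 + 0.1 -> 0.8) — because it preserves
the defining property that each arm changes on exactly ``step_prob`` of
trials; under ``"clamp"`` outward steps at the bounds are absorbed and the
realized change frequency drops below the nominal rate. ``"clamp"`` is
available for sensitivity checks.

Random-stream order (one :class:`numpy.random.Generator` per walk): first
the initial probabilities (left then right, if not fixed), then the
(n_trials-1, 2) change-indicator uniforms, then the (n_trials-1, 2)
direction uniforms. Reward draws use a separate stream supplied by the
caller so walks and outcomes are jointly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["WalkParams", "ProbabilityWalk", "simulate_walk", "draw_reward"]


@dataclass(frozen=True)
class WalkParams:
    """Parameters of the restless reward-probability walk."""

    n_trials: int = 300
    step_prob: float = 0.10
    step_size: float = 0.10
    p_min: float = 0.20
    p_max: float = 0.90
    p_init_left: float | None = None
    p_init_right: float | None = None
    boundary: str = "reflect"  # or "clamp"

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 0.0 <= self.step_prob <= 1.0:
            raise ValueError("step_prob must be in [0, 1]")
        if self.step_size <= 0:
            raise ValueError("step_size must be > 0")
        if not 0.0 < self.p_min < self.p_max < 1.0:
            raise ValueError("require 0 < p_min < p_max < 1")
        if self.boundary not in ("reflect", "clamp"):
            raise ValueError("boundary must be 'reflect' or 'clamp'")
        for p in (self.p_init_left, self.p_init_right):
            if p is not None and not self.p_min <= p <= self.p_max:
                raise ValueError("initial probabilities must lie in [p_min, p_max]")

    @property
    def grid(self) -> np.ndarray:
        """Allowed probability grid {p_min, p_min+step, ..., <= p_max}."""
        n = int(round((self.p_max - self.p_min) / self.step_size))
        g = self.p_min + self.step_size * np.arange(n + 1)
        return np.round(g[g <= self.p_max + 1e-12], 10)


@dataclass(frozen=True)
class ProbabilityWalk:
    """Per-trial reward probabilities for the two arms over one session."""

    p_left: np.ndarray
    p_right: np.ndarray
    params: WalkParams = field(default_factory=WalkParams)

    def __post_init__(self) -> None:
        if len(self.p_left) != len(self.p_right):
            raise ValueError("arm probability traces must have equal length")

    @property
    def n_trials(self) -> int:
        return len(self.p_left)

    def prob(self, t: int, side: str) -> float:
        if not 0 <= t < self.n_trials:
            raise IndexError(f"trial {t} out of range [0, {self.n_trials})")
        if side == "left":
            return float(self.p_left[t])
        if side == "right":
            return float(self.p_right[t])
        raise ValueError(f"unknown side {side!r}")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "trial": np.arange(self.n_trials),
                "p_left": self.p_left,
                "p_right": self.p_right,
            }
        )


def _step(p: np.ndarray, move: np.ndarray, params: WalkParams) -> np.ndarray:
    """Apply one trial's (possibly zero) signed steps for both arms."""
    q = p + move
    if params.boundary == "reflect":
        q = np.where(q > params.p_max, 2 * params.p_max - q, q)
        q = np.where(q < params.p_min, 2 * params.p_min - q, q)
    q = np.clip(q, params.p_min, params.p_max)
    # keep values on the exact grid; walk arithmetic must not drift
    return np.round(q, 10)


def simulate_walk(
    params: WalkParams = WalkParams(),
    seed: int | np.random.Generator = 0,
) -> ProbabilityWalk:
    """Simulate one restless probability walk, deterministic given seed."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    init = np.empty(2)
    for i, fixed in enumerate((params.p_init_left, params.p_init_right)):
        init[i] = rng.choice(params.grid) if fixed is None else fixed
    n = params.n_trials
    p = np.empty((n, 2))
    p[0] = np.round(init, 10)
    if n > 1:
        change = rng.random((n - 1, 2)) < params.step_prob
        sign = np.where(rng.random((n - 1, 2)) < 0.5, -1.0, 1.0)
        move = change * sign * params.step_size
        for t in range(1, n):
            p[t] = _step(p[t - 1], move[t - 1], params)
    return ProbabilityWalk(p_left=p[:, 0], p_right=p[:, 1], params=params)


def draw_reward(
    walk: ProbabilityWalk, t: int, side: str, rng: np.random.Generator
) -> bool:
    """Bernoulli reward draw at the chosen arm's probability for trial t."""
    return bool(rng.random() < walk.prob(t, side))
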