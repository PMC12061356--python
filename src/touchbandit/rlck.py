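"""Reinforcement-learning choice-kernel (RLCK) agent model.

The RLCK policy chooses left with probability

    P(left) = logistic( beta * (Q_L - Q_R) + b + kappa * (CK_L - CK_R) )

where Q are delta-rule value estimates (learning rate alpha), CK are
choice-kernel traces tracking recent choice repetition (kernel learning
rate tied to alpha, keeping four free parameters: alpha, beta, b, kappa),
b is a static left bias and kappa weights value-independent stickiness.
Rewards are binary; Q and CK therefore stay in [0, 1].

``RLCKModel`` holds one animal's sessions and fits the four parameters by
bounded multi-restart maximum likelihood (L-BFGS-B); ``RLCKResults``
carries the estimates and fit diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from ._kernels import rlck_negloglik, rlck_simulate

__all__ = [
    "AgentParams",
    "AgentState",
    "choice_prob_left",
    "update_agent",
    "negloglik",
    "simulate_agent",
    "RLCKModel",
    "RLCKResults",
]

SIDE_CODE = {"left": 0, "right": 1}

DEFAULT_BOUNDS = {
    "alpha": (0.0, 1.0),
    "beta": (0.0, 20.0),
    "bias": (-5.0, 5.0),
    "kappa": (-10.0, 10.0),
}


@dataclass(frozen=True)
class AgentParams:
    alpha: float  # learning rate, [0, 1]
    beta: float  # decision noise (inverse temperature), >= 0
    bias: float = 0.0  # side bias, positive favours left
    kappa: float = 0.0  # choice-kernel (stickiness) weight

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.bias, self.kappa])


@dataclass(frozen=True)
class AgentState:
    q_left: float = 0.5
    q_right: float = 0.5
    ck_left: float = 0.0
    ck_right: float = 0.0


def choice_prob_left(params: AgentParams, state: AgentState) -> float:
    """Probability of a left choice under the softmax-with-kernel policy."""
    z = (
        params.beta * (state.q_left - state.q_right)
        + params.bias
        + params.kappa * (state.ck_left - state.ck_right)
    )
    return float(expit(z))


def update_agent(
    params: AgentParams, state: AgentState, choice: str, reward: int
) -> AgentState:
    """Delta-rule value update for the chosen arm plus kernel decay."""
    if choice not in SIDE_CODE:
        raise ValueError(f"unknown side {choice!r}")
    if reward not in (0, 1):
        raise ValueError("reward must be 0 or 1")
    a = params.alpha
    if choice == "left":
        return replace(
            state,
            q_left=state.q_left + a * (reward - state.q_left),
            ck_left=state.ck_left + a * (1.0 - state.ck_left),
            ck_right=state.ck_right + a * (0.0 - state.ck_right),
        )
    return replace(
        state,
        q_right=state.q_right + a * (reward - state.q_right),
        ck_right=state.ck_right + a * (1.0 - state.ck_right),
        ck_left=state.ck_left + a * (0.0 - state.ck_left),
    )


def _as_code(choices) -> np.ndarray:
    arr = np.asarray(choices)
    if arr.dtype.kind in "UO":
        return np.array([SIDE_CODE[c] for c in arr], dtype=np.int64)
    return arr.astype(np.int64)


def negloglik(params: AgentParams, choices, rewards) -> float:
    """Summed -log P(choice) over one session, agent updated trial by trial."""
    c = _as_code(choices)
    r = np.asarray(rewards, dtype=np.float64)
    if len(c) != len(r):
        raise ValueError("choices and rewards must have equal length")
    return float(
        rlck_negloglik(params.alpha, params.beta, params.bias, params.kappa, c, r)
    )


def simulate_agent(
    params: AgentParams, walk, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate coded choices (0=left) and rewards on a ProbabilityWalk."""
    n = walk.n_trials
    u_choice = rng.random(n)
    u_reward = rng.random(n)
    return rlck_simulate(
        params.alpha,
        params.beta,
        params.bias,
        params.kappa,
        np.asarray(walk.p_left, dtype=np.float64),
        np.asarray(walk.p_right, dtype=np.float64),
        u_choice,
        u_reward,
    )


@dataclass
class RLCKResults:
    """Maximum-likelihood RLCK fit for one animal."""

    params: AgentParams
    nll: float
    converged: bool
    at_bound: dict[str, bool]
    n_trials: int
    n_restarts: int

    @property
    def aic(self) -> float:
        return 2 * 4 + 2 * self.nll

    def summary(self) -> str:
        lines = [
            "RLCK maximum-likelihood fit",
            f"  trials: {self.n_trials}   restarts: {self.n_restarts}",
            f"  -logL: {self.nll:.3f}   AIC: {self.aic:.3f}   "
            f"converged: {self.converged}",
        ]
        for name in ("alpha", "beta", "bias", "kappa"):
            flag = "  (at bound)" if self.at_bound[name] else ""
            lines.append(f"  {name:>6s} = {getattr(self.params, name): .4f}{flag}")
        return "\n".join(lines)


class RLCKModel:
    """RLCK model over one animal's sessions of (choices, rewards)."""

    def __init__(self, sessions: list[tuple]):
        if not sessions:
            raise ValueError("need at least one session")
        self.sessions = []
        for choices, rewards in sessions:
            c = _as_code(choices)
            r = np.asarray(rewards, dtype=np.float64)
            if len(c) != len(r):
                raise ValueError("choices and rewards must have equal length")
            if len(c) < 2:
                raise ValueError("each session needs >= 2 trials")
            self.sessions.append((c, r))
        self.n_trials = sum(len(c) for c, _ in self.sessions)

    @classmethod
    def from_dataframe(cls, trials, mouse_id=None):
        """Build from a trial table (columns side, reward, session[, mouse_id])."""
        df = trials
        if mouse_id is not None:
            df = df[df["mouse_id"] == mouse_id]
        sessions = [
            (g["side"].to_numpy(), g["reward"].to_numpy())
            for _, g in df.sort_values("trial").groupby("session")
        ]
        return cls(sessions)

    def _total_nll(self, x: np.ndarray) -> float:
        alpha, beta, bias, kappa = x
        return sum(
            rlck_negloglik(alpha, beta, bias, kappa, c, r)
            for c, r in self.sessions
        )

    def fit(
        self,
        n_restarts: int = 20,
        seed: int = 0,
        bounds: dict | None = None,
        tol: float = 1e-8,
    ) -> RLCKResults:
        """Bounded multi-restart ML fit; returns the best optimum found."""
        bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
        names = ("alpha", "beta", "bias", "kappa")
        lo = np.array([bounds[n][0] for n in names])
        hi = np.array([bounds[n][1] for n in names])
        rng = np.random.default_rng(seed)
        best, best_x, any_conv = np.inf, None, False
        starts = [np.array([0.5, 3.0, 0.0, 0.0])] + [
            lo + rng.random(4) * (hi - lo) for _ in range(max(0, n_restarts - 1))
        ]
        for x0 in starts:
            res = minimize(
                self._total_nll,
                x0,
                method="L-BFGS-B",
                bounds=list(zip(lo, hi)),
                tol=tol,
            )
            if res.fun < best:
                best, best_x = res.fun, res.x
                any_conv = bool(res.success)
        at_bound = {
            n: bool(
                np.isclose(best_x[i], lo[i], atol=1e-6)
                or np.isclose(best_x[i], hi[i], atol=1e-6)
            )
            for i, n in enumerate(names)
        }
        return RLCKResults(
            params=AgentParams(*best_x),
            nll=float(best),
            converged=any_conv,
            at_bound=at_bound,
            n_trials=self.n_trials,
            n_restarts=len(starts),
        )
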