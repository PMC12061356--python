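"""Transition-constrained explore/exploit hidden Markov model.

Three latent states — explore (0), exploit-left (1), exploit-right (2) —
generate the observed left/right choice sequence. Exploit states emit
their side deterministically; explore emits left with probability
``explore_emit_left`` (0.5 by default, fittable behind a flag). Direct
transitions between the two exploit states are structurally forbidden: an
animal cannot move from exploiting one aperture to exploiting the other
without passing through exploration. The two exploit states share one
persistence probability and explore exits split equally between them,
the most parsimonious parameterisation consistent with the allowed
transition diagram.

``ExploreExploitHMM`` fits the free parameters (stay probabilities,
initial distribution, optionally the explore emission) by Baum-Welch EM
with the structural zeros held exactly; ``HMMResults.decode`` returns
Viterbi labels (which can never violate the constraint, unlike per-trial
MAP labels) together with forward-backward posteriors P(explore).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import hmm_forward, hmm_forward_backward, hmm_viterbi

__all__ = [
    "HMMParams",
    "StateSequence",
    "ExploreExploitHMM",
    "HMMResults",
    "forward_loglik",
    "decode_states",
    "sample_states",
    "STATE_NAMES",
]

STATE_NAMES = ("explore", "exploit-left", "exploit-right")


@dataclass(frozen=True)
class HMMParams:
    stay_exploit: float = 0.9
    stay_explore: float = 0.7
    explore_emit_left: float = 0.5
    init: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

    def __post_init__(self) -> None:
        probs = (self.stay_exploit, self.stay_explore, self.explore_emit_left)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if len(self.init) != 3 or not np.isclose(sum(self.init), 1.0):
            raise ValueError("init must be a 3-vector summing to 1")

    @property
    def transition_matrix(self) -> np.ndarray:
        """Row-stochastic 3x3 matrix with exploit<->exploit entries zero."""
        se, sx = self.stay_explore, self.stay_exploit
        return np.array(
            [
                [se, (1 - se) / 2, (1 - se) / 2],
                [1 - sx, sx, 0.0],
                [1 - sx, 0.0, sx],
            ]
        )

    @property
    def emit_left(self) -> np.ndarray:
        """P(left choice | state) for (explore, exploit-L, exploit-R)."""
        return np.array([self.explore_emit_left, 1.0, 0.0])


@dataclass
class StateSequence:
    """Per-trial hard labels plus posterior probability of exploration."""

    states: np.ndarray  # int codes 0/1/2
    p_explore: np.ndarray
    posteriors: np.ndarray  # (T, 3) forward-backward gamma

    @property
    def labels(self) -> np.ndarray:
        return np.array([STATE_NAMES[s] for s in self.states])

    @property
    def explore_mask(self) -> np.ndarray:
        return self.states == 0


def _as_codes(choices) -> np.ndarray:
    arr = np.asarray(choices)
    if arr.dtype.kind in "UO":
        arr = np.array([0 if c == "left" else 1 for c in arr])
    arr = arr.astype(np.int64)
    if arr.size == 0:
        raise ValueError("choice sequence is empty")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("choices must be binary (left/right)")
    return arr


def forward_loglik(params: HMMParams, choices) -> float:
    """Log marginal likelihood of a choice sequence (scaled forward pass)."""
    c = _as_codes(choices)
    ll, _, _ = hmm_forward(
        c, params.transition_matrix, params.emit_left, np.asarray(params.init)
    )
    return float(ll)


def decode_states(params: HMMParams, choices) -> StateSequence:
    """Viterbi labels + posteriors under the constrained transition matrix."""
    c = _as_codes(choices)
    trans = params.transition_matrix
    emit = params.emit_left
    init = np.asarray(params.init)
    path = hmm_viterbi(c, trans, emit, init)
    _, gamma, _ = hmm_forward_backward(c, trans, emit, init)
    assert not _has_forbidden_jump(path), "Viterbi path violated structural zeros"
    return StateSequence(states=path, p_explore=gamma[:, 0], posteriors=gamma)


def _has_forbidden_jump(path: np.ndarray) -> bool:
    d = np.abs(np.diff(path))
    return bool(np.any((path[:-1] > 0) & (path[1:] > 0) & (d == 1)))


def sample_states(
    params: HMMParams, n_trials: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample a latent state chain from the constrained transition model."""
    trans = params.transition_matrix
    states = np.empty(n_trials, dtype=np.int64)
    states[0] = rng.choice(3, p=np.asarray(params.init))
    for t in range(1, n_trials):
        states[t] = rng.choice(3, p=trans[states[t - 1]])
    return states


@dataclass
class HMMResults:
    """Fitted constrained HMM with its EM trace and decode helpers."""

    params: HMMParams
    loglik: float
    ll_trace: np.ndarray
    converged: bool
    n_iter: int
    n_obs: int
    warning: str | None = None

    @property
    def aic(self) -> float:
        # free parameters: 2 stay probs + 2 init d.o.f. (+1 if emission fit)
        k = 4
        return 2 * k - 2 * self.loglik

    def decode(self, choices) -> StateSequence:
        return decode_states(self.params, choices)

    def summary(self) -> str:
        p = self.params
        return "\n".join(
            [
                "Constrained explore/exploit HMM (EM fit)",
                f"  sequences' total trials: {self.n_obs}   "
                f"logL: {self.loglik:.3f}   iterations: {self.n_iter}   "
                f"converged: {self.converged}",
                f"  stay_exploit = {p.stay_exploit:.4f}",
                f"  stay_explore = {p.stay_explore:.4f}",
                f"  explore_emit_left = {p.explore_emit_left:.4f}",
                "  init = ["
                + ", ".join(f"{v:.4f}" for v in p.init)
                + "]",
            ]
        )


class ExploreExploitHMM:
    """Constrained 3-state HMM over one or more choice sequences."""

    def __init__(self, sequences):
        def _is_seq(x):
            return isinstance(x, (list, tuple, np.ndarray)) and not isinstance(x, str)

        if _is_seq(sequences) and len(sequences) and _is_seq(sequences[0]):
            self.sequences = [_as_codes(s) for s in sequences]
        else:
            self.sequences = [_as_codes(sequences)]
        self.n_obs = sum(len(s) for s in self.sequences)

    @classmethod
    def from_dataframe(cls, trials, mouse_id=None):
        df = trials
        if mouse_id is not None:
            df = df[df["mouse_id"] == mouse_id]
        seqs = [
            g.sort_values("trial")["side"].to_numpy()
            for _, g in df.groupby(["mouse_id", "session"])
        ]
        return cls(seqs)

    def loglik(self, params: HMMParams) -> float:
        return sum(forward_loglik(params, s) for s in self.sequences)

    def _em_run(
        self, params: HMMParams, tol: float, max_iter: int, fit_emission: bool
    ):
        ll_prev = -np.inf
        trace = []
        for it in range(max_iter):
            trans = params.transition_matrix
            emit = params.emit_left
            init = np.asarray(params.init)
            ll_tot = 0.0
            xi_sum = np.zeros((3, 3))
            gamma0 = np.zeros(3)
            emit_num = 0.0  # expected left choices in explore
            emit_den = 0.0
            for seq in self.sequences:
                ll, gamma, xi = hmm_forward_backward(seq, trans, emit, init)
                ll_tot += ll
                xi_sum += xi
                gamma0 += gamma[0]
                if fit_emission:
                    emit_num += gamma[seq == 0, 0].sum()
                    emit_den += gamma[:, 0].sum()
            trace.append(ll_tot)
            if ll_tot - ll_prev < tol and it > 0:
                ll_prev = ll_tot
                break
            ll_prev = ll_tot
            # constrained M-step: pooled stay probabilities, free init simplex
            se = xi_sum[0, 0] / max(xi_sum[0].sum(), 1e-300)
            sx = (xi_sum[1, 1] + xi_sum[2, 2]) / max(
                xi_sum[1].sum() + xi_sum[2].sum(), 1e-300
            )
            init_new = gamma0 / gamma0.sum()
            eps = 1e-6
            new = {
                "stay_explore": float(np.clip(se, eps, 1 - eps)),
                "stay_exploit": float(np.clip(sx, eps, 1 - eps)),
                "init": tuple(init_new),
            }
            if fit_emission:
                new["explore_emit_left"] = float(
                    np.clip(emit_num / max(emit_den, 1e-300), eps, 1 - eps)
                )
            else:
                new["explore_emit_left"] = params.explore_emit_left
            params = HMMParams(**new)
        return params, np.array(trace)

    def fit(
        self,
        init_params: HMMParams | None = None,
        tol: float = 1e-6,
        max_iter: int = 300,
        n_restarts: int = 5,
        seed: int = 0,
        fit_emission: bool = False,
    ) -> HMMResults:
        """Baum-Welch EM with jittered restarts; structural zeros exact."""
        rng = np.random.default_rng(seed)
        base = init_params or HMMParams(stay_exploit=0.8, stay_explore=0.6)
        starts = [base]
        for _ in range(max(0, n_restarts - 1)):
            starts.append(
                HMMParams(
                    stay_exploit=float(np.clip(base.stay_exploit + 0.15 * rng.standard_normal(), 0.05, 0.99)),
                    stay_explore=float(np.clip(base.stay_explore + 0.15 * rng.standard_normal(), 0.05, 0.99)),
                    explore_emit_left=base.explore_emit_left,
                    init=base.init,
                )
            )
        best = None
        for start in starts:
            params, trace = self._em_run(start, tol, max_iter, fit_emission)
            if best is None or trace[-1] > best[1][-1]:
                best = (params, trace)
        params, trace = best
        converged = len(trace) < max_iter
        assert np.all(np.diff(trace) >= -1e-6), "EM log-likelihood decreased"
        return HMMResults(
            params=params,
            loglik=float(trace[-1]),
            ll_trace=trace,
            converged=converged,
            n_iter=len(trace),
            n_obs=self.n_obs,
            warning=None if converged else "EM reached max_iter without tol",
        )
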