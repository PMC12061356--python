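"""Constrained explore/exploit HMM: enumeration oracles, EM, decoding."""

import itertools

import numpy as np
import pytest

from touchbandit import (
    ExploreExploitHMM,
    HMMParams,
    decode_states,
    forward_loglik,
    sample_states,
)


def brute_force_loglik(params: HMMParams, choices) -> float:
    """Sum over all 3^T constrained paths (forbidden transitions give 0)."""
    A = params.transition_matrix
    e = params.emit_left
    init = np.asarray(params.init)
    total = 0.0
    T = len(choices)
    for path in itertools.product(range(3), repeat=T):
        p = init[path[0]]
        for t in range(1, T):
            p *= A[path[t - 1], path[t]]
        for t, c in enumerate(choices):
            p *= e[path[t]] if c == 0 else 1 - e[path[t]]
        total += p
    return float(np.log(total))


def brute_force_viterbi(params: HMMParams, choices):
    A = params.transition_matrix
    e = params.emit_left
    init = np.asarray(params.init)
    best_p, best_path = -1.0, None
    for path in itertools.product(range(3), repeat=len(choices)):
        p = init[path[0]]
        for t in range(1, len(choices)):
            p *= A[path[t - 1], path[t]]
        for t, c in enumerate(choices):
            p *= e[path[t]] if c == 0 else 1 - e[path[t]]
        if p > best_p:
            best_p, best_path = p, path
    return np.array(best_path), best_p


def test_transition_matrix_structure():
    par = HMMParams(stay_exploit=0.85, stay_explore=0.6)
    A = par.transition_matrix
    assert np.allclose(A.sum(axis=1), 1.0)
    assert A[1, 2] == 0.0 and A[2, 1] == 0.0  # exploit-L <-> exploit-R forbidden
    assert A[0, 1] == A[0, 2]  # explore exits split equally


def test_single_trial_closed_form():
    par = HMMParams(0.9, 0.7, init=(0.2, 0.5, 0.3))
    # left choice: init . emit_left = 0.2*0.5 + 0.5*1 + 0.3*0
    assert forward_loglik(par, [0]) == pytest.approx(np.log(0.2 * 0.5 + 0.5))
    with pytest.raises(ValueError):
        forward_loglik(par, [])


def test_forward_matches_exhaustive_enumeration(rng):
    for T in (2, 5, 8):
        for _ in range(3):
            par = HMMParams(
                stay_exploit=rng.uniform(0.5, 0.95),
                stay_explore=rng.uniform(0.3, 0.9),
            )
            c = rng.integers(0, 2, T)
            assert forward_loglik(par, c) == pytest.approx(
                brute_force_loglik(par, c), rel=1e-10
            )


def test_forward_symmetric_under_mirroring(rng):
    par = HMMParams(0.85, 0.65, explore_emit_left=0.5, init=(0.4, 0.3, 0.3))
    c = rng.integers(0, 2, 50)
    assert forward_loglik(par, c) == pytest.approx(
        forward_loglik(par, 1 - c), rel=1e-10
    )


def test_viterbi_matches_exhaustive_best_path(rng):
    for T in (4, 6, 8):
        for _ in range(3):
            par = HMMParams(
                stay_exploit=rng.uniform(0.6, 0.95),
                stay_explore=rng.uniform(0.3, 0.8),
                init=(0.4, 0.3, 0.3),
            )
            c = rng.integers(0, 2, T)
            seq = decode_states(par, c)
            _, best_p = brute_force_viterbi(par, c)
            # compare path probabilities (ties may pick different argmax paths)
            A, e, init = par.transition_matrix, par.emit_left, np.asarray(par.init)
            p = init[seq.states[0]]
            for t in range(1, T):
                p *= A[seq.states[t - 1], seq.states[t]]
            for t, ch in enumerate(c):
                p *= e[seq.states[t]] if ch == 0 else 1 - e[seq.states[t]]
            assert p == pytest.approx(best_p, rel=1e-10)


def test_long_same_side_run_decodes_as_exploit():
    par = HMMParams(stay_exploit=0.9, stay_explore=0.7)
    seq = decode_states(par, np.zeros(20, dtype=int))
    assert np.all(seq.states[2:] == 1)  # interior is exploit-left


def test_decoded_labels_never_jump_between_exploit_states(rng):
    par = HMMParams(0.9, 0.7)
    for _ in range(20):
        c = rng.integers(0, 2, 200)
        s = decode_states(par, c).states
        jumps = set(zip(s[:-1], s[1:]))
        assert (1, 2) not in jumps and (2, 1) not in jumps


def test_posteriors_normalise_and_mirror(rng):
    par = HMMParams(0.9, 0.7, init=(1 / 3, 1 / 3, 1 / 3))
    c = rng.integers(0, 2, 100)
    seq = decode_states(par, c)
    assert np.allclose(seq.posteriors.sum(axis=1), 1.0)
    assert np.all((seq.p_explore >= 0) & (seq.p_explore <= 1))
    mirrored = decode_states(par, 1 - c)
    assert np.allclose(seq.p_explore, mirrored.p_explore)
    swap = {0: 0, 1: 2, 2: 1}
    assert np.array_equal(seq.states, np.array([swap[s] for s in mirrored.states]))


def _simulate_sequences(par, n_seq, T, seed):
    rng = np.random.default_rng(seed)
    seqs = []
    for _ in range(n_seq):
        st = sample_states(par, T, rng)
        c = np.where(st == 1, 0, np.where(st == 2, 1, rng.integers(0, 2, T)))
        seqs.append(c)
    return seqs


def test_em_loglik_trace_is_monotone(rng):
    seqs = _simulate_sequences(HMMParams(0.9, 0.7), 5, 300, seed=4)
    res = ExploreExploitHMM(seqs).fit(seed=0, n_restarts=3)
    assert np.all(np.diff(res.ll_trace) >= -1e-6)


def test_em_recovers_stay_probabilities():
    true = HMMParams(stay_exploit=0.9, stay_explore=0.7)
    seqs = _simulate_sequences(true, 50, 300, seed=7)
    res = ExploreExploitHMM(seqs).fit(seed=0)
    assert res.params.stay_exploit == pytest.approx(0.9, abs=0.05)
    assert res.params.stay_explore == pytest.approx(0.7, abs=0.05)


def test_alternating_input_prefers_low_exploit_stay():
    c = np.tile([0, 1], 75)
    res = ExploreExploitHMM(c).fit(seed=0, n_restarts=3)
    assert res.params.stay_exploit < res.params.stay_explore
    # coarse grid oracle agrees on the likelihood ranking
    model = ExploreExploitHMM(c)
    lo = model.loglik(HMMParams(stay_exploit=0.2, stay_explore=0.8))
    hi = model.loglik(HMMParams(stay_exploit=0.8, stay_explore=0.2))
    assert lo > hi


def test_label_recovery_accuracy_on_own_generative_process():
    true = HMMParams(stay_exploit=0.9, stay_explore=0.7)
    rng = np.random.default_rng(21)
    states, seqs = [], []
    for _ in range(20):
        st = sample_states(true, 300, rng)
        c = np.where(st == 1, 0, np.where(st == 2, 1, rng.integers(0, 2, 300)))
        states.append(st)
        seqs.append(c)
    res = ExploreExploitHMM(seqs).fit(seed=0, n_restarts=3)
    acc = np.mean(
        [
            ((res.decode(c).states == 0) == (st == 0)).mean()
            for c, st in zip(seqs, states)
        ]
    )
    assert acc > 0.85


def test_sampled_chains_respect_structural_zeros(rng):
    st = sample_states(HMMParams(0.8, 0.5), 2000, rng)
    jumps = set(zip(st[:-1], st[1:]))
    assert (1, 2) not in jumps and (2, 1) not in jumps
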