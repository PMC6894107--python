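"""Linear-chain conditional random field: forward algorithm and Viterbi.

The CRF scores a label path ``y`` for a T-token sequence as

    score(y) = t[START, y_1] + sum_t e[t, y_t] + sum_t t[y_{t-1}, y_t]
               + t[y_T, STOP]

with emission scores ``e`` (from the Bi-LSTM) and a learned transition
matrix ``t`` of size ``(L+2) x (L+2)`` whose last two indices are the
virtual START and STOP states.  Training maximizes the log-likelihood
``score(gold) - log Z`` where the partition ``log Z`` is computed by the
forward algorithm with log-sum-exp stabilization; decoding is Viterbi with
ties broken toward the lower label index at every backtrack step, so output
is deterministic.

Transitions into START and out of STOP are masked to a large negative
constant (finite rather than -inf so log-sum-exp gradients stay finite);
the masked entries receive no gradient and therefore never move.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter, Tensor, logsumexp

NEG_MASK = -1.0e4


def make_transitions(n_labels: int, rng: np.random.Generator) -> Parameter:
    """Random-init transition matrix with START/STOP masking applied."""
    t = rng.normal(0.0, 0.1, size=(n_labels + 2, n_labels + 2))
    start, stop = n_labels, n_labels + 1
    t[:, start] = NEG_MASK   # nothing enters START
    t[stop, :] = NEG_MASK    # nothing leaves STOP
    t[start, stop] = NEG_MASK
    return Parameter(t)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def _reshape(x: Tensor, shape: tuple[int, ...]) -> Tensor:
    out = Tensor(x.data.reshape(shape), parents=(x,))

    def bw(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accum(g.reshape(x.data.shape))

    out._backward = bw
    return out


def crf_log_partition(emissions, transitions) -> Tensor:
    """log Z by the forward recursion (differentiable)."""
    e, t = _as_tensor(emissions), _as_tensor(transitions)
    T, L = e.shape
    start, stop = L, L + 1
    if T == 0:
        return Tensor(0.0)
    alpha = t[start, :L] + e[0]
    block = t[:L, :L]
    for i in range(1, T):
        alpha = logsumexp(_reshape(alpha, (L, 1)) + block, axis=0) + e[i]
    return logsumexp(alpha + t[:L, stop], axis=0)


def crf_path_score(emissions, transitions, labels: np.ndarray) -> Tensor:
    """Score of one label path (differentiable)."""
    e, t = _as_tensor(emissions), _as_tensor(transitions)
    T, L = e.shape
    labels = np.asarray(labels, dtype=np.intp)
    if labels.shape != (T,):
        raise ValueError("labels must have one entry per token")
    if T == 0:
        return Tensor(0.0)
    if labels.min() < 0 or labels.max() >= L:
        raise ValueError("label index outside label set")
    start, stop = L, L + 1
    frm = np.concatenate(([start], labels))
    to = np.concatenate((labels, [stop]))
    return e[np.arange(T), labels].sum() + t[frm, to].sum()


def crf_log_likelihood(emissions, transitions, labels) -> Tensor:
    """``score(gold) - log Z``; <= 0 up to float error for valid paths."""
    return crf_path_score(emissions, transitions, labels) - crf_log_partition(
        emissions, transitions
    )


def viterbi_decode(emissions, transitions) -> tuple[list[int], float]:
    """Maximum-score path and its score (pure numpy, no gradients).

    Ties are broken toward the lower label index (argmax takes the first
    maximum), so decoding is deterministic.
    """
    e = emissions.data if isinstance(emissions, Tensor) else np.asarray(emissions, float)
    t = transitions.data if isinstance(transitions, Tensor) else np.asarray(transitions, float)
    T, L = e.shape
    if T == 0:
        return [], 0.0
    start, stop = L, L + 1
    delta = t[start, :L] + e[0]
    psi = np.zeros((T, L), dtype=np.intp)
    for i in range(1, T):
        cand = delta[:, None] + t[:L, :L]  # (from, to)
        psi[i] = cand.argmax(axis=0)
        delta = cand[psi[i], np.arange(L)] + e[i]
    final = delta + t[:L, stop]
    last = int(final.argmax())
    path = [last]
    for i in range(T - 1, 0, -1):
        last = int(psi[i, last])
        path.append(last)
    path.reverse()
    return path, float(final.max())


def enumerate_paths_log_partition(emissions, transitions) -> float:
    """Brute-force log Z by enumerating every path (oracle for tiny cases)."""
    import itertools

    e = emissions.data if isinstance(emissions, Tensor) else np.asarray(emissions, float)
    t = transitions.data if isinstance(transitions, Tensor) else np.asarray(transitions, float)
    T, L = e.shape
    scores = [
        float(crf_path_score(e, t, np.array(path)).data)
        for path in itertools.product(range(L), repeat=T)
    ]
    m = max(scores)
    return m + float(np.log(np.sum(np.exp(np.array(scores) - m))))


def enumerate_paths_best(emissions, transitions) -> tuple[list[int], float]:
    """Brute-force argmax path (lowest lexicographic on ties)."""
    import itertools

    e = emissions.data if isinstance(emissions, Tensor) else np.asarray(emissions, float)
    t = transitions.data if isinstance(transitions, Tensor) else np.asarray(transitions, float)
    T, L = e.shape
    best_path, best_score = [], -np.inf
    for path in itertools.product(range(L), repeat=T):
        s = float(crf_path_score(e, t, np.array(path)).data)
        if s > best_score + 1e-12:
            best_path, best_score = list(path), s
    return best_path, best_score
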