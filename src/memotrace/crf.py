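"""Linear-chain CRF primitives: Viterbi decoding, log-partition, marginals.

A sequence of T tokens is scored against L tags.  A path score is the sum
of per-token emission scores and tag-to-tag transition scores, including
virtual START and STOP states:

    score(y) = trans[START, y_1] + sum_t emis[t, y_t]
             + sum_t trans[y_{t-1}, y_t] + trans[y_T, STOP]

``transitions`` is an (L+2, L+2) log-domain matrix whose last two rows and
columns are START and STOP; transitions that would violate BIO
well-formedness are held at a large negative constant (``NEG_INF``) so no
decoded or sampled path can use them.

All routines are in log-space with log-sum-exp for stability, and the
batched variants carry a boolean mask so padded positions contribute
nothing.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np

#: Effectively -inf, but finite so that arithmetic never produces NaN.
NEG_INF = -1e4


def bio_transition_mask(tags: Sequence[str]) -> np.ndarray:
    """Boolean (L+2, L+2) matrix of transitions allowed under BIO.

    ``I-L`` may only follow ``B-L`` or ``I-L``; START may not enter an
    ``I-`` tag; everything else (including any tag -> STOP) is allowed.
    Rows/columns L and L+1 are START and STOP.
    """
    L = len(tags)
    allowed = np.ones((L + 2, L + 2), dtype=bool)
    start, stop = L, L + 1
    allowed[:, start] = False           # nothing enters START
    allowed[stop, :] = False            # nothing leaves STOP
    allowed[start, stop] = False        # empty path disallowed
    for j, tj in enumerate(tags):
        if tj.startswith("I-"):
            label = tj[2:]
            for i, ti in enumerate(tags):
                if ti not in (f"B-{label}", f"I-{label}"):
                    allowed[i, j] = False
            allowed[start, j] = False
    return allowed


def _check(emissions: np.ndarray, transitions: np.ndarray) -> Tuple[int, int]:
    emissions = np.asarray(emissions)
    transitions = np.asarray(transitions)
    if emissions.ndim != 2 or transitions.ndim != 2:
        raise ValueError("emissions and transitions must be 2-D")
    T, L = emissions.shape
    if T < 1 or L < 1:
        raise ValueError("need T >= 1 tokens and L >= 1 tags")
    if transitions.shape != (L + 2, L + 2):
        raise ValueError(
            f"transitions must be ({L + 2}, {L + 2}) for L={L} tags, got "
            f"{transitions.shape}")
    return T, L


def viterbi_decode(emissions: np.ndarray,
                   transitions: np.ndarray) -> Tuple[List[int], float]:
    """Highest-scoring tag path and its score (START/STOP included).

    Ties are broken toward the lowest tag index, which makes decoding
    deterministic for degenerate score matrices.
    """
    T, L = _check(emissions, transitions)
    emissions = np.asarray(emissions, dtype=float)
    transitions = np.asarray(transitions, dtype=float)
    start, stop = L, L + 1
    delta = transitions[start, :L] + emissions[0]
    back = np.zeros((T, L), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + transitions[:L, :L]  # (prev, cur)
        back[t] = np.argmax(cand, axis=0)            # argmax -> lowest index
        delta = cand[back[t], np.arange(L)] + emissions[t]
    final = delta + transitions[:L, stop]
    last = int(np.argmax(final))
    score = float(final[last])
    path = [last]
    for t in range(T - 1, 0, -1):
        last = int(back[t, last])
        path.append(last)
    path.reverse()
    return path, score


def log_partition(emissions: np.ndarray, transitions: np.ndarray) -> float:
    """log sum over all tag paths of exp(path score), via the forward pass."""
    T, L = _check(emissions, transitions)
    emissions = np.asarray(emissions, dtype=float)
    transitions = np.asarray(transitions, dtype=float)
    start, stop = L, L + 1
    alpha = transitions[start, :L] + emissions[0]
    for t in range(1, T):
        alpha = _logsumexp_cols(alpha[:, None] + transitions[:L, :L]) \
            + emissions[t]
    return float(_logsumexp_cols(
        (alpha + transitions[:L, stop])[:, None])[0])


def _logsumexp_cols(m: np.ndarray) -> np.ndarray:
    mx = np.max(m, axis=0)
    return mx + np.log(np.sum(np.exp(m - mx[None, :]), axis=0))


def path_score(path: Sequence[int], emissions: np.ndarray,
               transitions: np.ndarray) -> float:
    """Score of one explicit tag path (oracle helper, also used in tests)."""
    T, L = _check(emissions, transitions)
    if len(path) != T:
        raise ValueError("path length must equal T")
    start, stop = L, L + 1
    s = transitions[start, path[0]] + emissions[0, path[0]]
    for t in range(1, T):
        s += transitions[path[t - 1], path[t]] + emissions[t, path[t]]
    return float(s + transitions[path[-1], stop])


# ---------------------------------------------------------------------------
# Batched forward-backward (training workhorse)
# ---------------------------------------------------------------------------

def _logsumexp(a: np.ndarray, axis: int) -> np.ndarray:
    mx = np.max(a, axis=axis, keepdims=True)
    out = mx + np.log(np.sum(np.exp(a - mx), axis=axis, keepdims=True))
    return np.squeeze(out, axis=axis)


def crf_nll_and_grad(emissions: np.ndarray, transitions: np.ndarray,
                     tags: np.ndarray, mask: np.ndarray
                     ) -> Tuple[float, np.ndarray, np.ndarray]:
    """Mean negative log-likelihood over a batch, with gradients.

    Parameters
    ----------
    emissions : (B, T, L) log-domain scores.
    transitions : (L+2, L+2) log-domain scores.
    tags : (B, T) int gold tag indices (ignored where mask is 0).
    mask : (B, T) {0,1}; every sequence must have mask[:, 0] == 1 and a
        contiguous prefix of ones.

    Returns
    -------
    (nll, d_emissions, d_transitions) where gradients are of the *mean*
    per-sequence NLL.
    """
    emissions = np.asarray(emissions, dtype=float)
    B, T, L = emissions.shape
    start, stop = L, L + 1
    mask = np.asarray(mask, dtype=bool)
    lengths = mask.sum(axis=1)
    if np.any(lengths < 1):
        raise ValueError("every sequence must have length >= 1")

    trans = np.asarray(transitions, dtype=float)
    tt = trans[:L, :L]  # (prev, cur)

    # Forward.
    alphas = np.empty((T, B, L))
    alphas[0] = trans[start, :L][None, :] + emissions[:, 0, :]
    for t in range(1, T):
        scores = alphas[t - 1][:, :, None] + tt[None, :, :]  # (B, prev, cur)
        new = _logsumexp(scores, axis=1) + emissions[:, t, :]
        m = mask[:, t][:, None]
        alphas[t] = np.where(m, new, alphas[t - 1])
    last = alphas[T - 1]  # (B, L), alpha at each sequence's final position
    logZ = _logsumexp(last + trans[:L, stop][None, :], axis=1)  # (B,)

    # Backward.
    betas = np.empty((T, B, L))
    betas[T - 1] = trans[:L, stop][None, :]
    for t in range(T - 2, -1, -1):
        nxt = betas[t + 1] + emissions[:, t + 1, :]          # (B, cur)
        new = _logsumexp(tt[None, :, :] + nxt[:, None, :], axis=2)
        m = mask[:, t + 1][:, None]
        # If position t is the last real token, beta = trans[:, stop].
        betas[t] = np.where(m, new, trans[:L, stop][None, :])

    # Unary marginals.
    log_marg = alphas + np.transpose(betas, (0, 1, 2)) - logZ[None, :, None]
    unary = np.exp(np.transpose(log_marg, (1, 0, 2)))        # (B, T, L)
    unary *= mask[:, :, None]

    # Gold score and gradients.
    bidx = np.arange(B)
    gold_unary = np.zeros_like(unary)
    gold_score = np.zeros(B)
    d_trans = np.zeros_like(trans)

    gold_score += trans[start, tags[:, 0]] + emissions[bidx, 0, tags[:, 0]]
    gold_unary[bidx, 0, tags[:, 0]] = 1.0
    np.add.at(d_trans, (np.full(B, start), tags[:, 0]), -1.0)
    for t in range(1, T):
        m = mask[:, t]
        prev, cur = tags[:, t - 1], tags[:, t]
        gold_score += m * (trans[prev, cur] + emissions[bidx, t, cur])
        gold_unary[bidx, t, cur] = m.astype(float)
        np.add.at(d_trans, (prev[m], cur[m]), -1.0)
    last_tags = tags[bidx, lengths - 1]
    gold_score += trans[last_tags, stop]
    np.add.at(d_trans, (last_tags, np.full(B, stop)), -1.0)

    # Expected pairwise transition counts.
    for t in range(1, T):
        m = mask[:, t]
        if not m.any():
            break
        lp = (alphas[t - 1][:, :, None] + tt[None, :, :]
              + emissions[:, t, :][:, None, :] + betas[t][:, None, :]
              - logZ[:, None, None])
        pair = np.exp(lp) * m[:, None, None]
        d_trans[:L, :L] += pair.sum(axis=0)
    # Expected START and STOP counts.
    start_marg = unary[:, 0, :]                              # (B, L)
    d_trans[start, :L] += start_marg.sum(axis=0)
    stop_marg = np.exp(last + trans[:L, stop][None, :] - logZ[:, None])
    d_trans[:L, stop] += stop_marg.sum(axis=0)

    nll = float(np.mean(logZ - gold_score))
    d_emis = (unary - gold_unary) / B
    d_trans /= B
    return nll, d_emis, d_trans
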