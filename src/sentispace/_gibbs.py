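"""Collapsed Gibbs sampling kernels for the biterm and LDA topic models.

Kernels are numba-jitted and use an internal xorshift64* generator so that a
fixed seed gives bit-identical assignments regardless of the global NumPy
random state.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_U11 = np.uint64(11)
_U12 = np.uint64(12)
_U25 = np.uint64(25)
_U27 = np.uint64(27)
_MULT = np.uint64(0x2545F4914F6CDD1D)
_INV53 = 1.0 / 9007199254740992.0  # 2^-53


@njit(cache=False)
def _rng_next(state):
    """One xorshift64* step; returns (new_state, uniform in [0, 1))."""
    state ^= state >> _U12
    state ^= state << _U25
    state ^= state >> _U27
    x = state * _MULT
    return state, np.float64(x >> _U11) * _INV53


def seed_state(seed: int) -> np.uint64:
    s = np.uint64(seed & 0xFFFFFFFFFFFFFFFF) ^ np.uint64(0x9E3779B97F4A7C15)
    if s == np.uint64(0):
        s = np.uint64(1)
    return s


@njit(cache=False)
def btm_gibbs(w1, w2, K, M, alpha, beta, iterations, state):
    """Collapsed Gibbs over biterm topic assignments.

    w1, w2: int64 word indices of each biterm (|B| long).  Returns
    (assignments z, topic counts n_k, word-topic counts n_wk).
    """
    B = w1.shape[0]
    n_k = np.zeros(K, np.int64)
    n_wk = np.zeros((M, K), np.int64)
    z = np.empty(B, np.int64)

    for b in range(B):
        state, u = _rng_next(state)
        k = int(u * K)
        if k >= K:
            k = K - 1
        z[b] = k
        n_k[k] += 1
        n_wk[w1[b], k] += 1
        n_wk[w2[b], k] += 1

    cum = np.empty(K, np.float64)
    for _ in range(iterations):
        for b in range(B):
            a = w1[b]
            c = w2[b]
            k = z[b]
            n_k[k] -= 1
            n_wk[a, k] -= 1
            n_wk[c, k] -= 1
            total = 0.0
            for kk in range(K):
                denom = 2.0 * n_k[kk] + M * beta
                p = (
                    (n_k[kk] + alpha)
                    * (n_wk[a, kk] + beta)
                    * (n_wk[c, kk] + beta)
                    / (denom * (denom + 1.0))
                )
                total += p
                cum[kk] = total
            state, u = _rng_next(state)
            r = u * total
            k = 0
            while k < K - 1 and cum[k] <= r:
                k += 1
            z[b] = k
            n_k[k] += 1
            n_wk[a, k] += 1
            n_wk[c, k] += 1
    return z, n_k, n_wk


@njit(cache=False)
def lda_gibbs(doc_ids, words, n_docs, K, M, alpha, beta, iterations, state):
    """Collapsed Gibbs over per-token topic assignments.

    doc_ids, words: int64 arrays over all token positions.  Returns
    (assignments z, doc-topic counts n_dk, word-topic counts n_wk,
    topic counts n_k).
    """
    N = words.shape[0]
    n_dk = np.zeros((n_docs, K), np.int64)
    n_wk = np.zeros((M, K), np.int64)
    n_k = np.zeros(K, np.int64)
    z = np.empty(N, np.int64)

    for t in range(N):
        state, u = _rng_next(state)
        k = int(u * K)
        if k >= K:
            k = K - 1
        z[t] = k
        n_dk[doc_ids[t], k] += 1
        n_wk[words[t], k] += 1
        n_k[k] += 1

    cum = np.empty(K, np.float64)
    for _ in range(iterations):
        for t in range(N):
            d = doc_ids[t]
            w = words[t]
            k = z[t]
            n_dk[d, k] -= 1
            n_wk[w, k] -= 1
            n_k[k] -= 1
            total = 0.0
            for kk in range(K):
                p = (
                    (n_dk[d, kk] + alpha)
                    * (n_wk[w, kk] + beta)
                    / (n_k[kk] + M * beta)
                )
                total += p
                cum[kk] = total
            state, u = _rng_next(state)
            r = u * total
            k = 0
            while k < K - 1 and cum[k] <= r:
                k += 1
            z[t] = k
            n_dk[d, k] += 1
            n_wk[w, k] += 1
            n_k[k] += 1
    return z, n_dk, n_wk, n_k
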