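"""Numba kernels for affine-gap alignment.

Two variants are used:

* local (Smith-Waterman) — best-scoring subsequence pair, 0-floored;
* fitting — the whole query against a local target span, used by the read
  mapper to enforce full-length placements (no soft clips by construction).

Matrices use the standard three-state affine decomposition: H (match state),
E (gap consuming target, a deletion from the query), F (gap consuming query,
an insertion). A gap of length k costs gap_open + k * gap_extend. Base code
4 (N) matches nothing, including another N.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10**8)


@njit(cache=True)
def local_matrices(q, t, match, mismatch, gap_open, gap_extend):
    n = q.shape[0]
    m = t.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = H[i, j - 1] - gap_open - gap_extend
            if E[i, j - 1] - gap_extend > e:
                e = E[i, j - 1] - gap_extend
            E[i, j] = e
            f = H[i - 1, j] - gap_open - gap_extend
            if F[i - 1, j] - gap_extend > f:
                f = F[i - 1, j] - gap_extend
            F[i, j] = f
            if q[i - 1] == t[j - 1] and q[i - 1] < 4:
                s = H[i - 1, j - 1] + match
            else:
                s = H[i - 1, j - 1] - mismatch
            h = s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
    return H, E, F


@njit(cache=True)
def fitting_matrices(q, t, match, mismatch, gap_open, gap_extend):
    """Query-global, target-local alignment matrices.

    Row 0 is free (any target start); the optimum is max over H[n, j].
    """
    n = q.shape[0]
    m = t.shape[0]
    H = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    for j in range(m + 1):
        H[0, j] = 0
    for i in range(1, n + 1):
        F[i, 0] = max(H[i - 1, 0] - gap_open - gap_extend, F[i - 1, 0] - gap_extend)
        H[i, 0] = F[i, 0]
        for j in range(1, m + 1):
            e = H[i, j - 1] - gap_open - gap_extend
            if E[i, j - 1] - gap_extend > e:
                e = E[i, j - 1] - gap_extend
            E[i, j] = e
            f = H[i - 1, j] - gap_open - gap_extend
            if F[i - 1, j] - gap_extend > f:
                f = F[i - 1, j] - gap_extend
            F[i, j] = f
            if q[i - 1] == t[j - 1] and q[i - 1] < 4:
                s = H[i - 1, j - 1] + match
            else:
                s = H[i - 1, j - 1] - mismatch
            h = s
            if e > h:
                h = e
            if f > h:
                h = f
            H[i, j] = h
    return H, E, F


@njit(cache=True)
def fitting_score(q, t, match, mismatch, gap_open, gap_extend):
    """Score-only fitting alignment with rolling rows: (best_score, best_end_j)."""
    n = q.shape[0]
    m = t.shape[0]
    Hp = np.zeros(m + 1, dtype=np.int32)
    Ep = np.full(m + 1, NEG, dtype=np.int32)
    Fp = np.full(m + 1, NEG, dtype=np.int32)
    Hc = np.empty(m + 1, dtype=np.int32)
    Ec = np.empty(m + 1, dtype=np.int32)
    Fc = np.empty(m + 1, dtype=np.int32)
    for i in range(1, n + 1):
        Fc[0] = max(Hp[0] - gap_open - gap_extend, Fp[0] - gap_extend)
        Hc[0] = Fc[0]
        Ec[0] = NEG
        for j in range(1, m + 1):
            e = Hc[j - 1] - gap_open - gap_extend
            if Ec[j - 1] - gap_extend > e:
                e = Ec[j - 1] - gap_extend
            Ec[j] = e
            f = Hp[j] - gap_open - gap_extend
            if Fp[j] - gap_extend > f:
                f = Fp[j] - gap_extend
            Fc[j] = f
            if q[i - 1] == t[j - 1] and q[i - 1] < 4:
                s = Hp[j - 1] + match
            else:
                s = Hp[j - 1] - mismatch
            h = s
            if e > h:
                h = e
            if f > h:
                h = f
            Hc[j] = h
        Hp, Hc = Hc, Hp
        Ep, Ec = Ec, Ep
        Fp, Fc = Fc, Fp
    best = NEG
    best_j = 0
    for j in range(m + 1):
        if Hp[j] > best:
            best = Hp[j]
            best_j = j
    return best, best_j
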