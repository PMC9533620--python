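"""Naive reference implementations used as independent oracles.

Everything here is written with explicit per-element loops and stays
deliberately independent of the vectorized package code paths it is
used to check.
"""

from __future__ import annotations

import math

import numpy as np


def naive_score_bundle(A: np.ndarray, FMS: np.ndarray, FDS: np.ndarray, T: float):
    """Triple-loop bidirectional scorer; returns a dict of intermediates."""
    A = np.asarray(A, dtype=float)
    n_m, n_d = A.shape

    def direction(assoc, F):
        n_src, n_tgt = assoc.shape
        S = np.zeros((n_src, n_tgt))
        W = np.zeros((n_src, n_tgt))
        for g in range(n_src):
            # nearest neighbour of g, self excluded, ties to smallest index
            best, best_sim = None, -math.inf
            for k in range(n_src):
                if k != g and F[g][k] > best_sim:
                    best, best_sim = k, F[g][k]
            for h in range(n_tgt):
                num = 0.0
                den = 0.0
                for k in range(n_src):
                    if F[g][k] >= T:
                        num += F[g][k] * assoc[k][h]
                    den += F[g][k] * assoc[k][h]
                S[g][h] = num / den if den > 0 else 0.0
                if assoc[g][h] != 0:
                    W[g][h] = math.exp(assoc[g][h])
                elif assoc[best][h] != 0:
                    W[g][h] = math.exp(F[g][best])
                else:
                    W[g][h] = 0.0
        return S, W

    S1, Wr = direction(A, np.asarray(FMS, float))
    S2, Wd = direction(A.T, np.asarray(FDS, float))
    Sd = S1 * Wr
    Sr = (S2 * Wd).T
    Sf = np.zeros((n_m, n_d))
    for g in range(n_m):
        for h in range(n_d):
            Sf[g][h] = (Sd[g][h] + Sr[g][h]) / 2.0
    return {"S1": S1, "S2": S2, "Wr": Wr, "Wd": Wd, "Sd": Sd, "Sr": Sr, "Sf": Sf}


def naive_auc(pos, neg) -> float:
    """Exhaustive pair-counting AUC with ties counted one half."""
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def random_instance(rng: np.random.Generator, n_m: int, n_d: int):
    """A random dense association matrix plus valid similarity matrices."""
    A = (rng.random((n_m, n_d)) < 0.4).astype(int)

    def random_similarity(n):
        raw = rng.random((n, n))
        sym = (raw + raw.T) / 2.0
        np.fill_diagonal(sym, 1.0)
        return sym

    return A, random_similarity(n_m), random_similarity(n_d)
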