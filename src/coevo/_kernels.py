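"""Numba kernels for the two inner loops that dominate runtime:
pairwise-identity neighbor counting and single-site Gibbs sampling."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def neighbor_counts(matrix: np.ndarray, min_matches: int) -> np.ndarray:
    """For each row, number of rows (itself included) sharing at least
    ``min_matches`` equal entries."""
    m, length = matrix.shape
    counts = np.ones(m, dtype=np.int64)
    for s in range(m):
        for t in range(s + 1, m):
            same = 0
            for k in range(length):
                if matrix[s, k] == matrix[t, k]:
                    same += 1
            if same >= min_matches:
                counts[s] += 1
                counts[t] += 1
    return counts


@njit(cache=True)
def gibbs_sample(
    h: np.ndarray,
    J: np.ndarray,
    n_samples: int,
    burn_in: int,
    thinning: int,
    seed: int,
    q_active: int,
) -> np.ndarray:
    """Single-chain single-site Gibbs sampler for a Potts model.

    ``q_active`` restricts updates to states 0..q_active-1 (the full
    alphabet when equal to q).  One sweep updates every position once in
    order; ``burn_in`` sweeps are discarded and one sample is kept every
    ``thinning`` sweeps thereafter.
    """
    np.random.seed(seed)
    L = h.shape[0]
    x = np.random.randint(0, q_active, size=L).astype(np.int8)
    out = np.empty((n_samples, L), dtype=np.int8)
    logits = np.empty(q_active)
    taken = 0
    sweep = 0
    while taken < n_samples:
        for i in range(L):
            for a in range(q_active):
                e = h[i, a]
                for j in range(L):
                    if j != i:
                        e += J[i, j, a, x[j]]
                logits[a] = e
            mx = logits[0]
            for a in range(1, q_active):
                if logits[a] > mx:
                    mx = logits[a]
            total = 0.0
            for a in range(q_active):
                logits[a] = np.exp(logits[a] - mx)
                total += logits[a]
            r = np.random.random() * total
            acc = 0.0
            newstate = q_active - 1
            for a in range(q_active):
                acc += logits[a]
                if r < acc:
                    newstate = a
                    break
            x[i] = newstate
        sweep += 1
        if sweep > burn_in and (sweep - burn_in) % thinning == 0:
            out[taken] = x
            taken += 1
    return out
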