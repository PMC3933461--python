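"""Simulated-annealing kernel for the weighted spin-glass partition.

Implements the Reichardt-Bornholdt Potts model on a weighted graph: each
node carries a spin in {0..q-1} and the Hamiltonian sums over co-assigned
pairs, with a configuration-model null:

    H = - sum_{i<j} (A_ij w_ij - gamma * s_i s_j / (2W)) * delta(sigma_i, sigma_j)
      = - sum_a W_in(a) + (gamma / (2 * 2W)) * (sum_a S_a^2 - sum_j s_j^2)

where s is the weighted node strength, S_a the total strength on spin a,
W the total edge weight and W_in(a) the weight inside spin a.  The module
search minimizes H by Metropolis moves of single spins over a geometric
cooling schedule, followed by a zero-temperature pass so the returned
partition is locally optimal; callers extract the community sharing the
seed's spin.  Compiled with numba over CSR arrays; deterministic for a
fixed rng seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["potts_anneal", "partition_hamiltonian_csr"]


@njit(cache=False)
def _strengths(indptr, indices, weights):
    n = indptr.shape[0] - 1
    s = np.zeros(n)
    for j in range(n):
        for idx in range(indptr[j], indptr[j + 1]):
            s[j] += weights[idx]
    return s


@njit(cache=False)
def partition_hamiltonian_csr(indptr, indices, weights, gamma, sigma):
    """Absolute Hamiltonian of a spin assignment."""
    n = indptr.shape[0] - 1
    s = _strengths(indptr, indices, weights)
    two_w = s.sum()
    w_in = 0.0
    for j in range(n):
        for idx in range(indptr[j], indptr[j + 1]):
            if sigma[indices[idx]] == sigma[j]:
                w_in += weights[idx]
    w_in *= 0.5
    q = 0
    for j in range(n):
        if sigma[j] + 1 > q:
            q = sigma[j] + 1
    S = np.zeros(q)
    s_sq = 0.0
    for j in range(n):
        S[sigma[j]] += s[j]
        s_sq += s[j] * s[j]
    null = 0.0
    for a in range(q):
        null += S[a] * S[a]
    return -w_in + gamma * (null - s_sq) / (2.0 * two_w)


@njit(cache=False)
def _neighbor_weight_to_spin(j, spin, sigma, indptr, indices, weights):
    k = 0.0
    for idx in range(indptr[j], indptr[j + 1]):
        if sigma[indices[idx]] == spin:
            k += weights[idx]
    return k


@njit(cache=False)
def _move_delta(j, b, sigma, S, s, gamma, two_w, indptr, indices, weights):
    a = sigma[j]
    k_a = _neighbor_weight_to_spin(j, a, sigma, indptr, indices, weights)
    k_b = _neighbor_weight_to_spin(j, b, sigma, indptr, indices, weights)
    return k_a - k_b + gamma * s[j] * (S[b] - S[a] + s[j]) / two_w


@njit(cache=False)
def _merge_pass(sigma, S, q, gamma, two_w, indptr, indices, weights, H):
    """Wholesale community merges (unreachable by single-node moves)."""
    n = sigma.shape[0]
    improved = True
    while improved:
        improved = False
        cross = np.zeros((q, q))
        for j in range(n):
            a = sigma[j]
            for idx in range(indptr[j], indptr[j + 1]):
                b = sigma[indices[idx]]
                if a != b:
                    cross[a, b] += weights[idx]
        best_d = -1e-12
        best_a = -1
        best_b = -1
        for a in range(q):
            if S[a] <= 0.0:
                continue
            for b in range(a + 1, q):
                if S[b] <= 0.0:
                    continue
                d = -cross[a, b] + gamma * S[a] * S[b] / two_w
                if d < best_d:
                    best_d = d
                    best_a = a
                    best_b = b
        if best_a >= 0:
            for j in range(n):
                if sigma[j] == best_a:
                    sigma[j] = best_b
            S[best_b] += S[best_a]
            S[best_a] = 0.0
            H += best_d
            improved = True
    return H


@njit(cache=False)
def _greedy_polish(sigma, S, s, q, gamma, two_w, indptr, indices, weights, H):
    n = sigma.shape[0]
    k = np.zeros(q)
    improved = True
    n_pass = 0
    while improved and n_pass < 200:
        improved = False
        n_pass += 1
        for j in range(n):
            k[:] = 0.0
            for idx in range(indptr[j], indptr[j + 1]):
                k[sigma[indices[idx]]] += weights[idx]
            a = sigma[j]
            best_b = a
            best_d = -1e-12
            for b in range(q):
                if b == a:
                    continue
                d = k[a] - k[b] + gamma * s[j] * (S[b] - S[a] + s[j]) / two_w
                if d < best_d:
                    best_d = d
                    best_b = b
            if best_b != a:
                S[a] -= s[j]
                S[best_b] += s[j]
                sigma[j] = best_b
                H += best_d
                improved = True
        h_after = _merge_pass(sigma, S, q, gamma, two_w, indptr, indices, weights, H)
        if h_after < H - 1e-12:
            H = h_after
            improved = True
    return H


@njit(cache=False)
def potts_anneal(
    indptr, indices, weights, q, gamma,
    t_start, t_stop, cooling, sweep_factor, rng_seed,
):
    """Anneal a q-state spin assignment; returns ``(sigma, H_absolute)``."""
    n = indptr.shape[0] - 1
    s = _strengths(indptr, indices, weights)
    two_w = s.sum()  # = 2 * total edge weight

    np.random.seed(rng_seed)
    sigma = np.empty(n, dtype=np.int64)
    for j in range(n):
        sigma[j] = int(np.random.random() * q) % q
    S = np.zeros(q)
    for j in range(n):
        S[sigma[j]] += s[j]
    H = partition_hamiltonian_csr(indptr, indices, weights, gamma, sigma)
    best_h = H
    best_sigma = sigma.copy()

    temp = t_start
    n_props = max(1, int(sweep_factor * n))
    while temp > t_stop:
        for _ in range(n_props):
            j = int(np.random.random() * n) % n
            b = int(np.random.random() * (q - 1)) % (q - 1)
            if b >= sigma[j]:
                b += 1
            d = _move_delta(j, b, sigma, S, s, gamma, two_w, indptr, indices, weights)
            if d <= 0.0 or np.random.random() < np.exp(-d / temp):
                S[sigma[j]] -= s[j]
                S[b] += s[j]
                sigma[j] = b
                H += d
                if H < best_h - 1e-12:
                    best_h = H
                    best_sigma[:] = sigma
        temp *= cooling

    H = _greedy_polish(sigma, S, s, q, gamma, two_w, indptr, indices, weights, H)
    if best_h < H - 1e-12:
        sigma2 = best_sigma.copy()
        S2 = np.zeros(q)
        for j in range(n):
            S2[sigma2[j]] += s[j]
        h2 = _greedy_polish(sigma2, S2, s, q, gamma, two_w, indptr, indices, weights, best_h)
        if h2 < H - 1e-12:
            return sigma2, h2
    return sigma, H
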