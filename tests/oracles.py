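"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive: explicit loops, exhaustive
enumeration, full recomputation.  Nothing imports the code paths it is
used to check.
"""

import itertools
import math

import numpy as np


def pair_frequencies_bruteforce(data: np.ndarray, q: int) -> np.ndarray:
    """f_ij(a,b) by explicit row enumeration; (L, L, q, q)."""
    M, L = data.shape
    out = np.zeros((L, L, q, q))
    for row in data:
        for i in range(L):
            for j in range(L):
                out[i, j, row[i], row[j]] += 1
    return out / M


def covariance_bruteforce(data: np.ndarray, q: int) -> np.ndarray:
    """c_ij(a,b) from indicator vectors; flattened (L*q, L*q)."""
    M, L = data.shape
    X = np.zeros((M, L * q))
    for m in range(M):
        for i in range(L):
            X[m, i * q + data[m, i]] = 1.0
    mean = X.mean(axis=0)
    return (X.T @ X) / M - np.outer(mean, mean)


def objective_bruteforce(data: np.ndarray, target_counts: np.ndarray) -> float:
    """Frobenius norm over the upper triangle of (d - d_target), from scratch."""
    M, L = data.shape
    ss = 0.0
    for m in range(M):
        for n in range(m + 1, M):
            diff = int((data[m] != data[n]).sum()) - int(target_counts[m, n])
            ss += diff * diff
    return math.sqrt(ss) / L


def potts_weights(J: np.ndarray, h: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All q^L states and their exact Boltzmann probabilities."""
    L, q = h.shape
    states = np.array(list(itertools.product(range(q), repeat=L)), dtype=int)
    logw = np.zeros(len(states))
    for k, s in enumerate(states):
        e = 0.0
        for i in range(L):
            e += h[i, s[i]]
            for j in range(i + 1, L):
                e += J[i, j, s[i], s[j]]
        logw[k] = e
    w = np.exp(logw - logw.max())
    return states, w / w.sum()


def potts_pair_marginals(J: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Exact f_ij(a,b) of a Potts model by full enumeration; (L, L, q, q)."""
    L, q = h.shape
    states, w = potts_weights(J, h)
    out = np.zeros((L, L, q, q))
    for s, p in zip(states, w):
        for i in range(L):
            for j in range(L):
                out[i, j, s[i], s[j]] += p
    return out


def felsenstein_site_likelihood_bruteforce(tree, leaf_states, mu, omega_i) -> float:
    """P(one column | tree) by summing over all internal-node states.

    ``leaf_states`` maps leaf node index -> observed symbol.
    """
    q = len(omega_i)
    internal = [v for v in range(tree.n_nodes) if tree.children[v]]

    def kernel(a, b, t):
        e = math.exp(-mu * t)
        return e * (1.0 if a == b else 0.0) + (1.0 - e) * omega_i[b]

    total = 0.0
    for assign in itertools.product(range(q), repeat=len(internal)):
        state = dict(zip(internal, assign))
        state.update(leaf_states)
        p = omega_i[state[0]]
        for v in range(1, tree.n_nodes):
            p *= kernel(state[tree.parent[v]], state[v], tree.blen[v])
        total += p
    return total


def apc_bruteforce(F: np.ndarray) -> np.ndarray:
    """Average-product correction evaluated entry by entry."""
    L = F.shape[0]
    row = np.array([sum(F[i, j] for j in range(L) if j != i) / (L - 1) for i in range(L)])
    tot = sum(F[i, j] for i in range(L) for j in range(L) if i != j) / (L * (L - 1))
    out = np.zeros_like(F)
    for i in range(L):
        for j in range(L):
            if i != j:
                out[i, j] = F[i, j] - row[i] * row[j] / tot
    return out


def ppv_bruteforce(scores: np.ndarray, contacts: np.ndarray, min_sep: int) -> np.ndarray:
    """PPV by sorting the eligible pair list explicitly."""
    L = scores.shape[0]
    pairs = [(i, j) for i in range(L) for j in range(i + 1, L) if j - i > min_sep]
    pairs.sort(key=lambda p: (-scores[p], p))
    hits = 0
    out = []
    for k, p in enumerate(pairs, start=1):
        hits += bool(contacts[p])
        out.append(hits / k)
    return np.array(out)
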