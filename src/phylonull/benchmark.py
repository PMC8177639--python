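"""Synthetic benchmark generators with known ground truth.

Two families of desk-scale stand-ins for real protein-family alignments:

* phylogeny-only alignments — site profiles drawn from a Dirichlet,
  evolved along a random tree under the Felsenstein kernel; sequences are
  correlated through shared ancestry but there are no couplings between
  sites by construction;
* equilibrium Potts alignments — i.i.d.-like Gibbs samples of a Potts
  model with "planted" coupling blocks on a known set of residue pairs,
  which serve as the true contact map for recovery experiments.

The two signals are generated separately on purpose: simulating coupled
(epistatic) evolution *on* a tree is a non-equilibrium process whose
inference is an open problem, and the evaluation logic here only needs
each signal in isolation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from numba import njit

from .alignment import AA_ALPHABET, Alignment
from .contacts import ContactMap
from .phylo import FelsensteinModel, Tree, resample_on_tree


@dataclass
class BenchmarkSpec:
    """Study conditions for one synthetic family.

    Defaults match the phylogenetic benchmark (M = 150 Yule-tree leaves,
    L = 50 columns, full 21-letter alphabet, mu calibrated so the mean
    pairwise Hamming distance is about 0.5).  For the planted-contact
    benchmark set ``planted_pairs`` (and typically M = 2000, L = 30).
    """

    M: int = 150
    L: int = 50
    q: int = 21
    tree_model: str = "yule"  # yule | kingman | star
    mu: float = 0.55
    dirichlet: float = 0.5
    planted_pairs: tuple[tuple[int, int], ...] = ()
    strength: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strength < 0:
            raise ValueError("coupling strength must be >= 0")
        for i, j in self.planted_pairs:
            if not (0 <= i < j < self.L):
                raise ValueError(f"planted pair ({i}, {j}) must satisfy 0 <= i < j < L")

    @property
    def alphabet(self) -> str:
        return AA_ALPHABET if self.q == len(AA_ALPHABET) else AA_ALPHABET[: self.q]


def random_contact_pairs(
    L: int, n_pairs: int, min_sep: int = 4, seed: int | np.random.Generator = 0
) -> tuple[tuple[int, int], ...]:
    """Draw distinct pairs (i, j), i < j, with |i - j| > min_sep."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    candidates = [(i, j) for i in range(L) for j in range(i + 1, L) if j - i > min_sep]
    if n_pairs > len(candidates):
        raise ValueError(f"only {len(candidates)} pairs with |i-j| > {min_sep}")
    idx = rng.choice(len(candidates), size=n_pairs, replace=False)
    return tuple(candidates[k] for k in sorted(idx))


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def _labels(M: int) -> list[str]:
    return [f"s{k + 1:04d}" for k in range(M)]


def sample_tree(M: int, tree_model: str = "yule", seed: int | np.random.Generator = 0) -> Tree:
    """Random tree with M leaves: Yule, Kingman coalescent, or star.

    Yule trees are pure-birth (unit rate) and rescaled to mean
    root-to-tip depth 1; Kingman trees use exponential coalescent waiting
    times and the same rescaling, so mu has the same meaning across tree
    models.  Star trees put every leaf at depth 1 under a single root.
    """
    if M < 2:
        raise ValueError("need at least 2 leaves")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = _labels(M)
    if tree_model == "star":
        parent = np.concatenate([[-1], np.zeros(M, dtype=int)])
        blen = np.concatenate([[0.0], np.ones(M)])
        return Tree(parent, blen, [None] + labels)
    if tree_model == "yule":
        return _yule_tree(M, labels, rng)
    if tree_model == "kingman":
        return _kingman_tree(M, labels, rng)
    raise ValueError(f"unknown tree model {tree_model!r}")


def _assemble(merge_order, times, leaf_times, M, labels) -> Tree:
    """Build a Tree from a bottom-up list of (child_a, child_b, time) merges."""
    n = 2 * M - 1
    parent = np.full(n, -2, dtype=int)
    node_time = np.zeros(n)
    node_time[:M] = leaf_times
    names: list[str | None] = list(labels) + [None] * (M - 1)
    for k, (a, b, t) in enumerate(merge_order):
        new = M + k
        parent[a] = parent[b] = new
        node_time[new] = t
    root_old = n - 1
    # re-index so the root is node 0 and children follow parents (preorder)
    order = [root_old]
    children: dict[int, list[int]] = {}
    for c in range(n):
        if parent[c] >= 0:
            children.setdefault(parent[c], []).append(c)
    stack = [root_old]
    order = []
    while stack:
        v = stack.pop()
        order.append(v)
        stack.extend(children.get(v, []))
    new_idx = {old: i for i, old in enumerate(order)}
    new_parent = np.full(n, -1, dtype=int)
    new_blen = np.zeros(n)
    new_names: list[str | None] = [None] * n
    for old, newi in new_idx.items():
        new_names[newi] = names[old]
        if parent[old] >= 0:
            new_parent[newi] = new_idx[parent[old]]
            new_blen[newi] = abs(node_time[parent[old]] - node_time[old])
    return Tree(new_parent, new_blen, new_names)


def _yule_tree(M: int, labels: list[str], rng: np.random.Generator) -> Tree:
    # forward pure-birth: split a random active lineage at Exp(k) intervals
    t = 0.0
    active = [0, 1]
    next_id = 2
    birth_time = {0: 0.0, 1: 0.0}
    children: dict[int, tuple[int, int]] = {}
    split_time: dict[int, float] = {}
    root_children = (0, 1)
    while len(active) < M:
        t += rng.exponential(1.0 / len(active))
        k = int(rng.integers(len(active)))
        v = active.pop(k)
        a, b = next_id, next_id + 1
        next_id += 2
        children[v] = (a, b)
        split_time[v] = t
        birth_time[a] = birth_time[b] = t
        active.extend([a, b])
    t_end = t + rng.exponential(1.0 / len(active))
    # convert to merge list over leaf indices
    leaf_ids = active
    depth = t_end
    # map: recursively collapse internal ids to merged clusters
    idx_of = {v: i for i, v in enumerate(leaf_ids)}
    merges = []
    times = []
    counter = len(leaf_ids)
    # process splits in reverse time order: each split merges its two subtrees
    for v in sorted(split_time, key=lambda u: -split_time[u]):
        a, b = children[v]
        ia, ib = idx_of.pop(a), idx_of.pop(b)
        merges.append((ia, ib, depth - split_time[v]))
        idx_of[v] = counter
        counter += 1
    # root joins the two original lineages at time `depth`
    ia, ib = idx_of.pop(root_children[0]), idx_of.pop(root_children[1])
    merges.append((ia, ib, depth))
    tree = _assemble(merges, None, np.zeros(M), M, labels)
    scale = tree.leaf_depths().mean()
    tree.blen /= scale
    return tree


def _kingman_tree(M: int, labels: list[str], rng: np.random.Generator) -> Tree:
    t = 0.0
    active = list(range(M))
    merges = []
    counter = M
    k = M
    while k > 1:
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[int(i)], active[int(j)]
        for x in sorted((int(i), int(j)), reverse=True):
            active.pop(x)
        merges.append((a, b, t))
        active.append(counter)
        counter += 1
        k -= 1
    tree = _assemble(merges, None, np.zeros(M), M, labels)
    scale = tree.leaf_depths().mean()
    tree.blen /= scale
    return tree


# ---------------------------------------------------------------------------
# phylogeny-only benchmark
# ---------------------------------------------------------------------------


class PhyloSample(NamedTuple):
    alignment: Alignment
    tree: Tree
    model: FelsensteinModel


def generate_phylo_msa(spec: BenchmarkSpec) -> PhyloSample:
    """Tree-evolved alignment with zero intrinsic couplings.

    Site profiles omega_i are drawn from a symmetric Dirichlet
    (concentration 0.5 by default, giving realistic conservation
    heterogeneity across columns), and sequences evolve on a sampled tree
    under the Felsenstein kernel at rate ``spec.mu``.
    """
    if spec.planted_pairs:
        raise ValueError("phylogenetic benchmark requires an empty planted graph")
    rng = np.random.default_rng(spec.seed)
    tree = sample_tree(spec.M, spec.tree_model, rng)
    omega = rng.dirichlet(np.full(spec.q, spec.dirichlet), size=spec.L)
    model = FelsensteinModel(spec.mu, omega)
    aln = resample_on_tree(model, tree, rng)
    aln.alphabet = spec.alphabet
    return PhyloSample(aln, tree, model)


# ---------------------------------------------------------------------------
# planted-contact Potts benchmark
# ---------------------------------------------------------------------------


@njit(cache=True)
def _gibbs_chain(J, h, n_burn, thin, n_samples, us):  # pragma: no cover
    """Systematic-scan Gibbs sampler for the Potts model; one chain.

    ``us`` is a pre-drawn array of uniforms, one per site update.
    Returns the thinned samples (n_samples, L).
    """
    L, q = h.shape
    seq = np.zeros(L, dtype=np.int8)
    # greedy-ish start from the fields alone using the first uniforms
    out = np.zeros((n_samples, L), dtype=np.int8)
    p = np.zeros(q)
    u_idx = 0
    total_sweeps = n_burn + n_samples * thin
    taken = 0
    for sweep in range(total_sweeps):
        for i in range(L):
            m = -1e300
            for a in range(q):
                e = h[i, a]
                for j in range(L):
                    if j != i:
                        e += J[i, j, a, seq[j]]
                p[a] = e
                if e > m:
                    m = e
            s = 0.0
            for a in range(q):
                p[a] = math.exp(p[a] - m)
                s += p[a]
            u = us[u_idx] * s
            u_idx += 1
            acc = 0.0
            choice = q - 1
            for a in range(q):
                acc += p[a]
                if u < acc:
                    choice = a
                    break
            seq[i] = choice
        if sweep >= n_burn and (sweep - n_burn) % thin == thin - 1:
            out[taken] = seq
            taken += 1
    return out


def build_planted_potts(
    spec: BenchmarkSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Couplings and fields for the planted-contact model.

    Planted pairs get a ferromagnetic-style diagonal block of strength
    ``s`` on the 20 non-gap states; fields are log-profiles drawn from a
    Dirichlet, giving conservation heterogeneity comparable to the
    phylogenetic benchmark.
    """
    L, q, s = spec.L, spec.q, spec.strength
    J = np.zeros((L, L, q, q))
    block = np.zeros((q, q))
    for a in range(1, q):
        block[a, a] = s
    for i, j in spec.planted_pairs:
        J[i, j] = block
        J[j, i] = block.T
    profile = rng.dirichlet(np.full(q, spec.dirichlet), size=L)
    h = np.log(np.maximum(profile, 1e-8))
    h -= h.mean(axis=1, keepdims=True)
    return J, h


def energy(J: np.ndarray, h: np.ndarray, seqs: np.ndarray) -> np.ndarray:
    """Potts energies -E (i.e. log-weights) of integer sequences, (n,)."""
    n, L = seqs.shape
    out = np.zeros(n)
    for i in range(L):
        out += h[i, seqs[:, i]]
        for j in range(i + 1, L):
            out += J[i, j, seqs[:, i], seqs[:, j]]
    return out


def gibbs_sample(
    J: np.ndarray,
    h: np.ndarray,
    n_samples: int,
    seed: int | np.random.Generator = 0,
    n_burn: int = 1000,
    thin: int = 10,
) -> np.ndarray:
    """Draw equilibrium-like Potts samples by single-chain Gibbs sampling.

    Systematic site order, burn-in ``n_burn`` sweeps, one sample every
    ``thin`` sweeps.  A lag-1 autocorrelation of the thinned log-weight
    series above 0.2 triggers a mixing warning.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = h.shape[0]
    total = (n_burn + n_samples * thin) * L
    us = rng.random(total)
    samples = _gibbs_chain(
        np.ascontiguousarray(J), np.ascontiguousarray(h), n_burn, thin, n_samples, us
    )
    if n_samples >= 10:
        e = energy(J, h, samples)
        if e.std() > 0:
            rho = float(np.corrcoef(e[:-1], e[1:])[0, 1])
            if rho > 0.2:
                warnings.warn(
                    f"thinned-sample log-weight autocorrelation {rho:.2f} > 0.2; "
                    "chain may be mixing poorly",
                    UserWarning,
                )
    return samples


def generate_potts_msa(spec: BenchmarkSpec) -> tuple[Alignment, ContactMap]:
    """Equilibrium Potts sample with planted contacts as ground truth."""
    if not spec.planted_pairs:
        raise ValueError("planted graph must be nonempty; use generate_phylo_msa "
                         "for the couplings-free benchmark")
    rng = np.random.default_rng(spec.seed)
    J, h = build_planted_potts(spec, rng)
    data = gibbs_sample(J, h, spec.M, rng)
    aln = Alignment(data, _labels(spec.M), spec.alphabet)
    contact = np.zeros((spec.L, spec.L), dtype=bool)
    for i, j in spec.planted_pairs:
        contact[i, j] = contact[j, i] = True
    return aln, ContactMap(contact)
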