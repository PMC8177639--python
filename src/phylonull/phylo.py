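"""Trees, the Felsenstein independent-site model, and sequence resampling.

Null model III re-emits alignments by evolving sequences on a phylogeny
under the Felsenstein substitution model: each site i evolves independently
with transition kernel

    P(b | a, t) = exp(-mu t) delta_ab + (1 - exp(-mu t)) omega_i(b),

whose stationary distribution is the site-specific profile omega_i.  The
root sequence is drawn site-wise from omega, evolved along every branch,
and the leaf sequences form the resampled alignment.  This preserves
conservation (through omega) and phylogeny (through the tree) but contains
no intrinsic couplings between sites.

Trees are read from Newick or built by neighbor joining with midpoint
rooting from a Hamming-distance matrix (scikit-bio backend).  Branch
lengths and the mutation rate mu are jointly non-identifiable up to
rescaling; the convention here is to keep the input tree's lengths fixed
and fit only mu.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .alignment import Alignment, DistanceMatrix, compute_profile


class TreeFormatError(ValueError):
    """Raised on malformed Newick input."""


class Tree:
    """Rooted tree stored as flat parent/children arrays.

    Node 0 is the root.  ``blen[k]`` is the length of the branch above node
    ``k`` (0 for the root).  Leaves carry labels; internal nodes may be
    anonymous.
    """

    def __init__(
        self,
        parent: np.ndarray,
        blen: np.ndarray,
        names: list[str | None],
    ) -> None:
        self.parent = np.asarray(parent, dtype=np.int64)
        self.blen = np.asarray(blen, dtype=float)
        self.names = list(names)
        n = len(self.parent)
        if len(self.blen) != n or len(self.names) != n:
            raise ValueError("parent/blen/names length mismatch")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1 or roots[0] != 0:
            raise ValueError("exactly one root required, at node 0")
        if np.any(~np.isfinite(self.blen)) or np.any(self.blen < 0):
            raise ValueError("branch lengths must be finite and >= 0")
        self.children: list[list[int]] = [[] for _ in range(n)]
        for k in range(1, n):
            self.children[self.parent[k]].append(k)
        self.leaves = [k for k in range(n) if not self.children[k]]

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def leaf_labels(self) -> list[str]:
        return [self.names[k] or f"leaf{k}" for k in self.leaves]

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [0]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        return order[::-1]

    def preorder(self) -> list[int]:
        order: list[int] = []
        stack = [0]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        return order

    def leaf_depths(self) -> np.ndarray:
        """Root-to-leaf path lengths, in leaf order."""
        depth = np.zeros(self.n_nodes)
        for node in self.preorder():
            if node != 0:
                depth[node] = depth[self.parent[node]] + self.blen[node]
        return depth[self.leaves]

    def leaf_distance_matrix(self) -> np.ndarray:
        """Pairwise leaf-to-leaf path lengths (n_leaves x n_leaves)."""
        n = self.n_nodes
        depth = np.zeros(n)
        for node in self.preorder():
            if node != 0:
                depth[node] = depth[self.parent[node]] + self.blen[node]
        # ancestor sets via repeated parent hops (trees here are small)
        anc: list[set[int]] = [set() for _ in range(n)]
        for k in range(n):
            p = k
            while p >= 0:
                anc[k].add(p)
                p = int(self.parent[p])
        leaves = self.leaves
        m = len(leaves)
        out = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                common = anc[leaves[i]] & anc[leaves[j]]
                mrca_depth = max(depth[c] for c in common)
                out[i, j] = out[j, i] = (
                    depth[leaves[i]] + depth[leaves[j]] - 2 * mrca_depth
                )
        return out

    # -- Newick I/O ---------------------------------------------------------

    @classmethod
    def from_skbio(cls, sk_root) -> "Tree":
        parent: list[int] = []
        blen: list[float] = []
        names: list[str | None] = []
        missing = 0

        def add(node, parent_idx: int) -> None:
            nonlocal missing
            idx = len(parent)
            parent.append(parent_idx)
            length = node.length
            if length is None:
                length = 0.0
                if parent_idx >= 0:
                    missing += 1
            blen.append(max(0.0, float(length)))
            names.append(node.name)
            for child in node.children:
                add(child, idx)

        add(sk_root, -1)
        if missing:
            warnings.warn(f"{missing} branches lacked lengths; set to 0", UserWarning)
        tree = cls(np.array(parent), np.array(blen), names)
        if tree.n_leaves < 2:
            raise ValueError("tree must have at least 2 leaves")
        return tree

    @classmethod
    def from_newick(cls, source: str) -> "Tree":
        """Parse a Newick string or file path."""
        import skbio

        text = source
        try:
            if "(" not in source:  # looks like a path
                with open(source) as fh:
                    text = fh.read()
            sk = skbio.TreeNode.read(io.StringIO(text), format="newick")
        except OSError:
            raise
        except Exception as exc:
            raise TreeFormatError(f"cannot parse Newick: {exc}") from exc
        return cls.from_skbio(sk)

    def to_newick(self) -> str:
        def render(node: int) -> str:
            if not self.children[node]:
                base = self.names[node] or ""
            else:
                inner = ",".join(render(c) for c in self.children[node])
                base = f"({inner})" + (self.names[node] or "")
            if node == 0:
                return base
            return f"{base}:{self.blen[node]:.10g}"

        return render(0) + ";"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")


def read_newick(path) -> Tree:
    """Read a rooted tree with branch lengths from a Newick file."""
    return Tree.from_newick(str(path))


def correct_saturation(d: DistanceMatrix, profile) -> DistanceMatrix:
    """Convert observed Hamming fractions to evolutionary distances.

    Observed distances saturate at b = 1 - mean_i sum_a f_i(a)^2, the
    expected distance between two independent profile draws; the
    correction t = -b log(1 - d/b) (the Jukes-Cantor form with the
    profile-estimated plateau) undoes the compression of deep branches
    before tree building.  Distances at or beyond the plateau are capped.
    """
    b = float(1.0 - (np.asarray(profile.freq) ** 2).sum(axis=1).mean())
    arg = np.clip(1.0 - d.d / b, 1e-2, 1.0)
    t = -b * np.log(arg)
    np.fill_diagonal(t, 0.0)
    return DistanceMatrix(t, list(d.labels))


def nj_tree(d: DistanceMatrix, labels: list[str] | None = None) -> Tree:
    """Neighbor-joining tree with midpoint rooting.

    Negative branch-length estimates are clamped to 0.  This is the
    internal distance-based fallback for when no externally inferred tree
    is supplied.
    """
    import skbio
    from skbio.tree import nj

    if d.M < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    labels = labels if labels is not None else d.labels
    dm = skbio.DistanceMatrix(d.d, ids=labels)
    unrooted = nj(dm)
    for node in unrooted.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    rooted = unrooted.root_at_midpoint()
    return Tree.from_skbio(rooted)


# ---------------------------------------------------------------------------
# Felsenstein model
# ---------------------------------------------------------------------------


@dataclass
class FelsensteinModel:
    """Independent-site substitution model: rate mu and site profiles omega."""

    mu: float
    omega: np.ndarray  # (L, q)
    log_likelihood: float | None = None

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if not np.allclose(self.omega.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("omega rows must sum to 1")

    @property
    def L(self) -> int:
        return self.omega.shape[0]

    @property
    def q(self) -> int:
        return self.omega.shape[1]


def transition_probability(a: int, b: int, t: float, mu: float, omega_i: np.ndarray) -> float:
    """P(b | a, t) = exp(-mu t) delta_ab + (1 - exp(-mu t)) omega_i(b)."""
    if t < 0:
        raise ValueError("branch length t must be >= 0")
    e = math.exp(-mu * t)
    return e * (1.0 if a == b else 0.0) + (1.0 - e) * float(omega_i[b])


def _aligned_leaf_rows(aln: Alignment, tree: Tree) -> np.ndarray:
    """Row indices of ``aln`` matching the tree's leaves, in leaf order."""
    index = {lab: i for i, lab in enumerate(aln.labels)}
    try:
        return np.array([index[lab] for lab in tree.leaf_labels], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"tree leaf {exc} not found among alignment labels") from exc


def _site_log_likelihoods(
    data_leaf_order: np.ndarray, tree: Tree, mu: float, omega: np.ndarray
) -> np.ndarray:
    """Per-site log-likelihoods by pruning, vectorized over sites.

    For this kernel the per-child message has the closed form
    ``exp(-mu t) * p_child(a) + (1 - exp(-mu t)) * <omega_i, p_child>``,
    so no q x q matrix products are needed.
    """
    L, q = omega.shape
    n = tree.n_nodes
    partial = np.zeros((n, L, q))
    logscale = np.zeros((n, L))
    leaf_of = {node: r for r, node in enumerate(tree.leaves)}
    for node in tree.postorder():
        if not tree.children[node]:
            row = data_leaf_order[leaf_of[node]]
            partial[node][np.arange(L), row] = 1.0
            continue
        acc = np.ones((L, q))
        lsc = np.zeros(L)
        for child in tree.children[node]:
            e = math.exp(-mu * tree.blen[child])
            mix = (omega * partial[child]).sum(axis=1)  # (L,)
            acc = acc * (e * partial[child] + (1.0 - e) * mix[:, None])
            lsc += logscale[child]
        scale = acc.max(axis=1)
        safe = np.where(scale > 0, scale, 1.0)
        partial[node] = acc / safe[:, None]
        with np.errstate(divide="ignore"):
            logscale[node] = lsc + np.log(scale)
    root_like = (omega * partial[0]).sum(axis=1)
    with np.errstate(divide="ignore"):
        return np.log(root_like) + logscale[0]


def site_log_likelihood(
    aln: Alignment, tree: Tree, model: FelsensteinModel, site: int
) -> float:
    """log P(column ``site`` | tree, mu, omega_i) by post-order pruning."""
    rows = _aligned_leaf_rows(aln, tree)
    col = aln.data[rows, site : site + 1]
    ll = _site_log_likelihoods(col, tree, model.mu, model.omega[site : site + 1])
    return float(ll[0])


def total_log_likelihood(aln: Alignment, tree: Tree, model: FelsensteinModel) -> float:
    rows = _aligned_leaf_rows(aln, tree)
    return float(_site_log_likelihoods(aln.data[rows], tree, model.mu, model.omega).sum())


LOG_MU_BOUNDS = (-6.0, 3.0)


def _expected_emission_counts(
    data_leaf_order: np.ndarray, tree: Tree, mu: float, omega: np.ndarray
) -> np.ndarray:
    """E-step: expected per-site counts of draws from omega, given the data.

    Under the kernel, a symbol is emitted from omega once at the root and
    once on every branch where a substitution event occurs; the expected
    counts of these emissions are the sufficient statistics for omega.
    All scale factors cancel inside the per-branch posterior ratios, so the
    max-normalized upward partials can be used directly.
    """
    L, q = omega.shape
    n = tree.n_nodes
    up = np.zeros((n, L, q))
    leaf_of = {node: r for r, node in enumerate(tree.leaves)}
    msg = np.zeros((n, L, q))  # message from node to its parent
    for node in tree.postorder():
        if not tree.children[node]:
            up[node][np.arange(L), data_leaf_order[leaf_of[node]]] = 1.0
        else:
            acc = np.ones((L, q))
            for child in tree.children[node]:
                acc = acc * msg[child]
            up[node] = acc / np.maximum(acc.max(axis=1, keepdims=True), 1e-300)
        if node != 0:
            e = math.exp(-mu * tree.blen[node])
            mix = (omega * up[node]).sum(axis=1)
            msg[node] = e * up[node] + (1.0 - e) * mix[:, None]
    counts = np.zeros((L, q))
    root_post = omega * up[0]
    counts += root_post / root_post.sum(axis=1, keepdims=True)
    # downward vectors T[c]: unnormalized distribution over the parent state
    # seen from branch c (outside data + siblings); root's T is omega itself
    T = np.zeros((n, L, q))
    for node in tree.preorder():
        if node == 0:
            parent_vec = np.broadcast_to(omega, (L, q))
        else:
            e = math.exp(-mu * tree.blen[node])
            # state distribution at this node from outside:
            # B(b) = e * T(b) + (1 - e) * omega(b) * sum_a T(a)
            parent_vec = e * T[node] + (1.0 - e) * omega * T[node].sum(
                axis=1, keepdims=True
            )
            parent_vec = parent_vec / np.maximum(
                parent_vec.max(axis=1, keepdims=True), 1e-300
            )
        for child in tree.children[node]:
            sib = np.broadcast_to(parent_vec, (L, q)).copy()
            for other in tree.children[node]:
                if other != child:
                    sib *= msg[other]
            T[child] = sib / np.maximum(sib.max(axis=1, keepdims=True), 1e-300)
            e = math.exp(-mu * tree.blen[child])
            mix = (omega * up[child]).sum(axis=1)
            t_sum = T[child].sum(axis=1)
            # normalizer: sum_{a,b} T(a) k(b|a) U(b)
            z = e * (T[child] * up[child]).sum(axis=1) + (1.0 - e) * t_sum * mix
            e_mut = (1.0 - e) * omega * up[child] * t_sum[:, None]
            counts += e_mut / np.maximum(z[:, None], 1e-300)
    return counts


def fit_felsenstein(
    aln: Alignment,
    tree: Tree,
    pseudocount: float | None = None,
    refine_omega: bool = True,
    em_rounds: int = 5,
    xatol: float = 1e-4,
) -> FelsensteinModel:
    """Maximum-likelihood fit of the Felsenstein model on a fixed tree.

    omega_i is initialized at the empirical column frequencies with a
    pseudocount (default 1/M, which also regularizes single-symbol
    columns), then mu is optimized by bounded 1-D maximization of the
    total pruning log-likelihood over log mu in [-6, 3].  With
    ``refine_omega``, up to ``em_rounds`` EM rounds re-estimate omega
    from the expected emission counts, re-optimizing mu after each round
    (the empirical initialization alone is a consistent but biased
    moment estimate: it overweights shallow parts of the tree).
    """
    if pseudocount is None:
        pseudocount = 1.0 / aln.M
    omega = compute_profile(aln, pseudocount=pseudocount).freq
    rows = _aligned_leaf_rows(aln, tree)
    data = aln.data[rows]

    def neg_ll(x: float, om: np.ndarray) -> float:
        return -float(_site_log_likelihoods(data, tree, math.exp(x), om).sum())

    res = minimize_scalar(
        neg_ll, bounds=LOG_MU_BOUNDS, args=(omega,), method="bounded",
        options={"xatol": xatol},
    )
    mu = math.exp(res.x)
    if refine_omega:
        prev_ll = -float(res.fun)
        for _ in range(em_rounds):
            counts = _expected_emission_counts(data, tree, mu, omega)
            omega = (counts + pseudocount) / (
                counts.sum(axis=1, keepdims=True) + aln.q * pseudocount
            )
            res = minimize_scalar(
                neg_ll, bounds=LOG_MU_BOUNDS, args=(omega,), method="bounded",
                options={"xatol": xatol},
            )
            mu = math.exp(res.x)
            if -float(res.fun) - prev_ll < 1e-3:
                break
            prev_ll = -float(res.fun)
    lo, hi = LOG_MU_BOUNDS
    if res.x - lo < 10 * xatol or hi - res.x < 10 * xatol:
        warnings.warn(
            f"fitted log mu = {res.x:.3f} lies at the search boundary "
            f"[{lo}, {hi}]; likelihood may be flat in mu",
            UserWarning,
        )
    return FelsensteinModel(mu, omega, log_likelihood=-float(res.fun))


def fit_resampling_model(
    aln: Alignment, tree: Tree | None = None, **fit_kwargs
) -> tuple[Tree, FelsensteinModel]:
    """Complete null-model-III setup: tree plus fitted substitution model.

    Without an externally inferred tree, one is built by neighbor joining
    on saturation-corrected Hamming distances with midpoint rooting.
    """
    if tree is None:
        from .alignment import hamming_matrix

        d = hamming_matrix(aln)
        tree = nj_tree(correct_saturation(d, compute_profile(aln)))
    return tree, fit_felsenstein(aln, tree, **fit_kwargs)


def _categorical_rows(prob: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one category per row of a (n, q) probability matrix."""
    c = prob.cumsum(axis=1)
    c[:, -1] = 1.0
    u = rng.random((prob.shape[0], 1))
    return (u > c[:, :-1]).sum(axis=1).astype(np.int8)


def resample_on_tree(
    model: FelsensteinModel, tree: Tree, seed: int | np.random.Generator = 0
) -> Alignment:
    """Emit one alignment by evolving a root draw from omega down the tree.

    Rows are the leaf sequences, labelled by the tree's leaf labels (in
    leaf-traversal order); different seeds give independent alignments on
    the same tree and model.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = model.L
    seqs = np.zeros((tree.n_nodes, L), dtype=np.int8)
    seqs[0] = _categorical_rows(model.omega, rng)
    for node in tree.preorder():
        if node == 0:
            continue
        parent_seq = seqs[tree.parent[node]]
        p_mut = 1.0 - math.exp(-model.mu * tree.blen[node])
        mask = rng.random(L) < p_mut
        child = parent_seq.copy()
        if mask.any():
            child[mask] = _categorical_rows(model.omega[mask], rng)
        seqs[node] = child
    from .alignment import AA_ALPHABET

    alphabet = AA_ALPHABET if model.q == len(AA_ALPHABET) else AA_ALPHABET[: model.q]
    return Alignment(seqs[tree.leaves], tree.leaf_labels, alphabet)


def model_to_tsv(model: FelsensteinModel, path, alphabet: str | None = None) -> None:
    """Dump the fitted model as TSV: mu scalar then the L x q omega table."""
    with open(path, "w") as fh:
        fh.write(f"# mu\t{model.mu:.10g}\n")
        header = alphabet if alphabet else [str(a) for a in range(model.q)]
        fh.write("site\t" + "\t".join(header) + "\n")
        for i, row in enumerate(model.omega, start=1):
            fh.write(f"{i}\t" + "\t".join(f"{x:.8g}" for x in row) + "\n")
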