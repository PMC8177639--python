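"""Pseudo-likelihood inference of a pairwise Potts model (plmDCA).

The sequence distribution is P(a_1..a_L) proportional to
``exp(sum_{i<j} J_ij(a_i, a_j) + sum_i h_i(a_i))``.  Exact maximum
likelihood is intractable (the partition function sums over q^L states),
so each site's conditional distribution given the rest — a multiclass
logistic model — is maximized independently with L2 regularization, the
two asymmetric estimates of every coupling block are averaged, and the
result is reported in the zero-sum gauge.  No sequence weighting is used.

The optimizer is deterministic (L-BFGS with fixed iteration order), so
repeated fits of the same alignment are bit-for-bit identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax

from .alignment import Alignment, _one_hot


class PlmConvergenceError(RuntimeError):
    """Optimizer failed; carries the per-site objective traces."""

    def __init__(self, message: str, traces: list[list[float]]):
        super().__init__(message)
        self.traces = traces


@dataclass
class PottsModel:
    """Couplings J (L, L, q, q) and fields h (L, q); gauge-tagged.

    ``J[i, j, a, b]`` couples symbol ``a`` at site ``i`` with ``b`` at
    ``j``; the tensor is symmetric under ``(i,a) <-> (j,b)`` and its
    diagonal blocks are zero.  The partition function is implicit.
    """

    J: np.ndarray
    h: np.ndarray
    gauge: str = "fitting"
    meta: dict = field(default_factory=dict)

    @property
    def L(self) -> int:
        return self.h.shape[0]

    @property
    def q(self) -> int:
        return self.h.shape[1]

    def to_zero_sum(self) -> "PottsModel":
        """Return the model re-expressed in the zero-sum (Ising) gauge.

        Site-dependent constants move from J into h and from h into the
        implicit constant; the distribution is unchanged.
        """
        L, q = self.L, self.q
        J = self.J.astype(float).copy()
        h = self.h.astype(float).copy()
        row = J.mean(axis=3)            # (L, L, q): mean over b
        col = J.mean(axis=2)            # (L, L, q): mean over a
        tot = J.mean(axis=(2, 3))       # (L, L)
        Jz = J - row[..., None] - col[:, :, None, :] + tot[..., None, None]
        for i in range(L):
            Jz[i, i] = 0.0
        # transfer row means of every partner block into the fields
        h = h + (row - tot[..., None]).sum(axis=1)
        h = h - h.mean(axis=1, keepdims=True)
        return PottsModel(Jz, h, gauge="zero-sum", meta=dict(self.meta))


@dataclass
class ScoreMatrix:
    """Symmetric L x L pair scores with zero diagonal."""

    F: np.ndarray
    corrected: bool = False

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if not np.allclose(self.F, self.F.T, atol=1e-9):
            raise ValueError("score matrix must be symmetric")

    @property
    def L(self) -> int:
        return self.F.shape[0]


def plm_fit(
    aln: Alignment,
    lambda_J: float | None = None,
    lambda_h: float = 0.01,
    max_iter: int = 500,
    grad_tol: float = 1e-5,
) -> PottsModel:
    """Fit the Potts model by asymmetric pseudo-likelihood maximization.

    For each site r the L2-regularized conditional log-likelihood of
    column r given all other columns is maximized (L-BFGS, analytic
    gradient).  ``lambda_J`` defaults to ``0.01 * (q - 1)`` and
    ``lambda_h`` to 0.01 per conditional.  The returned model is in the
    zero-sum gauge.
    """
    M, L, q = aln.M, aln.L, aln.q
    if M < 2 or L < 2:
        raise ValueError("plm_fit needs M >= 2 and L >= 2")
    if lambda_J is None:
        lambda_J = 0.01 * (q - 1)
    X_all = _one_hot(aln)
    J_hat = np.zeros((L, L, q, q))
    h_hat = np.zeros((L, q))
    traces: list[list[float]] = []
    n_feat = (L - 1) * q
    for r in range(L):
        mask = np.ones(L * q, dtype=bool)
        mask[r * q : (r + 1) * q] = False
        X = np.ascontiguousarray(X_all[:, mask])
        y = aln.data[:, r].astype(np.int64)
        trace: list[float] = []

        def fun_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
            h = theta[:q]
            W = theta[q:].reshape(n_feat, q)
            Z = X @ W + h
            lse = logsumexp(Z, axis=1)
            ll = Z[np.arange(M), y] - lse
            f = -ll.mean() + lambda_h * (h**2).sum() + 0.5 * lambda_J * (W**2).sum()
            P = softmax(Z, axis=1)
            P[np.arange(M), y] -= 1.0
            P /= M
            gh = P.sum(axis=0) + 2.0 * lambda_h * h
            gW = X.T @ P + lambda_J * W
            trace.append(float(f))
            return float(f), np.concatenate([gh, gW.ravel()])

        res = minimize(
            fun_grad,
            np.zeros(q + n_feat * q),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "gtol": grad_tol, "ftol": 1e-12},
        )
        traces.append(trace)
        if not res.success and "ITERATIONS" in str(res.message).upper():
            raise PlmConvergenceError(
                f"site {r}: optimizer did not converge ({res.message})", traces
            )
        W = res.x[q:].reshape(L - 1, q, q)  # [partner j', symbol at j, symbol at r]
        # within one conditional, row components of W and the intercept are
        # interchangeable; collecting the row means into the field gives the
        # gauge-invariant (zero-sum) field of site r directly
        h_zs = res.x[:q] + W.mean(axis=1).sum(axis=0)
        h_hat[r] = h_zs - h_zs.mean()
        others = [j for j in range(L) if j != r]
        for jp, j in enumerate(others):
            J_hat[r, j] = W[jp].T  # -> [symbol at r, symbol at j]
    J_sym = 0.5 * (J_hat + J_hat.transpose(1, 0, 3, 2))
    # zero-sum projection of every coupling block; the fields above already
    # carry each site's full row contribution, so no further transfer happens
    row = J_sym.mean(axis=3)
    col = J_sym.mean(axis=2)
    tot = J_sym.mean(axis=(2, 3))
    Jz = J_sym - row[..., None] - col[:, :, None, :] + tot[..., None, None]
    for i in range(L):
        Jz[i, i] = 0.0
    return PottsModel(
        Jz,
        h_hat,
        gauge="zero-sum",
        meta={"lambda_J": lambda_J, "lambda_h": lambda_h, "M": M},
    )


def frobenius_scores(model: PottsModel, exclude_gap: bool = True) -> ScoreMatrix:
    """Frobenius norms of the coupling blocks, F_ij = ||J_ij||_2.

    The gap state (code 0) is excluded from the norm by default, following
    standard plmDCA practice; the model must be in the zero-sum gauge.
    """
    if model.gauge != "zero-sum":
        raise ValueError("frobenius_scores requires a zero-sum gauge model")
    J = model.J
    if exclude_gap and model.q > 1:
        J = J[:, :, 1:, 1:]
    F = np.sqrt((J**2).sum(axis=(2, 3)))
    np.fill_diagonal(F, 0.0)
    return ScoreMatrix((F + F.T) / 2.0, corrected=False)


def apc(scores: ScoreMatrix) -> ScoreMatrix:
    """Average-product correction: F_ij - (Fbar_i * Fbar_j) / Fbar.

    Row means exclude the diagonal; subtracting the rank-one background
    removes conservation-related bias from the score matrix.
    """
    if scores.corrected:
        raise ValueError("scores are already APC-corrected")
    F = scores.F
    L = scores.L
    if L < 2:
        raise ValueError("APC needs L >= 2")
    row_mean = F.sum(axis=1) / (L - 1)
    total_mean = F.sum() / (L * (L - 1))
    if total_mean == 0:
        warnings.warn("all scores are zero; APC is a no-op", UserWarning)
        return ScoreMatrix(F.copy(), corrected=True)
    corrected = F - np.outer(row_mean, row_mean) / total_mean
    np.fill_diagonal(corrected, 0.0)
    return ScoreMatrix(corrected, corrected=True)


def coupling_scores(
    aln: Alignment, lambda_J: float | None = None, lambda_h: float = 0.01
) -> ScoreMatrix:
    """Convenience pipeline: plm_fit -> Frobenius norms -> APC."""
    return apc(frobenius_scores(plm_fit(aln, lambda_J=lambda_J, lambda_h=lambda_h)))


def scores_to_tsv(path, raw: ScoreMatrix, corrected: ScoreMatrix) -> None:
    """Write per-pair scores (1-based indices, i<j) as TSV."""
    with open(path, "w") as fh:
        fh.write("i\tj\tF\tF_APC\n")
        L = raw.L
        for i in range(L):
            for j in range(i + 1, L):
                fh.write(f"{i + 1}\t{j + 1}\t{raw.F[i, j]:.8g}\t{corrected.F[i, j]:.8g}\n")
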