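"""Integer-encoded multiple sequence alignments and their summary statistics.

An alignment of M protein sequences over L columns is stored as an integer
matrix with values in ``[0, q)``; code 0 is the alignment gap ``-`` and codes
1..20 are the standard amino acids in alphabetical one-letter order.  The gap
is treated as a full 21st symbol everywhere: column statistics, pair
statistics, and Hamming distances all count it like any other character.
No sequence weighting is applied anywhere in this package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

#: Default 21-letter alphabet: gap first, then the 20 amino acids.
AA_ALPHABET = "-ACDEFGHIKLMNPQRSTVWY"

#: Ambiguous / non-standard residue codes that are mapped to the gap state.
AMBIGUOUS_CODES = set("XBZUOJ*")


class AlignmentFormatError(ValueError):
    """Raised when an input file cannot be interpreted as an alignment."""


class AlignmentInputError(ValueError):
    """Raised when alignment content violates the type contract."""


@dataclass
class Alignment:
    """An M x L integer-encoded alignment over a fixed alphabet.

    Parameters
    ----------
    data:
        Integer matrix of shape (M, L) with entries in ``[0, q)``.
    labels:
        Sequence identifiers, one per row.
    alphabet:
        Ordered symbol string; ``alphabet[0]`` is the gap.  Defaults to the
        21-letter amino-acid alphabet.
    """

    data: np.ndarray
    labels: list[str]
    alphabet: str = AA_ALPHABET

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.ndim != 2:
            raise AlignmentInputError("alignment data must be a 2-D matrix")
        if len(self.labels) != self.data.shape[0]:
            raise AlignmentInputError(
                f"{len(self.labels)} labels for {self.data.shape[0]} rows"
            )
        if self.data.size and (self.data.min() < 0 or self.data.max() >= self.q):
            raise AlignmentInputError("alignment codes outside [0, q)")

    @property
    def M(self) -> int:
        return self.data.shape[0]

    @property
    def L(self) -> int:
        return self.data.shape[1]

    @property
    def q(self) -> int:
        return len(self.alphabet)

    def sequences(self) -> list[str]:
        """Decode rows back to strings."""
        lut = np.array(list(self.alphabet))
        return ["".join(lut[row]) for row in self.data]

    def reorder(self, labels: Sequence[str]) -> "Alignment":
        """Return a copy with rows in the order of ``labels``."""
        index = {lab: i for i, lab in enumerate(self.labels)}
        try:
            rows = [index[lab] for lab in labels]
        except KeyError as exc:  # pragma: no cover - defensive
            raise AlignmentInputError(f"unknown label {exc}") from exc
        return Alignment(self.data[rows].copy(), list(labels), self.alphabet)

    @classmethod
    def from_sequences(
        cls,
        seqs: Iterable[str],
        labels: Sequence[str] | None = None,
        alphabet: str = AA_ALPHABET,
    ) -> "Alignment":
        """Encode equal-length uppercase strings into an Alignment."""
        seqs = list(seqs)
        if labels is None:
            labels = [f"s{i + 1}" for i in range(len(seqs))]
        code = {c: i for i, c in enumerate(alphabet)}
        n_ambiguous = 0
        rows = []
        for s in seqs:
            row = np.empty(len(s), dtype=np.int8)
            for k, c in enumerate(s):
                if c in code:
                    row[k] = code[c]
                elif c.upper() in AMBIGUOUS_CODES or c == ".":
                    row[k] = 0
                    n_ambiguous += 1
                else:
                    raise AlignmentFormatError(f"unknown symbol {c!r}")
            rows.append(row)
        lengths = {len(r) for r in rows}
        if len(lengths) > 1:
            raise AlignmentFormatError(
                f"ragged alignment: sequence lengths {sorted(lengths)}"
            )
        if n_ambiguous:
            logger.info("mapped %d ambiguous residue codes to gap", n_ambiguous)
        return cls(np.vstack(rows), list(labels), alphabet)


def read_msa(path: str | Path, format: str = "fasta") -> Alignment:
    """Read an alignment from FASTA or Stockholm.

    Lowercase letters and ``.`` (Pfam insert states, which are not aligned)
    are removed before encoding; ``-`` maps to the gap code and ambiguous
    residue codes (X, B, Z, U, O, ...) map to gap as well.
    """
    from Bio import SeqIO

    if format not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported format {format!r}")
    try:
        records = list(SeqIO.parse(str(path), format))
    except (ValueError, AssertionError) as exc:
        raise AlignmentFormatError(f"cannot parse {path} as {format}: {exc}") from exc
    if not records:
        raise AlignmentInputError(f"no sequences found in {path}")
    labels = [r.id for r in records]
    seqs = [str(r.seq) for r in records]
    lengths = {len(s) for s in seqs}
    if len(lengths) == 1:
        # drop insert columns (any lowercase residue marks the column);
        # this is column-consistent by construction
        n = lengths.pop()
        keep = [k for k in range(n) if not any(s[k].islower() or s[k] == "." for s in seqs)]
        seqs = ["".join(s[k] for k in keep) for s in seqs]
    else:
        # ragged input: strip per-sequence insert states, then re-check
        seqs = ["".join(c for c in s if not (c.islower() or c == ".")) for s in seqs]
    aln = Alignment.from_sequences(seqs, labels)
    if aln.L == 0:
        raise AlignmentInputError(f"alignment in {path} has no match columns")
    return aln


def write_fasta(aln: Alignment, path: str | Path) -> None:
    """Write an alignment as uncompressed aligned FASTA."""
    with open(path, "w") as fh:
        for label, seq in zip(aln.labels, aln.sequences()):
            fh.write(f">{label}\n{seq}\n")


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


@dataclass
class Profile:
    """Per-column symbol frequencies f_i(a), shape (L, q)."""

    freq: np.ndarray

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.ndim != 2:
            raise AlignmentInputError("profile must be (L, q)")
        if np.any(self.freq < 0):
            raise AlignmentInputError("negative frequencies")
        if not np.allclose(self.freq.sum(axis=1), 1.0, atol=1e-12):
            raise AlignmentInputError("profile rows must sum to 1")


@dataclass
class PairFrequencies:
    """Joint pair frequencies f_ij(a, b), stored as a full (L, L, q, q) tensor.

    ``freq[i, j, a, b]`` is the fraction of rows with symbol ``a`` in column
    ``i`` and ``b`` in column ``j``; diagonal blocks hold f_i(a) * delta_ab.
    """

    freq: np.ndarray

    @property
    def L(self) -> int:
        return self.freq.shape[0]

    @property
    def q(self) -> int:
        return self.freq.shape[2]


@dataclass
class CovarianceMatrix:
    """Connected correlations c_ij(a,b) = f_ij(a,b) - f_i(a) f_j(b).

    Stored flattened as a symmetric (L*q) x (L*q) matrix; ``tensor`` exposes
    the (L, q, L, q) view.
    """

    matrix: np.ndarray
    L: int
    q: int

    @property
    def tensor(self) -> np.ndarray:
        return self.matrix.reshape(self.L, self.q, self.L, self.q)


@dataclass
class SpectrumResult:
    """Descending eigenvalues plus the survival function of the spectrum."""

    eigenvalues: np.ndarray

    def __post_init__(self) -> None:
        self.eigenvalues = np.sort(np.asarray(self.eigenvalues, float))[::-1]

    def cumulative(self, lam: float | np.ndarray) -> np.ndarray | float:
        """Fraction of eigenvalues strictly larger than ``lam``."""
        lam = np.asarray(lam, dtype=float)
        # eigenvalues sorted descending; count strictly greater
        asc = self.eigenvalues[::-1]
        n = len(asc)
        counts = n - np.searchsorted(asc, lam, side="right")
        out = counts / n
        return out if out.ndim else float(out)

    def to_table(self) -> np.ndarray:
        """Two-column (lambda, cumulative fraction) table at the eigenvalues."""
        lam = self.eigenvalues
        return np.column_stack([lam, self.cumulative(lam)])

    @classmethod
    def pooled(cls, spectra: Iterable["SpectrumResult"]) -> "SpectrumResult":
        """Unify spectra from several alignments into one distribution."""
        return cls(np.concatenate([s.eigenvalues for s in spectra]))


@dataclass
class DistanceMatrix:
    """Symmetric M x M matrix of normalized Hamming distances in [0, 1]."""

    d: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.ndim != 2 or self.d.shape[0] != self.d.shape[1]:
            raise AlignmentInputError("distance matrix must be square")
        if not np.allclose(self.d, self.d.T, atol=1e-9):
            raise AlignmentInputError("distance matrix must be symmetric")
        if not self.labels:
            self.labels = [f"s{i + 1}" for i in range(self.d.shape[0])]

    @property
    def M(self) -> int:
        return self.d.shape[0]

    def upper(self) -> np.ndarray:
        """Upper-triangle (i<j) entries as a flat vector."""
        iu = np.triu_indices(self.M, k=1)
        return self.d[iu]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join(self.labels) + "\n")
            for row in self.d:
                fh.write("\t".join(f"{x:.10g}" for x in row) + "\n")


def _one_hot(aln: Alignment) -> np.ndarray:
    """(M, L*q) one-hot encoding as float64."""
    M, L, q = aln.M, aln.L, aln.q
    X = np.zeros((M, L * q))
    cols = np.arange(L) * q
    X[np.arange(M)[:, None], cols[None, :] + aln.data] = 1.0
    return X


def compute_profile(aln: Alignment, pseudocount: float = 0.0) -> Profile:
    """Column frequencies f_i(a) with an optional symmetric pseudocount.

    ``freq[i, a] = (count_i(a) + pseudocount) / (M + q * pseudocount)``.
    """
    if pseudocount < 0:
        raise AlignmentInputError("pseudocount must be >= 0")
    counts = np.zeros((aln.L, aln.q))
    for i in range(aln.L):
        counts[i] = np.bincount(aln.data[:, i], minlength=aln.q)
    freq = (counts + pseudocount) / (aln.M + aln.q * pseudocount)
    return Profile(freq)


def compute_pair_frequencies(aln: Alignment) -> PairFrequencies:
    """Joint frequencies f_ij(a, b) for all column pairs, gap included."""
    X = _one_hot(aln)
    flat = (X.T @ X) / aln.M
    return PairFrequencies(flat.reshape(aln.L, aln.q, aln.L, aln.q).transpose(0, 2, 1, 3))


def covariance_matrix(p: Profile, pf: PairFrequencies) -> CovarianceMatrix:
    """c_ij(a,b) = f_ij(a,b) - f_i(a) f_j(b), flattened to (L*q) x (L*q).

    Diagonal blocks are f_i(a) delta_ab - f_i(a) f_i(b), which the full pair
    tensor already provides.
    """
    L, q = pf.L, pf.q
    if p.freq.shape != (L, q):
        raise AlignmentInputError("profile and pair frequencies disagree in shape")
    f = p.freq.reshape(L * q)
    flat = pf.freq.transpose(0, 2, 1, 3).reshape(L * q, L * q)
    c = flat - np.outer(f, f)
    return CovarianceMatrix(c, L, q)


def eigen_spectrum(C: CovarianceMatrix | np.ndarray, atol: float = 1e-8) -> SpectrumResult:
    """Real eigenvalue spectrum of a symmetric covariance matrix."""
    mat = C.matrix if isinstance(C, CovarianceMatrix) else np.asarray(C, float)
    if not np.allclose(mat, mat.T, atol=atol):
        raise AlignmentInputError("covariance matrix is not symmetric")
    vals = np.linalg.eigvalsh((mat + mat.T) / 2.0)
    return SpectrumResult(vals)


def hamming_matrix(aln: Alignment) -> DistanceMatrix:
    """Normalized pairwise Hamming distances; gap counts as a 21st symbol."""
    if aln.M == 1:
        return DistanceMatrix(np.zeros((1, 1)), list(aln.labels))
    d = squareform(pdist(aln.data, metric="hamming"))
    return DistanceMatrix(d, list(aln.labels))


def hamming_count_matrix(aln: Alignment) -> np.ndarray:
    """Integer matrix of differing-column counts (M x M, int32)."""
    d = hamming_matrix(aln).d * aln.L
    return np.rint(d).astype(np.int32)
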