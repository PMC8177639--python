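"""Contact maps, score histograms, PPV curves and null-ensemble z-scores.

Residue pairs are contacts when the minimum distance between their heavy
atoms is at most 8 Angstrom (the standard cutoff in the coevolution
literature).  Trivial short-range pairs are removed with a sequence-
separation filter |i - j| > min_sep (default 4; 24 for the long-range
view).  All reported indices are 0-based in the API and 1-based in TSV
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .plm import ScoreMatrix


@dataclass
class ContactMap:
    """Boolean L x L contact matrix with optional distances and column mask.

    ``column_mask[i]`` is False for alignment columns without a mapped
    structure residue; masked columns are excluded from histograms and
    PPV computations.
    """

    contact: np.ndarray
    distances: np.ndarray | None = None
    cutoff: float = 8.0
    column_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.contact = np.asarray(self.contact, dtype=bool)
        if not np.array_equal(self.contact, self.contact.T):
            raise ValueError("contact map must be symmetric")
        if self.contact.diagonal().any():
            raise ValueError("contact map diagonal must be False")
        if self.column_mask is None:
            self.column_mask = np.ones(self.contact.shape[0], dtype=bool)

    @property
    def L(self) -> int:
        return self.contact.shape[0]


def contacts_from_distances(dist: np.ndarray, cutoff: float = 8.0) -> ContactMap:
    """Threshold a symmetric residue-residue distance matrix (Angstrom)."""
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-6):
        raise ValueError("distance matrix must be symmetric")
    contact = dist <= cutoff
    np.fill_diagonal(contact, False)
    return ContactMap(contact, distances=dist, cutoff=cutoff)


def contacts_from_pdb(
    pdb_path: str | Path,
    chain: str,
    mapping: dict[int, int],
    L: int,
    cutoff: float = 8.0,
) -> ContactMap:
    """Contact map from a PDB chain via minimum heavy-atom distances.

    ``mapping`` sends 0-based alignment columns to PDB residue numbers;
    unmapped columns are masked out.  Hydrogens (and deuteriums) are
    excluded from the distance minimum.
    """
    from Bio.PDB import PDBParser

    structure = PDBParser(QUIET=True).get_structure("s", str(pdb_path))
    model = next(structure.get_models())
    residues = {}
    for res in model[chain]:
        if res.id[0] != " ":
            continue
        coords = np.array(
            [a.coord for a in res if (a.element or "").upper() not in ("H", "D")]
        )
        if len(coords):
            residues[res.id[1]] = coords
    cols = sorted(c for c, r in mapping.items() if r in residues)
    if not cols:
        raise ValueError("no alignment columns map onto resolved residues")
    dist = np.full((L, L), np.inf)
    np.fill_diagonal(dist, 0.0)
    for ai, ci in enumerate(cols):
        xi = residues[mapping[ci]]
        for cj in cols[ai + 1 :]:
            xj = residues[mapping[cj]]
            d = np.sqrt(((xi[:, None, :] - xj[None, :, :]) ** 2).sum(-1)).min()
            dist[ci, cj] = dist[cj, ci] = d
    contact = dist <= cutoff
    np.fill_diagonal(contact, False)
    mask = np.zeros(L, dtype=bool)
    mask[cols] = True
    return ContactMap(contact, distances=dist, cutoff=cutoff, column_mask=mask)


def _eligible_pairs(
    L: int, min_sep: int, column_mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    ii, jj = np.triu_indices(L, k=min_sep + 1)
    if column_mask is not None:
        keep = column_mask[ii] & column_mask[jj]
        ii, jj = ii[keep], jj[keep]
    return ii, jj


def score_histograms(
    scores: ScoreMatrix,
    contact_map: ContactMap | None = None,
    min_sep: int = 4,
    bins: int | Sequence[float] = 50,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Normalized score histograms over pairs with |i - j| > min_sep.

    Returns ``{name: (bin_edges, density)}``; with a contact map the
    pairs are split into "contact" and "noncontact", otherwise a single
    "all" histogram is returned.  Every histogram integrates to one.
    """
    mask = contact_map.column_mask if contact_map is not None else None
    ii, jj = _eligible_pairs(scores.L, min_sep, mask)
    if len(ii) == 0:
        raise ValueError(f"no pairs with |i-j| > {min_sep} at L = {scores.L}")
    values = scores.F[ii, jj]
    edges = np.histogram_bin_edges(values, bins=bins)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if contact_map is None:
        dens, _ = np.histogram(values, bins=edges, density=True)
        out["all"] = (edges, dens)
    else:
        is_contact = contact_map.contact[ii, jj]
        for name, sel in (("contact", is_contact), ("noncontact", ~is_contact)):
            if sel.any():
                dens, _ = np.histogram(values[sel], bins=edges, density=True)
                out[name] = (edges, dens)
    return out


@dataclass
class PPVCurve:
    """Positive predictive value among the top-k ranked pairs, k = 1..K."""

    ppv: np.ndarray
    scores: np.ndarray | None = None
    is_contact: np.ndarray | None = None
    pairs: np.ndarray | None = None  # (K, 2) 0-based (i, j)

    @property
    def ranks(self) -> np.ndarray:
        return np.arange(1, len(self.ppv) + 1)

    def ppv_at_threshold(self, theta: float) -> float:
        """Fraction of true contacts among pairs scoring >= theta."""
        if self.scores is None or self.is_contact is None:
            raise ValueError("threshold view needs per-pair scores")
        sel = self.scores >= theta
        if not sel.any():
            return float("nan")
        return float(self.is_contact[sel].mean())

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("rank\tscore\ti\tj\tis_contact\tppv\n")
            for k in range(len(self.ppv)):
                s = self.scores[k] if self.scores is not None else float("nan")
                i, j = (self.pairs[k] + 1) if self.pairs is not None else (0, 0)
                c = int(self.is_contact[k]) if self.is_contact is not None else -1
                fh.write(f"{k + 1}\t{s:.8g}\t{i}\t{j}\t{c}\t{self.ppv[k]:.8g}\n")


def ppv_curve(scores: ScoreMatrix, cmap: ContactMap, min_sep: int = 4) -> PPVCurve:
    """PPV as a function of rank, scores sorted descending.

    Ties are broken lexicographically by (i, j) so the ranking is
    deterministic.
    """
    if scores.L != cmap.L:
        raise ValueError("scores and contact map disagree in L")
    ii, jj = _eligible_pairs(scores.L, min_sep, cmap.column_mask)
    if len(ii) == 0:
        raise ValueError("no eligible pairs")
    vals = scores.F[ii, jj]
    order = np.lexsort((jj, ii, -vals))
    truth = cmap.contact[ii, jj][order].astype(float)
    ppv = np.cumsum(truth) / np.arange(1, len(truth) + 1)
    return PPVCurve(
        ppv,
        scores=vals[order],
        is_contact=truth.astype(bool),
        pairs=np.column_stack([ii, jj])[order],
    )


def joint_and_average_ppv(
    families: Sequence[tuple[ScoreMatrix, ContactMap]], min_sep: int = 4
) -> tuple[PPVCurve, PPVCurve]:
    """Pooled-ranking ("joint") and per-rank averaged PPV over families.

    The joint curve ranks all pairs of all families together, so the
    largest scores of any family come first.  The averaged curve computes
    each family's own PPV curve and takes the mean at every rank over the
    families that still have pairs at that rank.
    """
    if not families:
        raise ValueError("at least one family required")
    all_scores, all_truth, keys = [], [], []
    curves = []
    for fam_idx, (scores, cmap) in enumerate(families):
        ii, jj = _eligible_pairs(scores.L, min_sep, cmap.column_mask)
        if len(ii) == 0:
            raise ValueError(f"family {fam_idx}: no eligible pairs")
        all_scores.append(scores.F[ii, jj])
        all_truth.append(cmap.contact[ii, jj])
        keys.append(np.column_stack([np.full(len(ii), fam_idx), ii, jj]))
        curves.append(ppv_curve(scores, cmap, min_sep))
    vals = np.concatenate(all_scores)
    truth = np.concatenate(all_truth).astype(float)
    key = np.vstack(keys)
    order = np.lexsort((key[:, 2], key[:, 1], key[:, 0], -vals))
    joint_ppv = np.cumsum(truth[order]) / np.arange(1, len(truth) + 1)
    joint = PPVCurve(joint_ppv, scores=vals[order], is_contact=truth[order].astype(bool))
    K = max(len(c.ppv) for c in curves)
    avg = np.empty(K)
    for k in range(K):
        vals_k = [c.ppv[k] for c in curves if len(c.ppv) > k]
        avg[k] = float(np.mean(vals_k))
    return joint, PPVCurve(avg)


@dataclass
class ZScoreMatrix:
    """Per-pair z-scores of real couplings against a null ensemble."""

    z: np.ndarray
    n_null: int
    null_mean: np.ndarray
    null_sd: np.ndarray
    defined: np.ndarray

    @property
    def L(self) -> int:
        return self.z.shape[0]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("i\tj\tz\tnull_mean\tnull_sd\tdefined\n")
            for i in range(self.L):
                for j in range(i + 1, self.L):
                    fh.write(
                        f"{i + 1}\t{j + 1}\t{self.z[i, j]:.8g}\t"
                        f"{self.null_mean[i, j]:.8g}\t{self.null_sd[i, j]:.8g}\t"
                        f"{int(self.defined[i, j])}\n"
                    )


def zscores(
    real_scores: ScoreMatrix, null_scores: Sequence[ScoreMatrix]
) -> ZScoreMatrix:
    """z_ij = (F_real,ij - mean_null,ij) / sd_null,ij over the null samples.

    The standard deviation is the n-1 sample estimate, individually per
    residue pair.  Pairs whose null SD is below 1e-12 are flagged
    undefined (z set to NaN, never silently zeroed).
    """
    if len(null_scores) < 2:
        raise ValueError("z-scores need at least 2 null samples")
    L = real_scores.L
    stack = np.stack([s.F for s in null_scores])
    if stack.shape[1:] != (L, L):
        raise ValueError("null score matrices disagree in L with real scores")
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    defined = sd >= 1e-12
    np.fill_diagonal(defined, False)
    z = np.full((L, L), np.nan)
    z[defined] = (real_scores.F[defined] - mean[defined]) / sd[defined]
    return ZScoreMatrix(z, len(null_scores), mean, sd, defined)


def hypothetical_ppv(
    real_scores: ScoreMatrix,
    null_scores: ScoreMatrix,
    cmap: ContactMap,
    min_sep: int = 4,
) -> PPVCurve:
    """PPV attainable if phylogenetic/finite-size noise were removed.

    Builds a composite score matrix — real scores on contact pairs,
    null-model scores on non-contacts — and ranks it like any other
    prediction.  When the null scores are stochastically smaller than the
    real contact scores, this curve dominates the real one.
    """
    if not (real_scores.L == null_scores.L == cmap.L):
        raise ValueError("score matrices and contact map disagree in L")
    composite = np.where(cmap.contact, real_scores.F, null_scores.F)
    composite = (composite + composite.T) / 2.0
    np.fill_diagonal(composite, 0.0)
    return ppv_curve(
        ScoreMatrix(composite, corrected=real_scores.corrected), cmap, min_sep
    )


def read_contact_tsv(path, L: int, cutoff: float = 8.0) -> ContactMap:
    """Read a (i, j, distance) TSV with 1-based indices into a ContactMap."""
    dist = np.full((L, L), np.inf)
    np.fill_diagonal(dist, 0.0)
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("i"):
            fh.seek(0)
        for line in fh:
            if not line.strip():
                continue
            i_s, j_s, d_s = line.split("\t")[:3]
            i, j = int(i_s) - 1, int(j_s) - 1
            dist[i, j] = dist[j, i] = float(d_s)
    contact = dist <= cutoff
    np.fill_diagonal(contact, False)
    return ContactMap(contact, distances=dist, cutoff=cutoff)
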