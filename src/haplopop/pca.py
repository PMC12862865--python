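"""Missing-data-aware PCA via a pairwise-complete similarity matrix.

Each SNP column is centred on its mean over non-missing calls; the genetic
similarity of individuals *i* and *k* is the mean product of their centred
genotypes over the SNPs observed in both.  Eigendecomposition of this
matrix gives the principal components.  Because each cell averages over a
different SNP set the matrix can be slightly indefinite; negative
eigenvalues are reported as-is and excluded from the variance-explained
denominator, and no imputation is ever performed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import MISSING, Dataset

__all__ = [
    "SimilarityMatrix",
    "PcaResult",
    "center_genotypes",
    "similarity_matrix",
    "eigen_pca",
    "subset_pca",
    "pca",
]


@dataclass
class SimilarityMatrix:
    """Pairwise-complete genetic similarity with per-cell SNP counts."""

    ids: list[str]
    values: np.ndarray   # (n, n) mean products; NaN where no SNP overlaps
    n_pairs: np.ndarray  # (n, n) count of SNPs observed in both individuals
    min_pairs: int = 100

    @property
    def low_pairs(self) -> np.ndarray:
        """Boolean mask of cells backed by fewer than ``min_pairs`` SNPs."""
        return self.n_pairs < self.min_pairs

    def subset(self, keep_ids) -> "SimilarityMatrix":
        index = {s: i for i, s in enumerate(self.ids)}
        unknown = [s for s in keep_ids if s not in index]
        if unknown:
            raise KeyError(f"unknown sample ids: {unknown}")
        idx = np.array([index[s] for s in keep_ids])
        return SimilarityMatrix(list(keep_ids), self.values[np.ix_(idx, idx)],
                                self.n_pairs[np.ix_(idx, idx)], self.min_pairs)


@dataclass
class PcaResult:
    """Eigendecomposition of a similarity matrix.

    ``coordinates`` holds eigenvector entries (components in columns,
    descending eigenvalue order); ``variance_explained`` is each retained
    component's share of the positive-eigenvalue total.
    """

    ids: list[str]
    coordinates: np.ndarray        # (n, n_components)
    eigenvalues: np.ndarray        # all n, descending
    variance_explained: np.ndarray # (n_components,)
    scaled: bool = False


def center_genotypes(calls: np.ndarray) -> np.ndarray:
    """Subtract each SNP's mean over non-missing calls; missing -> NaN.

    Raises on all-missing SNP columns (they should be filtered upstream).
    """
    calls = np.asarray(calls)
    observed = calls != MISSING
    n = observed.sum(axis=0)
    if np.any(n == 0):
        bad = np.flatnonzero(n == 0)
        raise ValueError(f"all-missing SNP columns (pre-filter them): {bad[:10].tolist()}")
    centred = np.where(observed, calls, 0).astype(float)
    means = centred.sum(axis=0) / n
    centred -= means
    centred[~observed] = np.nan
    return centred


def similarity_matrix(centred: np.ndarray, ids=None, min_pairs: int = 100) -> SimilarityMatrix:
    """Mean product of centred genotypes over jointly observed SNPs.

    Cell ``(i, k)`` averages ``c_i[j] * c_k[j]`` over SNPs *j* observed in
    both individuals; cells with fewer than ``min_pairs`` joint SNPs are
    flagged (not excluded).  The diagonal's pair count equals each
    individual's call count.
    """
    centred = np.asarray(centred, dtype=float)
    if centred.shape[0] < 2:
        raise ValueError("need at least two individuals")
    observed = ~np.isnan(centred)
    filled = np.where(observed, centred, 0.0)
    numer = filled @ filled.T
    n_pairs = observed.astype(np.float64) @ observed.astype(np.float64).T
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(n_pairs > 0, numer / np.maximum(n_pairs, 1), np.nan)
    values = (values + values.T) / 2.0  # exact symmetry
    if ids is None:
        ids = [str(i) for i in range(centred.shape[0])]
    return SimilarityMatrix(list(ids), values, np.rint(n_pairs).astype(np.int64), min_pairs)


def eigen_pca(similarity: SimilarityMatrix, n_components: int = 10,
              scaled: bool = False) -> PcaResult:
    """Eigendecomposition of the similarity matrix, eigenvalues descending.

    Per-component sign is fixed so the largest-magnitude loading is
    positive.  ``scaled=True`` multiplies coordinates by sqrt(eigenvalue)
    (non-positive eigenvalues scale to 0); the default leaves raw
    eigenvector entries.
    """
    values = similarity.values
    if np.isnan(values).any():
        raise ValueError("similarity matrix has empty (no-overlap) cells; "
                         "filter the data or drop the offending individuals")
    if not np.allclose(values, values.T, atol=1e-10):
        raise ValueError("similarity matrix is asymmetric beyond 1e-10")
    n = values.shape[0]
    n_components = min(n_components, n)
    eigval, eigvec = np.linalg.eigh(values)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    for c in range(n):
        lead = np.argmax(np.abs(eigvec[:, c]))
        if eigvec[lead, c] < 0:
            eigvec[:, c] = -eigvec[:, c]
    positive = eigval[eigval > 0].sum()
    variance = np.where(eigval[:n_components] > 0,
                        eigval[:n_components] / positive if positive > 0 else 0.0, 0.0)
    coords = eigvec[:, :n_components].copy()
    if scaled:
        coords *= np.sqrt(np.maximum(eigval[:n_components], 0.0))
    return PcaResult(similarity.ids, coords, eigval, variance, scaled)


def subset_pca(similarity: SimilarityMatrix, keep_ids, n_components: int = 10,
               scaled: bool = False) -> PcaResult:
    """Eigendecomposition of a row/column submatrix of an existing
    similarity matrix (no re-centring from genotypes).

    This mirrors dropping individuals *after* the matrix was built.  To
    instead recompute centring and similarity on the subset, call
    :func:`pca` on the subset dataset — that variant re-centres and will
    generally differ.
    """
    return eigen_pca(similarity.subset(keep_ids), n_components, scaled)


def pca(dataset: Dataset, n_components: int = 10, min_pairs: int = 100,
        scaled: bool = False) -> tuple[PcaResult, SimilarityMatrix]:
    """Centre, build the similarity matrix, and decompose, in one call."""
    centred = center_genotypes(dataset.calls)
    sim = similarity_matrix(centred, ids=dataset.sample_ids, min_pairs=min_pairs)
    return eigen_pca(sim, n_components, scaled), sim
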