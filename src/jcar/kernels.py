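"""Similarity kernels and CAR precision ingredients.

The CAR random effects are specified through an n x n similarity matrix
``S`` (zero diagonal), its row-sum diagonal ``D``, and an autocorrelation
parameter ``gamma``; the implied joint covariance of the effect vector is
``sigma^2 (D - gamma S)^{-1}``.  This module builds the two similarity
matrices used for gene-based testing — the normalized identity-by-state
(IBS) kernel for SNP genotypes and a Gaussian kernel for CpG beta values —
together with the data-driven defaults for the kernel bandwidth and for
``gamma``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: smallest eigenvalue of D - gamma*S accepted as positive definite
PD_TOL = 1e-8
#: a row-sum below this marks a subject with no similarity mass
ROWSUM_TOL = 1e-10


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs additive genotype codes (0/1/2, NaN = missing)."""

    values: np.ndarray
    subject_ids: list[str]
    snp_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D matrix")
        if self.values.shape[0] < 2:
            raise ValueError("need at least 2 subjects")
        if self.values.shape[1] < 1:
            raise ValueError("need at least 1 SNP")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing genotype codes must be 0, 1 or 2")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]


@dataclass
class MethylationMatrix:
    """Subjects x CpG beta values (or visit differences), NaN = missing.

    ``difference`` marks visit-difference mode, where entries live in
    [-1, 1] instead of [0, 1].
    """

    values: np.ndarray
    subject_ids: list[str]
    cpg_ids: list[str]
    difference: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("methylation values must be a 2-D matrix")
        if self.values.shape[0] < 2:
            raise ValueError("need at least 2 subjects")
        if self.values.shape[1] < 1:
            raise ValueError("need at least 1 CpG site")
        lo, hi = (-1.0, 1.0) if self.difference else (0.0, 1.0)
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < lo - 1e-12 or finite.max() > hi + 1e-12):
            raise ValueError(
                f"methylation values outside [{lo}, {hi}] "
                f"({'difference' if self.difference else 'beta'} mode)"
            )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]


@dataclass
class SimilarityPair:
    """Zero-diagonal similarity matrix S, row-sum diagonal D and gamma.

    Invariant: the CAR precision ``D - gamma*S`` is symmetric positive
    definite, so the implied effect covariance exists.
    """

    S: np.ndarray
    D: np.ndarray
    gamma: float
    min_precision_eigenvalue: float = field(default=np.nan)

    def precision(self) -> np.ndarray:
        """The CAR precision matrix D - gamma*S (unit variance scale)."""
        return self.D - self.gamma * self.S

    @property
    def n(self) -> int:
        return self.S.shape[0]


def ibs_similarity(G: GenotypeMatrix) -> np.ndarray:
    """Normalized identity-by-state kernel.

    s_ij = sum_k (2 - |g_ik - g_jk|) / (2K); entries in [0, 1], unit
    diagonal.  Requires a complete matrix: impute missing genotypes first.
    """
    X = G.values
    if np.isnan(X).any():
        raise ValueError(
            "genotype matrix contains missing values; apply impute_mean first"
        )
    K = X.shape[1]
    if K == 0:
        raise ValueError("no SNPs in genotype matrix")
    # |g_i - g_j| summed over loci via pairwise L1 distance
    diff = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
    S = (2.0 * K - diff) / (2.0 * K)
    return (S + S.T) / 2.0


def gaussian_similarity(M: MethylationMatrix, sigma: float) -> np.ndarray:
    """Gaussian kernel s_ij = exp(-||m_i - m_j||^2 / (2 sigma^2))."""
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    X = M.values
    if np.isnan(X).any():
        raise ValueError(
            "methylation matrix contains missing values; apply impute_mean first"
        )
    sq = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=2)
    S = np.exp(-sq / (2.0 * sigma**2))
    return (S + S.T) / 2.0


def default_bandwidth(M: MethylationMatrix) -> float:
    """Kernel bandwidth: pooled sample SD over all entries of the matrix.

    Uses the unbiased (N-1) denominator over the flattened non-missing
    entries of the gene's methylation matrix.
    """
    vals = M.values[np.isfinite(M.values)]
    if vals.size < 2:
        raise ValueError("need at least 2 non-missing methylation values")
    sd = float(np.std(vals, ddof=1))
    if sd <= 0.0:
        raise ValueError(
            "constant methylation matrix: zero bandwidth would degenerate the kernel"
        )
    return sd


def default_gamma(X: np.ndarray, include_diagonal: bool = True) -> float:
    """Autocorrelation default: mean of the marker correlation matrix.

    Computes the column-by-column Pearson correlation matrix of the gene's
    markers (SNPs for gamma_1, CpGs for gamma_2) and averages over all
    entries, including the unit diagonal by default.  Constant columns are
    dropped (their correlation is undefined); with fewer than two
    non-constant columns the fallback is gamma = 0.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D marker matrix")
    keep = np.nanstd(X, axis=0) > 0
    if keep.sum() < 2:
        logger.warning(
            "fewer than 2 non-constant columns; falling back to gamma = 0"
        )
        return 0.0
    C = np.corrcoef(X[:, keep], rowvar=False)
    if include_diagonal:
        return float(C.mean())
    off = C[~np.eye(C.shape[0], dtype=bool)]
    return float(off.mean())


def _admissible_gamma_interval(S: np.ndarray, D: np.ndarray) -> tuple[float, float]:
    """Open interval of gamma for which D - gamma*S is positive definite."""
    d = np.sqrt(np.diag(D))
    W = S / np.outer(d, d)  # similarity normalized by sqrt row sums
    mu = np.linalg.eigvalsh((W + W.T) / 2.0)
    hi = 1.0 / mu.max() if mu.max() > 0 else np.inf
    lo = 1.0 / mu.min() if mu.min() < 0 else -np.inf
    return lo, hi


def build_similarity_pair(S_raw: np.ndarray, gamma: float) -> SimilarityPair:
    """Mask the diagonal, form D from row sums, and validate the precision.

    ``S_raw`` is a raw kernel matrix (symmetric, unit diagonal).  Rejects
    subjects with (near-)zero total similarity and any gamma for which
    D - gamma*S is not positive definite, reporting the admissible range.
    """
    S_raw = np.asarray(S_raw, dtype=float)
    if S_raw.ndim != 2 or S_raw.shape[0] != S_raw.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not np.allclose(S_raw, S_raw.T, atol=1e-10):
        raise ValueError("similarity matrix must be symmetric")
    S = S_raw.copy()
    np.fill_diagonal(S, 0.0)
    rowsums = S.sum(axis=1)
    bad = np.nonzero(rowsums <= ROWSUM_TOL)[0]
    if bad.size:
        raise ValueError(
            f"subjects at rows {bad.tolist()} have (near-)zero similarity row sums; "
            "an isolated subject makes the CAR model improper"
        )
    D = np.diag(rowsums)
    prec = D - gamma * S
    min_eig = float(np.linalg.eigvalsh(prec).min())
    if min_eig <= PD_TOL:
        lo, hi = _admissible_gamma_interval(S, D)
        raise ValueError(
            f"D - gamma*S is not positive definite for gamma={gamma} "
            f"(smallest eigenvalue {min_eig:.3e}); admissible gamma interval "
            f"is ({lo:.6g}, {hi:.6g})"
        )
    return SimilarityPair(S=S, D=D, gamma=float(gamma),
                          min_precision_eigenvalue=min_eig)


def genetic_pair(G: GenotypeMatrix, gamma: float | None = None) -> SimilarityPair:
    """IBS kernel + default (or supplied) gamma, packaged for the test."""
    if gamma is None:
        gamma = default_gamma(G.values)
    return build_similarity_pair(ibs_similarity(G), gamma)


def methylation_pair(
    M: MethylationMatrix,
    gamma: float | None = None,
    sigma: float | None = None,
) -> SimilarityPair:
    """Gaussian kernel + default (or supplied) gamma/bandwidth."""
    if sigma is None:
        sigma = default_bandwidth(M)
    if gamma is None:
        gamma = default_gamma(M.values)
    return build_similarity_pair(gaussian_similarity(M, sigma), gamma)
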