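"""The JCAR linear score test.

The model is the linear mixed model

    y_i = x_i' beta + g_i + m_i + eps_i,    eps ~ N(0, sigma^2 K),

where g and m are CAR random effects with joint covariances
sigma_g^2 (D_1 - gamma_1 S_1)^{-1} and sigma_m^2 (D_2 - gamma_2 S_2)^{-1},
and K is the (kinship-derived) error correlation matrix.  The score test
on the profiled restricted likelihood tests sigma_g^2 = 0 and/or
sigma_m^2 = 0 without estimating any variance component.

With A the (n-r) x n matrix satisfying A K^{-1/2} X = 0 and A A' = I
(r = rank(X)) and y* = A K^{-1/2} y, each layer's score statistic is

    S_l = (df/2) * (y*' A K^{-1/2} P_l^{-1} K^{-1/2} A' y*) / (y*' y*)
          - (1/2) tr(K^{-1/2} P_l^{-1} K^{-1/2}),     P_l = D_l - gamma_l S_l,

with df = n - r, and the joint statistic is S = (S_1 + S_2)/2.  The
p-value is P[y*' B y* > 0] for a fresh null draw of y*, where B subtracts
the observed threshold so that the observed quadratic form sits exactly
at zero; the tail probability over the spectrum of B comes from the
Davies-type inversion in :mod:`jcar.quadform`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .kernels import SimilarityPair
from .quadform import QuadFormSpec, davies_tail

logger = logging.getLogger(__name__)

PD_TOL = 1e-10


@dataclass
class KinshipMatrix:
    """Symmetric positive-definite error-correlation matrix K.

    For family samples this is typically twice the kinship coefficient
    matrix (the additive relationship matrix); for unrelated samples the
    identity.
    """

    values: np.ndarray
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        V = self.values
        if V.ndim != 2 or V.shape[0] != V.shape[1]:
            raise ValueError("kinship matrix must be square")
        if not np.allclose(V, V.T, atol=1e-8):
            raise ValueError("kinship matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @classmethod
    def identity(cls, subject_ids: list[str]) -> "KinshipMatrix":
        n = len(subject_ids)
        return cls(np.eye(n), list(subject_ids))


@dataclass
class CovariateMatrix:
    """n x p covariate matrix including an intercept column."""

    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("covariates must be complete and finite")
        self.rank = int(np.linalg.matrix_rank(self.values))
        if self.values.shape[0] <= self.rank:
            raise ValueError("no residual degrees of freedom (n <= rank(X))")

    @classmethod
    def intercept_only(cls, n: int) -> "CovariateMatrix":
        return cls(np.ones((n, 1)), ["intercept"])


@dataclass
class ResidualBasis:
    """The projection A, the kinship whitener K^{-1/2}, and y* = A K^{-1/2} y."""

    A: np.ndarray
    K_inv_sqrt: np.ndarray
    y_star: np.ndarray

    @property
    def df(self) -> int:
        return self.A.shape[0]


@dataclass
class ScoreTestResult:
    """Score statistics, the spectrum of B and the association p-value."""

    mode: str  # "genetic" | "methylation" | "joint"
    S: float
    p_value: float
    S1: float | None = None
    S2: float | None = None
    spectrum: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)


def inverse_sqrt(Kin: KinshipMatrix, jitter: bool = False) -> np.ndarray:
    """Symmetric inverse square root of K via eigendecomposition."""
    V = Kin.values
    if jitter:
        V = V + 1e-8 * np.eye(V.shape[0])
    w, U = linalg.eigh(V)
    if w.min() <= PD_TOL:
        raise ValueError(
            f"kinship matrix is not positive definite "
            f"(smallest eigenvalue {w.min():.3e}); enable jitter or fix the input"
        )
    return (U / np.sqrt(w)) @ U.T


def residual_basis(
    Kin: KinshipMatrix, X: CovariateMatrix, y: np.ndarray,
    method: str = "svd",
) -> ResidualBasis:
    """Orthonormal basis of the residual space of K^{-1/2} X, and y*.

    The rows of A span the orthogonal complement of the column space of
    K^{-1/2} X, so A K^{-1/2} X = 0 and A A' = I_{n-rank(X)}.  ``method``
    selects the construction ("svd" or "qr"); any valid basis gives the
    same test, which the suite verifies.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = Kin.n
    if X.values.shape[0] != n or y.shape[0] != n:
        raise ValueError("kinship, covariates and phenotype sizes disagree")
    Kihalf = inverse_sqrt(Kin)
    W = Kihalf @ X.values
    s = np.linalg.svd(W, compute_uv=False)
    tol = max(W.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    r = int(np.sum(s > tol))
    if r < X.values.shape[1]:
        logger.warning(
            "covariate matrix is rank deficient (rank %d of %d columns)",
            r, X.values.shape[1],
        )
    if method == "svd":
        U, _, _ = np.linalg.svd(W, full_matrices=True)
        A = U[:, r:].T
    elif method == "qr":
        Q, _, _ = linalg.qr(W, mode="full", pivoting=True)
        A = Q[:, r:].T
    else:
        raise ValueError("method must be 'svd' or 'qr'")
    y_star = A @ (Kihalf @ y)
    return ResidualBasis(A=A, K_inv_sqrt=Kihalf, y_star=y_star)


def _layer_matrix(rb: ResidualBasis, pair: SimilarityPair) -> tuple[np.ndarray, float]:
    """Q_l = A K^{-1/2} (D-gamma*S)^{-1} K^{-1/2} A' and the full trace."""
    R = rb.K_inv_sqrt @ linalg.inv(pair.precision()) @ rb.K_inv_sqrt
    R = (R + R.T) / 2.0
    return rb.A @ R @ rb.A.T, float(np.trace(R))


def score_statistic_layer(
    rb: ResidualBasis, pair: SimilarityPair, df: int | None = None
) -> float:
    """One layer's score statistic S_l."""
    if df is None:
        df = rb.df
    ystar = rb.y_star
    denom = float(ystar @ ystar)
    if denom <= 1e-14:
        raise ValueError(
            "y* is numerically zero (phenotype lies in the covariate span); "
            "the score test is degenerate"
        )
    Q, tr = _layer_matrix(rb, pair)
    return float(df / 2.0 * (ystar @ Q @ ystar) / denom - tr / 2.0)


def jcar_test(
    rb: ResidualBasis,
    genetic: SimilarityPair | None = None,
    methylation: SimilarityPair | None = None,
    accuracy: float = 1e-6,
) -> ScoreTestResult:
    """Run the score test for the layers supplied.

    Joint mode (both layers): S = (S_1 + S_2)/2 and the threshold constant
    is c = (4S + tr_full)/df.  Single-layer modes use the same derivation
    with one layer, giving c = (2 S_l + tr_l)/df.  In either case the
    observed quadratic form y*' B y* is exactly zero, and the p-value is
    the probability that a fresh null draw exceeds the observed statistic.
    """
    if genetic is None and methylation is None:
        raise ValueError("at least one similarity layer is required")
    ystar = rb.y_star
    df = rb.df
    denom = float(ystar @ ystar)
    if denom <= 1e-14:
        raise ValueError("y* is numerically zero; p-value undefined")

    M = np.zeros((df, df))
    tr_full = 0.0
    S1 = S2 = None
    for pair, which in ((genetic, "S1"), (methylation, "S2")):
        if pair is None:
            continue
        Q, tr = _layer_matrix(rb, pair)
        M += Q
        tr_full += tr
        stat = float(df / 2.0 * (ystar @ Q @ ystar) / denom - tr / 2.0)
        if which == "S1":
            S1 = stat
        else:
            S2 = stat

    if genetic is not None and methylation is not None:
        mode = "joint"
        S = (S1 + S2) / 2.0
        c = (4.0 * S + tr_full) / df
    else:
        mode = "genetic" if genetic is not None else "methylation"
        S = S1 if S1 is not None else S2
        c = (2.0 * S + tr_full) / df

    B = M - c * np.eye(df)
    lam = np.linalg.eigvalsh(B)
    amax = np.abs(lam).max(initial=0.0)
    diagnostics: dict = {"threshold_constant": c, "df": df}
    if amax <= 1e-12:
        logger.warning("B is numerically zero; returning p = 1")
        return ScoreTestResult(mode=mode, S=S, p_value=1.0, S1=S1, S2=S2,
                               spectrum=lam, diagnostics=diagnostics)
    lam_used = lam[np.abs(lam) > 1e-10 * amax]
    tail = davies_tail(QuadFormSpec(lam_used, 0.0), accuracy=accuracy)
    diagnostics["tail_method"] = tail.method
    diagnostics["tail_fallback"] = tail.fallback
    return ScoreTestResult(
        mode=mode, S=S, p_value=tail.value, S1=S1, S2=S2,
        spectrum=lam, diagnostics=diagnostics,
    )
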