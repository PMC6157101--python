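"""Tail probabilities of quadratic forms in standard normal variables.

The association p-value is P[Q > q] for Q = sum_i lambda_i z_i^2 with
independent standard normal z_i and a possibly indefinite spectrum
{lambda_i}.  The primary route inverts the characteristic function
numerically (the Davies/Imhof approach):

    P[Q > q] = 1/2 + (1/pi) * int_0^inf sin(theta(u)) / (u * rho(u)) du
    theta(u) = (1/2) * sum_i arctan(lambda_i u) - q u / 2
    rho(u)   = prod_i (1 + lambda_i^2 u^2)^(1/4)

A seeded Monte-Carlo estimator serves as an independent oracle, and a
three-moment noncentral chi-square match is the fallback when the
numerical integration fails to reach the requested accuracy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

logger = logging.getLogger(__name__)

#: relative threshold below which eigenvalues are treated as numerically null
EIG_TRUNC = 1e-10


@dataclass(frozen=True)
class QuadFormSpec:
    """Spectrum and threshold of the quadratic form sum_i lambda_i z_i^2 > q."""

    eigenvalues: np.ndarray
    threshold: float = 0.0

    def __post_init__(self) -> None:
        lam = np.atleast_1d(np.asarray(self.eigenvalues, dtype=float))
        if not np.all(np.isfinite(lam)):
            raise ValueError("eigenvalues must be finite")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        object.__setattr__(self, "eigenvalues", lam)


@dataclass(frozen=True)
class TailProbability:
    """A tail probability plus how it was obtained."""

    value: float
    method: str  # "davies" | "moment_match" | "degenerate"
    fallback: bool = False

    def __float__(self) -> float:
        return self.value


def _truncate(lam: np.ndarray) -> np.ndarray:
    amax = np.abs(lam).max(initial=0.0)
    if amax == 0.0:
        return lam[:0]
    return lam[np.abs(lam) > EIG_TRUNC * amax]


def davies_tail(spec: QuadFormSpec, accuracy: float = 1e-6) -> TailProbability:
    """P[sum lambda_i z_i^2 > q] by characteristic-function inversion.

    Absolute error is targeted at ``accuracy``; the result is clamped to
    [0, 1].  On integration failure the three-moment fallback is used and
    flagged in the result.
    """
    if not 0.0 < accuracy <= 1e-2:
        raise ValueError("accuracy must lie in (0, 1e-2]")
    lam = _truncate(spec.eigenvalues)
    q = float(spec.threshold)
    if lam.size == 0:
        logger.warning("all eigenvalues are (numerically) zero")
        return TailProbability(1.0 if q < 0 else 0.0, "degenerate")

    def integrand(u: float) -> float:
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * q * u
        log_rho = 0.25 * np.sum(np.log1p((lam * u) ** 2))
        return float(np.sin(theta) * np.exp(-log_rho) / u)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", integrate.IntegrationWarning)
            val, err = integrate.quad(
                integrand, 0.0, np.inf, epsabs=accuracy / 10.0,
                epsrel=0.0, limit=1000,
            )
        if not np.isfinite(val) or err > max(accuracy, 1e-8) * 10.0:
            raise RuntimeError(f"integration error estimate too large ({err:.2e})")
    except (integrate.IntegrationWarning, RuntimeError, FloatingPointError) as exc:
        logger.warning("Davies integration failed (%s); using moment matching", exc)
        fb = moment_match_tail(spec)
        return TailProbability(fb.value, "moment_match", fallback=True)
    p = 0.5 + val / np.pi
    return TailProbability(float(np.clip(p, 0.0, 1.0)), "davies")


def mc_tail(spec: QuadFormSpec, n_draws: int, seed: int) -> float:
    """Monte-Carlo oracle: empirical frequency of the tail event."""
    if n_draws < 10_000:
        raise ValueError("n_draws must be at least 10^4")
    lam = spec.eigenvalues
    rng = np.random.default_rng(seed)
    hits = 0
    block = 1_000_000
    for start in range(0, n_draws, block):
        m = min(block, n_draws - start)
        z2 = rng.standard_normal((m, lam.size)) ** 2
        hits += int(np.count_nonzero(z2 @ lam > spec.threshold))
    return hits / n_draws


def _pearson_tail(lam: np.ndarray, q: float) -> float:
    """Three-moment (a + b*chi^2_v) match for an all-positive spectrum."""
    c1, c2, c3 = lam.sum(), np.sum(lam**2), np.sum(lam**3)
    b = c3 / c2
    v = c2**3 / c3**2
    a = c1 - b * v
    return float(stats.chi2.sf((q - a) / b, v))


def moment_match_tail(spec: QuadFormSpec) -> TailProbability:
    """Moment-matching chi-square/gamma approximation to the tail.

    Same-sign spectra use a three-moment shifted chi-square match
    (a + b*chi^2_v).  Indefinite spectra are split by sign, each part
    moment-matched by a gamma, and the tail of their difference obtained
    by one-dimensional integration.  Approximate; used as the fallback
    when the characteristic-function inversion fails.
    """
    lam = _truncate(spec.eigenvalues)
    q = float(spec.threshold)
    if lam.size == 0:
        return TailProbability(1.0 if q < 0 else 0.0, "degenerate")
    pos = lam[lam > 0]
    neg = -lam[lam < 0]
    if neg.size == 0:
        p = 1.0 if q <= 0 else _pearson_tail(pos, q)
    elif pos.size == 0:
        # P[-Q_neg > q] = 1 - P[Q_neg >= -q]
        p = 0.0 if q >= 0 else 1.0 - _pearson_tail(neg, -q)
    else:
        # Satterthwaite gamma for each sign part, then P[X - Y > q]
        kx = pos.sum() ** 2 / (2.0 * np.sum(pos**2))
        tx = 2.0 * np.sum(pos**2) / pos.sum()
        ky = neg.sum() ** 2 / (2.0 * np.sum(neg**2))
        ty = 2.0 * np.sum(neg**2) / neg.sum()

        def integrand(y: float) -> float:
            return stats.gamma.pdf(y, ky, scale=ty) * \
                stats.gamma.sf(y + q, kx, scale=tx)

        p, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
    return TailProbability(float(np.clip(p, 0.0, 1.0)), "moment_match")
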