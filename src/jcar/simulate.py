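"""Synthetic data under the null and the CAR alternative.

Generates family-structured genotypes (founders under Hardy-Weinberg,
offspring by Mendelian gene dropping), logit-normal CpG beta values, and
phenotypes from the generative model

    y = X beta + g + m + eps,
    g ~ N(0, sigma_g^2 (D_1 - gamma_1 S_1)^{-1}),
    m ~ N(0, sigma_m^2 (D_2 - gamma_2 S_2)^{-1}),
    eps ~ N(0, sigma^2 K),

the joint distribution implied by the CAR conditionals (standard Gaussian
Markov random field factorization).  A rejection-rate harness reruns the
full analysis pipeline per replicate for calibration and power studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, special, stats

from . import kernels
from .car_test import CovariateMatrix, KinshipMatrix, jcar_test, residual_basis
from .kernels import GenotypeMatrix, MethylationMatrix
from .kinship import Pedigree, error_covariance, kinship_coefficients


@dataclass
class SimScenario:
    """Generative conditions for one simulated gene/cohort.

    ``family_structure`` is either "unrelated" (n_subjects singletons) or a
    list of children counts for nuclear families (each family = 2 founder
    parents + that many offspring); in the family case n_subjects is
    derived.  MAFs and CpG means default to a fixed draw from the scenario
    seed so a scenario is fully reproducible.
    """

    n_subjects: int = 100
    family_structure: str | list[int] = "unrelated"
    n_snps: int = 10
    mafs: np.ndarray | None = None
    n_cpgs: int = 10
    cpg_means: np.ndarray | None = None
    cpg_sds: np.ndarray | None = None
    sigma_g2: float = 0.0
    sigma_m2: float = 0.0
    sigma2: float = 1.0
    gamma1: float = 0.5
    gamma2: float = 0.5
    beta: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.2, 0.5]))
    methylation_family_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if self.sigma_g2 < 0 or self.sigma_m2 < 0:
            raise ValueError("variance components must be nonnegative")
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0xA11CE]))
        if self.mafs is None:
            self.mafs = rng.uniform(0.05, 0.5, size=self.n_snps)
        self.mafs = np.asarray(self.mafs, dtype=float)
        if np.any(self.mafs <= 0) or np.any(self.mafs > 0.5):
            raise ValueError("MAFs must lie in (0, 0.5]")
        self.n_snps = self.mafs.size
        if self.cpg_means is None:
            self.cpg_means = rng.uniform(0.3, 0.7, size=self.n_cpgs)
        self.cpg_means = np.asarray(self.cpg_means, dtype=float)
        self.n_cpgs = self.cpg_means.size
        if self.cpg_sds is None:
            self.cpg_sds = np.full(self.n_cpgs, 0.1)
        self.cpg_sds = np.asarray(self.cpg_sds, dtype=float)


@dataclass
class SimulatedData:
    """One simulated cohort: pedigree-derived kinship plus all inputs."""

    subject_ids: list[str]
    pedigree: Pedigree | None
    kinship: KinshipMatrix
    genotypes: GenotypeMatrix
    methylation: MethylationMatrix
    covariates: CovariateMatrix
    phenotype: np.ndarray


def simulate_pedigree(sc: SimScenario) -> tuple[Pedigree | None, list[str]]:
    """Subjects of the scenario; None pedigree means everyone is unrelated."""
    if sc.family_structure == "unrelated":
        return None, [f"S{i}" for i in range(sc.n_subjects)]
    ids: list[str] = []
    father: dict[str, str | None] = {}
    mother: dict[str, str | None] = {}
    for f, n_children in enumerate(sc.family_structure):
        pa, ma = f"F{f}_P1", f"F{f}_P2"
        for pid in (pa, ma):
            ids.append(pid)
            father[pid] = mother[pid] = None
        for c in range(n_children):
            cid = f"F{f}_C{c}"
            ids.append(cid)
            father[cid], mother[cid] = pa, ma
    return Pedigree(ids=ids, father=father, mother=mother), ids


def scenario_kinship(sc: SimScenario) -> KinshipMatrix:
    ped, ids = simulate_pedigree(sc)
    if ped is None:
        return KinshipMatrix.identity(ids)
    return error_covariance(kinship_coefficients(ped), "relationship")


def simulate_genotypes(sc: SimScenario, rng: np.random.Generator) -> GenotypeMatrix:
    """Founders binomial(2, MAF) under HWE; offspring by gene dropping.

    Unlinked loci: each transmitted allele is an independent Bernoulli
    draw with probability equal to half the parent's allele count.
    """
    ped, ids = simulate_pedigree(sc)
    K = sc.n_snps
    geno: dict[str, np.ndarray] = {}
    order = ids if ped is None else ped.topological_order()
    for iid in order:
        f = None if ped is None else ped.father.get(iid)
        m = None if ped is None else ped.mother.get(iid)
        if f is None and m is None:
            geno[iid] = rng.binomial(2, sc.mafs).astype(float)
        else:
            from_f = rng.binomial(1, geno[f] / 2.0) if f is not None \
                else rng.binomial(1, sc.mafs)
            from_m = rng.binomial(1, geno[m] / 2.0) if m is not None \
                else rng.binomial(1, sc.mafs)
            geno[iid] = (from_f + from_m).astype(float)
    values = np.vstack([geno[i] for i in ids])
    return GenotypeMatrix(values, ids, [f"snp{k}" for k in range(K)])


def _logit_normal_params(mean: float, sd: float) -> tuple[float, float]:
    """Logit-scale (mu, s) whose expit-transformed mean matches ``mean``.

    s comes from the delta method, mu from a 1-D root find with
    Gauss-Hermite quadrature so the beta-scale mean is matched closely
    rather than only to first order.
    """
    s = sd / (mean * (1.0 - mean))
    nodes, weights = np.polynomial.hermite_e.hermegauss(64)
    weights = weights / weights.sum()

    def mean_gap(mu: float) -> float:
        return float(weights @ special.expit(mu + s * nodes)) - mean

    mu0 = special.logit(mean)
    try:
        mu = optimize.brentq(mean_gap, mu0 - 5.0, mu0 + 5.0, xtol=1e-10)
    except ValueError:
        mu = mu0
    return mu, s


def simulate_methylation(sc: SimScenario, rng: np.random.Generator) -> MethylationMatrix:
    """Per-site logit-normal beta values, optional within-family intercept."""
    ped, ids = simulate_pedigree(sc)
    n = len(ids)
    logits = np.empty((n, sc.n_cpgs))
    for l in range(sc.n_cpgs):
        mu, s = _logit_normal_params(sc.cpg_means[l], sc.cpg_sds[l])
        logits[:, l] = mu + s * rng.standard_normal(n)
    if sc.methylation_family_sd > 0 and ped is not None:
        fam_of = {iid: iid.split("_")[0] for iid in ids}
        fams = sorted(set(fam_of.values()))
        eff = dict(zip(fams, sc.methylation_family_sd * rng.standard_normal(len(fams))))
        logits += np.array([eff[fam_of[i]] for i in ids])[:, None]
    values = special.expit(logits)
    return MethylationMatrix(values, ids, [f"cpg{l}" for l in range(sc.n_cpgs)])


def simulate_covariates(sc: SimScenario, rng: np.random.Generator) -> CovariateMatrix:
    """Intercept, a standardized age analogue, and a binary sex column."""
    _, ids = simulate_pedigree(sc)
    n = len(ids)
    age = rng.standard_normal(n)
    sex = rng.binomial(1, 0.5, size=n).astype(float)
    return CovariateMatrix(np.column_stack([np.ones(n), age, sex]),
                           ["intercept", "age", "sex"])


def sample_car_effect(
    pair: kernels.SimilarityPair, sigma2: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw from N(0, sigma2 * (D - gamma*S)^{-1}) via the precision Cholesky."""
    if sigma2 == 0.0:
        return np.zeros(pair.n)
    L = linalg.cholesky(pair.precision(), lower=True)
    z = rng.standard_normal(pair.n)
    return np.sqrt(sigma2) * linalg.solve_triangular(L, z, lower=True, trans="T")


def simulate_phenotype(
    sc: SimScenario,
    G: GenotypeMatrix,
    M: MethylationMatrix,
    Kin: KinshipMatrix,
    X: CovariateMatrix,
    rng: np.random.Generator,
) -> np.ndarray:
    """Assemble y = X beta + g + m + eps under the scenario.

    sigma_g2 = sigma_m2 = 0 yields the exact null.  The generative kernels
    are the analysis kernels (IBS, Gaussian with pooled-SD bandwidth) with
    the scenario's gamma values.
    """
    n = len(G.subject_ids)
    y = X.values @ np.asarray(sc.beta, dtype=float)[: X.values.shape[1]]
    if sc.sigma_g2 > 0:
        pair_g = kernels.build_similarity_pair(
            kernels.ibs_similarity(G), sc.gamma1)
        y = y + sample_car_effect(pair_g, sc.sigma_g2, rng)
    if sc.sigma_m2 > 0:
        pair_m = kernels.build_similarity_pair(
            kernels.gaussian_similarity(M, kernels.default_bandwidth(M)),
            sc.gamma2)
        y = y + sample_car_effect(pair_m, sc.sigma_m2, rng)
    Lk = linalg.cholesky(Kin.values, lower=True)
    y = y + np.sqrt(sc.sigma2) * (Lk @ rng.standard_normal(n))
    return y


def simulate_dataset(sc: SimScenario, seed: int | None = None) -> SimulatedData:
    """One full cohort; bitwise reproducible from (scenario, seed)."""
    rng = np.random.default_rng(sc.seed if seed is None else seed)
    ped, ids = simulate_pedigree(sc)
    kin = scenario_kinship(sc)
    G = simulate_genotypes(sc, rng)
    M = simulate_methylation(sc, rng)
    X = simulate_covariates(sc, rng)
    y = simulate_phenotype(sc, G, M, kin, X, rng)
    return SimulatedData(subject_ids=ids, pedigree=ped, kinship=kin,
                         genotypes=G, methylation=M, covariates=X, phenotype=y)


def analyze_dataset(data: SimulatedData, mode: str = "joint",
                    accuracy: float = 1e-6):
    """The per-gene analysis pipeline on one simulated cohort.

    Kernel parameters (gamma, bandwidth) are re-estimated from the data,
    exactly as the scan does.
    """
    rb = residual_basis(data.kinship, data.covariates, data.phenotype)
    gen = kernels.genetic_pair(data.genotypes) if mode in ("genetic", "joint") else None
    meth = kernels.methylation_pair(data.methylation) \
        if mode in ("methylation", "joint") else None
    return jcar_test(rb, genetic=gen, methylation=meth, accuracy=accuracy)


@dataclass
class RejectionRate:
    rate: float
    ci_low: float
    ci_high: float
    n_reps: int
    p_values: np.ndarray


def rejection_rate(
    sc: SimScenario, n_reps: int, alpha: float, mode: str = "joint"
) -> RejectionRate:
    """Empirical rejection frequency of the full pipeline, with exact CI.

    Per-replicate seeds are spawned deterministically from the scenario
    seed; the Clopper-Pearson interval is reported at 95%.
    """
    child_seeds = np.random.SeedSequence(sc.seed).generate_state(n_reps) % (2**31)
    pvals = np.empty(n_reps)
    for r in range(n_reps):
        data = simulate_dataset(sc, seed=int(child_seeds[r]))
        pvals[r] = analyze_dataset(data, mode=mode).p_value
    k = int(np.sum(pvals < alpha))
    lo = stats.beta.ppf(0.025, k, n_reps - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(0.975, k + 1, n_reps - k) if k < n_reps else 1.0
    return RejectionRate(rate=k / n_reps, ci_low=float(lo), ci_high=float(hi),
                         n_reps=n_reps, p_values=pvals)
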