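"""Readers, writers and preprocessing for the gene-based scan.

Conventions: internal coordinates are 0-based half-open (VCF's 1-based
positions are converted on ingestion; a leading ``chr`` prefix is
stripped); the phenotype table's subject order is canonical and all other
inputs are reordered to match; missing genotypes/methylation values are
NaN until mean imputation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .kernels import GenotypeMatrix, MethylationMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneRegion:
    """A gene interval: 0-based half-open [start, end) on a chromosome."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", _norm_chrom(self.chrom))
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")

    def contains(self, chrom: str, pos: int) -> bool:
        return _norm_chrom(chrom) == self.chrom and self.start <= pos < self.end


def _norm_chrom(c: str) -> str:
    c = str(c)
    return c[3:] if c.lower().startswith("chr") else c


@dataclass
class PhenotypeTable:
    """One row per subject: phenotype value plus covariate columns."""

    subject_ids: list[str]
    phenotype: np.ndarray
    covariates: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.subject_ids)


def read_regions(path: str | Path, flank: int = 0) -> list[GeneRegion]:
    """BED (3+ columns: chrom, start, end, [name, score, strand])."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    regions = []
    for i, row in df.iterrows():
        name = row.iloc[3] if df.shape[1] > 3 and pd.notna(row.iloc[3]) else f"region_{i}"
        strand = row.iloc[5] if df.shape[1] > 5 and pd.notna(row.iloc[5]) else "."
        regions.append(GeneRegion(
            gene_id=str(name), chrom=str(row.iloc[0]),
            start=max(0, int(row.iloc[1]) - flank),
            end=int(row.iloc[2]) + flank, strand=strand,
        ))
    return regions


def read_phenotype(
    path: str | Path, phenotype_col: str, covariate_cols: list[str],
    subject_col: str | None = None,
) -> PhenotypeTable:
    """Phenotype/covariate TSV; rows with any missing value are dropped."""
    df = pd.read_csv(path, sep="\t", dtype={0: str} if subject_col is None else None)
    sub = subject_col if subject_col is not None else df.columns[0]
    cols = [sub, phenotype_col] + list(covariate_cols)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns {missing}")
    sel = df[cols].copy()
    before = len(sel)
    sel = sel.dropna()
    if len(sel) < before:
        logger.info("dropped %d subjects with missing phenotype/covariates",
                    before - len(sel))
    return PhenotypeTable(
        subject_ids=sel[sub].astype(str).tolist(),
        phenotype=sel[phenotype_col].to_numpy(dtype=float),
        covariates=sel[list(covariate_cols)].astype(float).reset_index(drop=True),
    )


def read_genotypes(
    path: str | Path, region: GeneRegion | None = None
) -> GenotypeMatrix | None:
    """Genotypes from VCF (GT field, biallelic rows) or dosage TSV.

    VCF rows with more than one ALT allele are skipped (count logged).
    Returns None (the empty-gene sentinel) when no variant survives the
    region filter.  Additive coding counts alternate alleles; missing
    genotypes become NaN.
    """
    path = Path(path)
    if path.suffix in (".vcf",) or path.name.endswith((".vcf.gz", ".vcf.bgz")):
        return _read_vcf(path, region)
    return _read_dosage_tsv(path, region)


def _read_vcf(path: Path, region: GeneRegion | None) -> GenotypeMatrix | None:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    cols: list[np.ndarray] = []
    snp_ids: list[str] = []
    positions: list[tuple[str, int]] = []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        pos0 = var.POS - 1  # VCF is 1-based
        if region is not None and not region.contains(var.CHROM, pos0):
            continue
        gt = np.array(var.gt_types, dtype=float)  # 0 hom-ref,1 het,2 unknown,3 hom-alt
        dose = np.where(gt == 3, 2.0, gt)
        dose[gt == 2] = np.nan
        cols.append(dose)
        snp_ids.append(var.ID or f"{_norm_chrom(var.CHROM)}:{var.POS}")
        positions.append((_norm_chrom(var.CHROM), pos0))
    vcf.close()
    if n_multi:
        logger.info("skipped %d multiallelic VCF records", n_multi)
    if not cols:
        return None
    G = GenotypeMatrix(np.column_stack(cols), subjects, snp_ids)
    G.positions = positions
    return G


def _read_dosage_tsv(path: Path, region: GeneRegion | None) -> GenotypeMatrix | None:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if region is not None:
        keep = [c for c in df.columns if _id_in_region(c, region)]
        df = df[keep]
    if df.shape[1] == 0:
        return None
    bad = df.apply(lambda s: pd.to_numeric(s, errors="coerce"))
    invalid = bad.isna() & df.notna()
    if invalid.to_numpy().any():
        r, c = np.argwhere(invalid.to_numpy())[0]
        raise ValueError(
            f"malformed dosage at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    return GenotypeMatrix(bad.to_numpy(dtype=float),
                          [str(s) for s in df.index], list(df.columns))


def _id_in_region(marker_id: str, region: GeneRegion) -> bool:
    """Markers named 'chrom:pos' can be filtered positionally."""
    if ":" not in marker_id:
        return True
    chrom, _, pos = marker_id.partition(":")
    try:
        return region.contains(chrom, int(pos))
    except ValueError:
        return True


def read_methylation(
    path: str | Path, sites: list[str] | None = None
) -> MethylationMatrix | None:
    """Methylation beta TSV (subjects x CpGs, header = CpG ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if sites is not None:
        missing = [s for s in sites if s not in df.columns]
        if missing:
            raise ValueError(f"requested CpG sites not in file: {missing}")
        df = df[list(sites)]
    if df.shape[1] == 0:
        return None
    num = df.apply(lambda s: pd.to_numeric(s, errors="coerce"))
    invalid = num.isna() & df.notna()
    if invalid.to_numpy().any():
        r, c = np.argwhere(invalid.to_numpy())[0]
        raise ValueError(
            f"non-numeric methylation value at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    return MethylationMatrix(num.to_numpy(dtype=float),
                             [str(s) for s in df.index], list(df.columns))


def write_genotypes(G: GenotypeMatrix, path: str | Path) -> None:
    pd.DataFrame(G.values, index=G.subject_ids, columns=G.snp_ids).to_csv(
        path, sep="\t")


def write_methylation(M: MethylationMatrix, path: str | Path) -> None:
    pd.DataFrame(M.values, index=M.subject_ids, columns=M.cpg_ids).to_csv(
        path, sep="\t")


def impute_mean(values: np.ndarray) -> np.ndarray:
    """Replace missing entries by their column (variable) mean."""
    X = np.asarray(values, dtype=float).copy()
    all_missing = np.all(np.isnan(X), axis=0)
    if all_missing.any():
        raise ValueError(
            f"columns {np.nonzero(all_missing)[0].tolist()} are entirely missing"
        )
    col_means = np.nanmean(X, axis=0)
    idx = np.nonzero(np.isnan(X))
    X[idx] = col_means[idx[1]]
    return X


def quantile_transform(y: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform: rank r -> Phi^{-1}((r-0.5)/n).

    Ties receive average ranks; output order matches input order.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(y) == 0:
        raise ValueError("constant phenotype cannot be quantile transformed")
    ranks = stats.rankdata(y, method="average")
    return stats.norm.ppf((ranks - 0.5) / n)


def difference_mode(
    earlier: pd.DataFrame, later: pd.DataFrame
) -> pd.DataFrame:
    """Later-minus-earlier differences on the subject intersection.

    Both inputs are indexed by subject id; the result keeps the canonical
    (earlier-visit) order restricted to shared subjects.
    """
    shared = [s for s in earlier.index if s in set(later.index)]
    if len(shared) < 2:
        raise ValueError("fewer than 2 subjects shared between visits")
    dropped = (len(earlier) - len(shared)) + (len(later) - len(shared))
    if dropped:
        logger.info("difference mode dropped %d subject records present "
                    "in only one visit", dropped)
    cols = [c for c in earlier.columns if c in set(later.columns)]
    return later.loc[shared, cols] - earlier.loc[shared, cols]


def group_markers(
    regions: list[GeneRegion],
    snp_positions: dict[str, tuple[str, int]] | None,
    cpg_positions: dict[str, tuple[str, int]] | None,
) -> dict[str, tuple[list[str], list[str]]]:
    """Assign markers to genes by half-open containment [start, end).

    Positions map marker id -> (chromosome, 0-based position).  A marker
    inside several overlapping genes is assigned to each.  Empty
    assignments are data, not errors.
    """
    out: dict[str, tuple[list[str], list[str]]] = {}
    for reg in regions:
        snps = [mid for mid, (c, p) in (snp_positions or {}).items()
                if reg.contains(c, p)]
        cpgs = [mid for mid, (c, p) in (cpg_positions or {}).items()
                if reg.contains(c, p)]
        out[reg.gene_id] = (snps, cpgs)
    return out


RESULT_COLUMNS = ["gene", "chromosome", "n_snps", "n_cpgs",
                  "S1", "S2", "S", "p_value", "flags"]


def write_results(rows: list[dict], path: str | Path) -> None:
    """One TSV row per tested gene, fixed column schema."""
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
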