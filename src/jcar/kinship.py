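"""Theoretical kinship from pedigrees.

Kinship coefficients follow the classical recursion over a topologically
sorted pedigree: founders are unrelated and non-inbred (phi_ii = 1/2,
phi_ij = 0), and for a non-founder j with parents f and m,

    phi_ij = (phi_{i,f} + phi_{i,m}) / 2      (i already processed)
    phi_jj = (1 + phi_{f,m}) / 2.

The mixed-model error covariance sigma^2 K uses either the additive
relationship matrix 2*Phi (unit diagonal for outbred subjects, the
default, so sigma^2 is the residual variance of an outbred singleton) or
the raw kinship matrix Phi.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .car_test import KinshipMatrix

PD_TOL = 1e-10


@dataclass
class Pedigree:
    """Individuals with optional father/mother links (None = founder side)."""

    ids: list[str]
    father: dict[str, str | None]
    mother: dict[str, str | None]

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate individual ids in pedigree")
        known = set(self.ids)
        for parents in (self.father, self.mother):
            for child, par in parents.items():
                if par is not None and par not in known:
                    raise ValueError(
                        f"parent {par!r} of {child!r} is not in the pedigree; "
                        "use None/0 for unknown founders"
                    )

    def topological_order(self) -> list[str]:
        """Ids ordered parents-before-offspring; rejects cycles."""
        order: list[str] = []
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(v: str, path: list[str]) -> None:
            if state.get(v) == 1:
                return
            if state.get(v) == 0:
                cycle = path[path.index(v):] + [v]
                raise ValueError(f"pedigree cycle detected: {' -> '.join(cycle)}")
            state[v] = 0
            for par in (self.father.get(v), self.mother.get(v)):
                if par is not None:
                    visit(par, path + [v])
            state[v] = 1
            order.append(v)

        for v in self.ids:
            visit(v, [])
        return order


def read_pedigree(path: str | Path) -> Pedigree:
    """PED/FAM-style whitespace-delimited file; 0 = unknown parent.

    Columns: family id, individual id, father id, mother id, [sex,
    phenotype...]; extra columns are ignored.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
    if df.shape[1] < 4:
        raise ValueError("pedigree file needs at least 4 columns")
    ids = df.iloc[:, 1].tolist()
    father = {}
    mother = {}
    for _, row in df.iterrows():
        iid, fid, mid = row.iloc[1], row.iloc[2], row.iloc[3]
        father[iid] = None if fid in ("0", "", "NA") else fid
        mother[iid] = None if mid in ("0", "", "NA") else mid
    return Pedigree(ids=ids, father=father, mother=mother)


def kinship_coefficients(ped: Pedigree) -> pd.DataFrame:
    """Full kinship coefficient matrix Phi, indexed by individual id.

    Processing order is internal (topological), so the result is
    independent of record order; inbreeding is handled by the recursion
    itself.
    """
    order = ped.topological_order()
    idx = {v: k for k, v in enumerate(order)}
    n = len(order)
    phi = np.zeros((n, n))
    for j_id in order:
        j = idx[j_id]
        f, m = ped.father.get(j_id), ped.mother.get(j_id)
        fi = idx[f] if f is not None else None
        mi = idx[m] if m is not None else None
        for i in range(j):
            pf = phi[i, fi] if fi is not None else 0.0
            pm = phi[i, mi] if mi is not None else 0.0
            phi[i, j] = phi[j, i] = 0.5 * (pf + pm)
        pfm = phi[fi, mi] if (fi is not None and mi is not None) else 0.0
        phi[j, j] = 0.5 * (1.0 + pfm)
    out = pd.DataFrame(phi, index=order, columns=order)
    return out.loc[ped.ids, ped.ids]


def error_covariance(
    phi: pd.DataFrame | np.ndarray,
    scale_mode: str = "relationship",
    subject_ids: list[str] | None = None,
) -> KinshipMatrix:
    """Error-correlation matrix for the mixed model from kinship Phi.

    ``relationship`` returns 2*Phi (additive relationship, the default);
    ``kinship`` returns Phi unchanged.  Positive definiteness is enforced.
    """
    if scale_mode not in ("relationship", "kinship"):
        raise ValueError("scale_mode must be 'relationship' or 'kinship'")
    if isinstance(phi, pd.DataFrame):
        ids = phi.index.tolist()
        V = phi.to_numpy(dtype=float)
    else:
        V = np.asarray(phi, dtype=float)
        ids = subject_ids if subject_ids is not None else [str(i) for i in range(V.shape[0])]
    if scale_mode == "relationship":
        V = 2.0 * V
    w = np.linalg.eigvalsh((V + V.T) / 2.0)
    if w.min() <= PD_TOL:
        raise ValueError(
            f"error covariance is not positive definite "
            f"(smallest eigenvalue {w.min():.3e}); consider the jitter flag"
        )
    return KinshipMatrix(values=V, subject_ids=ids)


def read_kinship(path: str | Path) -> KinshipMatrix:
    """Kinship/relationship matrix from TSV with id header row and column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError("kinship TSV row and column ids must match")
    return KinshipMatrix(values=df.to_numpy(dtype=float),
                         subject_ids=[str(s) for s in df.index])


def write_kinship(kin: KinshipMatrix, path: str | Path) -> None:
    pd.DataFrame(kin.values, index=kin.subject_ids,
                 columns=kin.subject_ids).to_csv(path, sep="\t")
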