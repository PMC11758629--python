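"""Pedigree animal model: numerator relationship matrix, Henderson's mixed
model equations, adjusted phenotypes and the marker correlation filter.

The adjustment model is  y = mu + Sex + beta(Sex) * IBW + a + e  with
a ~ N(0, A sigma_a^2) over the full pedigree (A the numerator relationship
matrix from the tabular method).  The adjusted phenotype of individual j is
y*_j = a_hat_j + e_hat_j, i.e. the phenotype with the fixed-effect fit
removed; suggestive GWAS loci are then screened by the Pearson correlation
of dosage with y*, keeping |r| > 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotypes import DosageMatrix
from .gwas import MixedModelSpec, VarianceComponents, reml_fit
from .relatedness import Grm

__all__ = [
    "Pedigree",
    "AMatrix",
    "BlupResult",
    "pedigree_a_matrix",
    "animal_model_blup",
    "adjust_phenotypes",
    "correlate_dosage",
    "read_pedigree_tsv",
]

_UNKNOWN = {None, "", "0", 0, np.nan}


@dataclass
class Pedigree:
    """(id, sire, dam) records, reordered parents-first at construction.

    Unknown parents are encoded as None ("0" or empty in files).  A cycle
    (an individual among its own ancestors) raises ``ValueError`` naming it.
    """

    records: pd.DataFrame  # columns id, sire, dam; topologically ordered

    def __init__(self, records: pd.DataFrame):
        df = records[["id", "sire", "dam"]].copy()
        for c in df.columns:
            df[c] = df[c].map(lambda v: None if v in _UNKNOWN or (isinstance(v, float) and np.isnan(v)) else str(v))
        if df["id"].isna().any() or df["id"].duplicated().any():
            raise ValueError("pedigree ids must be unique and non-null")
        known = set(df["id"])
        parents = {r.id: tuple(p for p in (r.sire, r.dam) if p is not None) for r in df.itertuples()}
        for pid, ps in parents.items():
            for p in ps:
                if p not in known:
                    raise ValueError(f"parent {p} of {pid} missing from pedigree")
        order: list[str] = []
        state: dict[str, int] = {}

        def visit(node: str, stack: list[str]) -> None:
            st = state.get(node, 0)
            if st == 1:
                raise ValueError(f"pedigree cycle detected at individual {node}")
            if st == 2:
                return
            state[node] = 1
            stack.append(node)
            for p in parents[node]:
                visit(p, stack)
            stack.pop()
            state[node] = 2
            order.append(node)

        for pid in df["id"]:
            visit(pid, [])
        df = df.set_index("id").loc[order].reset_index()
        self.records = df

    @property
    def ids(self) -> list[str]:
        return list(self.records["id"])

    def parent_indices(self) -> list[tuple[int, int]]:
        """(sire_idx, dam_idx) per individual in topological order; -1 unknown."""
        pos = {v: i for i, v in enumerate(self.ids)}
        out = []
        for r in self.records.itertuples():
            out.append(
                (pos[r.sire] if r.sire is not None else -1, pos[r.dam] if r.dam is not None else -1)
            )
        return out


@dataclass
class AMatrix:
    ids: list[str]
    matrix: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)


def read_pedigree_tsv(path) -> Pedigree:
    df = pd.read_csv(path, sep="\t", dtype=str).rename(columns=str.lower)
    return Pedigree(df)


def pedigree_a_matrix(ped: Pedigree) -> AMatrix:
    """Numerator relationship matrix by the tabular method.

    a_ii = 1 + 0.5 * a(sire, dam); a_ij = 0.5 * (a_j,sire(i) + a_j,dam(i))
    for earlier j, with unknown parents contributing zero.
    """
    n = len(ped.ids)
    A = np.zeros((n, n))
    for i, (s, d) in enumerate(ped.parent_indices()):
        row = np.zeros(i)
        if s >= 0:
            row += A[s, :i]
        if d >= 0:
            row += A[d, :i]
        A[i, :i] = A[:i, i] = 0.5 * row
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return AMatrix(ids=ped.ids, matrix=A)


@dataclass
class BlupResult:
    b_hat: pd.Series  # fixed-effect solutions by design column
    a_hat: pd.Series  # breeding values for every pedigree member
    e_hat: pd.Series  # residuals for phenotyped individuals
    fitted_fixed: pd.Series  # X b_hat for phenotyped individuals
    varcomp: VarianceComponents
    design_columns: list[str]


def _eq2_design(ph: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Fixed effects of the adjustment model: intercept, sex, IBW within sex."""
    cols = [np.ones(len(ph))]
    names = ["intercept"]
    sex = ph["sex"].astype(str)
    sex_d = pd.get_dummies(sex, prefix="sex", drop_first=True)
    for c in sex_d.columns:
        cols.append(sex_d[c].to_numpy(float))
        names.append(c)
    ibw = ph["ibw"].to_numpy(float)
    for lvl in sorted(sex.unique()):
        cols.append(ibw * (sex == lvl).to_numpy(float))
        names.append(f"ibw:sex_{lvl}")
    return np.column_stack(cols), names


def animal_model_blup(
    pheno: pd.DataFrame,
    ped: Pedigree,
    varcomp: VarianceComponents | None = None,
    trait: str = "hbw",
) -> BlupResult:
    """Solve Henderson's mixed model equations for the pedigree animal model.

    ``pheno`` is indexed by id with columns sex, ibw and the trait; every
    phenotyped id must appear in the pedigree.  Variance components are
    estimated by REML on the observed submatrix of A unless supplied.
    Individuals without a phenotype still receive a breeding value.
    """
    amat = pedigree_a_matrix(ped)
    pos = {v: i for i, v in enumerate(amat.ids)}
    obs_ids = [i for i in pheno.index.astype(str) if not pd.isna(pheno.loc[i, trait])]
    missing = [i for i in obs_ids if i not in pos]
    if missing:
        raise ValueError(f"phenotyped ids absent from pedigree: {missing[:5]}")
    ph = pheno.loc[obs_ids]
    y = ph[trait].to_numpy(float)
    X, names = _eq2_design(ph)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"singular fixed-effect design; check columns {names}")
    n_obs, q = X.shape
    n_ped = len(amat.ids)
    obs_idx = np.array([pos[i] for i in obs_ids])
    A_obs = amat.matrix[np.ix_(obs_idx, obs_idx)]

    if varcomp is None:
        spec = MixedModelSpec(
            y=y, X=X, grm=Grm(obs_ids, A_obs, float("nan")), sample_ids=list(obs_ids), column_names=names
        )
        varcomp = reml_fit(spec)

    Z = np.zeros((n_obs, n_ped))
    Z[np.arange(n_obs), obs_idx] = 1.0
    if varcomp.sigma_a2 <= 1e-10 * max(varcomp.sigma_e2, 1.0):
        # lambda -> infinity: breeding values shrink to zero, fixed by OLS
        b = np.linalg.lstsq(X, y, rcond=None)[0]
        a = np.zeros(n_ped)
    else:
        lam = varcomp.sigma_e2 / varcomp.sigma_a2
        Ainv = np.linalg.inv(amat.matrix)
        top = np.hstack([X.T @ X, X.T @ Z])
        bot = np.hstack([Z.T @ X, Z.T @ Z + Ainv * lam])
        lhs = np.vstack([top, bot])
        rhs = np.concatenate([X.T @ y, Z.T @ y])
        sol = np.linalg.solve(lhs, rhs)
        b, a = sol[:q], sol[q:]
    fitted = X @ b
    e = y - fitted - a[obs_idx]
    return BlupResult(
        b_hat=pd.Series(b, index=names),
        a_hat=pd.Series(a, index=amat.ids),
        e_hat=pd.Series(e, index=obs_ids),
        fitted_fixed=pd.Series(fitted, index=obs_ids),
        varcomp=varcomp,
        design_columns=names,
    )


def adjust_phenotypes(blup: BlupResult) -> pd.Series:
    """Adjusted phenotype y* = a_hat + e_hat for every phenotyped individual."""
    ids = blup.e_hat.index
    return (blup.a_hat.loc[ids] + blup.e_hat).rename("y_star")


def correlate_dosage(
    matrix: DosageMatrix,
    adjusted: pd.Series,
    loci: list[str] | None = None,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Pearson correlation of each locus's dosage with adjusted phenotypes.

    Uses pairwise-complete observations; a locus passes iff |r| > threshold.
    Loci with constant dosage or fewer than 3 paired observations are flagged
    degenerate.
    """
    locus_ids = loci if loci is not None else matrix.locus_ids
    common = [s for s in matrix.samples if s in adjusted.index]
    ys = adjusted.loc[common].to_numpy(float)
    rows = []
    for locus_id in locus_ids:
        s = matrix.dosage.loc[locus_id, common].to_numpy(float)
        ok = ~np.isnan(s) & ~np.isnan(ys)
        rec = {"locus_id": locus_id, "n": int(ok.sum()), "r": np.nan, "p_value": np.nan,
               "passes": False, "degenerate": True}
        if ok.sum() >= 3 and np.var(s[ok]) > 0 and np.var(ys[ok]) > 0:
            r, p = sps.pearsonr(s[ok], ys[ok])
            rec.update(r=float(r), p_value=float(p), passes=bool(abs(r) > threshold), degenerate=False)
        rows.append(rec)
    cols = ["locus_id", "n", "r", "p_value", "passes", "degenerate"]
    return pd.DataFrame(rows, columns=cols).set_index("locus_id")
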