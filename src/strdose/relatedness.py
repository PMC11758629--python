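"""Genomic relationship matrix (GRM) from STR dosages, and its principal
components.

The VanRaden-style GRM generalised to multiallelic signed dosages: missing
dosages are imputed to the locus mean, each locus is mean-centred, and
G = W W' / s where s is the sum over loci of the dosage variance among
observed calls (population variance, divisor n).  In the biallelic 0/1/2
case s reduces to VanRaden's 2*sum(p(1-p)), and E[diag(G)] is ~1 for an
unrelated HWE sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import DosageMatrix

__all__ = ["Grm", "PcCovariates", "vanraden_grm", "grm_pca", "write_grm_tsv", "read_grm_tsv", "write_pcs_tsv", "read_pcs_tsv"]


@dataclass
class Grm:
    sample_ids: list[str]
    matrix: np.ndarray  # n x n, symmetric, numerically PSD
    scale_constant: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class PcCovariates:
    sample_ids: list[str]
    components: np.ndarray  # n x k score matrix
    explained_variance: np.ndarray  # fractions, length k

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.components.shape[1])]
        return pd.DataFrame(self.components, index=self.sample_ids, columns=cols)


def vanraden_grm(matrix: DosageMatrix) -> Grm:
    """Build the genomic relationship matrix from a GRM-filtered dosage matrix."""
    D = matrix.dosage.to_numpy(dtype=float)  # loci x samples
    if D.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    mean = np.nanmean(D, axis=1, keepdims=True)
    # population variance over observed calls, per locus
    var = np.nanmean((D - mean) ** 2, axis=1)
    s = float(var.sum())
    if s <= 0:
        raise ValueError("all loci monomorphic; GRM scale is zero")
    W = np.where(np.isnan(D), 0.0, D - mean)  # imputed entries contribute 0
    G = W.T @ W / s
    G = (G + G.T) / 2.0
    return Grm(sample_ids=matrix.samples, matrix=G, scale_constant=s)


def grm_pca(g: Grm, k: int = 5) -> PcCovariates:
    """Top-k principal-component scores of a GRM.

    Scores are eigenvectors scaled by sqrt(eigenvalue); each component's sign
    is fixed so its largest-magnitude loading is positive.  Explained-variance
    fractions are over the positive part of the spectrum.
    """
    n = g.matrix.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    vals, vecs = np.linalg.eigh(g.matrix)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if vals.min() < -1e-8 * max(vals.max(), 1.0):
        raise ValueError("GRM is not numerically PSD")
    pos = np.clip(vals, 0.0, None)
    top_vals, top_vecs = pos[:k], vecs[:, :k]
    for j in range(k):
        i = np.argmax(np.abs(top_vecs[:, j]))
        if top_vecs[i, j] < 0:
            top_vecs[:, j] = -top_vecs[:, j]
    scores = top_vecs * np.sqrt(top_vals)
    total = pos.sum()
    frac = top_vals / total if total > 0 else np.zeros(k)
    return PcCovariates(sample_ids=g.sample_ids, components=scores, explained_variance=frac)


def write_grm_tsv(g: Grm, path: str | Path) -> None:
    g.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def read_grm_tsv(path: str | Path) -> Grm:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    m = df.to_numpy(dtype=float)
    # reconstruct the scale constant is impossible from the file; store NaN
    return Grm(sample_ids=list(df.index.astype(str)), matrix=(m + m.T) / 2.0, scale_constant=float("nan"))


def write_pcs_tsv(p: PcCovariates, path: str | Path) -> None:
    p.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def read_pcs_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")
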