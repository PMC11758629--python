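"""Expression-side integration: FPKM normalisation, two-group differential
expression by t-test, and assignment of STR loci to nearby genes."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "fpkm_normalize",
    "de_ttest",
    "annotate_str_to_genes",
    "read_counts_tsv",
    "read_gene_annotation",
]

DE_ALPHA = 0.05


def fpkm_normalize(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """FPKM_gs = counts_gs * 1e9 / (length_g * library_size_s).

    ``counts`` is genes x samples; ``gene_lengths`` is in bp, indexed like
    the counts.  A sample with zero total counts is an error.
    """
    lengths = gene_lengths.loc[counts.index].to_numpy(float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    lib = counts.sum(axis=0).to_numpy(float)
    if (lib <= 0).any():
        bad = list(counts.columns[lib <= 0])
        raise ValueError(f"zero library size for sample(s): {bad}")
    vals = counts.to_numpy(float) * 1e9 / (lengths[:, None] * lib[None, :])
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


def de_ttest(
    fpkm: pd.DataFrame,
    groups: pd.Series,
    variant: str = "student",
    alpha: float = DE_ALPHA,
    log_transform: bool = False,
) -> pd.DataFrame:
    """Per-gene two-sided two-sample t-test between the two group labels.

    ``groups`` maps sample id -> label (e.g. HBW/LBW); Student's pooled test
    is the default, Welch available via ``variant="welch"``.  Values may be
    log2(x+1)-transformed first.  Genes with zero variance in both groups are
    flagged degenerate (p = 1 when the means are also equal).
    """
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    g1 = [s for s in fpkm.columns if groups.get(s) == labels[0]]
    g2 = [s for s in fpkm.columns if groups.get(s) == labels[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 samples")
    M = fpkm.to_numpy(float)
    if log_transform:
        M = np.log2(M + 1.0)
    i1 = [fpkm.columns.get_loc(s) for s in g1]
    i2 = [fpkm.columns.get_loc(s) for s in g2]
    A, B = M[:, i1], M[:, i2]
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sps.ttest_ind(A, B, axis=1, equal_var=(variant == "student"))
    zero_var = (A.var(axis=1) == 0) & (B.var(axis=1) == 0)
    equal_means = np.isclose(A.mean(axis=1), B.mean(axis=1))
    t = np.where(zero_var & equal_means, 0.0, t)
    p = np.where(zero_var & equal_means, 1.0, p)
    out = pd.DataFrame(
        {
            f"mean_{labels[0].lower()}": A.mean(axis=1),
            f"mean_{labels[1].lower()}": B.mean(axis=1),
            "t_statistic": t,
            "p_value": p,
            "degenerate": zero_var,
        },
        index=fpkm.index,
    )
    out["significant"] = out["p_value"] < alpha
    return out


def annotate_str_to_genes(
    loci: pd.DataFrame,
    genes: pd.DataFrame,
    max_distance_bp: int = 25_000,
) -> pd.DataFrame:
    """Assign each STR locus to overlapping or nearby genes.

    ``loci`` needs columns locus_id, scaffold, start, end (1-based inclusive;
    a ``pos`` column is accepted for point loci); ``genes`` needs gene_id,
    scaffold, start, end and optionally strand.  A locus overlapping a gene
    span is ``inside`` that gene; otherwise every gene whose span lies within
    ``max_distance_bp`` is reported as ``upstream``/``downstream`` relative
    to gene orientation, with the gap distance in bp.  Loci with no gene in
    range yield no rows.
    """
    if max_distance_bp < 0:
        raise ValueError("max_distance_bp must be >= 0")
    loc = loci.copy()
    if "start" not in loc.columns:
        loc["start"] = loc["pos"]
        loc["end"] = loc["pos"]
    rows = []
    for scaffold, lg in loc.groupby("scaffold"):
        gg = genes[genes["scaffold"] == scaffold]
        if gg.empty:
            continue
        for l in lg.itertuples():
            hits = gg[(gg["start"] <= l.end + max_distance_bp) & (gg["end"] >= l.start - max_distance_bp)]
            inside = hits[(hits["start"] <= l.end) & (hits["end"] >= l.start)]
            if len(inside):
                hits = inside  # a contained locus reports only its host gene(s)
            for g in hits.itertuples():
                if g.start <= l.end and g.end >= l.start:
                    relation, dist = "inside", 0
                else:
                    strand = getattr(g, "strand", "+") or "+"
                    before_gene = l.end < g.start
                    dist = g.start - l.end if before_gene else l.start - g.end
                    if strand == "+":
                        relation = "upstream" if before_gene else "downstream"
                    else:
                        relation = "downstream" if before_gene else "upstream"
                rows.append(
                    {
                        "locus_id": l.locus_id,
                        "gene_id": g.gene_id,
                        "relation": relation,
                        "distance_bp": int(dist),
                    }
                )
    return pd.DataFrame(rows, columns=["locus_id", "gene_id", "relation", "distance_bp"])


def read_counts_tsv(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    """Counts TSV with columns gene, length, then one column per sample."""
    df = pd.read_csv(path, sep="\t", index_col="gene")
    lengths = df.pop("length")
    return df, lengths


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Gene spans from GFF3 (``gene`` features, ID= attribute) or BED6."""
    path = str(path)
    if path.endswith((".bed", ".bed6")):
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["scaffold", "start0", "end", "gene_id", "score", "strand"],
            dtype={"scaffold": str},
        )
        return pd.DataFrame(
            {
                "gene_id": df["gene_id"],
                "scaffold": df["scaffold"],
                "start": df["start0"] + 1,
                "end": df["end"],
                "strand": df["strand"].fillna("+"),
            }
        )
    import gffutils

    db = gffutils.create_db(path, ":memory:", merge_strategy="create_unique", keep_order=True)
    rows = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        rows.append(
            {"gene_id": gene_id, "scaffold": feat.seqid, "start": feat.start, "end": feat.end,
             "strand": feat.strand if feat.strand in "+-" else "+"}
        )
    return pd.DataFrame(rows, columns=["gene_id", "scaffold", "start", "end", "strand"])
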