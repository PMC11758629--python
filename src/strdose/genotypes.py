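"""STR genotype handling: VCF parsing, call/locus QC and dosage coding.

An STR allele is summarised by its signed base-pair length difference from
the reference allele; dividing by the motif period gives the allele's
*relative copy number*, and the per-individual *dosage* at a locus is the sum
of its two alleles' relative copy numbers (0 for a homozygous-reference
call).  Calls are accepted when the genotype posterior is >= 0.90 and at most
15% of reads show a flanking indel or a stutter artifact; rejected calls
become missing.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from scipy import stats as sps

from .scan import StrCatalog

__all__ = [
    "StrCall",
    "CallSet",
    "DosageMatrix",
    "HweResult",
    "read_str_vcf",
    "filter_calls",
    "dosage_matrix",
    "filter_loci",
    "allele_frequencies",
    "genotype_counts",
    "pic",
    "polymorphism_class",
    "hwe_test",
    "locus_qc",
    "write_dosage_tsv",
    "read_dosage_tsv",
]

CALL_COLUMNS = ["locus_id", "sample_id", "bp1", "bp2", "posterior", "flank_frac", "stutter_frac"]


@dataclass(frozen=True)
class StrCall:
    """A single sample x locus STR genotype call.

    ``allele_bp_diffs`` holds the two alleles' signed bp differences from the
    reference allele, or ``None`` for a missing call.
    """

    sample_id: str
    locus_id: str
    allele_bp_diffs: tuple[float, float] | None
    posterior: float
    flank_indel_frac: float
    stutter_frac: float

    def __post_init__(self) -> None:
        for v, name in (
            (self.posterior, "posterior"),
            (self.flank_indel_frac, "flank_indel_frac"),
            (self.stutter_frac, "stutter_frac"),
        ):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass
class CallSet:
    """Observed calls (one row per non-missing sample x locus) plus metadata.

    ``calls`` columns: locus_id, sample_id, bp1, bp2, posterior, flank_frac,
    stutter_frac.  ``loci`` columns: locus_id, scaffold, pos, period.
    """

    calls: pd.DataFrame
    loci: pd.DataFrame
    samples: list[str]


@dataclass
class DosageMatrix:
    """Loci x samples relative-copy-number dosages; NaN marks missing.

    When built from a :class:`CallSet` the two per-allele relative copy
    numbers are retained (``allele1``/``allele2``) so allele frequencies stay
    computable; matrices read back from TSV carry only the dosage.
    ``nonintegral`` flags calls whose bp difference is not a multiple of the
    period (partial-unit indels); they are kept as rational dosages.
    """

    loci: pd.DataFrame  # index locus_id; columns scaffold, pos, period
    dosage: pd.DataFrame  # index locus_id, columns sample ids
    allele1: pd.DataFrame | None = None
    allele2: pd.DataFrame | None = None
    nonintegral: pd.DataFrame | None = None

    @property
    def samples(self) -> list[str]:
        return list(self.dosage.columns)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.dosage.index)

    def presence_rate(self) -> pd.Series:
        return self.dosage.notna().mean(axis=1)

    def subset_loci(self, locus_ids) -> "DosageMatrix":
        return DosageMatrix(
            loci=self.loci.loc[locus_ids],
            dosage=self.dosage.loc[locus_ids],
            allele1=None if self.allele1 is None else self.allele1.loc[locus_ids],
            allele2=None if self.allele2 is None else self.allele2.loc[locus_ids],
            nonintegral=None if self.nonintegral is None else self.nonintegral.loc[locus_ids],
        )


def read_str_vcf(path: str | Path, catalog: StrCatalog | None = None) -> CallSet:
    """Read a HipSTR-dialect STR VCF into a :class:`CallSet`.

    Expects FORMAT fields GB (bp-difference genotype "a|b"), Q (posterior),
    DP (depth), DFLANKINDEL and DSTUTTER (artifact read counts); the locus
    period comes from INFO/PERIOD or, failing that, from ``catalog``.
    Loci absent from a supplied catalog are skipped with a warning.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    known = None
    if catalog is not None:
        known = {(l.scaffold, l.start): l.period for l in catalog.loci}
    rows: list[tuple] = []
    loci_rows: list[tuple] = []
    for i, rec in enumerate(vf):
        try:
            locus_id = f"{rec.chrom}:{rec.pos}"
            period = rec.info.get("PERIOD")
            if known is not None:
                cat_period = known.get((rec.chrom, rec.pos))
                if cat_period is None:
                    warnings.warn(f"locus {locus_id} absent from catalog; skipped")
                    continue
                period = period if period is not None else cat_period
            if period is None:
                raise ValueError("no PERIOD in INFO and no catalog supplied")
            loci_rows.append((locus_id, rec.chrom, rec.pos, int(period)))
            for sample in samples:
                sd = rec.samples[sample]
                gt = sd.get("GT")
                gb = sd.get("GB")
                if gb is None or gt is None or gt[0] is None:
                    continue
                bp1, bp2 = (float(x) for x in str(gb).split("|"))
                q = float(sd.get("Q", 1.0))
                dp = sd.get("DP") or 0
                flank = (sd.get("DFLANKINDEL") or 0) / dp if dp else 0.0
                stut = (sd.get("DSTUTTER") or 0) / dp if dp else 0.0
                rows.append((locus_id, sample, bp1, bp2, q, flank, stut))
        except Exception as exc:  # noqa: BLE001 - annotate parse failures
            raise ValueError(f"malformed VCF record #{i + 1} in {path}: {exc}") from exc
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    loci = pd.DataFrame(loci_rows, columns=["locus_id", "scaffold", "pos", "period"])
    return CallSet(calls=calls, loci=loci, samples=samples)


def filter_calls(
    callset: CallSet,
    q_min: float = 0.90,
    flank_max: float = 0.15,
    stutter_max: float = 0.15,
) -> CallSet:
    """Drop calls failing any of the three artifact filters.

    A call survives iff posterior >= q_min, flank fraction <= flank_max and
    stutter fraction <= stutter_max; dropped calls become missing.  The
    operation is idempotent.
    """
    for v in (q_min, flank_max, stutter_max):
        if not 0.0 <= v <= 1.0:
            raise ValueError("thresholds must be in [0,1]")
    c = callset.calls
    keep = (
        (c["posterior"] >= q_min)
        & (c["flank_frac"] <= flank_max)
        & (c["stutter_frac"] <= stutter_max)
    )
    return CallSet(calls=c[keep].reset_index(drop=True), loci=callset.loci, samples=callset.samples)


def dosage_matrix(callset: CallSet) -> DosageMatrix:
    """Pivot surviving calls into a loci x samples dosage matrix.

    Dosage = (bp1 + bp2) / period; per-allele relative copies are retained.
    """
    loci = callset.loci.set_index("locus_id")
    c = callset.calls.merge(
        loci[["period"]], left_on="locus_id", right_index=True, how="left"
    )
    c["a1"] = c["bp1"] / c["period"]
    c["a2"] = c["bp2"] / c["period"]
    c["dose"] = c["a1"] + c["a2"]
    c["nonint"] = (np.mod(c["bp1"], c["period"]) != 0) | (np.mod(c["bp2"], c["period"]) != 0)

    def _pivot(col: str) -> pd.DataFrame:
        return (
            c.pivot(index="locus_id", columns="sample_id", values=col)
            .reindex(index=loci.index, columns=callset.samples)
        )

    return DosageMatrix(
        loci=loci,
        dosage=_pivot("dose"),
        allele1=_pivot("a1"),
        allele2=_pivot("a2"),
        nonintegral=_pivot("nonint").astype("boolean"),
    )


def filter_loci(
    matrix: DosageMatrix,
    min_presence: float = 0.2,
    max_missing: float = 0.1,
    purpose: str = "gwas",
) -> DosageMatrix:
    """Locus-level filtering for association (``gwas``) or GRM (``grm``) use.

    gwas keeps loci with presence rate strictly > ``min_presence``; grm keeps
    loci with missing rate strictly < ``max_missing``.  Monomorphic loci are
    dropped for both purposes.
    """
    if purpose not in ("gwas", "grm"):
        raise ValueError(f"unknown purpose {purpose!r}")
    presence = matrix.presence_rate()
    if purpose == "gwas":
        keep = presence > min_presence
    else:
        keep = (1.0 - presence) < max_missing
    nun = matrix.dosage.nunique(axis=1, dropna=True)
    keep &= nun > 1
    if not keep.any():
        raise ValueError(
            "all loci removed by filtering; review presence/missing thresholds"
        )
    return matrix.subset_loci(matrix.dosage.index[keep])


def allele_frequencies(matrix: DosageMatrix, locus_id: str) -> dict[float, float]:
    """Allele relative-copy-number frequencies over observed calls at a locus."""
    if matrix.allele1 is None or matrix.allele2 is None:
        raise ValueError("matrix does not carry per-allele values")
    a = np.concatenate(
        [matrix.allele1.loc[locus_id].to_numpy(float), matrix.allele2.loc[locus_id].to_numpy(float)]
    )
    a = a[~np.isnan(a)]
    if a.size == 0:
        raise ValueError(f"locus {locus_id} has no observed calls")
    vals, counts = np.unique(a, return_counts=True)
    return {float(v): float(c) / a.size for v, c in zip(vals, counts)}


def genotype_counts(matrix: DosageMatrix, locus_id: str) -> dict[tuple[float, float], int]:
    """Unordered allele-pair genotype counts over observed calls at a locus."""
    if matrix.allele1 is None or matrix.allele2 is None:
        raise ValueError("matrix does not carry per-allele values")
    a1 = matrix.allele1.loc[locus_id].to_numpy(float)
    a2 = matrix.allele2.loc[locus_id].to_numpy(float)
    ok = ~np.isnan(a1)
    out: dict[tuple[float, float], int] = {}
    for x, y in zip(a1[ok], a2[ok]):
        key = (min(x, y), max(x, y))
        out[key] = out.get(key, 0) + 1
    return out


def pic(allele_freqs: Mapping[float, float] | np.ndarray) -> float:
    """Polymorphism information content (Botstein et al. convention).

    PIC = 1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2.
    """
    p = np.asarray(list(allele_freqs.values()) if isinstance(allele_freqs, Mapping) else allele_freqs, dtype=float)
    if (p < 0).any():
        raise ValueError("allele frequencies must be non-negative")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError(f"allele frequencies sum to {p.sum()}, not 1")
    sq = p**2
    # sum_{i<j} 2 p_i^2 p_j^2 = (sum sq)^2 - sum(sq^2), since 2ab summed over i<j
    cross = sq.sum() ** 2 - (sq**2).sum()
    return float(1.0 - sq.sum() - cross)


def polymorphism_class(pic_value: float) -> str:
    """Botstein classes: low (<0.25), medium ([0.25, 0.5]), high (>0.5)."""
    if not 0.0 <= pic_value < 1.0:
        raise ValueError(f"PIC must be in [0,1), got {pic_value}")
    if pic_value < 0.25:
        return "low"
    if pic_value <= 0.5:
        return "medium"
    return "high"


@dataclass(frozen=True)
class HweResult:
    p_value: float
    statistic: float
    method: str
    degenerate: bool = False


def hwe_test(
    counts: Mapping[tuple[float, float], int],
    method: str = "montecarlo",
    n_perm: int = 10_000,
    seed: int = 0,
) -> HweResult:
    """Hardy-Weinberg equilibrium test for a (possibly multiallelic) locus.

    ``chisq`` compares observed genotype counts with HWE expectations
    (n p_i^2 on the diagonal, 2 n p_i p_j off it) on k(k-1)/2 df.
    ``montecarlo`` permutes the pooled alleles into random diploid pairings
    and returns the tail proportion of permuted tables whose chi-square
    statistic is at least the observed one (add-one corrected).
    ``chisq_biallelic`` collapses to major allele vs rest first (plink-style
    compatibility).
    """
    pairs = {(min(a, b), max(a, b)): int(c) for (a, b), c in counts.items()}
    n = sum(pairs.values())
    if n == 0:
        raise ValueError("no genotypes supplied")
    allele_count: dict[float, int] = {}
    for (a, b), c in pairs.items():
        allele_count[a] = allele_count.get(a, 0) + c
        allele_count[b] = allele_count.get(b, 0) + c
    alleles = sorted(allele_count)
    k = len(alleles)
    if k < 2:
        return HweResult(p_value=1.0, statistic=0.0, method=method, degenerate=True)

    if method == "chisq_biallelic":
        major = max(alleles, key=lambda a: allele_count[a])
        collapsed: dict[tuple[float, float], int] = {}
        for (a, b), c in pairs.items():
            key = (0.0 if a == major else 1.0, 0.0 if b == major else 1.0)
            key = (min(key), max(key))
            collapsed[key] = collapsed.get(key, 0) + c
        return hwe_test(collapsed, method="chisq")

    idx = {a: i for i, a in enumerate(alleles)}
    obs = np.zeros((k, k))
    for (a, b), c in pairs.items():
        obs[idx[a], idx[b]] += c
    freq = np.array([allele_count[a] for a in alleles], dtype=float) / (2 * n)
    exp = np.zeros((k, k))
    for i in range(k):
        exp[i, i] = n * freq[i] ** 2
        for j in range(i + 1, k):
            exp[i, j] = 2 * n * freq[i] * freq[j]
    iu = np.triu_indices(k)
    exp_u = exp[iu]
    obs_u = obs[iu]
    with np.errstate(divide="ignore", invalid="ignore"):
        cells = np.where(exp_u > 0, (obs_u - exp_u) ** 2 / exp_u, 0.0)
    stat = float(cells.sum())

    if method == "chisq":
        df = k * (k - 1) / 2
        return HweResult(p_value=float(sps.chi2.sf(stat, df)), statistic=stat, method="chisq")
    if method != "montecarlo":
        raise ValueError(f"unknown method {method!r}")

    # permutation null: shuffle the pooled 2n alleles into n random pairs
    rng = np.random.default_rng(seed)
    flat = np.repeat(
        [idx[a] for a in alleles], [allele_count[a] for a in alleles]
    ).astype(np.int64)
    perms = rng.permuted(np.broadcast_to(flat, (n_perm, flat.size)).copy(), axis=1)
    a1 = perms[:, 0::2]
    a2 = perms[:, 1::2]
    lo = np.minimum(a1, a2)
    hi = np.maximum(a1, a2)
    code = lo * k + hi
    row = np.repeat(np.arange(n_perm), n)
    tab = np.bincount(row * k * k + code.ravel(), minlength=n_perm * k * k).reshape(
        n_perm, k, k
    )
    tab_u = tab[:, iu[0], iu[1]].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        perm_stat = np.where(exp_u > 0, (tab_u - exp_u) ** 2 / exp_u, 0.0).sum(axis=1)
    p = (1.0 + np.sum(perm_stat >= stat - 1e-12)) / (1.0 + n_perm)
    return HweResult(p_value=float(p), statistic=stat, method="montecarlo")


def locus_qc(
    matrix: DosageMatrix,
    hwe: bool = False,
    hwe_method: str = "montecarlo",
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-locus QC table: presence rate, PIC, polymorphism class, optional HWE p."""
    rows = []
    presence = matrix.presence_rate()
    for locus_id in matrix.locus_ids:
        freqs = allele_frequencies(matrix, locus_id)
        v = pic(freqs)
        row = {
            "locus_id": locus_id,
            "presence_rate": float(presence.loc[locus_id]),
            "n_alleles": len(freqs),
            "pic": v,
            "polymorphism_class": polymorphism_class(v),
        }
        if hwe:
            res = hwe_test(
                genotype_counts(matrix, locus_id), method=hwe_method, n_perm=n_perm, seed=seed
            )
            row["hwe_p"] = res.p_value
        rows.append(row)
    return pd.DataFrame(rows).set_index("locus_id")


def write_dosage_tsv(matrix: DosageMatrix, path: str | Path) -> None:
    """Dosage TSV: locus rows (with scaffold/pos/period columns), sample columns."""
    out = matrix.loci.join(matrix.dosage)
    out.to_csv(path, sep="\t", na_rep="NA", index_label="locus_id")


def read_dosage_tsv(path: str | Path) -> DosageMatrix:
    df = pd.read_csv(path, sep="\t", index_col="locus_id", dtype={"scaffold": str})
    meta = df[["scaffold", "pos", "period"]]
    dose = df.drop(columns=["scaffold", "pos", "period"])
    return DosageMatrix(loci=meta, dosage=dose)
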