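"""Synthetic study generator with known ground truth.

Emulates the structure of a family-based aquaculture resequencing cohort:
unrelated founder pairs produce full-sib families; offspring are genotyped
at multiallelic STR loci (founder alleles drawn under HWE from
Dirichlet-distributed frequencies, offspring alleles by Mendelian
transmission), and the harvest-weight phenotype combines a sex effect, a
per-tank initial-body-weight slope, a handful of causal STR dosage effects,
a pedigree-structured polygenic breeding value and Gaussian residual noise.

The polygenic background is drawn through the pedigree (Cholesky of the
numerator relationship matrix), not through the marker loci, so a
marker-based GRM is a genuine estimate of relatedness rather than an
identity.  The default dimensions — 60 families with 6 genotyped offspring
each, two tanks, ~2,000 multiallelic loci, three planted causal dosage
effects and a polygenic heritability of 0.3 against a total phenotypic
variance of 60 g^2 — mirror a mid-sized selective-breeding cohort.

Every output is fully determined by the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .blup import Pedigree, pedigree_a_matrix
from .genotypes import DosageMatrix
from .scan import ScanThresholds, StrCatalog, StrLocus, scan_sequence

__all__ = [
    "SimConfig",
    "TruthTable",
    "CohortSim",
    "simulate_genome",
    "simulate_cohort",
    "simulate_str_vcf",
    "simulate_expression",
    "write_fasta",
]

_MOTIFS = ("A", "T", "AT", "AC", "AG", "AAT", "ATT", "ACC", "AATG")


@dataclass
class SimConfig:
    """Generative parameters of the synthetic cohort; the seed fixes everything."""

    seed: int = 0
    n_families: int = 60
    offspring_per_family: int = 6
    n_loci: int = 2000
    allele_values: tuple[float, ...] = (-2.0, -1.0, 0.0, 1.0, 2.0)
    dirichlet_alpha: float = 1.0
    causal_effects: tuple[float, ...] = (1.6, 2.0, 3.3)  # g per relative copy
    causal_loci: tuple[int, ...] | None = None  # locus indices; see below
    causal_var_s_target: float = 2.0  # dosage variance of auto-picked causal loci
    h2: float = 0.3  # polygenic fraction of total phenotypic variance
    var_p: float = 60.0  # total phenotypic variance target, g^2
    mu: float = 25.0  # population mean harvest weight, g
    sex_effect: float = 1.5  # g added for females
    n_tanks: int = 2
    ibw_slopes: tuple[float, ...] = (1.1, 1.3)  # per-tank IBW regression, g/g
    ibw_mean_by_sex: tuple[float, ...] = (5.5, 6.0)  # male, female, g
    ibw_sd_by_sex: tuple[float, ...] = (1.0, 1.1)
    mutation_rate: float = 0.0  # stepwise +-1 copy per meiosis per locus
    # HipSTR-style call noise
    low_posterior_frac: float = 0.03
    high_flank_frac: float = 0.01
    high_stutter_frac: float = 0.01
    missing_frac: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must be in [0,1]")
        if len(self.ibw_slopes) != self.n_tanks:
            raise ValueError("one IBW slope per tank required")
        for r in (self.low_posterior_frac, self.high_flank_frac, self.high_stutter_frac, self.missing_frac):
            if not 0.0 <= r <= 1.0:
                raise ValueError("noise rates must be in [0,1]")


@dataclass
class TruthTable:
    """Ground truth for recovery tests."""

    breeding_values: pd.Series  # per pedigree member
    dosages: pd.DataFrame  # loci x genotyped individuals (no noise)
    allele_freqs: pd.DataFrame  # loci x allele values (configured frequencies)
    causal: pd.DataFrame  # locus_id, effect g/copy
    sigma_a2: float
    sigma_e2: float
    causal_var: float
    realized_h2: float


@dataclass
class CohortSim:
    config: SimConfig
    pedigree: Pedigree
    phenotypes: pd.DataFrame  # id-indexed: sex, tank, ibw, hbw
    dosage: DosageMatrix  # noise-free truth genotypes of offspring
    truth: TruthTable


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _redraw(arr: np.ndarray, lo: int, hi: int, rng: np.random.Generator) -> None:
    lo, hi = max(lo, 0), min(hi, arr.size)
    arr[lo:hi] = rng.integers(0, 4, size=hi - lo)


def simulate_genome(
    n_scaffolds: int,
    scaffold_bp: int,
    planted: list[tuple[int, int, str, int]],
    seed: int = 0,
    thresholds: ScanThresholds | None = None,
    max_iter: int = 200,
) -> tuple[dict[str, str], StrCatalog]:
    """Random genome whose only threshold-passing STRs are the planted ones.

    ``planted`` entries are (scaffold_index, 1-based position, motif,
    n_repeats); overlapping plants raise ``ValueError``.  Background sequence
    is re-drawn by rejection until a scan of each scaffold recovers exactly
    its planted loci, so scanner recall and precision against the returned
    truth catalog are both 1 by construction.
    """
    if thresholds is None:
        thresholds = ScanThresholds()
    rng = np.random.default_rng(seed)
    bases = np.array([ord(c) for c in "ACGT"], dtype=np.uint8)
    names = [f"scf{i + 1}" for i in range(n_scaffolds)]
    per_scaffold: dict[int, list[tuple[int, str, int]]] = {i: [] for i in range(n_scaffolds)}
    for si, pos, motif, n_rep in planted:
        if si < 0 or si >= n_scaffolds:
            raise ValueError(f"scaffold index {si} out of range")
        L = len(motif) * n_rep
        if pos < 1 or pos + L - 1 > scaffold_bp:
            raise ValueError(f"planted locus at {pos} exceeds scaffold bounds")
        per_scaffold[si].append((pos, motif.upper(), n_rep))
    truth: list[StrLocus] = []
    seqs: dict[str, str] = {}
    for si, name in enumerate(names):
        plants = sorted(per_scaffold[si])
        prev_end = 0
        for pos, motif, n_rep in plants:
            if pos <= prev_end:
                raise ValueError(f"planted loci overlap on scaffold {name} at {pos}")
            prev_end = pos + len(motif) * n_rep - 1
        want = {
            (pos, pos + len(m) * k - 1, m, k): None for pos, m, k in plants
        }
        arr = rng.integers(0, 4, size=scaffold_bp)
        for _ in range(max_iter):
            code = bases[arr]
            for pos, m, k in plants:
                ins = np.frombuffer((m * k).encode(), dtype=np.uint8)
                code[pos - 1 : pos - 1 + ins.size] = ins
            seq = code.tobytes().decode("ascii")
            found = scan_sequence(seq, thresholds, scaffold=name)
            found_keys = {(l.start, l.end, l.motif, l.n_repeats) for l in found}
            extras = found_keys - set(want)
            missing = set(want) - found_keys
            if not extras and not missing:
                seqs[name] = seq
                break
            # redraw background around every offending span and planted edge
            for start, end, m, _k in extras:
                _redraw(arr, start - 1 - len(m), end + len(m), rng)
            for start, end, m, _k in missing:
                _redraw(arr, start - 1 - len(m), start - 1, rng)
                _redraw(arr, end, end + len(m), rng)
            # never overwrite the planted repeats themselves
        else:
            raise RuntimeError(f"could not build a clean background for {name}")
        for pos, m, k in plants:
            truth.append(
                StrLocus(name, pos, pos + len(m) * k - 1, m, len(m), k)
            )
    catalog = StrCatalog(loci=truth, genome_lengths={n: scaffold_bp for n in names})
    return seqs, catalog


def _feasible_sigma_e2(cfg: SimConfig, causal_var: float) -> tuple[float, float]:
    sigma_a2 = cfg.h2 * cfg.var_p
    sigma_e2 = cfg.var_p - sigma_a2 - causal_var
    if sigma_e2 <= 0:
        h2_max = max(0.0, 1.0 - causal_var / cfg.var_p)
        raise ValueError(
            f"h2={cfg.h2} infeasible: causal variance {causal_var:.2f} g^2 leaves "
            f"no residual variance (feasible h2 range: [0, {h2_max:.3f}))"
        )
    return sigma_a2, sigma_e2


def simulate_cohort(config: SimConfig) -> CohortSim:
    """Pedigreed families with multiallelic STR genotypes and phenotypes."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_alleles = len(cfg.allele_values)
    allele_vals = np.asarray(cfg.allele_values, dtype=float)

    # locus metadata: spread over 20 synthetic scaffolds, mixed periods
    n_scf = min(20, cfg.n_loci) or 1
    motifs = [ _MOTIFS[i % len(_MOTIFS)] for i in range(cfg.n_loci) ]
    loci = pd.DataFrame(
        {
            "locus_id": [f"scf{i % n_scf + 1}:{(i // n_scf + 1) * 10_000}" for i in range(cfg.n_loci)],
            "scaffold": [f"scf{i % n_scf + 1}" for i in range(cfg.n_loci)],
            "pos": [(i // n_scf + 1) * 10_000 for i in range(cfg.n_loci)],
            "period": [len(m) for m in motifs],
            "motif": motifs,
        }
    ).set_index("locus_id")

    freqs = rng.dirichlet([cfg.dirichlet_alpha] * n_alleles, size=cfg.n_loci)

    # pedigree: per family a founder sire and dam, then offspring
    fam_ids = [f"F{f + 1:03d}" for f in range(cfg.n_families)]
    sires = [f"{f}_S" for f in fam_ids]
    dams = [f"{f}_D" for f in fam_ids]
    offspring = [
        f"{f}_O{k + 1}" for f in fam_ids for k in range(cfg.offspring_per_family)
    ]
    ped_df = pd.DataFrame(
        {
            "id": sires + dams + offspring,
            "sire": [None] * 2 * cfg.n_families
            + [s for s in sires for _ in range(cfg.offspring_per_family)],
            "dam": [None] * 2 * cfg.n_families
            + [d for d in dams for _ in range(cfg.offspring_per_family)],
        }
    )
    ped = Pedigree(ped_df)

    # founder genotypes under HWE; offspring by Mendelian transmission
    n_f = cfg.n_families
    n_o = len(offspring)
    cum = np.cumsum(freqs, axis=1)

    def draw_alleles(n_ind: int) -> np.ndarray:
        u = rng.random((cfg.n_loci, n_ind))
        return allele_vals[(u[..., None] > cum[:, None, :]).sum(axis=2)]

    sire_a = np.stack([draw_alleles(n_f), draw_alleles(n_f)])  # 2 x loci x fam
    dam_a = np.stack([draw_alleles(n_f), draw_alleles(n_f)])

    fam_of = np.repeat(np.arange(n_f), cfg.offspring_per_family)
    pick_s = rng.integers(0, 2, size=(cfg.n_loci, n_o))
    pick_d = rng.integers(0, 2, size=(cfg.n_loci, n_o))
    li = np.arange(cfg.n_loci)[:, None]
    off_a1 = sire_a[pick_s, li, fam_of[None, :]]
    off_a2 = dam_a[pick_d, li, fam_of[None, :]]
    if cfg.mutation_rate > 0:
        for arr in (off_a1, off_a2):
            mut = rng.random(arr.shape) < cfg.mutation_rate
            step = rng.choice([-1.0, 1.0], size=arr.shape)
            arr += np.where(mut, step, 0.0)
    dosage_vals = off_a1 + off_a2

    a1 = pd.DataFrame(off_a1, index=loci.index, columns=offspring)
    a2 = pd.DataFrame(off_a2, index=loci.index, columns=offspring)
    dosage = DosageMatrix(
        loci=loci[["scaffold", "pos", "period"]],
        dosage=a1 + a2,
        allele1=a1,
        allele2=a2,
    )

    # causal loci and effects; when unset, pick the loci whose realized
    # offspring dosage variance is closest to the configured target, so the
    # planted effects act on common variants of known informativeness
    effects = np.asarray(cfg.causal_effects, dtype=float)
    if cfg.causal_loci is None:
        realized = np.var(dosage_vals, axis=1)
        order = np.argsort(np.abs(realized - cfg.causal_var_s_target), kind="stable")
        chosen: list[int] = []
        for idx in order:
            if len(chosen) == effects.size:
                break
            # causal loci must be mutually (near-)uncorrelated so their
            # variance contributions add as designed
            if all(
                abs(np.corrcoef(dosage_vals[idx], dosage_vals[j])[0, 1]) < 0.1
                for j in chosen
            ):
                chosen.append(int(idx))
        if len(chosen) < effects.size:
            raise ValueError("could not find enough uncorrelated causal loci")
        causal_idx = np.asarray(chosen, dtype=int)
    else:
        causal_idx = np.asarray(cfg.causal_loci, dtype=int)
        if causal_idx.size != effects.size:
            raise ValueError("causal_loci and causal_effects lengths differ")
    causal_component = effects @ dosage_vals[causal_idx]
    causal_var = float(np.var(causal_component))
    sigma_a2, sigma_e2 = _feasible_sigma_e2(cfg, causal_var)

    # polygenic breeding values via pedigree Cholesky
    amat = pedigree_a_matrix(ped)
    L = np.linalg.cholesky(amat.matrix + 1e-10 * np.eye(len(amat.ids)))
    a_all = pd.Series(
        L @ rng.standard_normal(len(amat.ids)) * np.sqrt(sigma_a2), index=amat.ids
    )

    # covariates and phenotype (offspring are the phenotyped individuals)
    sex = rng.integers(0, 2, size=n_o)  # 0 male, 1 female
    tank = rng.integers(0, cfg.n_tanks, size=n_o)
    ibw = rng.normal(
        np.asarray(cfg.ibw_mean_by_sex)[sex], np.asarray(cfg.ibw_sd_by_sex)[sex]
    )
    slopes = np.asarray(cfg.ibw_slopes)
    e = rng.normal(0.0, np.sqrt(sigma_e2), size=n_o)
    a_off = a_all.loc[offspring].to_numpy()
    y = (
        cfg.mu
        + cfg.sex_effect * sex
        + slopes[tank] * ibw
        + causal_component
        + a_off
        + e
    )
    phen = pd.DataFrame(
        {
            "sex": np.where(sex == 1, "F", "M"),
            "tank": [f"T{t + 1}" for t in tank],
            "ibw": ibw,
            "hbw": y,
        },
        index=pd.Index(offspring, name="id"),
    )
    resid_var = float(np.var(y - causal_component - a_off))
    truth = TruthTable(
        breeding_values=a_all,
        dosages=dosage.dosage.copy(),
        allele_freqs=pd.DataFrame(freqs, index=loci.index, columns=allele_vals),
        causal=pd.DataFrame(
            {"locus_id": loci.index[causal_idx], "effect": effects}
        ).set_index("locus_id"),
        sigma_a2=sigma_a2,
        sigma_e2=sigma_e2,
        causal_var=causal_var,
        realized_h2=float(np.var(a_off) / np.var(y)),
    )
    return CohortSim(config=cfg, pedigree=ped, phenotypes=phen, dosage=dosage, truth=truth)


def simulate_str_vcf(
    cohort: CohortSim,
    path: str | Path,
    seed: int | None = None,
) -> None:
    """Write the cohort's genotypes as a HipSTR-dialect VCF with planted noise.

    Per call, independently of the others: with probability ``missing_frac``
    the genotype is missing; with ``low_posterior_frac`` the posterior is
    drawn below 0.9; with ``high_flank_frac``/``high_stutter_frac`` more than
    15% of reads carry the artifact.  Calls failing the three filters are
    exactly the planted noisy ones.
    """
    cfg = cohort.config
    rng = np.random.default_rng(cfg.seed + 101 if seed is None else seed)
    dm = cohort.dosage
    samples = dm.samples
    loci = dm.loci
    n_loci, n_s = len(loci), len(samples)
    a1 = dm.allele1.to_numpy(float)
    a2 = dm.allele2.to_numpy(float)
    period = loci["period"].to_numpy(int)[:, None]
    bp1 = a1 * period
    bp2 = a2 * period
    dp = 40
    missing = rng.random((n_loci, n_s)) < cfg.missing_frac
    low_q = rng.random((n_loci, n_s)) < cfg.low_posterior_frac
    hi_flank = rng.random((n_loci, n_s)) < cfg.high_flank_frac
    hi_stut = rng.random((n_loci, n_s)) < cfg.high_stutter_frac
    q = np.where(low_q, rng.uniform(0.50, 0.89, (n_loci, n_s)), rng.uniform(0.95, 1.0, (n_loci, n_s)))
    flank = np.where(hi_flank, rng.integers(7, 16, (n_loci, n_s)), rng.integers(0, 3, (n_loci, n_s)))
    stut = np.where(hi_stut, rng.integers(7, 16, (n_loci, n_s)), rng.integers(0, 3, (n_loci, n_s)))

    scaffolds = {}
    for s, g in loci.groupby("scaffold", sort=False):
        scaffolds[s] = int(g["pos"].max()) + 10_000
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=strdose-simulate\n")
        for s, length in scaffolds.items():
            fh.write(f"##contig=<ID={s},length={length}>\n")
        fh.write('##INFO=<ID=PERIOD,Number=1,Type=Integer,Description="Repeat unit length (bp)">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GB,Number=1,Type=String,Description="Base pair differences of genotype from reference">\n')
        fh.write('##FORMAT=<ID=Q,Number=1,Type=Float,Description="Posterior probability of unphased genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=DSTUTTER,Number=1,Type=Integer,Description="Reads with a stutter artifact">\n')
        fh.write('##FORMAT=<ID=DFLANKINDEL,Number=1,Type=Integer,Description="Reads with an indel in the flanks">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for i, (locus_id, row) in enumerate(loci.iterrows()):
            fields = [
                row["scaffold"], str(int(row["pos"])), locus_id, "A", ".", ".", ".",
                f"PERIOD={int(row['period'])}", "GT:GB:Q:DP:DSTUTTER:DFLANKINDEL",
            ]
            for j in range(n_s):
                if missing[i, j] or np.isnan(a1[i, j]):
                    fields.append("./.")
                else:
                    fields.append(
                        f"0/0:{bp1[i, j]:g}|{bp2[i, j]:g}:{q[i, j]:.4f}:{dp}:{stut[i, j]}:{flank[i, j]}"
                    )
            fh.write("\t".join(fields) + "\n")


def simulate_expression(
    n_genes: int = 200,
    n_per_group: int = 20,
    n_de: int = 10,
    fold_change: float = 4.0,
    dispersion: float = 0.2,
    base_mean: float = 200.0,
    gene_length_bp: tuple[int, int] = (500, 5000),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.Series, pd.DataFrame]:
    """Negative-binomial counts for an HBW/LBW two-group design.

    The first ``n_de`` genes are up-regulated ``fold_change``-fold in the
    HBW group.  Returns (counts, gene_lengths, groups, truth) where truth
    records each gene's group means and DE status.
    """
    if fold_change <= 0:
        raise ValueError("fold changes must be positive")
    rng = np.random.default_rng(seed)
    genes = [f"gene{i + 1:04d}" for i in range(n_genes)]
    samples = [f"HBW_{i + 1}" for i in range(n_per_group)] + [
        f"LBW_{i + 1}" for i in range(n_per_group)
    ]
    groups = pd.Series(
        ["HBW"] * n_per_group + ["LBW"] * n_per_group, index=samples, name="group"
    )
    lengths = pd.Series(
        rng.integers(gene_length_bp[0], gene_length_bp[1], size=n_genes),
        index=genes,
        name="length",
    )
    base = rng.lognormal(np.log(base_mean), 1.0, size=n_genes)
    mean_lbw = base
    mean_hbw = base * np.where(np.arange(n_genes) < n_de, fold_change, 1.0)
    # counts scale with gene length so FPKM is comparable across genes
    len_scale = lengths.to_numpy() / 1000.0

    def nb(mean_vec: np.ndarray, n_samples: int) -> np.ndarray:
        m = np.maximum(mean_vec[:, None] * len_scale[:, None], 1e-8)
        m = np.broadcast_to(m, (n_genes, n_samples))
        r = 1.0 / dispersion
        p = r / (r + m)
        return rng.negative_binomial(r, p)

    counts = np.hstack([nb(mean_hbw, n_per_group), nb(mean_lbw, n_per_group)])
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    truth = pd.DataFrame(
        {
            "mean_hbw": mean_hbw,
            "mean_lbw": mean_lbw,
            "is_de": np.arange(n_genes) < n_de,
        },
        index=genes,
    )
    return counts_df, lengths, groups, truth
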