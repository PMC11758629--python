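# Methods

This note documents the statistical models, defaults, simulation design and
numerical choices behind `strdose`, and what its tests do and do not show.

## STR discovery

A locus is a maximal run of a *primitive* repeat unit (one that is not
itself a repetition of a shorter unit) of period 1–6 bp, repeated perfectly
with no interruptions. Thresholds follow the MISA convention for dense
genomes: the repeat region must span at least 10 bp (`min_region_bp`), with
per-period minimum repeat counts {1:10, 2:5, 3:4, 4:3, 5:3, 6:3}. Trailing
partial units are excluded from the reported locus; a run that is periodic
at several lags (a poly-A run also matches lag 2) is reported once, at its
smallest primitive period. Compound/interrupted SSR merging is deliberately
not implemented: each maximal perfect run is an independent genotyping
target. Runs touching an N are never reported; characters outside
A/C/G/T/N are an error naming the offending position. When two maximal runs
of different motifs overlap (e.g. a poly-A shoulder running into an AT
tract), both are reported if each passes thresholds independently —
deterministic and oracle-checkable. Coordinates are 1-based inclusive in
all emitted files, 0-based half-open internally.

Motif classes are the lexicographically smallest cyclic rotation of the
unit; with `merge_revcomp` the rotations of the reverse complement compete
too (so AAT/ATA/TAA/ATT/TTA/TAT form one class). Published STR surveys are
inconsistent here — dinucleotide classes are often kept strand-specific
(AT/TA vs AG/GA) while trinucleotide classes merge strands — so both modes
are exposed rather than guessing a single intent; `merge_revcomp=False` is
the default.

Landscape statistics: relative abundance (loci/Mb), density (STR bp/Mb) and
percent of genome; the last two are the same quantity on different scales
(percent = density / 10⁴). Window occupancy tiles scaffolds with
non-overlapping windows `[kw+1, (k+1)w]` (last window may be short) and
reports the fraction containing ≥ 1 marker. Region marker density reports
markers/Mb inside and outside a merged interval set; a side with zero span
is undefined (NaN), not zero.

## Genotypes and dosage

The VCF dialect mirrors targeted STR callers: per call, `GB` holds the two
alleles' signed bp differences from the reference allele, `Q` the genotype
posterior, and `DSTUTTER`/`DFLANKINDEL` over `DP` give artifact read
fractions. A call survives QC iff posterior ≥ 0.90, flank fraction ≤ 0.15
and stutter fraction ≤ 0.15; failures become missing, and all rates
downstream use observed calls only (missing never contributes zeros).
Relative copy number = bp difference / period; bp differences that are not
multiples of the period (partial-unit indels) are kept as rational copy
numbers and flagged rather than silently dropped, which would bias dosage.

Locus filters are purpose-specific, as the two downstream consumers use
different rules: association keeps presence rate strictly > 0.2;
relationship-matrix construction keeps missing rate strictly < 0.1.
Monomorphic loci are dropped for both. The two resulting locus sets need
not be nested.

PIC uses the classic Botstein form `1 − Σpᵢ² − ΣΣ_{i<j} 2pᵢ²pⱼ²` with class
boundaries low < 0.25 ≤ medium ≤ 0.5 < high. The Hardy–Weinberg test is by
default a Monte-Carlo exact test suited to multiallelic loci: the pooled 2n
alleles are repeatedly permuted into random diploid pairings and the
chi-square distance of each permuted genotype table from its HWE
expectation is compared with the observed one (add-one-corrected tail
proportion; default 10,000 permutations, seeded). A plain chi-square on
k(k−1)/2 df and a collapse-to-biallelic (major vs rest) compatibility mode
are available. Single-allele tables report p = 1 with a degenerate flag.

## Relationship matrices

Genomic: the classic biallelic scaling 2Σp(1−p) is undefined for signed
multiallelic dosages, so the GRM uses `G = W W' / s` with W the
mean-centred (mean-imputed) loci × samples dosage matrix and
`s = Σⱼ var(sⱼ)` the summed per-locus population variance (divisor n) over
observed calls. This reduces to the standard form in the biallelic case and
keeps E[diag(G)] ≈ 1 for an unrelated HWE sample. Mean imputation makes
missing entries contribute zero to W — standard GRM practice that avoids
pairwise-complete instability. Principal components come from the
eigendecomposition of G (scores = eigenvectors × √eigenvalue, sign fixed so
the largest-magnitude loading is positive); whether association covariates
should instead come from an independent SNP set is an open design question
in this kind of study, and STR-GRM PCs are used here.

Pedigree: the numerator relationship matrix by the tabular method,
`a_ii = 1 + ½a(sire,dam)`, `a_ij = ½(a_{j,sire(i)} + a_{j,dam(i)})`, unknown
parents contributing zero; pedigrees are topologically sorted at
construction and cycles are an error naming the individual.

## Mixed-model association

Model: `y = 1μ + Xb + Su + Za + e` with `a ~ N(0, G σ²ₐ)` and
`e ~ N(0, I σ²ₑ)`. Fixed effects: sex as a two-level factor (reference
dropped), the top-5 GRM PCs as covariates, and initial body weight nested
in tank (one IBW slope per tank). REML estimation eigendecomposes G once
and profiles the restricted likelihood in h = σ²ₐ/(σ²ₐ+σ²ₑ): a 64-point
grid seeds a bounded scalar optimisation; the σ²ₐ = 0 boundary (pure-OLS)
model is evaluated explicitly and returned with a boundary flag when it
dominates. The reported log-likelihood is the Harville restricted
likelihood including the ln|X'V⁻¹X| term (without the constant ln|X'X|),
which matches a dense-matrix evaluation exactly and is what the grid-search
oracle test checks.

The genome scan defaults to the P3D/EMMAX strategy — variance components
estimated once under the null, then a per-locus GLS Wald test with the
dosage appended to the fixed effects — because per-locus REML refits are
quadratically more expensive at catalog scale; `mode="exact"` refits per
locus for fidelity to a full per-marker mixed-model fit. The per-locus test
re-estimates the residual *scale* from the augmented model
(σ̂² = r'V⁻¹r/df, df = n − rank([X s])) and uses a t reference with that df,
so when G = I the test collapses exactly to the ordinary regression t-test.
Individuals missing a locus's dosage are case-wise deleted for that locus
only (the dosage is the tested covariate; imputing it would dilute the
effect), and the GRM is never re-estimated per locus. Loci with fewer than
10 observed individuals or zero dosage variance in the tested subset yield
degenerate records without p-values. Suggestive associations are exactly
p < 5×10⁻⁴; no multiple-testing correction beyond that fixed threshold is
applied. PVE for a locus is û²·Var(s)/Var(y) clipped to [0,1]; this formula
is a declared convention (several variants circulate) and is recorded here
so results are auditable.

## Adjusted phenotypes and the correlation filter

The adjustment model is deliberately simpler than the association model
(no tank, no PCs): `y = μ + Sex + β(Sex)·IBW + a + e` with `a ~ N(0, A σ²ₐ)`
over the full pedigree. Variance components are re-estimated by REML on
this model (using the same engine with A restricted to phenotyped
individuals), not copied from the genomic model. Henderson's mixed-model
equations are solved densely with λ = σ²ₑ/σ²ₐ; at the σ²ₐ → 0 boundary
breeding values are zero and fixed effects come from OLS. Unphenotyped
pedigree members still receive breeding values. The adjusted phenotype is
y* = â + ê, i.e. the phenotype minus its fixed-effect fit; the screen keeps
loci with pairwise-complete Pearson |r| > 0.5 against y* (the p-value is
reported but not used for filtering). Which phenotyped subset feeds y* is
configurable by passing a restricted phenotype table.

## Expression integration

FPKM_gs = counts_gs × 10⁹ / (length_g × library_s). The two-group test is
an equal-variance Student t-test by default (the common choice in
point-and-click analysis tools), Welch optional, on untransformed FPKM with
a log2(x+1) flag; genes with zero variance in both groups are flagged
degenerate. STR-to-gene assignment is plain interval logic replacing a
variant-annotator dependency: a locus overlapping a gene span reports only
its host gene(s) (relation `inside`); otherwise all genes within
`max_distance_bp` (default 25 kb — declared, configurable, no canonical
value exists) are reported as upstream/downstream relative to gene
orientation. Exon-level consequence classes are out of scope.

## Synthetic cohort design

The generator emulates a mid-sized selective-breeding study: 60 full-sib
families (unrelated founder pairs), 6 genotyped offspring each (n = 360),
two tanks, ~2,000 multiallelic STR loci. Founders draw two alleles per
locus under HWE from Dirichlet(1,…,1) frequencies over relative copies
{−2…+2}; offspring inherit one allele per parent (optional stepwise ±1
mutation, off by default). The phenotype (harvest weight, g) is

μ(25) + sex effect (1.5, females) + per-tank IBW slope (1.1, 1.3) ×
IBW(sex-specific N(5.5,1)/N(6,1.1)) + Σ causal effects × dosage +
a + e,

with the polygenic a drawn through the *pedigree* Cholesky (not through the
markers), so the marker GRM is a genuine estimate of relatedness rather
than an identity — and, consequently, REML on the marker GRM mildly
attenuates a pedigree-defined h², which the tests account for by checking
estimator recovery under its own model (a ~ N(0, Gσ²ₐ)). The variance
budget targets total Var(y) = 60 g² (CV ≈ 30% at a 25 g mean): σ²ₐ = h²·60
with default h² = 0.3, σ²ₑ = 60 − σ²ₐ − causal variance; an infeasible h²
given the causal effects raises an error stating the feasible range.

Causal loci default to three planted dosage effects of (1.6, 2.0, 3.3)
g/copy. The loci are auto-selected as those whose realized offspring
dosage variance is closest to 2.0 and whose dosages are mutually
near-uncorrelated (|r| < 0.1) — planted effects act on common, independent
variants, so their variance contributions add as designed. The effect
sizes are a power-design choice: the smallest gives an expected per-locus
Wald statistic ≈ 5 at n = 360 (reliable top-1% ranking), and the largest an
expected adjusted-phenotype correlation ≈ 0.60, mid-range of the
correlations such studies report for passing loci. Call noise defaults
(3% low-posterior, 1% high-flank, 1% high-stutter, 2% missing) put expected
post-QC missingness near 7%, below the relationship-matrix locus filter, as
in well-behaved targeted STR data.

What the synthetic data does *not* emulate: read-level error and stutter
generation (noise is planted at the call level), linkage between loci
(loci segregate independently), selection, overlapping generations, and
genotype–environment interaction. Passing tests therefore demonstrate the
correctness and calibration of the estimators under the stated generative
model, not robustness to all features of real resequencing data.

## Problem sizes used in tests and the acceptance script

Calibration and recovery use 84 families × 6 offspring (n = 504) with
1,500–2,000 loci; the end-to-end run uses the default 360-individual,
2,000-locus cohort through the full VCF → filters → GRM → GWAS → BLUP →
correlation path; scanner oracle checks use 100 seeded 2-kb sequences with
planted repeats; BLUP oracle checks use 50-individual random pedigrees.
Heritability recovery averages three replicate trait draws on one GRM.
These sizes give stable stochastic checks (type-I error within ±2 pp,
h² within ±0.1) while keeping a full test run in tens of seconds.

## Known limitations

- Perfect repeats only; imperfect/compound SSRs are out of scope.
- P3D p-values are slightly conservative/liberal relative to exact
  per-locus refits when a locus has large effect (the null variance
  components absorb it); the exact mode exists for final candidate lists.
- The Monte-Carlo HWE p-value has resolution 1/(n_perm+1).
- Dense linear algebra throughout: comfortable to a few thousand samples;
  beyond that the GRM eigendecomposition and per-locus subsetting would
  need iterative or blocked implementations.
- The correlation filter ignores family structure (as does the convention
  it implements); its p-values are not independence-corrected.
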