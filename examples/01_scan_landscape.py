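"""Scan a small synthetic genome for perfect STRs and summarise the landscape.

Builds a two-scaffold genome with known planted repeats, runs the scanner,
and prints the landscape statistics (count, abundance, density, percent of
genome) plus window occupancy — the same summaries used to compare STR
content across species.
"""

from strdose import landscape_stats, scan_sequence, window_occupancy
from strdose.scan import StrCatalog
from strdose.simulate import simulate_genome

plants = [
    (0, 1_001, "AT", 8),     # (AT)8 on scaffold 1
    (0, 5_000, "A", 15),     # poly-A run
    (1, 2_500, "AAT", 6),    # trinucleotide repeat
    (1, 9_000, "AC", 7),
]
seqs, truth = simulate_genome(n_scaffolds=2, scaffold_bp=20_000, planted=plants, seed=11)

loci = []
for name, seq in seqs.items():
    loci.extend(scan_sequence(seq, scaffold=name))
catalog = StrCatalog(loci=loci, genome_lengths={n: len(s) for n, s in seqs.items()})

stats = landscape_stats(catalog)
print(f"found {stats.n_str} STRs (planted {len(truth.loci)})")
print(f"relative abundance: {stats.relative_abundance:.1f} loci/Mb")
print(f"density: {stats.density_bp_per_mb:.0f} bp/Mb = {stats.percent_genome:.3f}% of genome")
# percent_genome is density/1e4 by construction: 10^4 bp/Mb = 1%

positions = {l.scaffold: [x.start for x in catalog.loci if x.scaffold == l.scaffold]
             for l in catalog.loci}
occ = window_occupancy(positions, 10_000, catalog.genome_lengths)
print(f"fraction of 10 kb windows containing an STR: {occ:.2f}")
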