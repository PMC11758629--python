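"""Perfect short-tandem-repeat (STR) discovery and genome landscape statistics.

A microsatellite here is a maximal run of a primitive 1-6 bp motif repeated
perfectly (no interruptions), subject to a minimum repeat count per motif
period and a minimum total region length.  The default thresholds are the
classic MISA settings used for dense invertebrate genomes: a locus must span
at least 10 bp, with at least 10 copies for mononucleotide motifs and
5, 4, 3, 3 and 3 copies for di- through hexanucleotide motifs.

Coordinates are 1-based inclusive in all public objects and emitted files
(VCF/GFF convention); internal arithmetic is 0-based half-open.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "StrLocus",
    "ScanThresholds",
    "StrCatalog",
    "LandscapeStats",
    "scan_sequence",
    "scan_fasta",
    "canonical_motif",
    "reverse_complement",
    "is_primitive",
    "landscape_stats",
    "window_occupancy",
    "region_marker_density",
    "write_catalog_bed",
    "read_catalog_bed",
    "write_hipstr_regions",
]

_BASES = frozenset(b"ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: MISA-style per-period minimum repeat counts (period -> repeats).
DEFAULT_MIN_REPEATS: Mapping[int, int] = {1: 10, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}


@dataclass(frozen=True, order=True)
class StrLocus:
    """One perfect STR: ``motif`` repeated ``n_repeats`` times at 1-based
    inclusive coordinates ``start``..``end`` on ``scaffold``."""

    scaffold: str
    start: int
    end: int
    motif: str = field(compare=False)
    period: int = field(compare=False)
    n_repeats: int = field(compare=False)

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def locus_id(self) -> str:
        return f"{self.scaffold}:{self.start}"


@dataclass(frozen=True)
class ScanThresholds:
    """Minimum repeat count per motif period and minimum region length (bp)."""

    min_repeats_by_period: Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_REPEATS)
    )
    min_region_bp: int = 10

    def __post_init__(self) -> None:
        for p, r in self.min_repeats_by_period.items():
            if p < 1 or p > 6 or r < 2:
                raise ValueError(f"invalid threshold: period {p} -> {r} repeats")
        if self.min_region_bp < 1:
            raise ValueError("min_region_bp must be >= 1")


@dataclass
class StrCatalog:
    """An ordered collection of loci plus the scaffold lengths they live on."""

    loci: list[StrLocus]
    genome_lengths: dict[str, int]

    def __post_init__(self) -> None:
        self.loci = sorted(self.loci, key=lambda l: (l.scaffold, l.start, l.end))
        for loc in self.loci:
            n = self.genome_lengths.get(loc.scaffold)
            if n is None or loc.end > n or loc.start < 1:
                raise ValueError(f"locus {loc.locus_id} outside scaffold bounds")

    def __len__(self) -> int:
        return len(self.loci)

    def total_genome_bp(self) -> int:
        return sum(self.genome_lengths.values())

    def total_str_bp(self) -> int:
        return sum(l.length_bp for l in self.loci)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scaffold": [l.scaffold for l in self.loci],
                "start": [l.start for l in self.loci],
                "end": [l.end for l in self.loci],
                "motif": [l.motif for l in self.loci],
                "period": [l.period for l in self.loci],
                "n_repeats": [l.n_repeats for l in self.loci],
            }
        )


@dataclass(frozen=True)
class LandscapeStats:
    """Genome-level STR landscape summary.

    relative_abundance is loci per Mb, density_bp_per_mb is STR bases per Mb,
    and percent_genome = density_bp_per_mb / 1e4 (the two are the same
    quantity on different scales).
    """

    n_str: int
    relative_abundance: float
    density_bp_per_mb: float
    percent_genome: float
    unit_size_proportions: dict[int, float]
    motif_class_proportions: dict[str, float]


def is_primitive(motif: str) -> bool:
    """True if ``motif`` is not itself a repetition of a shorter unit."""
    p = len(motif)
    for d in range(1, p):
        if p % d == 0 and motif == motif[:d] * (p // d):
            return False
    return True


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_motif(motif: str, merge_revcomp: bool = False) -> str:
    """Canonical class label for a repeat unit.

    The label is the lexicographically smallest cyclic rotation of the motif;
    with ``merge_revcomp`` the rotations of the reverse complement compete as
    well, so e.g. AAT, ATA, TAA, ATT, TTA and TAT all map to "AAT".
    """
    if not motif or len(motif) > 6:
        raise ValueError(f"motif must be 1-6 bases, got {motif!r}")
    m = motif.upper()
    if set(m) - set("ACGT"):
        raise ValueError(f"motif {motif!r} contains non-ACGT characters")
    candidates = [m[i:] + m[:i] for i in range(len(m))]
    if merge_revcomp:
        rc = reverse_complement(m)
        candidates += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(candidates)


def scan_sequence(
    seq: str,
    thresholds: ScanThresholds | None = None,
    scaffold: str = "seq",
) -> list[StrLocus]:
    """Find every maximal perfect STR in ``seq`` passing ``thresholds``.

    Each maximal run is reported once, at the smallest primitive period that
    generates it; trailing partial units are excluded from the locus.  Runs
    touching an N are never reported.  Characters other than A/C/G/T/N raise
    ``ValueError`` naming the first offending position (1-based).
    """
    if thresholds is None:
        thresholds = ScanThresholds()
    if not seq:
        return []
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    valid = np.isin(arr, np.frombuffer(b"ACGTN", dtype=np.uint8))
    if not valid.all():
        pos = int(np.argmin(valid))
        raise ValueError(
            f"invalid character {chr(arr[pos])!r} at position {pos + 1} of {scaffold}"
        )
    acgt = arr != ord("N")
    s = seq.upper()
    n = len(s)
    out: list[StrLocus] = []
    for period, min_rep in sorted(thresholds.min_repeats_by_period.items()):
        if n < 2 * period:
            continue
        # match[i]: position i repeats `period` bases later, and is a real base
        match = (arr[:-period] == arr[period:]) & acgt[:-period]
        if not match.any():
            continue
        padded = np.concatenate(([False], match, [False]))
        edges = np.flatnonzero(np.diff(padded.view(np.int8)))
        starts, stops = edges[0::2], edges[1::2]
        for i, j in zip(starts, stops):
            m = j - i  # run of matches; repeated region spans m + period bases
            n_rep = (m + period) // period
            if n_rep < min_rep or n_rep * period < thresholds.min_region_bp:
                continue
            motif = s[i : i + period]
            if not is_primitive(motif):
                continue  # captured at its smaller primitive period
            out.append(
                StrLocus(
                    scaffold=scaffold,
                    start=int(i) + 1,
                    end=int(i) + int(n_rep) * period,
                    motif=motif,
                    period=period,
                    n_repeats=int(n_rep),
                )
            )
    out.sort(key=lambda l: (l.start, l.period))
    return out


def scan_fasta(
    fasta_path: str | Path, thresholds: ScanThresholds | None = None
) -> StrCatalog:
    """Scan every record of a (multi-)FASTA file into a :class:`StrCatalog`."""
    loci: list[StrLocus] = []
    lengths: dict[str, int] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq)
        lengths[rec.id] = len(seq)
        loci.extend(scan_sequence(seq, thresholds, scaffold=rec.id))
    if not lengths:
        raise ValueError(f"no FASTA records found in {fasta_path}")
    return StrCatalog(loci=loci, genome_lengths=lengths)


def landscape_stats(catalog: StrCatalog, merge_revcomp: bool = False) -> LandscapeStats:
    """Count, abundance, density and motif composition of a catalog."""
    total_bp = catalog.total_genome_bp()
    if total_bp <= 0:
        raise ValueError("total genome length must be positive")
    mb = total_bp / 1e6
    n = len(catalog)
    str_bp = catalog.total_str_bp()
    unit_props: dict[int, float] = {p: 0.0 for p in range(1, 7)}
    motif_props: dict[str, float] = {}
    if n:
        for loc in catalog.loci:
            unit_props[loc.period] = unit_props.get(loc.period, 0.0) + 1.0
            lab = canonical_motif(loc.motif, merge_revcomp=merge_revcomp)
            motif_props[lab] = motif_props.get(lab, 0.0) + 1.0
        unit_props = {p: c / n for p, c in unit_props.items()}
        motif_props = {m: c / n for m, c in sorted(motif_props.items())}
    return LandscapeStats(
        n_str=n,
        relative_abundance=n / mb,
        density_bp_per_mb=str_bp / mb,
        percent_genome=100.0 * str_bp / total_bp,
        unit_size_proportions=unit_props,
        motif_class_proportions=motif_props,
    )


def window_occupancy(
    marker_positions: Mapping[str, Sequence[int]],
    window_bp: int,
    genome_lengths: Mapping[str, int],
) -> float:
    """Fraction of non-overlapping ``window_bp`` windows containing >= 1 marker.

    Windows tile each scaffold as [k*w+1, (k+1)*w] in 1-based coordinates; the
    last window of a scaffold may be short.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    total = 0
    occupied = 0
    for scaffold, length in genome_lengths.items():
        n_win = math.ceil(length / window_bp)
        total += n_win
        pos = np.asarray(marker_positions.get(scaffold, ()), dtype=np.int64)
        if pos.size:
            if pos.min() < 1 or pos.max() > length:
                raise ValueError(f"marker position outside {scaffold} bounds")
            occupied += np.unique((pos - 1) // window_bp).size
    if total == 0:
        raise ValueError("genome has no windows")
    return occupied / total


def region_marker_density(
    markers: Mapping[str, Sequence[int]],
    regions: Mapping[str, Sequence[tuple[int, int]]],
    genome_lengths: Mapping[str, int],
) -> tuple[float, float]:
    """Marker density (per Mb) inside vs outside a merged interval set.

    Regions are 1-based inclusive, non-overlapping and sorted per scaffold.
    When one side has zero span its density is undefined and reported as NaN.
    """
    inside_bp = 0
    inside_n = 0
    total_n = 0
    for scaffold, length in genome_lengths.items():
        regs = sorted(regions.get(scaffold, ()))
        prev_end = 0
        for a, b in regs:
            if a < 1 or b > length or a > b:
                raise ValueError(f"region ({a},{b}) invalid on {scaffold}")
            if a <= prev_end:
                raise ValueError(f"regions overlap on {scaffold} near {a}")
            prev_end = b
            inside_bp += b - a + 1
        pos = np.asarray(markers.get(scaffold, ()), dtype=np.int64)
        if pos.size == 0:
            continue
        if pos.min() < 1 or pos.max() > length:
            raise ValueError(f"marker position outside {scaffold} bounds")
        total_n += pos.size
        if regs:
            starts = np.array([a for a, _ in regs])
            ends = np.array([b for _, b in regs])
            idx = np.searchsorted(starts, pos, side="right") - 1
            hit = (idx >= 0) & (pos <= ends[np.clip(idx, 0, None)])
            inside_n += int(hit.sum())
    total_bp = sum(genome_lengths.values())
    outside_bp = total_bp - inside_bp
    inside = inside_n / (inside_bp / 1e6) if inside_bp > 0 else math.nan
    outside = (total_n - inside_n) / (outside_bp / 1e6) if outside_bp > 0 else math.nan
    return inside, outside


def write_catalog_bed(catalog: StrCatalog, path: str | Path) -> None:
    """BED-like TSV: scaffold, start-1 (0-based), end, motif, period, n_repeats."""
    df = catalog.to_frame()
    df["start"] = df["start"] - 1
    df.to_csv(path, sep="\t", header=False, index=False)


def read_catalog_bed(
    path: str | Path, genome_lengths: Mapping[str, int] | None = None
) -> StrCatalog:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["scaffold", "start0", "end", "motif", "period", "n_repeats"],
        dtype={"scaffold": str},
    )
    loci = [
        StrLocus(r.scaffold, int(r.start0) + 1, int(r.end), r.motif, int(r.period), int(r.n_repeats))
        for r in df.itertuples()
    ]
    if genome_lengths is None:
        genome_lengths = {
            s: int(g["end"].max()) for s, g in df.groupby("scaffold")
        }
    return StrCatalog(loci=loci, genome_lengths=dict(genome_lengths))


def write_hipstr_regions(catalog: StrCatalog, path: str | Path) -> None:
    """HipSTR-style regions file: scaffold, start, end, period, n_repeats, name."""
    with open(path, "w") as fh:
        for loc in catalog.loci:
            fh.write(
                f"{loc.scaffold}\t{loc.start}\t{loc.end}\t{loc.period}\t"
                f"{loc.n_repeats}\t{loc.locus_id}\n"
            )
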