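"""Build labelled bags and localization-validation sets from peaks + genome.

Positives are the called peaks; negatives are sampled from the non-peak
territory of peak-carrying genes, matched in number and length to the
positives so that condition-specific expression does not leak into the
labels.  Two validation constructions probe localization:

* *peak-margin* sequences: 600 nt straddling a peak boundary, 300 nt inside
  and 300 nt outside, so the modification is expected in one known half;
* *centered-site* sequences: 601 nt with a base-resolution modified
  nucleotide at offset 300.

All interval logic is 0-based half-open (BED convention).  5'/3' are defined
on the transcript strand: for a minus-strand peak the genomic-left margin is
the 3' margin, and extracted sequences are reverse-complemented before T→U.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .bagging import Bag, clean_sequence, reverse_complement


@dataclass(frozen=True)
class Region:
    """Genomic interval, 0-based half-open, with strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    id: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"region {self.id or '?'}: require 0 <= start < end, got "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in "+-":
            raise ValueError(f"region {self.id or '?'}: strand must be + or -")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Region") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class MarginSequence:
    """600-nt sequence straddling a peak boundary in transcript orientation.

    ``side`` says which peak end the margin was taken from; ``expected_half``
    is where the modification should sit: the second (3') half for a
    five-prime margin, the first (5') half for a three-prime margin.
    """

    sequence: str
    side: str  # five_prime | three_prime
    expected_half: str  # first | second
    peak_id: str
    region: Region

    def __post_init__(self) -> None:
        if len(self.sequence) != 600:
            raise ValueError("margin sequence must be exactly 600 nt")
        expect = "second" if self.side == "five_prime" else "first"
        if self.expected_half != expect:
            raise ValueError(f"{self.side} margin must expect the {expect} half")


@dataclass(frozen=True)
class CenteredSiteSequence:
    """601-nt sequence with a known modified nucleotide at offset 300."""

    sequence: str
    site_offset: int
    site_id: str
    region: Region | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != 2 * self.site_offset + 1:
            raise ValueError("site must sit at the central offset")


def load_regions(path: str | Path) -> list[Region]:
    """Read BED3/BED6 intervals; strand defaults to '+' when absent."""
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else f"{path}:{lineno}"
            strand = fields[5] if len(fields) > 5 else "+"
            try:
                regions.append(Region(fields[0], start, end, strand, name))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return regions


def write_regions(regions: Sequence[Region], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.id or '.'}\t0\t{r.strand}\n")


def _fetch(genome: Mapping[str, str], region: Region) -> str:
    """Strand-aware sequence over a region; genome values index 0-based."""
    try:
        chrom = genome[region.chrom]
    except KeyError as exc:
        raise KeyError(f"chromosome {region.chrom!r} not in genome") from exc
    if region.end > len(chrom):
        raise ValueError(
            f"region {region.id or '?'} [{region.start},{region.end}) exceeds "
            f"{region.chrom} length {len(chrom)}"
        )
    seq = str(chrom[region.start : region.end]).upper()
    if region.strand == "-":
        seq = reverse_complement(seq.replace("T", "U"))
    return clean_sequence(seq)


def open_genome(path: str | Path) -> Mapping[str, str]:
    """Open an (indexed) FASTA as a chromosome-name → sequence mapping."""
    from pyfaidx import Fasta

    return Fasta(str(path), sequence_always_upper=True)


def extract_sequences(regions: Sequence[Region], genome: Mapping[str, str], labels: int | Sequence[int] = 1) -> list[Bag]:
    """Extract strand-aware bag sequences (minus strand reverse-complemented,
    T aliased to U)."""
    if isinstance(labels, int):
        labels = [labels] * len(regions)
    return [
        Bag(id=r.id or f"{r.chrom}:{r.start}-{r.end}", sequence=_fetch(genome, r), label=lab, source_region=r)
        for r, lab in zip(regions, labels)
    ]


def build_negatives(
    gene_regions: Sequence[Region],
    peaks: Sequence[Region],
    target_count: int,
    target_lengths: Sequence[int],
    rng: np.random.Generator,
) -> list[Region]:
    """Sample negative regions from non-peak territory of peak-carrying genes.

    Lengths are drawn from the positive-length multiset so negatives match the
    positives in width distribution; emitted regions never intersect a peak.
    Source windows are sampled without replacement where possible.
    """
    # non-peak sub-intervals per gene, restricted to genes overlapping >= 1 peak
    free: list[tuple[Region, int, int]] = []
    for gene in gene_regions:
        touching = [p for p in peaks if p.overlaps(gene)]
        if not touching:
            continue  # only peak-carrying genes contribute
        cut = [(gene.start, gene.end)]
        for p in sorted(touching, key=lambda p: p.start):
            nxt = []
            for a, b in cut:
                if p.end <= a or p.start >= b:
                    nxt.append((a, b))
                else:
                    if a < p.start:
                        nxt.append((a, p.start))
                    if p.end < b:
                        nxt.append((p.end, b))
            cut = nxt
        free.extend((gene, a, b) for a, b in cut)

    lengths = list(target_lengths)
    if len(lengths) < target_count:
        raise ValueError("need at least target_count target lengths")
    chosen = rng.choice(len(lengths), size=target_count, replace=False)

    out: list[Region] = []
    used: set[tuple[str, int, int]] = set()
    shortfall = 0
    for n, li in enumerate(chosen):
        length = int(lengths[int(li)])
        slots = [(g, a, b) for g, a, b in free if b - a >= length]
        placed = False
        if slots:
            for _ in range(200):  # rejection-sample a fresh window
                g, a, b = slots[int(rng.integers(0, len(slots)))]
                s = int(rng.integers(a, b - length + 1))
                key = (g.chrom, s, s + length)
                if key in used and len(used) < 10_000:
                    continue
                used.add(key)
                out.append(Region(g.chrom, s, s + length, g.strand, f"neg_{n}"))
                placed = True
                break
        if not placed:
            shortfall += 1
    if shortfall:
        raise ValueError(
            f"insufficient non-peak territory: {shortfall}/{target_count} "
            "negative regions could not be placed"
        )
    return out


def build_peak_margin_set(
    peaks: Sequence[Region],
    genome: Mapping[str, str],
    flank: int = 300,
) -> list[MarginSequence]:
    """600-nt margins straddling each peak boundary (300 in / 300 out).

    For a +strand peak [a, b): the 5' margin covers [a-300, a+300) and the 3'
    margin [b-300, b+300).  Margins of minus-strand peaks mirror this in
    transcript orientation.  Peaks shorter than ``flank`` or margins running
    off-chromosome are skipped with a warning.
    """
    out: list[MarginSequence] = []
    skipped = 0
    for peak in peaks:
        if len(peak) < flank:
            skipped += 1
            continue
        a, b = peak.start, peak.end
        if peak.strand == "+":
            pairs = [("five_prime", a - flank, a + flank), ("three_prime", b - flank, b + flank)]
        else:
            pairs = [("five_prime", b - flank, b + flank), ("three_prime", a - flank, a + flank)]
        for side, s, e in pairs:
            if s < 0 or e > len(genome[peak.chrom]):
                skipped += 1
                continue
            region = Region(peak.chrom, s, e, peak.strand, f"{peak.id}_{side}")
            out.append(
                MarginSequence(
                    sequence=_fetch(genome, region),
                    side=side,
                    expected_half="second" if side == "five_prime" else "first",
                    peak_id=peak.id,
                    region=region,
                )
            )
    if skipped:
        warnings.warn(f"build_peak_margin_set: skipped {skipped} short or out-of-bounds margins")
    return out


def build_centered_site_set(
    sites: Sequence[Region],
    genome: Mapping[str, str],
    flank: int = 300,
) -> list[CenteredSiteSequence]:
    """(2*flank + 1)-nt sequences with a single-nucleotide site at the center.

    Sites too close to a chromosome edge are skipped with a warning.
    """
    out: list[CenteredSiteSequence] = []
    skipped = 0
    for site in sites:
        if len(site) != 1:
            raise ValueError(f"site {site.id or '?'} is not single-nucleotide")
        p = site.start
        if p - flank < 0 or p + flank + 1 > len(genome[site.chrom]):
            skipped += 1
            continue
        region = Region(site.chrom, p - flank, p + flank + 1, site.strand, site.id)
        out.append(
            CenteredSiteSequence(
                sequence=_fetch(genome, region),
                site_offset=flank,
                site_id=site.id,
                region=region,
            )
        )
    if skipped:
        warnings.warn(f"build_centered_site_set: skipped {skipped} sites near chromosome edges")
    return out
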