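"""Synthetic immunoprecipitation-peak data with known planted sites.

Emulates the structure of FRIP-seq-derived training data: positive bags are
variable-width sequences carrying at least one occurrence of a short
degenerate motif around a fixed modified base (recorded as ground truth);
wide positives (> 400 nt) carry several occurrences, mirroring wide peaks
formed by clustered sites.  Negatives are length-matched background
sequences with no exact motif occurrence, optionally seeded with
one-mismatch decoys that emulate near-motif false positives.  Everything is
reproducible from a single seed, so training, localization and attribution
are all testable without downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .bagging import ALPHABET, Bag
from .genomic_datasets import CenteredSiteSequence

#: degenerate 6-mer: R A G A C U with the fixed G (index 2) as the modified
#: base analog; degeneracy keeps localization non-trivial
DEFAULT_MOTIF: tuple[tuple[str, ...], ...] = (
    ("A", "G"), ("A",), ("G",), ("A",), ("C",), ("U",),
)
#: offset of the fixed modified base within the motif
MOTIF_SITE_INDEX = 2


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters.

    Bag lengths are uniform over ``[min_length, max_length]`` (default
    200-600 nt, so roughly half the bags exceed the 400-nt cropping
    threshold); ``frac_wide`` optionally fixes the fraction longer than
    400 nt.  ``background`` gives mononucleotide frequencies in A, C, G, U
    order.  ``decoy_rate`` is the probability that a negative carries a
    one-mismatch decoy of the motif.
    """

    n_pos: int = 200
    n_neg: int = 200
    min_length: int = 200
    max_length: int = 600
    frac_wide: float | None = None
    motif: tuple[tuple[str, ...], ...] = DEFAULT_MOTIF
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    decoy_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be positive")
        if not 50 <= self.min_length <= self.max_length:
            raise ValueError("need 50 <= min_length <= max_length")
        if len(self.motif) >= self.min_length:
            raise ValueError("motif must be shorter than the minimum bag length")
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")
        # a motif whose every position admits every letter cannot be excluded
        # from the background, making negatives infeasible
        if all(len(set(p)) >= 4 for p in self.motif):
            raise ValueError("motif matches everything; negatives are infeasible")


@dataclass(frozen=True)
class PlantedSite:
    """Ground-truth record: the fixed modified base of one planted motif."""

    bag_id: str
    offset: int  # offset of the modified base within the bag
    motif_start: int
    motif_seq: str


def _match_at(seq: str, motif: Sequence[tuple[str, ...]], i: int) -> bool:
    return all(seq[i + j] in allowed for j, allowed in enumerate(motif))


def scan_motif(seq: str, motif: Sequence[tuple[str, ...]]) -> list[int]:
    """All start offsets where the degenerate motif matches exactly."""
    m = len(motif)
    return [i for i in range(len(seq) - m + 1) if _match_at(seq, motif, i)]


def _background(length: int, spec: SyntheticSpec, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(ALPHABET), size=length, p=spec.background))


def _sample_motif(motif: Sequence[tuple[str, ...]], rng: np.random.Generator) -> str:
    return "".join(allowed[int(rng.integers(len(allowed)))] for allowed in motif)


def _sample_length(spec: SyntheticSpec, rng: np.random.Generator) -> int:
    if spec.frac_wide is None:
        return int(rng.integers(spec.min_length, spec.max_length + 1))
    if rng.random() < spec.frac_wide:
        lo, hi = max(401, spec.min_length), spec.max_length
    else:
        lo, hi = spec.min_length, min(400, spec.max_length)
    return int(rng.integers(lo, hi + 1))


def generate(spec: SyntheticSpec) -> tuple[list[Bag], list[PlantedSite]]:
    """Generate labelled bags plus the truth table of planted site offsets.

    Each positive contains >= 1 exact motif occurrence at a uniformly random
    recorded offset; positives wider than 400 nt carry 2-3 occurrences.
    Negatives are rejection-sampled until motif-free, then optionally receive
    a one-mismatch decoy.
    """
    rng = np.random.default_rng(spec.seed)
    m = len(spec.motif)
    bags: list[Bag] = []
    truth: list[PlantedSite] = []

    for i in range(spec.n_pos):
        bag_id = f"pos_{i}"
        length = _sample_length(spec, rng)
        seq = list(_background(length, spec, rng))
        n_occ = 1 if length <= 400 else int(rng.integers(2, 4))
        starts: list[int] = []
        for _ in range(200):
            s = int(rng.integers(0, length - m + 1))
            if all(abs(s - t) >= m for t in starts):
                starts.append(s)
            if len(starts) == n_occ:
                break
        for s in sorted(starts):
            planted = _sample_motif(spec.motif, rng)
            seq[s : s + m] = planted
            truth.append(PlantedSite(bag_id, s + MOTIF_SITE_INDEX, s, planted))
        bags.append(Bag(id=bag_id, sequence="".join(seq), label=1))

    for i in range(spec.n_neg):
        length = _sample_length(spec, rng)
        for attempt in range(1000):
            seq = _background(length, spec, rng)
            if not scan_motif(seq, spec.motif):
                break
        else:
            raise RuntimeError(
                "could not sample a motif-free negative; the motif is too "
                "degenerate for the requested lengths"
            )
        if rng.random() < spec.decoy_rate:
            for _ in range(100):
                decoy = list(_sample_motif(spec.motif, rng))
                j = int(rng.integers(m))
                wrong = [ch for ch in ALPHABET if ch not in spec.motif[j]]
                decoy[j] = wrong[int(rng.integers(len(wrong)))]
                s = int(rng.integers(0, length - m + 1))
                cand = seq[:s] + "".join(decoy) + seq[s + m :]
                if not scan_motif(cand, spec.motif):
                    seq = cand
                    break
        bags.append(Bag(id=f"neg_{i}", sequence=seq, label=0))
    return bags, truth


def make_centered_eval(
    truth: Sequence[PlantedSite],
    spec: SyntheticSpec,
    flank: int = 300,
) -> list[CenteredSiteSequence]:
    """Centered-site evaluation sequences of length ``2*flank + 1``.

    One sequence per bag with a planted site: the recorded motif is placed so
    its fixed modified base sits exactly at the central offset, inside a
    freshly drawn motif-free background (re-drawn until the planted
    occurrence is the only exact match).  A unique reference site is what
    makes the signed-distance distribution of the top-attention instance
    interpretable; bags can carry several planted sites, so reusing the bag
    context would put additional true sites inside the validation window.
    """
    rng = np.random.default_rng(spec.seed + 1)
    m = len(spec.motif)
    seen: set[str] = set()
    out: list[CenteredSiteSequence] = []
    for site in truth:
        if site.bag_id in seen:  # one evaluation sequence per bag
            continue
        seen.add(site.bag_id)
        start = flank - MOTIF_SITE_INDEX
        for _ in range(1000):
            background = _background(2 * flank + 1, spec, rng)
            seq = background[:start] + site.motif_seq + background[start + m :]
            if scan_motif(seq, spec.motif) == [start]:
                out.append(
                    CenteredSiteSequence(sequence=seq, site_offset=flank, site_id=site.bag_id)
                )
                break
        else:
            raise RuntimeError("could not draw a motif-free background")
    return out


def write_dataset(
    bags: Sequence[Bag],
    truth: Sequence[PlantedSite],
    out_dir: str | Path,
    prefix: str = "synthetic",
) -> dict[str, Path]:
    """Write FASTA + labels TSV + truth BED, ingestible by the other modules."""
    from .bagging import write_bags

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / f"{prefix}.fa"
    labels = out_dir / f"{prefix}_labels.tsv"
    bed = out_dir / f"{prefix}_truth.bed"
    write_bags(bags, fasta, labels)
    with open(bed, "w") as fh:
        for s in truth:
            fh.write(f"{s.bag_id}\t{s.offset}\t{s.offset + 1}\t{s.motif_seq}\t0\t+\n")
    return {"fasta": fasta, "labels": labels, "truth": bed}
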