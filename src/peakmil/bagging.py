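"""Bags, instances and one-hot encoding for multi-instance sequence learning.

An immunoprecipitation peak (or a matched negative region) is treated as a
labelled *bag* of overlapping fixed-length windows (*instances*).  A sliding
window of length ``c`` with stride ``s`` over a bag of length ``l`` yields
``ceil((l - c) / s) + 1`` instances; the label is attached to the bag only —
at least one instance of a positive bag is presumed to carry the modification
signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

ALPHABET = "ACGU"
#: channel order of the one-hot encoding: A, C, G, U
CHANNEL_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}
_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


class AlphabetError(ValueError):
    """A sequence contains a letter outside {A, C, G, U, T, N}."""


def clean_sequence(sequence: str) -> str:
    """Upper-case a nucleotide string and alias T to U.

    Raises :class:`AlphabetError` naming the first offending position if any
    character outside ``{A, C, G, U, T, N}`` remains.
    """
    seq = sequence.upper().replace("T", "U")
    for i, ch in enumerate(seq):
        if ch not in "ACGUN":
            raise AlphabetError(
                f"invalid nucleotide {ch!r} at position {i} (alphabet is A/C/G/U/T/N)"
            )
    return seq


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def encode_onehot(sequence: str) -> np.ndarray:
    """One-hot encode an RNA string into an L x 4 matrix (channels A, C, G, U).

    ``T`` is treated as ``U``; ``N`` becomes an all-zero row (no information).
    """
    seq = clean_sequence(sequence)
    out = np.zeros((len(seq), 4), dtype=np.float32)
    for i, ch in enumerate(seq):
        if ch != "N":
            out[i, CHANNEL_INDEX[ch]] = 1.0
    return out


def decode_onehot(matrix: np.ndarray) -> str:
    """Inverse of :func:`encode_onehot`; all-zero rows decode to ``N``."""
    matrix = np.asarray(matrix)
    letters = []
    for row in matrix:
        if row.sum() == 0:
            letters.append("N")
        else:
            letters.append(ALPHABET[int(np.argmax(row))])
    return "".join(letters)


@dataclass(frozen=True)
class InstanceConfig:
    """Windowing and augmentation parameters.

    Parameters
    ----------
    window_length:
        Instance length ``c`` in nucleotides (default 50).
    stride:
        Step ``s`` of the sliding window (default 10); ``1 <= s <= c``.
    crop_threshold:
        Bags longer than this (default 400 nt) are randomly cropped during
        augmented training.
    crop_fraction:
        Fraction of the bag retained by a crop (default 3/4).
    """

    window_length: int = 50
    stride: int = 10
    crop_threshold: int = 400
    crop_fraction: float = 0.75

    def __post_init__(self) -> None:
        if self.window_length < 1:
            raise ValueError("window_length must be a positive integer")
        if not 1 <= self.stride <= self.window_length:
            raise ValueError("stride must satisfy 1 <= stride <= window_length")
        if not 0.0 < self.crop_fraction <= 1.0:
            raise ValueError("crop_fraction must be in (0, 1]")
        if self.crop_fraction * self.crop_threshold < self.window_length:
            raise ValueError(
                "crop_fraction * crop_threshold must be >= window_length so a "
                "cropped bag still holds at least one full window"
            )

    def n_instances(self, bag_length: int) -> int:
        """``ceil((l - c) / s) + 1`` for a bag of length ``l``."""
        if bag_length < self.window_length:
            raise ValueError("bag shorter than window")
        return -(-(bag_length - self.window_length) // self.stride) + 1


@dataclass
class Bag:
    """A labelled nucleotide sequence — the MIL unit.

    ``label`` is 1 for a peak (modification-containing) bag, 0 for a negative.
    ``source_region`` optionally records the genomic interval of origin.
    """

    id: str
    sequence: str
    label: int
    source_region: object | None = None

    def __post_init__(self) -> None:
        self.sequence = clean_sequence(self.sequence)
        if self.label not in (0, 1):
            raise ValueError(f"bag {self.id}: label must be 0 or 1, got {self.label!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class InstanceSet:
    """Ordered one-hot windows cut from one bag.

    ``instances`` is K x c x 4; ``mask`` marks real instances (1) versus
    padding (0); ``spans`` are 0-based half-open offsets within the bag.
    """

    instances: np.ndarray
    mask: np.ndarray
    spans: list[tuple[int, int]]
    bag_id: str = ""
    label: int | None = None

    @property
    def n_instances(self) -> int:
        return int(self.mask.sum())


def instance_spans(bag_length: int, cfg: InstanceConfig) -> list[tuple[int, int]]:
    """Window offsets for a bag of the given length.

    Window ``i`` starts at ``min(i*s, l - c)``: when ``l - c`` is not a
    multiple of ``s`` the final window is clamped so it ends exactly at ``l``,
    keeping every instance on real sequence.
    """
    c, s = cfg.window_length, cfg.stride
    k = cfg.n_instances(bag_length)
    return [(min(i * s, bag_length - c), min(i * s, bag_length - c) + c) for i in range(k)]


def make_instances(bag: Bag, cfg: InstanceConfig) -> InstanceSet:
    """Cut a bag into its one-hot instance set."""
    l = len(bag)
    if l < cfg.window_length:
        raise ValueError(
            f"bag {bag.id!r} has length {l} < window_length {cfg.window_length}"
        )
    spans = instance_spans(l, cfg)
    onehot = encode_onehot(bag.sequence)
    inst = np.stack([onehot[a:b] for a, b in spans])
    return InstanceSet(
        instances=inst,
        mask=np.ones(len(spans), dtype=np.float32),
        spans=spans,
        bag_id=bag.id,
        label=bag.label,
    )


def random_crop(bag: Bag, cfg: InstanceConfig, rng: np.random.Generator) -> Bag:
    """Per-epoch random-cropping augmentation.

    Bags longer than ``crop_threshold`` are replaced by a uniformly placed
    contiguous fragment of ``floor(crop_fraction * l)`` nucleotides with the
    same label; shorter bags pass through unchanged.  Wide peaks arise from
    several modified nucleotides in proximity, so a 3/4-length fragment of a
    positive still contains at least one site; any fragment of a negative
    remains negative.
    """
    l = len(bag)
    if l <= cfg.crop_threshold:
        return bag
    new_len = int(cfg.crop_fraction * l)
    start = int(rng.integers(0, l - new_len + 1))
    return Bag(
        id=bag.id,
        sequence=bag.sequence[start : start + new_len],
        label=bag.label,
        source_region=bag.source_region,
    )


def batch_pad(sets: Sequence[InstanceSet]) -> tuple[np.ndarray, np.ndarray, list[list[tuple[int, int]]]]:
    """Pad instance sets to a common K with all-zero instances and mask 0.

    Returns ``(instances, mask, spans)`` with shapes (B, Kmax, c, 4) and
    (B, Kmax).  Downstream pooling must ignore mask-0 entries.
    """
    if not sets:
        return (
            np.zeros((0, 0, 0, 4), dtype=np.float32),
            np.zeros((0, 0), dtype=np.float32),
            [],
        )
    widths = {s.instances.shape[1] for s in sets}
    if len(widths) != 1:
        raise ValueError(f"mixed window lengths in batch: {sorted(widths)}")
    c = widths.pop()
    kmax = max(s.instances.shape[0] for s in sets)
    batch = np.zeros((len(sets), kmax, c, 4), dtype=np.float32)
    mask = np.zeros((len(sets), kmax), dtype=np.float32)
    spans: list[list[tuple[int, int]]] = []
    for i, s in enumerate(sets):
        k = s.instances.shape[0]
        batch[i, :k] = s.instances
        mask[i, :k] = s.mask
        spans.append(list(s.spans))
    return batch, mask, spans


# ---------------------------------------------------------------------------
# FASTA ingest

def _iter_fasta(path: Path) -> Iterable[tuple[str, str]]:
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    yield name, "".join(chunks)
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name is not None:
        yield name, "".join(chunks)


def read_bags(
    fasta: str | Path,
    labels: str | Path | dict[str, int] | None = None,
    *,
    default_label: int | None = None,
    max_n_fraction: float = 0.10,
) -> list[Bag]:
    """Read bags from a FASTA file plus a two-column TSV ``id<TAB>label``.

    Alternatively pass ``default_label`` to label every record (e.g. separate
    positive and negative FASTA files).  Records with more than
    ``max_n_fraction`` ambiguous (N) positions are rejected with a warning.
    """
    if isinstance(labels, (str, Path)):
        table: dict[str, int] = {}
        with open(labels) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                parts = line.split()
                if len(parts) != 2 or parts[1] not in ("0", "1"):
                    raise ValueError(f"{labels}:{lineno}: expected 'id<TAB>0|1'")
                table[parts[0]] = int(parts[1])
        labels = table

    bags = []
    for name, seq in _iter_fasta(Path(fasta)):
        if labels is not None:
            if name not in labels:
                raise KeyError(f"no label for FASTA record {name!r}")
            label = labels[name]
        elif default_label is not None:
            label = default_label
        else:
            raise ValueError("provide a label table or a default_label")
        seq = clean_sequence(seq)
        if seq and seq.count("N") / len(seq) > max_n_fraction:
            warnings.warn(
                f"bag {name!r}: {seq.count('N')}/{len(seq)} ambiguous positions "
                f"exceed the {max_n_fraction:.0%} threshold; skipped"
            )
            continue
        bags.append(Bag(id=name, sequence=seq, label=label))
    return bags


def write_bags(bags: Sequence[Bag], fasta: str | Path, labels: str | Path) -> None:
    """Write bags as FASTA plus an ``id<TAB>label`` TSV (the ingest format)."""
    with open(fasta, "w") as ff, open(labels, "w") as lf:
        for bag in bags:
            ff.write(f">{bag.id}\n{bag.sequence}\n")
            lf.write(f"{bag.id}\t{bag.label}\n")
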