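"""Genome binning and read counting.

The genome is partitioned into fixed-size, non-overlapping, half-open bins
(default 200 bp).  Reads are assigned to bins after shifting their 5' mapping
coordinate downstream by roughly half the average fragment length (default
75 bp), because ChIP'd proteins sit near fragment midpoints while sequencing
starts at fragment ends.  Counting all marks over all bins yields one
bins x marks integer matrix per chromosome — the observation sequences of
the segmentation HMM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "BinningScheme",
    "CountMatrix",
    "make_bins",
    "shifted_position",
    "count_reads",
    "count_positions",
    "read_chrom_sizes",
    "read_count_matrix",
    "write_count_matrix",
]


@dataclass(frozen=True)
class BinningScheme:
    """A partition of every chromosome into half-open, non-overlapping bins.

    With ``offset == 0`` bin ``i`` of a chromosome covers
    ``[i * bin_size, (i + 1) * bin_size)``; the last bin is truncated at the
    chromosome end.  With ``offset > 0`` the first bin covers ``[0, offset)``
    and regular bins follow, so every base pair still belongs to exactly one
    bin (this is the shifted scheme used for bin-offset robustness checks).
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    bin_size: int = 200
    offset: int = 0

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError(f"bin_size must be >= 1, got {self.bin_size}")
        if not (0 <= self.offset < self.bin_size):
            raise ValueError(
                f"offset must satisfy 0 <= offset < bin_size, got {self.offset}"
            )
        if len(self.chrom_names) != len(set(self.chrom_names)):
            raise ValueError("duplicate chromosome names")
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths length mismatch")
        for name, length in zip(self.chrom_names, self.chrom_lengths):
            if length < 1:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    def chrom_length(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[self.chrom_names.index(chrom)]
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def n_bins(self, chrom: str) -> int:
        length = self.chrom_length(chrom)
        if self.offset == 0:
            return math.ceil(length / self.bin_size)
        if length <= self.offset:
            return 1
        return 1 + math.ceil((length - self.offset) / self.bin_size)

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.chrom_names)

    def bin_edges(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Start/end coordinates (half-open) of every bin of ``chrom``."""
        length = self.chrom_length(chrom)
        if self.offset == 0:
            starts = np.arange(0, length, self.bin_size, dtype=np.int64)
        else:
            starts = np.concatenate(
                [[0], np.arange(self.offset, length, self.bin_size, dtype=np.int64)]
            )
        ends = np.minimum(starts + self.bin_size, length)
        if self.offset > 0:
            ends[0] = min(self.offset, length)
        return starts, ends

    def bin_widths(self, chrom: str) -> np.ndarray:
        starts, ends = self.bin_edges(chrom)
        return ends - starts

    def bin_index(self, positions: np.ndarray | int) -> np.ndarray | int:
        """Bin index of 0-based base-pair position(s)."""
        pos = np.asarray(positions)
        if self.offset == 0:
            idx = pos // self.bin_size
        else:
            idx = np.where(pos < self.offset, 0, 1 + (pos - self.offset) // self.bin_size)
        return idx if idx.ndim else int(idx)


def make_bins(
    chrom_sizes: Mapping[str, int], bin_size: int = 200, offset: int = 0
) -> BinningScheme:
    """Build the binning scheme for a set of chromosome lengths."""
    return BinningScheme(
        chrom_names=tuple(chrom_sizes),
        chrom_lengths=tuple(int(v) for v in chrom_sizes.values()),
        bin_size=int(bin_size),
        offset=int(offset),
    )


@dataclass
class CountMatrix:
    """Per-chromosome bins x marks matrices of non-negative integer read counts."""

    scheme: BinningScheme
    mark_names: tuple[str, ...]
    counts: dict[str, np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        self.mark_names = tuple(self.mark_names)
        if len(self.mark_names) != len(set(self.mark_names)):
            raise ValueError("mark names must be unique")
        if set(self.counts) != set(self.scheme.chrom_names):
            raise ValueError("count matrices do not match the scheme's chromosomes")
        for chrom in self.scheme.chrom_names:
            mat = np.asarray(self.counts[chrom])
            if mat.ndim != 2 or mat.shape != (self.scheme.n_bins(chrom), len(self.mark_names)):
                raise ValueError(
                    f"chromosome {chrom!r}: expected shape "
                    f"({self.scheme.n_bins(chrom)}, {len(self.mark_names)}), got {mat.shape}"
                )
            if np.any(mat < 0):
                raise ValueError(f"negative counts on chromosome {chrom!r}")
            if not np.issubdtype(mat.dtype, np.integer):
                if not np.all(mat == np.floor(mat)):
                    raise ValueError(f"non-integer counts on chromosome {chrom!r}")
                mat = mat.astype(np.int64)
            self.counts[chrom] = np.ascontiguousarray(mat, dtype=np.int64)

    @property
    def n_marks(self) -> int:
        return len(self.mark_names)

    def matrices(self) -> list[np.ndarray]:
        """Per-chromosome matrices in scheme order (the HMM's sequences)."""
        return [self.counts[c] for c in self.scheme.chrom_names]

    def stacked(self) -> np.ndarray:
        """All bins of all chromosomes stacked in scheme order."""
        return np.concatenate(self.matrices(), axis=0)


def shifted_position(read_start_5prime: int, strand: str, shift: int, chrom_length: int) -> int:
    """Fragment-midpoint proxy of a read: 5' coordinate shifted 5'->3'.

    Plus-strand reads move downstream, minus-strand reads upstream; the result
    is clamped into ``[0, chrom_length - 1]`` so edge reads are kept.
    """
    if shift < 0:
        raise ValueError("shift must be >= 0")
    if strand == "+":
        pos = read_start_5prime + shift
    elif strand == "-":
        pos = read_start_5prime - shift
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    return int(min(max(pos, 0), chrom_length - 1))


def count_positions(
    positions: Mapping[str, Mapping[str, np.ndarray]],
    scheme: BinningScheme,
    mark_names: Iterable[str] | None = None,
) -> CountMatrix:
    """Bin pre-shifted base-pair positions into a count matrix.

    ``positions[mark][chrom]`` is an array of 0-based coordinates, each already
    shifted; useful to re-bin the same reads under a different offset.
    """
    marks = tuple(mark_names) if mark_names is not None else tuple(positions)
    counts: dict[str, np.ndarray] = {}
    for chrom in scheme.chrom_names:
        nb = scheme.n_bins(chrom)
        mat = np.zeros((nb, len(marks)), dtype=np.int64)
        for j, mark in enumerate(marks):
            pos = np.asarray(positions[mark].get(chrom, np.empty(0, dtype=np.int64)))
            if pos.size:
                if pos.min() < 0 or pos.max() >= scheme.chrom_length(chrom):
                    raise ValueError(f"position outside chromosome {chrom!r}")
                mat[:, j] = np.bincount(scheme.bin_index(pos), minlength=nb)
        counts[chrom] = mat
    return CountMatrix(scheme=scheme, mark_names=marks, counts=counts)


def count_reads(
    bam_paths: Mapping[str, str],
    scheme: BinningScheme,
    shift: int | Mapping[str, int] = 75,
    mapq_min: int = 0,
    allow_missing_chroms: bool = False,
) -> CountMatrix:
    """Count shifted read positions per bin and mark from indexed BAM files.

    Unmapped, secondary and supplementary records and reads below ``mapq_min``
    are skipped; for paired-end data only first-in-pair reads are counted so
    each fragment contributes once under single-end shift semantics.
    """
    import pysam

    marks = tuple(bam_paths)
    positions: dict[str, dict[str, np.ndarray]] = {m: {} for m in marks}
    for mark in marks:
        per_mark_shift = shift[mark] if isinstance(shift, Mapping) else int(shift)
        with pysam.AlignmentFile(str(bam_paths[mark]), "rb") as bam:
            refs = set(bam.references)
            for chrom in scheme.chrom_names:
                if chrom not in refs:
                    if allow_missing_chroms:
                        positions[mark][chrom] = np.empty(0, dtype=np.int64)
                        continue
                    raise ValueError(
                        f"chromosome {chrom!r} absent from alignment file for mark {mark!r}"
                    )
                length = scheme.chrom_length(chrom)
                pos_list: list[int] = []
                for read in bam.fetch(chrom):
                    if read.is_unmapped or read.is_secondary or read.is_supplementary:
                        continue
                    if read.mapping_quality < mapq_min:
                        continue
                    if read.is_paired and not read.is_read1:
                        continue
                    if read.is_reverse:
                        pos_list.append(
                            shifted_position(read.reference_end - 1, "-", per_mark_shift, length)
                        )
                    else:
                        pos_list.append(
                            shifted_position(read.reference_start, "+", per_mark_shift, length)
                        )
                positions[mark][chrom] = np.asarray(pos_list, dtype=np.int64)
    return count_positions(positions, scheme, marks)


def read_chrom_sizes(path: str) -> dict[str, int]:
    """Read a two-column (name, length) chromosome sizes file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, length = line.split()[:2]
            sizes[name] = int(length)
    return sizes


def write_count_matrix(cm: CountMatrix, path: str) -> None:
    """Write the TSV dialect: chrom, start, end, then one column per mark."""
    frames = []
    for chrom in cm.scheme.chrom_names:
        starts, ends = cm.scheme.bin_edges(chrom)
        df = pd.DataFrame({"chrom": chrom, "start": starts, "end": ends})
        for j, mark in enumerate(cm.mark_names):
            df[mark] = cm.counts[chrom][:, j]
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_count_matrix(path: str) -> CountMatrix:
    """Read a count matrix TSV, reconstructing the binning scheme."""
    df = pd.read_csv(path, sep="\t")
    required = ["chrom", "start", "end"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"count matrix must start with columns {required}")
    marks = tuple(df.columns[3:])
    if not marks:
        raise ValueError("count matrix has no mark columns")
    if len(df) == 0:
        raise ValueError("empty matrix")
    values = df[list(marks)].to_numpy()
    if np.any(values < 0):
        raise ValueError("negative count entries")
    if not np.issubdtype(values.dtype, np.integer):
        raise ValueError("non-integer count entries")

    chrom_order = list(dict.fromkeys(df["chrom"]))
    widths = (df["end"] - df["start"]).to_numpy()
    bin_size = int(widths.max())
    first = df.groupby("chrom", sort=False).first()
    first_ends = first["end"]
    offsets = {int(e) % bin_size if int(e) != bin_size else 0 for e in first_ends}
    if len(offsets) != 1:
        raise ValueError("inconsistent bin offsets across chromosomes")
    offset = offsets.pop()
    sizes = {c: int(df.loc[df["chrom"] == c, "end"].max()) for c in chrom_order}
    scheme = make_bins(sizes, bin_size=bin_size, offset=offset)

    counts: dict[str, np.ndarray] = {}
    for chrom in chrom_order:
        sub = df[df["chrom"] == chrom]
        starts, ends = scheme.bin_edges(chrom)
        if not (
            np.array_equal(sub["start"].to_numpy(), starts)
            and np.array_equal(sub["end"].to_numpy(), ends)
        ):
            raise ValueError(f"bins of chromosome {chrom!r} do not form a valid scheme")
        counts[chrom] = sub[list(marks)].to_numpy(dtype=np.int64)
    return CountMatrix(scheme=scheme, mark_names=marks, counts=counts)
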