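"""Genome coordinate bookkeeping: chromosome layouts, fixed-width window
grids and per-window fraction-of-bases-covered statistics.

All coordinates are 0-based, half-open. Windows tile each chromosome
exactly: every window has ``end - start == window_size`` except possibly
the last one per chromosome, whose fraction-covered values are normalised
by the true (shorter) window length.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

SUBGENOME_LABELS = ("a", "f", "none")


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    subgenome: str = "none"

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name}: length must be > 0")
        if self.subgenome not in SUBGENOME_LABELS:
            raise ValueError(f"chromosome {self.name}: bad subgenome label "
                             f"{self.subgenome!r}")


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes of one genome, with optional subgenome labels.

    Hybrid genomes label every chromosome "a" or "f"; ancestral genomes use
    "none".
    """

    genome_id: str
    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in layout")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return {c.name: c.length for c in self.chromosomes}

    def length(self, name: str) -> int:
        return self.lengths[name]

    def label(self, name: str) -> str:
        for c in self.chromosomes:
            if c.name == name:
                return c.subgenome
        raise KeyError(name)

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)

    @classmethod
    def from_tsv(cls, path: str | Path, genome_id: str | None = None) -> "GenomeLayout":
        """Read a layout from a 2- or 3-column TSV (name, length[, subgenome])."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if df.shape[1] < 2:
            raise ValueError("layout TSV needs at least (name, length) columns")
        chroms = []
        for _, row in df.iterrows():
            label = str(row[2]) if df.shape[1] > 2 else "none"
            chroms.append(Chromosome(str(row[0]), int(row[1]), label))
        return cls(genome_id or Path(path).stem, tuple(chroms))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for c in self.chromosomes:
                fh.write(f"{c.name}\t{c.length}\t{c.subgenome}\n")


class WindowGrid:
    """Fixed-width half-open windows tiling every chromosome of a layout.

    Windows are stored as flat arrays in layout order then window index; the
    window holding position p on a chromosome has index floor(p/window_size).
    """

    def __init__(self, layout: GenomeLayout, window_size: int):
        if window_size <= 0:
            raise ValueError("window_size must be > 0")
        if not layout.chromosomes:
            raise ValueError("empty layout")
        self.layout = layout
        self.window_size = int(window_size)

        chrom_idx, index, starts, ends = [], [], [], []
        offsets = {}
        total = 0
        for ci, chrom in enumerate(layout.chromosomes):
            n = -(-chrom.length // window_size)  # ceil division
            offsets[chrom.name] = total
            total += n
            s = np.arange(n, dtype=np.int64) * window_size
            e = np.minimum(s + window_size, chrom.length)
            chrom_idx.append(np.full(n, ci, dtype=np.int64))
            index.append(np.arange(n, dtype=np.int64))
            starts.append(s)
            ends.append(e)
        self.chrom_idx = np.concatenate(chrom_idx)
        self.index = np.concatenate(index)
        self.start = np.concatenate(starts)
        self.end = np.concatenate(ends)
        self._offsets = offsets

    @property
    def n_windows(self) -> int:
        return int(self.start.size)

    def __len__(self) -> int:
        return self.n_windows

    def chrom_names(self) -> np.ndarray:
        names = np.array(self.layout.names, dtype=object)
        return names[self.chrom_idx]

    def chrom_slice(self, name: str) -> slice:
        """Flat-index slice of the windows of one chromosome."""
        off = self._offsets[name]
        n = -(-self.layout.length(name) // self.window_size)
        return slice(off, off + n)

    def window_of(self, chromosome: str, pos: int) -> int:
        """Flat index of the window containing (chromosome, pos)."""
        if not 0 <= pos < self.layout.length(chromosome):
            raise ValueError(f"position {pos} outside {chromosome}")
        return self._offsets[chromosome] + pos // self.window_size

    def lengths(self) -> np.ndarray:
        return self.end - self.start

    def subgenome_labels(self) -> np.ndarray:
        labels = np.array([c.subgenome for c in self.layout.chromosomes], dtype=object)
        return labels[self.chrom_idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chromosome": self.chrom_names(),
                "index": self.index,
                "start": self.start,
                "end": self.end,
            }
        )


def make_windows(layout: GenomeLayout, window_size: int) -> WindowGrid:
    """Tile every chromosome of ``layout`` with half-open windows."""
    return WindowGrid(layout, window_size)


def depth_from_intervals(
    intervals: Iterable[tuple[int, int]], chrom_length: int
) -> np.ndarray:
    """Per-base depth on one chromosome from half-open aligned intervals.

    depth(x) = number of intervals containing x.
    """
    diff = np.zeros(chrom_length + 1, dtype=np.int32)
    for start, end in intervals:
        if not (0 <= start < end <= chrom_length):
            raise ValueError(f"interval [{start},{end}) outside chromosome "
                             f"of length {chrom_length}")
        diff[start] += 1
        diff[end] -= 1
    return np.cumsum(diff[:-1]).astype(np.int32)


def depth_from_interval_arrays(
    starts: np.ndarray, ends: np.ndarray, chrom_length: int
) -> np.ndarray:
    """Vectorised variant of :func:`depth_from_intervals` for large inputs."""
    if starts.size and (starts.min() < 0 or ends.max() > chrom_length or
                        (starts >= ends).any()):
        raise ValueError("interval outside chromosome bounds")
    diff = np.zeros(chrom_length + 1, dtype=np.int32)
    np.add.at(diff, starts, 1)
    np.add.at(diff, ends, -1)
    return np.cumsum(diff[:-1]).astype(np.int32)


def fraction_covered(
    depth: np.ndarray, grid: WindowGrid, chromosome: str, depth_threshold: int = 1
) -> np.ndarray:
    """Per-window fraction of bases at depth >= threshold for one chromosome.

    Trailing partial windows are normalised by their true length.
    """
    length = grid.layout.length(chromosome)
    if depth.size != length:
        raise ValueError(
            f"depth track length {depth.size} != {chromosome} length {length}")
    if depth_threshold < 1:
        raise ValueError("depth_threshold must be >= 1")
    sl = grid.chrom_slice(chromosome)
    covered = (depth >= depth_threshold).astype(np.int64)
    sums = np.add.reduceat(covered, grid.start[sl])
    return sums / grid.lengths()[sl]


@dataclass
class CoverageTrack:
    """Per-window fraction-of-bases-covered over a full window grid.

    ``intervals`` optionally retains the per-chromosome aligned intervals the
    track was computed from, enabling base-level pooling across datasets.
    """

    dataset_id: str
    grid: WindowGrid
    values: np.ndarray
    depth_threshold: int = 1
    intervals: dict[str, np.ndarray] | None = None  # chrom -> (n,2) array

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.grid.n_windows:
            raise ValueError("one value per window required")
        if ((self.values < 0) | (self.values > 1)).any():
            raise ValueError("fractions must lie in [0,1]")

    @classmethod
    def from_intervals(
        cls,
        dataset_id: str,
        grid: WindowGrid,
        intervals: dict[str, np.ndarray],
        depth_threshold: int = 1,
    ) -> "CoverageTrack":
        """Build a track from per-chromosome (n,2) interval arrays."""
        values = np.zeros(grid.n_windows)
        for name in grid.layout.names:
            iv = np.asarray(intervals.get(name, np.empty((0, 2), dtype=np.int64)))
            iv = iv.reshape(-1, 2)
            depth = depth_from_interval_arrays(
                iv[:, 0], iv[:, 1], grid.layout.length(name))
            values[grid.chrom_slice(name)] = fraction_covered(
                depth, grid, name, depth_threshold)
        keep = {n: np.asarray(v).reshape(-1, 2) for n, v in intervals.items()}
        return cls(dataset_id, grid, values, depth_threshold, keep)

    def to_frame(self) -> pd.DataFrame:
        df = self.grid.to_frame()
        df["fraction_covered"] = self.values
        return df

    def to_bedgraph(self, path: str | Path) -> None:
        df = self.to_frame()
        df[["chromosome", "start", "end", "fraction_covered"]].to_csv(
            path, sep="\t", header=False, index=False)


def read_bedgraph_intervals(path: str | Path) -> dict[str, np.ndarray]:
    """Read bedGraph records into per-chromosome (n,2) interval arrays.

    Intervals with value > 0 count as aligned; 0-value records are skipped.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"])
    out: dict[str, np.ndarray] = {}
    for chrom, sub in df[df["value"] > 0].groupby("chrom"):
        out[str(chrom)] = sub[["start", "end"]].to_numpy(dtype=np.int64)
    return out
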