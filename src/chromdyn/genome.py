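"""Core genomic containers: genome description, window grids, regions.

All coordinates are 0-based, half-open ``[start, end)`` (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeSpec",
    "WindowGrid",
    "Region",
    "merge_intervals",
    "interval_overlap_bp",
    "regions_to_frame",
    "frame_to_regions",
]


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome names and lengths (bp) of a (toy or real) assembly."""

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.names) == 0:
            raise ValueError("genome must have at least one chromosome")
        if len(self.names) != len(set(self.names)):
            raise ValueError("chromosome names must be unique")
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths differ in length")
        for n, l in zip(self.names, self.lengths):
            if int(l) <= 0:
                raise ValueError(f"chromosome {n!r} has non-positive length {l}")

    @property
    def sizes(self) -> dict[str, int]:
        return dict(zip(self.names, (int(l) for l in self.lengths)))

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))


@dataclass
class WindowGrid:
    """Ordered fixed-size windows over a genome.

    Windows tile each chromosome from 0 with the given step; a terminal
    window that would extend past the chromosome end is dropped.  With
    ``step == size`` the grid is a non-overlapping tiling; with
    ``step < size`` windows overlap (sliding grid).
    """

    genome: GenomeSpec
    size: int
    step: int
    frame: pd.DataFrame = field(repr=False)  # columns chrom, start, end
    _chrom_bounds: dict[str, tuple[int, int]] = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.frame)

    def chrom_slice(self, chrom: str) -> slice:
        lo, hi = self._chrom_bounds[chrom]
        return slice(lo, hi)

    def n_windows(self, chrom: str) -> int:
        lo, hi = self._chrom_bounds[chrom]
        return hi - lo

    def windows_containing(self, chrom: str, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Index range [lo, hi) of windows containing each position.

        A window [w, w+size) contains pos iff w <= pos < w+size, i.e. the
        window index i (start = i*step) satisfies
        ceil((pos-size+1)/step) <= i <= floor(pos/step).
        """
        pos = np.asarray(pos, dtype=np.int64)
        nwin = self.n_windows(chrom)
        lo = np.maximum(0, -(-(pos - self.size + 1) // self.step))
        hi = np.minimum(nwin, pos // self.step + 1)
        return lo, hi

    def windows_overlapping(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """Index range [lo, hi) of windows with >= 1 bp overlap with [start, end)."""
        if chrom not in self._chrom_bounds:
            raise KeyError(f"unknown chromosome {chrom!r}")
        nwin = self.n_windows(chrom)
        lo = max(0, -(-(start - self.size + 1) // self.step))
        hi = min(nwin, -(-end // self.step))
        return int(lo), int(max(lo, hi))

    def global_index(self, chrom: str, local: int) -> int:
        return self._chrom_bounds[chrom][0] + local


def make_windows(genome: GenomeSpec, size: int, step: int | None = None) -> WindowGrid:
    """Build a window grid (sliding if step < size, tiling if step == size)."""
    if step is None:
        step = size
    if size <= 0 or step <= 0:
        raise ValueError("window size and step must be positive")
    if step > size:
        raise ValueError(f"step ({step}) must not exceed window size ({size})")
    chroms, starts = [], []
    bounds: dict[str, tuple[int, int]] = {}
    offset = 0
    for name, length in zip(genome.names, genome.lengths):
        n = 0 if length < size else (int(length) - size) // step + 1
        chroms.append(np.repeat(name, n))
        starts.append(np.arange(n, dtype=np.int64) * step)
        bounds[name] = (offset, offset + n)
        offset += n
    start = np.concatenate(starts) if starts else np.array([], dtype=np.int64)
    frame = pd.DataFrame(
        {
            "chrom": pd.Categorical(np.concatenate(chroms) if chroms else [], categories=genome.names),
            "start": start,
            "end": start + size,
        }
    )
    return WindowGrid(genome=genome, size=size, step=step, frame=frame, _chrom_bounds=bounds)


@dataclass(frozen=True)
class Region:
    """A genomic interval produced by merging enriched windows."""

    chrom: str
    start: int
    end: int
    n_windows: int = 1

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end


def regions_to_frame(regions: list[Region]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "n_windows": [r.n_windows for r in regions],
        }
    )


def frame_to_regions(frame: pd.DataFrame) -> list[Region]:
    nw = frame["n_windows"] if "n_windows" in frame.columns else np.ones(len(frame), dtype=int)
    return [
        Region(str(c), int(s), int(e), int(n))
        for c, s, e, n in zip(frame["chrom"], frame["start"], frame["end"], nw)
    ]


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of strictly overlapping intervals; book-ended intervals stay apart."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s < out[-1][1]:  # strict overlap only (half-open)
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def interval_overlap_bp(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    """Total overlap (bp) between two lists of sorted, non-overlapping intervals."""
    total = 0
    i = j = 0
    a = sorted(a)
    b = sorted(b)
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            total += e - s
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return total
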