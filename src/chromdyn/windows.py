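"""Window-level ChIP signal processing.

Tag counting with fragment-shift, library-size normalization, the
pseudo-count log2 enrichment score, replicate averaging, threshold calling
and merging of enriched windows into regions.

The enrichment statistic for a window is

    log2((n_ChIP + c) / (n_input + c)),    c = 8 by default,

computed after scaling every library to the mean total read count across
samples.  The pseudo-count shrinks enrichments toward zero where coverage
is low, so sparse windows cannot produce extreme ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import Region, WindowGrid, make_windows

__all__ = [
    "CountMatrix",
    "EnrichmentTrack",
    "make_windows",
    "count_tags",
    "normalize_libraries",
    "enrichment",
    "enrichment_track",
    "average_replicates",
    "call_enriched_windows",
    "merge_regions",
    "score_region",
    "score_regions",
]

DEFAULT_PSEUDOCOUNT = 8.0
DEFAULT_SHIFT = 60
DEFAULT_CUTOFF = 1.5


@dataclass
class CountMatrix:
    """Per-window counts, one column per sample, plus raw library totals.

    ``totals`` are the pre-normalization library sizes used for scaling;
    after :func:`normalize_libraries` the stored counts are non-integer but
    ``totals`` still records the raw sizes.
    """

    grid: WindowGrid
    data: pd.DataFrame
    totals: dict[str, float]
    normalized: bool = False

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class EnrichmentTrack:
    """Per-window log2 ChIP/input enrichment for one mark in one stage."""

    grid: WindowGrid
    values: np.ndarray
    mark: str = ""
    stage: str = ""
    n_replicates: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.grid.n:
            raise ValueError("track length does not match grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("enrichment values must be finite")


def count_tags(
    tags: dict[str, pd.DataFrame],
    grid: WindowGrid,
    shift: int = DEFAULT_SHIFT,
    strand_aware: bool = True,
) -> CountMatrix:
    """Count shifted tag positions per window for each sample.

    ``tags`` maps sample name to a DataFrame with columns ``chrom``,
    ``pos`` and ``strand`` ('+'/'-').  Each tag is moved ``shift`` bases in
    its 3' direction (plus-strand tags downstream, minus-strand tags
    upstream; uniformly downstream if ``strand_aware`` is False) and then
    assigned to every window containing the shifted position — on a sliding
    grid one tag can fall into more than one window.  Tags on chromosomes
    absent from the grid raise an error.
    """
    n = grid.n
    columns: dict[str, np.ndarray] = {}
    totals: dict[str, float] = {}
    known = set(grid.genome.names)
    for sample, df in tags.items():
        counts = np.zeros(n, dtype=float)
        bad = sorted(set(df["chrom"].astype(str)) - known)
        if bad:
            raise ValueError(f"sample {sample!r} has tags on unknown chromosomes: {bad}")
        for chrom, sub in df.groupby("chrom", observed=True):
            chrom = str(chrom)
            pos = sub["pos"].to_numpy(dtype=np.int64)
            if strand_aware:
                sign = np.where(sub["strand"].to_numpy() == "-", -1, 1)
            else:
                sign = 1
            shifted = pos + sign * shift
            length = grid.genome.sizes[chrom]
            shifted = np.clip(shifted, 0, length - 1)
            lo, hi = grid.windows_containing(chrom, shifted)
            offset = grid.chrom_slice(chrom).start
            for a, b in zip(lo, hi):
                if a < b:
                    counts[offset + a : offset + b] += 1.0
        columns[sample] = counts
        totals[sample] = float(len(df))
    data = pd.DataFrame(columns, index=np.arange(n))
    return CountMatrix(grid=grid, data=data, totals=totals, normalized=False)


def normalize_libraries(counts: CountMatrix) -> CountMatrix:
    """Scale each sample to the mean total library size across samples.

    Column ``j`` is multiplied by ``mean(totals) / totals[j]``, so all
    post-normalization library sizes equal the mean raw size.  A sample
    with zero total is an error.
    """
    totals = pd.Series(counts.totals, dtype=float)
    if (totals <= 0).any():
        zero = list(totals.index[totals <= 0])
        raise ValueError(f"samples with zero library total: {zero}")
    factors = totals.mean() / totals
    data = counts.data.mul(factors, axis=1)
    return replace(counts, data=data, normalized=True)


def enrichment(
    chip: np.ndarray | float,
    input_: np.ndarray | float,
    pseudo: float = DEFAULT_PSEUDOCOUNT,
) -> np.ndarray | float:
    """log2((chip + pseudo) / (input + pseudo)); finite for all counts >= 0."""
    chip = np.asarray(chip, dtype=float)
    input_ = np.asarray(input_, dtype=float)
    if np.any(chip < 0) or np.any(input_ < 0):
        raise ValueError("counts must be non-negative")
    if pseudo <= 0:
        raise ValueError("pseudo-count must be positive")
    out = np.log2((chip + pseudo) / (input_ + pseudo))
    return float(out) if out.ndim == 0 else out


def enrichment_track(
    counts: CountMatrix,
    chip_samples: list[str],
    input_sample: str,
    pseudo: float = DEFAULT_PSEUDOCOUNT,
    mark: str = "",
    stage: str = "",
) -> EnrichmentTrack:
    """Normalize, score each ChIP replicate against input, and average."""
    norm = counts if counts.normalized else normalize_libraries(counts)
    inp = norm.data[input_sample].to_numpy()
    tracks = [
        EnrichmentTrack(
            grid=counts.grid,
            values=enrichment(norm.data[s].to_numpy(), inp, pseudo),
            mark=mark,
            stage=stage,
        )
        for s in chip_samples
    ]
    return average_replicates(tracks)


def average_replicates(tracks: list[EnrichmentTrack]) -> EnrichmentTrack:
    """Arithmetic mean of per-window log2 enrichments across replicates."""
    if not tracks:
        raise ValueError("no tracks to average")
    first = tracks[0]
    for t in tracks[1:]:
        if t.grid is not first.grid and not t.grid.frame.equals(first.grid.frame):
            raise ValueError("tracks are on different window grids")
    values = np.mean([t.values for t in tracks], axis=0)
    return EnrichmentTrack(
        grid=first.grid,
        values=values,
        mark=first.mark,
        stage=first.stage,
        n_replicates=sum(t.n_replicates for t in tracks),
    )


def call_enriched_windows(track: EnrichmentTrack, cutoff: float = DEFAULT_CUTOFF) -> pd.DataFrame:
    """Windows with enrichment >= cutoff (inclusive), as a chrom/start/end/value frame."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    mask = track.values >= cutoff
    out = track.grid.frame.loc[mask, ["chrom", "start", "end"]].copy()
    out["value"] = track.values[mask]
    return out.reset_index(drop=True)


def merge_regions(windows: pd.DataFrame) -> list[Region]:
    """Merge coordinate-overlapping windows into maximal regions.

    Half-open intervals: book-ended windows (end == next start) share no
    base and are NOT merged.  Output regions are sorted and non-overlapping;
    ``n_windows`` records how many constituent windows each region absorbed.
    """
    regions: list[Region] = []
    for chrom, sub in windows.groupby("chrom", observed=True, sort=False):
        sub = sub.sort_values(["start", "end"])
        cur_s = cur_e = None
        cur_n = 0
        for s, e in zip(sub["start"], sub["end"]):
            s, e = int(s), int(e)
            if cur_s is None:
                cur_s, cur_e, cur_n = s, e, 1
            elif s < cur_e:
                cur_e = max(cur_e, e)
                cur_n += 1
            else:
                regions.append(Region(str(chrom), cur_s, cur_e, cur_n))
                cur_s, cur_e, cur_n = s, e, 1
        if cur_s is not None:
            regions.append(Region(str(chrom), cur_s, cur_e, cur_n))
    return regions


def score_region(region: Region, track: EnrichmentTrack) -> float:
    """Region score = maximum enrichment over all windows overlapping the region."""
    lo, hi = track.grid.windows_overlapping(region.chrom, region.start, region.end)
    if hi <= lo:
        raise ValueError(f"region {region} overlaps no window of the track grid")
    offset = track.grid.chrom_slice(region.chrom).start
    return float(np.max(track.values[offset + lo : offset + hi]))


def score_regions(regions: list[Region], track: EnrichmentTrack) -> np.ndarray:
    return np.array([score_region(r, track) for r in regions])
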