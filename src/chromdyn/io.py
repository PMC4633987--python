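"""Readers and writers for the plain-text formats the pipeline touches.

BED (0-based, half-open) is the canonical interval dialect; tracks are
serialized as bedGraph, gene models as a refGene-like tab table with a
header, window counts as tab-separated tables, configuration as YAML.
All writers round-trip through their readers.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genome import GenomeSpec, Region, WindowGrid, make_windows
from .windows import CountMatrix, EnrichmentTrack

__all__ = [
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_gene_models",
    "write_gene_models",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_count_table",
    "write_count_table",
    "read_tags_bed",
    "load_config",
    "save_config",
]


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3+ file; validates coordinates and sorts (warning if unsorted)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: expected >= 3 tab-separated fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise ValueError(f"{path}:{ln}: invalid interval [{start}, {end})")
            rows.append(
                {
                    "chrom": parts[0],
                    "start": start,
                    "end": end,
                    "name": parts[3] if len(parts) > 3 else ".",
                }
            )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    sorted_df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    if not df.reset_index(drop=True).equals(sorted_df):
        warnings.warn(f"{path}: records were not sorted; sorted on load", stacklevel=2)
    return sorted_df


def write_bed(intervals: pd.DataFrame | list[Region], path: str | Path) -> None:
    if isinstance(intervals, list):
        intervals = pd.DataFrame(
            {
                "chrom": [r.chrom for r in intervals],
                "start": [r.start for r in intervals],
                "end": [r.end for r in intervals],
            }
        )
    cols = [c for c in ("chrom", "start", "end", "name", "score", "strand") if c in intervals.columns]
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(track: EnrichmentTrack, path: str | Path) -> None:
    frame = track.grid.frame[["chrom", "start", "end"]].copy()
    frame["value"] = track.values
    frame.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def read_bedgraph(path: str | Path, genome: GenomeSpec) -> EnrichmentTrack:
    """Read a fixed-window bedGraph back into a track on its inferred grid.

    Records must be non-overlapping per chromosome for a tiling grid; a
    sliding grid (step < size) is inferred from the start spacing.  Every
    grid window must be covered exactly once.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"])
    sizes = (df["end"] - df["start"]).unique()
    if len(sizes) != 1:
        raise ValueError(f"{path}: windows are not fixed-size")
    size = int(sizes[0])
    steps = set()
    for _, sub in df.groupby("chrom", observed=True):
        s = np.diff(np.sort(sub["start"].to_numpy()))
        steps.update(np.unique(s).tolist())
        if np.any(s == 0):
            raise ValueError(f"{path}: duplicate/overlapping records")
    step = int(min(steps)) if steps else size
    if step < size:
        pass  # sliding grid: overlap is expected
    grid = make_windows(genome, size, step)
    values = np.full(grid.n, np.nan)
    for chrom, sub in df.groupby("chrom", observed=True):
        off = grid.chrom_slice(str(chrom)).start
        idx = sub["start"].to_numpy() // step
        if np.any(sub["start"].to_numpy() % step != 0):
            raise ValueError(f"{path}: starts not aligned to step {step}")
        values[off + idx] = sub["value"].to_numpy()
    if np.isnan(values).any():
        raise ValueError(f"{path}: not every grid window has a value")
    return EnrichmentTrack(grid=grid, values=values)


REFGENE_COLUMNS = ["name", "chrom", "strand", "txStart", "txEnd", "exonStarts", "exonEnds"]


def _parse_exon_list(s: str) -> list[int]:
    return [int(x) for x in str(s).rstrip(",").split(",") if x != ""]


def read_gene_models(path: str | Path) -> pd.DataFrame:
    """Read a refGene-like tab table (header with at least REFGENE_COLUMNS).

    Exon coordinate lists are comma-separated; the trailing comma of the
    UCSC dialect is tolerated.  Transcripts sharing a name are kept as
    separate rows (grouping happens at exon-union time).
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(REFGENE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = set(df["strand"]) - {"+", "-"}
    if bad:
        raise ValueError(f"{path}: malformed strand values {sorted(bad)}")
    df = df.copy()
    df["exonStarts"] = df["exonStarts"].map(_parse_exon_list)
    df["exonEnds"] = df["exonEnds"].map(_parse_exon_list)
    for i, (ss, ee) in enumerate(zip(df["exonStarts"], df["exonEnds"])):
        if len(ss) != len(ee):
            raise ValueError(f"{path}: row {i}: exonStarts/exonEnds length mismatch")
        if any(s >= e for s, e in zip(ss, ee)):
            raise ValueError(f"{path}: row {i}: empty or inverted exon")
    df["tss"] = np.where(df["strand"] == "+", df["txStart"], df["txEnd"])
    return df


def write_gene_models(genes: pd.DataFrame, path: str | Path) -> None:
    out = genes.copy()
    out["exonStarts"] = out["exonStarts"].map(lambda xs: ",".join(str(x) for x in xs) + ",")
    out["exonEnds"] = out["exonEnds"].map(lambda xs: ",".join(str(x) for x in xs) + ",")
    out[REFGENE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_chrom_sizes(path: str | Path) -> GenomeSpec:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return GenomeSpec(names=tuple(df["chrom"].astype(str)), lengths=tuple(df["length"].astype(int)))


def write_chrom_sizes(genome: GenomeSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        for n, l in zip(genome.names, genome.lengths):
            fh.write(f"{n}\t{l}\n")


def write_count_table(counts: CountMatrix, path: str | Path) -> None:
    frame = counts.grid.frame[["chrom", "start", "end"]].copy()
    for c in counts.data.columns:
        frame[c] = counts.data[c].to_numpy()
    frame.to_csv(path, sep="\t", index=False)


def read_count_table(path: str | Path, genome: GenomeSpec) -> CountMatrix:
    df = pd.read_csv(path, sep="\t")
    sizes = (df["end"] - df["start"]).unique()
    if len(sizes) != 1:
        raise ValueError(f"{path}: windows are not fixed-size")
    size = int(sizes[0])
    starts = np.sort(df["start"].unique())
    step = int(np.diff(starts).min()) if len(starts) > 1 else size
    grid = make_windows(genome, size, step)
    if len(df) != grid.n:
        raise ValueError(f"{path}: table rows do not match the inferred grid")
    samples = [c for c in df.columns if c not in ("chrom", "start", "end")]
    data = df[samples].reset_index(drop=True)
    totals = {c: float(data[c].sum()) for c in samples}
    return CountMatrix(grid=grid, data=data, totals=totals, normalized=False)


def read_tags_bed(path: str | Path) -> pd.DataFrame:
    """Read tag positions from BED6: 5' end of each alignment, per strand."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{ln}: tag BED needs 6 fields (strand required)")
            start, end, strand = int(parts[1]), int(parts[2]), parts[5]
            if strand not in "+-":
                raise ValueError(f"{path}:{ln}: bad strand {strand!r}")
            rows.append(
                {"chrom": parts[0], "pos": start if strand == "+" else end - 1, "strand": strand}
            )
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand"])


def save_config(config, path: str | Path) -> None:
    """Serialize a (dataclass) configuration to YAML, seed included."""
    d = dataclasses.asdict(config) if dataclasses.is_dataclass(config) else dict(config)

    def clean(v):
        if isinstance(v, tuple):
            return [clean(x) for x in v]
        if isinstance(v, dict):
            return {k: clean(x) for k, x in v.items()}
        if isinstance(v, (np.integer, np.floating)):
            return v.item()
        return v

    with open(path, "w") as fh:
        yaml.safe_dump(clean(d), fh, sort_keys=True)


def load_config(path: str | Path, cls):
    with open(path) as fh:
        d = yaml.safe_load(fh)
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - fields
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    for k, v in d.items():
        if isinstance(v, list):
            d[k] = tuple(tuple(x) if isinstance(x, list) else x for x in v)
    return cls(**d)
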