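"""Enhancer identification and three-state classification.

Putative enhancers are merged H3K4me1-enriched regions that (i) share no
base with an annotated promoter and (ii) are depleted of H3K4me3.  Each
candidate is then classified by its H3K27ac and H3K27me3 region scores:

* ``active``  — H3K27ac at or above the cutoff (acetylated);
* ``poised``  — H3K27ac below but H3K27me3 at or above the cutoff;
* ``primed``  — neither modification above its cutoff (H3K4me1 only).

Classification is a total function: every candidate receives exactly one
state.  Regions carrying both H3K27ac and H3K27me3 above cutoff are called
active (acetylation is the activity mark) and flagged for audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import Region
from .windows import DEFAULT_CUTOFF, EnrichmentTrack, score_region, score_regions

__all__ = [
    "PromoterSet",
    "EnhancerSet",
    "define_promoters",
    "identify_putative_enhancers",
    "classify_enhancers",
    "state_counts",
]

STATES = ("active", "primed", "poised")
DEFAULT_K4ME3_DEPLETED = 1.0


@dataclass
class PromoterSet:
    """Non-overlapping TSS-flanking intervals, each tied to >= 1 gene.

    ``frame`` columns: chrom, start, end, gene, strand, tss.
    """

    frame: pd.DataFrame
    flank: int = 1000

    def __len__(self) -> int:
        return len(self.frame)

    def intervals(self, chrom: str) -> np.ndarray:
        sub = self.frame[self.frame["chrom"] == chrom]
        return sub[["start", "end"]].to_numpy(dtype=np.int64)


@dataclass
class EnhancerSet:
    """Classified enhancer regions for one differentiation stage.

    ``frame`` columns: chrom, start, end, n_windows, score_k4me1,
    score_k4me3, score_k27ac, score_k27me3, state, dual_mark (audit flag
    for regions above cutoff in both K27ac and K27me3).
    """

    frame: pd.DataFrame
    stage: str = ""
    cutoff: float = DEFAULT_CUTOFF

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def states(self) -> pd.Series:
        return self.frame["state"]

    def regions(self, state: str | None = None) -> list[Region]:
        sub = self.frame if state is None else self.frame[self.frame["state"] == state]
        return [
            Region(str(c), int(s), int(e), int(n))
            for c, s, e, n in zip(sub["chrom"], sub["start"], sub["end"], sub["n_windows"])
        ]


def define_promoters(annotation: pd.DataFrame, flank: int = 1000) -> PromoterSet:
    """Build non-overlapping promoter intervals [TSS - flank, TSS + flank).

    ``annotation`` needs columns chrom, strand, txStart, txEnd, name.  The
    TSS is txStart on the plus strand and txEnd on the minus strand.
    Intervals are processed in coordinate order; an interval overlapping a
    previously accepted one is dropped (first kept wins).
    """
    bad = set(annotation["strand"]) - {"+", "-"}
    if bad:
        raise ValueError(f"malformed strand values: {sorted(bad)}")
    tss = np.where(annotation["strand"] == "+", annotation["txStart"], annotation["txEnd"])
    prom = pd.DataFrame(
        {
            "chrom": annotation["chrom"].astype(str),
            "start": np.maximum(0, tss - flank),
            "end": tss + flank,
            "gene": annotation["name"].astype(str),
            "strand": annotation["strand"].astype(str),
            "tss": tss,
        }
    ).sort_values(["chrom", "start", "end"], kind="mergesort")
    keep = []
    last_end: dict[str, int] = {}
    for idx, row in prom.iterrows():
        if row["start"] >= last_end.get(row["chrom"], -1):
            keep.append(idx)
            last_end[row["chrom"]] = row["end"]
    return PromoterSet(frame=prom.loc[keep].reset_index(drop=True), flank=flank)


def _overlaps_any(region: Region, intervals: np.ndarray) -> bool:
    if len(intervals) == 0:
        return False
    return bool(np.any((intervals[:, 0] < region.end) & (region.start < intervals[:, 1])))


def identify_putative_enhancers(
    k4me1_regions: list[Region],
    k4me3_track: EnrichmentTrack,
    promoters: PromoterSet,
    k4me3_depleted_cutoff: float = DEFAULT_K4ME3_DEPLETED,
) -> list[Region]:
    """Keep H3K4me1 regions that avoid promoters and lack H3K4me3.

    A single shared base with any promoter interval excludes a region.
    H3K4me3 depletion means region score strictly below the depletion
    cutoff (default 1.0 log2); anything at or above it is excluded.
    """
    by_chrom = {c: promoters.intervals(c) for c in set(r.chrom for r in k4me1_regions)}
    kept = []
    for region in k4me1_regions:
        if _overlaps_any(region, by_chrom[region.chrom]):
            continue
        if score_region(region, k4me3_track) >= k4me3_depleted_cutoff:
            continue
        kept.append(region)
    return kept


def classify_enhancers(
    candidates: list[Region],
    k4me1_track: EnrichmentTrack,
    k27ac_track: EnrichmentTrack,
    k27me3_track: EnrichmentTrack | None,
    k4me3_track: EnrichmentTrack | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    stage: str = "",
) -> EnhancerSet:
    """Score candidates on each mark and assign active/primed/poised.

    Without a K27me3 track the poised state cannot be detected and its
    candidates fall back to primed (the K27me3 score column is NaN).
    """
    if not candidates:
        cols = [
            "chrom", "start", "end", "n_windows", "score_k4me1", "score_k4me3",
            "score_k27ac", "score_k27me3", "state", "dual_mark",
        ]
        return EnhancerSet(frame=pd.DataFrame(columns=cols), stage=stage, cutoff=cutoff)
    k4me1 = score_regions(candidates, k4me1_track)
    k27ac = score_regions(candidates, k27ac_track)
    if k27me3_track is not None:
        k27me3 = score_regions(candidates, k27me3_track)
    else:
        k27me3 = np.full(len(candidates), np.nan)
    k4me3 = (
        score_regions(candidates, k4me3_track)
        if k4me3_track is not None
        else np.full(len(candidates), np.nan)
    )
    ac_pos = k27ac >= cutoff
    me3_pos = np.nan_to_num(k27me3, nan=-np.inf) >= cutoff
    state = np.where(ac_pos, "active", np.where(me3_pos, "poised", "primed"))
    frame = pd.DataFrame(
        {
            "chrom": [r.chrom for r in candidates],
            "start": [r.start for r in candidates],
            "end": [r.end for r in candidates],
            "n_windows": [r.n_windows for r in candidates],
            "score_k4me1": k4me1,
            "score_k4me3": k4me3,
            "score_k27ac": k27ac,
            "score_k27me3": k27me3,
            "state": state,
            "dual_mark": ac_pos & me3_pos,
        }
    )
    return EnhancerSet(frame=frame, stage=stage, cutoff=cutoff)


def state_counts(enhancers: EnhancerSet) -> pd.DataFrame:
    """Counts and fractions of active/primed/poised enhancers."""
    if len(enhancers) == 0:
        raise ValueError("empty enhancer set")
    counts = enhancers.states.value_counts().reindex(STATES, fill_value=0)
    return pd.DataFrame({"count": counts, "fraction": counts / counts.sum()})
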