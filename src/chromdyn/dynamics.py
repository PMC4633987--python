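"""Cross-stage enhancer dynamics.

A stage-A enhancer repertoire is re-scored at its own coordinates in the
tracks of a later stage B and each region is placed in a quadrant of the
(H3K4me1, H3K27ac) plane:

* ``active`` — both marks at or above their cutoffs;
* ``primed`` — H3K4me1 retained, H3K27ac below cutoff;
* ``closed`` — H3K4me1 lost (regions that keep H3K27ac without H3K4me1 are
  counted closed and reported separately in an audit column);
* ``poised`` — only when a target-stage H3K27me3 track is supplied:
  H3K4me1 retained, H3K27ac below cutoff, H3K27me3 above.

Coordinates are fixed at the source stage: regions are not re-called in
the target stage, so boundary drift is deliberately ignored.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import Region, interval_overlap_bp, merge_intervals
from .windows import DEFAULT_CUTOFF, EnrichmentTrack, score_regions

__all__ = [
    "rescore_in_stage",
    "classify_transition",
    "transition_fractions",
    "presence_matrix",
]


def rescore_in_stage(
    regions: list[Region],
    k4me1: EnrichmentTrack,
    k27ac: EnrichmentTrack,
    k27me3: EnrichmentTrack | None = None,
) -> pd.DataFrame:
    """Score fixed regions in another stage's tracks (max over windows)."""
    out = pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "score_k4me1": score_regions(regions, k4me1),
            "score_k27ac": score_regions(regions, k27ac),
        }
    )
    if k27me3 is not None:
        out["score_k27me3"] = score_regions(regions, k27me3)
    return out


def classify_transition(
    k4me1_score: float,
    k27ac_score: float,
    k27me3_score: float | None = None,
    k4me1_cutoff: float = DEFAULT_CUTOFF,
    k27ac_cutoff: float = DEFAULT_CUTOFF,
    k27me3_cutoff: float = DEFAULT_CUTOFF,
) -> str:
    """Quadrant outcome for one region: active, primed, poised or closed.

    Loss of H3K4me1 dominates: a region below the H3K4me1 cutoff is closed
    regardless of acetylation.  Poised requires a K27me3 score.
    """
    if not (np.isfinite(k4me1_score) and np.isfinite(k27ac_score)):
        raise ValueError("scores must be finite")
    if k4me1_score < k4me1_cutoff:
        return "closed"
    if k27ac_score >= k27ac_cutoff:
        return "active"
    if k27me3_score is not None and k27me3_score >= k27me3_cutoff:
        return "poised"
    return "primed"


def transition_fractions(
    source_regions: list[Region],
    target_tracks: dict[str, tuple[EnrichmentTrack, EnrichmentTrack]]
    | dict[str, tuple[EnrichmentTrack, EnrichmentTrack, EnrichmentTrack]],
    k4me1_cutoff: float = DEFAULT_CUTOFF,
    k27ac_cutoff: float = DEFAULT_CUTOFF,
) -> pd.DataFrame:
    """Outcome counts and fractions of one source class in each target stage.

    ``target_tracks`` maps target-stage name to (K4me1, K27ac) or
    (K4me1, K27ac, K27me3) track tuples.  Output rows are target stages;
    columns hold per-outcome counts, fractions (summing to 1 per row) and
    the closed-but-acetylated audit count.
    """
    if not source_regions:
        raise ValueError("empty source enhancer class")
    rows = []
    for stage, tracks in target_tracks.items():
        k4me1, k27ac = tracks[0], tracks[1]
        k27me3 = tracks[2] if len(tracks) > 2 else None
        scored = rescore_in_stage(source_regions, k4me1, k27ac, k27me3)
        outcomes = [
            classify_transition(
                row["score_k4me1"],
                row["score_k27ac"],
                row.get("score_k27me3"),
                k4me1_cutoff,
                k27ac_cutoff,
            )
            for _, row in scored.iterrows()
        ]
        acetyl_retained = int(
            ((scored["score_k4me1"] < k4me1_cutoff) & (scored["score_k27ac"] >= k27ac_cutoff)).sum()
        )
        counts = pd.Series(outcomes).value_counts()
        n = len(outcomes)
        row: dict[str, object] = {"target_stage": stage, "n": n}
        labels = ["active", "primed", "poised", "closed"] if k27me3 is not None else [
            "active", "primed", "closed",
        ]
        for label in labels:
            c = int(counts.get(label, 0))
            row[f"count_{label}"] = c
            row[f"frac_{label}"] = c / n
        row["count_closed_acetyl_retained"] = acetyl_retained
        rows.append(row)
    return pd.DataFrame(rows).set_index("target_stage")


def presence_matrix(region_sets: dict[str, list[Region]]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binary marked/unmarked matrix over the union repertoire, plus Jaccard.

    Rows are the merged union of all stages' regions; an entry is True iff
    the row region overlaps >= 1 called region of that stage.  The second
    frame holds base-level pairwise Jaccard similarities between stages.
    """
    if len(region_sets) < 2:
        raise ValueError("need at least two stages")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for regions in region_sets.values():
        for r in regions:
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    union_rows: list[Region] = []
    for chrom in sorted(by_chrom):
        for s, e in merge_intervals(by_chrom[chrom]):
            union_rows.append(Region(chrom, s, e))

    data = {}
    for stage, regions in region_sets.items():
        stage_ivs = {c: sorted((r.start, r.end) for r in regions if r.chrom == c) for c in by_chrom}
        marked = []
        for row in union_rows:
            ivs = stage_ivs.get(row.chrom, [])
            marked.append(any(s < row.end and row.start < e for s, e in ivs))
        data[stage] = marked
    matrix = pd.DataFrame(
        data, index=[f"{r.chrom}:{r.start}-{r.end}" for r in union_rows]
    )

    stages = list(region_sets)
    jac = pd.DataFrame(np.eye(len(stages)), index=stages, columns=stages)
    merged = {
        st: {
            c: merge_intervals([(r.start, r.end) for r in region_sets[st] if r.chrom == c])
            for c in by_chrom
        }
        for st in stages
    }
    for i, a in enumerate(stages):
        for b in stages[i + 1 :]:
            inter = sum(
                interval_overlap_bp(merged[a][c], merged[b][c]) for c in by_chrom
            )
            size_a = sum(e - s for c in by_chrom for s, e in merged[a][c])
            size_b = sum(e - s for c in by_chrom for s, e in merged[b][c])
            union = size_a + size_b - inter
            val = inter / union if union else 0.0
            jac.loc[a, b] = jac.loc[b, a] = val
    return matrix, jac
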