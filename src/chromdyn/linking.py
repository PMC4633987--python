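"""Expression quantification and enhancer-promoter assignment.

Expression per gene is the sum of exonic reads, normalized to the mean
library size and to the average unique exonic length across genes, then
binarized into expressed/silent at a threshold placed at the antimode of
the bimodal log-scale distribution (overridable).

Enhancers are assigned to promoters in two passes: active enhancers first,
each to its nearest promoter (midpoint-to-TSS distance) within 500 kb;
promoters that received an active enhancer are then withheld when primed
and poised enhancers are assigned.  Enhancers with no eligible promoter in
range stay unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .enhancers import EnhancerSet, PromoterSet
from .genome import merge_intervals

__all__ = [
    "exonic_union_length",
    "quantify_expression",
    "bimodal_threshold",
    "binarize_expression",
    "assign_enhancers",
    "expression_by_class",
    "expression_by_active_count",
]

DEFAULT_MAX_DISTANCE = 500_000
CLASS_PRIORITY = ("active", "primed", "poised")


def exonic_union_length(exons: list[tuple[int, int]]) -> int:
    """Unique exonic bases: length of the union of all exon intervals."""
    if not exons:
        raise ValueError("gene has no exons")
    return sum(e - s for s, e in merge_intervals(list(exons)))


def quantify_expression(
    counts: pd.DataFrame,
    exonic_lengths: pd.Series,
) -> pd.DataFrame:
    """Library- and length-normalize per-gene exonic read counts.

    ``counts`` is genes x samples.  Normalized value for gene g in sample s:
    count * (mean library total / total_s) * (mean exonic length / length_g).
    Returns a frame with per-sample normalized columns plus ``exonic_length``.
    """
    lengths = exonic_lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive exonic length")
    totals = counts.sum(axis=0).astype(float)
    if (totals <= 0).any():
        raise ValueError("samples with zero total counts")
    depth_factor = totals.mean() / totals
    length_factor = lengths.mean() / lengths
    norm = counts.mul(depth_factor, axis=1).mul(length_factor, axis=0)
    out = norm.copy()
    out["exonic_length"] = lengths
    return out


def bimodal_threshold(values: np.ndarray, grid_points: int = 512) -> float:
    """Antimode of a bimodal distribution of log2(x + 1) expression values.

    A Gaussian KDE is evaluated on a grid; the threshold is the density
    minimum between the two highest local maxima, mapped back to the
    original scale.  Falls back to the midpoint of the log-scale range when
    the density has a single mode.
    """
    logv = np.log2(np.asarray(values, dtype=float) + 1.0)
    if np.ptp(logv) == 0:
        return float(2.0 ** logv[0] - 1.0)
    kde = gaussian_kde(logv)
    grid = np.linspace(logv.min(), logv.max(), grid_points)
    dens = kde(grid)
    interior = np.arange(1, grid_points - 1)
    maxima = interior[(dens[interior] > dens[interior - 1]) & (dens[interior] >= dens[interior + 1])]
    if len(maxima) < 2:
        cut = 0.5 * (logv.min() + logv.max())
    else:
        top2 = maxima[np.argsort(dens[maxima])][-2:]
        lo, hi = sorted(top2)
        cut = grid[lo + int(np.argmin(dens[lo : hi + 1]))]
    return float(2.0 ** cut - 1.0)


def binarize_expression(
    expression: pd.Series,
    threshold: float | None = None,
) -> tuple[pd.Series, float]:
    """Classify genes as expressed (value >= threshold) or silent.

    With ``threshold=None`` the cut is placed at the antimode of the
    bimodal log-scale distribution.  Returns (classes, threshold used).
    """
    if threshold is None:
        threshold = bimodal_threshold(expression.to_numpy())
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    classes = pd.Series(
        np.where(expression >= threshold, "expressed", "silent"),
        index=expression.index,
        name="class",
    )
    return classes, float(threshold)


def _nearest_promoter(
    chrom: str,
    midpoint: float,
    promoters: pd.DataFrame,
    eligible: np.ndarray,
    max_distance: float,
) -> int | None:
    """Index of the nearest eligible promoter by |midpoint - TSS|; ties go to
    the promoter with the lower genomic coordinate."""
    sub = promoters[(promoters["chrom"] == chrom) & eligible]
    if len(sub) == 0:
        return None
    dist = np.abs(sub["tss"].to_numpy(dtype=float) - midpoint)
    order = np.lexsort((sub["tss"].to_numpy(), dist))
    best = order[0]
    if dist[best] > max_distance:
        return None
    return int(sub.index[best])


def assign_enhancers(
    enhancers: EnhancerSet,
    promoters: PromoterSet,
    max_distance: int = DEFAULT_MAX_DISTANCE,
) -> pd.DataFrame:
    """Two-pass enhancer-to-promoter assignment with active-first exclusion.

    Returns one row per enhancer: enhancer coordinates, state, assigned
    gene (or <NA>), promoter TSS and distance.  Pass 1 links every active
    enhancer to its nearest promoter within ``max_distance``; those
    promoters are removed from the pool before pass 2 links primed and
    poised enhancers.
    """
    prom = promoters.frame
    consumed = np.zeros(len(prom), dtype=bool)
    ef = enhancers.frame
    genes: list[object] = [pd.NA] * len(ef)
    dists: list[float] = [np.nan] * len(ef)
    tsss: list[float] = [np.nan] * len(ef)

    order_groups = [
        ef.index[ef["state"] == "active"],
        ef.index[ef["state"] != "active"],
    ]
    for pass_no, idxs in enumerate(order_groups):
        eligible = ~consumed if pass_no == 1 else np.ones(len(prom), dtype=bool)
        hit_this_pass = []
        for i in idxs:
            row = ef.loc[i]
            mid = (row["start"] + row["end"]) / 2
            j = _nearest_promoter(str(row["chrom"]), mid, prom, eligible, max_distance)
            if j is None:
                continue
            pos = ef.index.get_loc(i)
            genes[pos] = prom.at[j, "gene"]
            tsss[pos] = prom.at[j, "tss"]
            dists[pos] = abs(mid - prom.at[j, "tss"])
            hit_this_pass.append(j)
        if pass_no == 0:
            consumed[[prom.index.get_loc(j) for j in hit_this_pass]] = True

    out = ef[["chrom", "start", "end", "state"]].copy()
    out["gene"] = pd.array(genes, dtype="string")
    out["tss"] = tsss
    out["distance"] = dists
    return out


def expression_by_class(links: pd.DataFrame, expression: pd.Series) -> pd.DataFrame:
    """Summarize expression by each gene's best-associated enhancer class.

    A gene linked to enhancers of several states is grouped under the
    highest-priority one (active > primed > poised); unlinked genes form
    the "none" group.  Returns group size, median and quartiles.
    """
    rank = {s: i for i, s in enumerate(CLASS_PRIORITY)}
    linked = links.dropna(subset=["gene"])
    best: dict[str, str] = {}
    for gene, state in zip(linked["gene"], linked["state"]):
        if gene not in best or rank[state] < rank[best[gene]]:
            best[gene] = state
    group = pd.Series(
        [best.get(g, "none") for g in expression.index], index=expression.index, name="group"
    )
    rows = []
    for name in list(CLASS_PRIORITY) + ["none"]:
        vals = expression[group == name]
        if len(vals) == 0:
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append({"group": name, "n": len(vals), "q1": q1, "median": med, "q3": q3})
    return pd.DataFrame(rows).set_index("group")


def expression_by_active_count(
    links: pd.DataFrame, expression: pd.Series, max_count: int = 3
) -> pd.DataFrame:
    """Expression summaries grouped by the number of linked active enhancers.

    Counts above ``max_count`` are pooled into the top bin (e.g. "3+").
    """
    active = links[(links["state"] == "active") & links["gene"].notna()]
    counts = active.groupby("gene").size()
    n_active = pd.Series(
        [min(int(counts.get(g, 0)), max_count) for g in expression.index],
        index=expression.index,
    )
    rows = []
    for k in range(max_count + 1):
        vals = expression[n_active == k]
        if len(vals) == 0:
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        label = f"{k}+" if k == max_count else str(k)
        rows.append({"n_active": label, "n_genes": len(vals), "q1": q1, "median": med, "q3": q3})
    return pd.DataFrame(rows).set_index("n_active")
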