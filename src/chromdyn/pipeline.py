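"""End-to-end orchestration on synthetic data.

Runs the whole analysis — simulation, enrichment scoring, enhancer calling
and classification per stage, expression quantification and linking,
cross-stage transition analysis, and heterochromatin-domain segmentation —
and collects the results together with recovery metrics against the
generator's ground truth.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dynamics as dyn
from . import hmm as hc
from . import io as cio
from . import linking as lk
from .enhancers import (
    EnhancerSet,
    classify_enhancers,
    define_promoters,
    identify_putative_enhancers,
    state_counts,
)
from .genome import Region, make_windows
from .simulate import (
    SimulationConfig,
    TruthSet,
    simulate_chip_counts,
    simulate_genome,
    simulate_k9me2_track,
    simulate_rnaseq,
    simulate_truth,
)
from .windows import (
    DEFAULT_CUTOFF,
    EnrichmentTrack,
    call_enriched_windows,
    enrichment_track,
    merge_regions,
)

logger = logging.getLogger("chromdyn")

STAGE_NAMES = (
    "simulate",
    "enrich",
    "call_enhancers",
    "expression",
    "linking",
    "dynamics",
    "heterochromatin",
)


@dataclass
class AnalysisParams:
    """Window, cutoff and assignment parameters of the analysis itself."""

    window_size: int = 1000
    window_step: int = 500
    pseudo: float = 8.0
    k4me1_cutoff: float = DEFAULT_CUTOFF
    k27ac_cutoff: float = DEFAULT_CUTOFF
    k27me3_cutoff: float = DEFAULT_CUTOFF
    k4me3_depleted_cutoff: float = 1.0
    promoter_flank: int = 1000
    max_link_distance: int = 500_000
    hmm_tol: float = 1e-6
    hmm_max_iter: int = 500
    train_chrom: str | None = None  # default: first chromosome
    include_k27me3: bool = True  # False: no K27me3 input, poised calling disabled


@dataclass
class PipelineResult:
    truth: TruthSet
    params: AnalysisParams
    tracks: dict[str, dict[str, EnrichmentTrack]]
    enhancer_sets: dict[str, EnhancerSet]
    state_fractions: dict[str, pd.DataFrame]
    expression: pd.DataFrame  # per-gene normalized values + classes per stage
    expression_threshold: float
    links: dict[str, pd.DataFrame]
    transition_tables: dict[str, pd.DataFrame]  # per source state, stage1 -> later stages
    presence: pd.DataFrame
    jaccard: pd.DataFrame
    hmm_models: dict[str, hc.HmmModel]
    domain_sets: dict[str, hc.DomainSet]
    genome_fractions: dict[str, float]
    domain_venn: pd.DataFrame
    k9_correlations: pd.DataFrame
    closed_enhancer_domain_fraction: float
    closed_enhancer_n: int
    metrics: dict[str, float] = field(default_factory=dict)


def _match_truth_states(enh: EnhancerSet, truth: TruthSet, stage: str) -> pd.DataFrame:
    """Pair each truth enhancer with the called region overlapping it (if any)."""
    called = enh.frame
    rows = []
    for _, t in truth.enhancers.iterrows():
        hit = called[
            (called["chrom"] == t["chrom"])
            & (called["start"] < t["end"])
            & (called["end"] > t["start"])
        ]
        rows.append(
            {
                "id": t["id"],
                "true_state": t[f"state_{stage}"],
                "called_state": hit.iloc[0]["state"] if len(hit) else "closed",
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    sim: SimulationConfig | None = None, params: AnalysisParams | None = None
) -> PipelineResult:
    """Run the complete analysis on a synthetic dataset and score it."""
    sim = sim or SimulationConfig()
    params = params or AnalysisParams()

    logger.info("stage simulate: genome + truth (seed=%d)", sim.seed)
    genome = simulate_genome(sim)
    truth = simulate_truth(genome, sim)
    grid = make_windows(genome, params.window_size, params.window_step)

    logger.info("stage enrich: %d stages x 4 marks on %d windows", len(sim.stages), grid.n)
    marks = ("K4me1", "K4me3", "K27ac", "K27me3") if params.include_k27me3 else (
        "K4me1", "K4me3", "K27ac",
    )
    tracks: dict[str, dict[str, EnrichmentTrack]] = {}
    for stage in sim.stages:
        tracks[stage] = {}
        for mark in marks:
            counts = simulate_chip_counts(truth, genome, mark, stage, sim, grid=grid)
            chip = [c for c in counts.samples if c.startswith(mark)]
            inp = [c for c in counts.samples if c.startswith("input")][0]
            tracks[stage][mark] = enrichment_track(
                counts, chip, inp, pseudo=params.pseudo, mark=mark, stage=stage
            )

    logger.info("stage call_enhancers")
    promoters = define_promoters(truth.genes, flank=params.promoter_flank)
    enhancer_sets: dict[str, EnhancerSet] = {}
    state_fractions: dict[str, pd.DataFrame] = {}
    for stage in sim.stages:
        k4me1_windows = call_enriched_windows(tracks[stage]["K4me1"], params.k4me1_cutoff)
        regions = merge_regions(k4me1_windows)
        k27me3 = tracks[stage].get("K27me3")
        if k27me3 is None:
            warnings.warn(
                f"{stage}: no K27me3 track; poised classification disabled", stacklevel=2
            )
        candidates = identify_putative_enhancers(
            regions, tracks[stage]["K4me3"], promoters, params.k4me3_depleted_cutoff
        )
        enh = classify_enhancers(
            candidates,
            tracks[stage]["K4me1"],
            tracks[stage]["K27ac"],
            k27me3,
            k4me3_track=tracks[stage]["K4me3"],
            cutoff=params.k27ac_cutoff,
            stage=stage,
        )
        enhancer_sets[stage] = enh
        state_fractions[stage] = state_counts(enh)
        logger.info("  %s: %d enhancers (%s)", stage, len(enh),
                    ", ".join(f"{s}={c}" for s, c in enh.states.value_counts().items()))

    logger.info("stage expression")
    rna = pd.DataFrame({st: simulate_rnaseq(truth, sim, st) for st in sim.stages})
    lengths = truth.expression["exonic_length"]
    expr = lk.quantify_expression(rna, lengths)
    norm_cols = list(sim.stages)
    pooled = expr[norm_cols].to_numpy().ravel()
    threshold = lk.bimodal_threshold(pooled)
    for st in sim.stages:
        classes, _ = lk.binarize_expression(expr[st], threshold)
        expr[f"class_{st}"] = classes

    logger.info("stage linking")
    links = {
        st: lk.assign_enhancers(enhancer_sets[st], promoters, params.max_link_distance)
        for st in sim.stages
    }

    logger.info("stage dynamics")
    stage1 = sim.stages[0]
    later = list(sim.stages[1:]) or [stage1]
    transition_tables = {}
    for state in ("active", "primed", "poised"):
        source = enhancer_sets[stage1].regions(state)
        if not source:
            continue
        target = {
            st: (
                (tracks[st]["K4me1"], tracks[st]["K27ac"], tracks[st]["K27me3"])
                if params.include_k27me3
                else (tracks[st]["K4me1"], tracks[st]["K27ac"])
            )
            for st in later
        }
        transition_tables[state] = dyn.transition_fractions(
            source, target, params.k4me1_cutoff, params.k27ac_cutoff
        )
    presence, jaccard = dyn.presence_matrix(
        {st: enhancer_sets[st].regions() for st in sim.stages}
    )

    logger.info("stage heterochromatin")
    k9_tracks: dict[str, EnrichmentTrack] = {}
    hmm_models: dict[str, hc.HmmModel] = {}
    domain_sets: dict[str, hc.DomainSet] = {}
    genome_fractions: dict[str, float] = {}
    paths: dict[str, np.ndarray] = {}
    grid5k = make_windows(genome, sim.hmm_window, sim.hmm_window)
    train_chrom = params.train_chrom or genome.names[0]
    for st in sim.stages:
        track, _, _ = simulate_k9me2_track(genome, sim, truth=truth, stage=st)
        k9_tracks[st] = track
        sl = grid5k.chrom_slice(train_chrom)
        model = hc.em_fit(
            track.values[sl], tol=params.hmm_tol, max_iter=params.hmm_max_iter
        )
        hmm_models[st] = model
        path = np.concatenate(
            [hc.viterbi(model, track.values[grid5k.chrom_slice(c)]) for c in genome.names]
        )
        paths[st] = path
        domain_sets[st] = hc.states_to_domains(path, grid5k, stage=st)
        genome_fractions[st] = hc.genome_fraction(path)
    domain_venn = hc.domain_overlap(domain_sets)
    corr_rows = []
    for i, a in enumerate(sim.stages):
        for b in sim.stages[i + 1 :]:
            corr_rows.append(
                {
                    "stage_a": a,
                    "stage_b": b,
                    "pearson_r": hc.correlate_tracks(k9_tracks[a].values, k9_tracks[b].values),
                }
            )
    k9_correlations = pd.DataFrame(corr_rows)

    # enhancers marked at stage 1 but closed at stage 2: overlap with stage-2 domains
    stage2 = sim.stages[1] if len(sim.stages) > 1 else stage1
    src_regions = enhancer_sets[stage1].regions()
    scored = dyn.rescore_in_stage(
        src_regions, tracks[stage2]["K4me1"], tracks[stage2]["K27ac"]
    )
    closed_mask = [
        dyn.classify_transition(r["score_k4me1"], r["score_k27ac"],
                                k4me1_cutoff=params.k4me1_cutoff,
                                k27ac_cutoff=params.k27ac_cutoff) == "closed"
        for _, r in scored.iterrows()
    ]
    closed_regions = [r for r, m in zip(src_regions, closed_mask) if m]
    if closed_regions:
        closed_frac, _ = hc.enhancer_domain_overlap(closed_regions, domain_sets[stage2])
    else:
        closed_frac = float("nan")

    metrics = _recovery_metrics(
        truth, enhancer_sets, paths, transition_tables, closed_frac, sim
    )

    return PipelineResult(
        truth=truth,
        params=params,
        tracks=tracks,
        enhancer_sets=enhancer_sets,
        state_fractions=state_fractions,
        expression=expr,
        expression_threshold=threshold,
        links=links,
        transition_tables=transition_tables,
        presence=presence,
        jaccard=jaccard,
        hmm_models=hmm_models,
        domain_sets=domain_sets,
        genome_fractions=genome_fractions,
        domain_venn=domain_venn,
        k9_correlations=k9_correlations,
        closed_enhancer_domain_fraction=closed_frac,
        closed_enhancer_n=len(closed_regions),
        metrics=metrics,
    )


def _recovery_metrics(truth, enhancer_sets, paths, transition_tables, closed_frac, sim):
    metrics: dict[str, float] = {}
    correct = total = 0
    for stage in sim.stages:
        matched = _match_truth_states(enhancer_sets[stage], truth, stage)
        nonclosed = matched[matched["true_state"] != "closed"]
        correct += int((nonclosed["true_state"] == nonclosed["called_state"]).sum())
        total += len(nonclosed)
    metrics["enhancer_state_recovery"] = correct / total if total else float("nan")

    acc_num = acc_den = 0
    for stage in sim.stages:
        acc_num += int((paths[stage] == truth.domain_states[stage]).sum())
        acc_den += len(paths[stage])
    metrics["domain_base_accuracy"] = acc_num / acc_den

    if "primed" in transition_tables and len(sim.stages) > 1:
        tt = transition_tables["primed"]
        st2 = sim.stages[1]
        metrics["primed_to_active_fraction"] = float(tt.loc[st2, "frac_active"])
        metrics["primed_to_active_n"] = float(tt.loc[st2, "n"])
    metrics["closed_enhancer_domain_fraction"] = closed_frac
    return metrics


def write_outputs(result: PipelineResult, out_dir: str | Path) -> Path:
    """Serialize the full output bundle plus a reproducibility manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = result.truth.config
    cio.write_chrom_sizes(result.truth.genome, out / "genome.chrom.sizes")
    cio.write_gene_models(result.truth.genes, out / "genes.refgene.tsv")
    cio.save_config(sim, out / "simulation_config.yaml")

    for stage, marks in result.tracks.items():
        for mark, track in marks.items():
            cio.write_bedgraph(track, out / f"{stage}.{mark}.enrichment.bedgraph")
    for stage, enh in result.enhancer_sets.items():
        frame = enh.frame.copy()
        frame["name"] = frame["state"]
        cio.write_bed(frame, out / f"{stage}.enhancers.bed")
        frame.to_csv(out / f"{stage}.enhancers.tsv", sep="\t", index=False)
    result.expression.to_csv(out / "expression.tsv", sep="\t")
    for stage, link in result.links.items():
        link.to_csv(out / f"{stage}.links.tsv", sep="\t", index=False)
    for state, table in result.transition_tables.items():
        table.to_csv(out / f"transitions.{state}.tsv", sep="\t")
    result.presence.astype(int).to_csv(out / "presence_matrix.tsv", sep="\t")
    result.jaccard.to_csv(out / "jaccard.tsv", sep="\t")
    for stage, ds in result.domain_sets.items():
        cio.write_bed(ds.frame, out / f"{stage}.k9me2_domains.bed")
    for stage, model in result.hmm_models.items():
        pd.DataFrame(
            {
                "state": ["depleted", "enriched"],
                "startprob": model.startprob,
                "stay_prob": np.diag(model.transmat),
                "mean": model.means,
                "variance": model.variances,
            }
        ).to_csv(out / f"{stage}.hmm_model.tsv", sep="\t", index=False)
    result.domain_venn.to_csv(out / "domain_venn.tsv", sep="\t", index=False)
    result.k9_correlations.to_csv(out / "k9me2_correlations.tsv", sep="\t", index=False)

    manifest = {
        "seed": sim.seed,
        "stages_completed": list(STAGE_NAMES),
        "n_stages": len(sim.stages),
        "analysis_params": {
            k: v for k, v in result.params.__dict__.items() if v is not None
        },
        "expression_threshold": result.expression_threshold,
        "metrics": {k: float(v) for k, v in result.metrics.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
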