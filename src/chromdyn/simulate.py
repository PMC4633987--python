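"""Synthetic chromatin-state data with known ground truth.

Generates a toy multi-chromosome genome, a refGene-like gene annotation,
per-stage latent enhancer states evolving under a Markov chain, broad
two-state heterochromatin domains, and the observable data the analysis
consumes: per-window ChIP/input tag counts with state-dependent fold
enrichment, Gaussian log2-enrichment tracks for the broad mark, and
per-gene RNA read counts.

Counts are Poisson by default (negative binomial when ``overdispersion``
is set): the simplest generative model whose normalized log-ratio matches
the pseudo-count enrichment statistic.  RNA counts are negative binomial
with dispersion 0.1 and means proportional to exonic length, raised for
genes with truly active enhancers nearby.

Determinism: a single master seed; every sub-simulation derives its own
child stream from the master seed and a fixed text tag, so outputs are
byte-identical across runs and independent of call order.
"""

from __future__ import annotations

import zlib
from bisect import bisect_left, insort
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeSpec, Region, make_windows, merge_intervals
from .hmm import DomainSet
from .windows import CountMatrix, EnrichmentTrack

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "simulate_genome",
    "simulate_truth",
    "simulate_chip_counts",
    "simulate_k9me2_track",
    "simulate_rnaseq",
]

ENHANCER_STATES = ("active", "primed", "poised", "closed")
MARKS = ("K4me1", "K4me3", "K27ac", "K27me3")


def child_rng(seed: int, tag: str) -> np.random.Generator:
    """Deterministic, order-independent child stream for one sub-simulation."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(tag.encode())]))


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults define the study conditions."""

    seed: int = 0
    chrom_lengths: tuple[int, ...] = (5_000_000, 5_000_000)
    stages: tuple[str, ...] = ("stage1", "stage2", "stage3")
    n_genes: int = 300
    n_enhancers: int = 500
    enhancer_width: int = 1500
    min_tss_distance: int = 4000
    min_enhancer_gap: int = 3000
    # latent enhancer-state chain over stages (rows/cols in ENHANCER_STATES order)
    initial_state_probs: tuple[float, ...] = (0.336, 0.452, 0.012, 0.200)
    transition_matrix: tuple[tuple[float, ...], ...] = (
        (0.60, 0.10, 0.000, 0.300),
        (0.04, 0.16, 0.000, 0.800),
        (0.30, 0.20, 0.400, 0.100),
        (0.10, 0.05, 0.005, 0.845),
    )
    # ChIP model (reads per 1 kb window; folds are pre-normalization)
    background_mean: float = 40.0
    k4me1_fold: float = 16.0
    k27ac_fold: float = 16.0
    k27me3_fold: float = 12.0
    promoter_k4me3_fold: float = 16.0
    promoter_k4me1_fold: float = 5.0
    replicates: dict[str, int] = field(
        default_factory=lambda: {"K4me1": 2, "K4me3": 1, "K27ac": 2, "K27me3": 2}
    )
    overdispersion: float | None = None  # None = Poisson; else NB with this dispersion
    # heterochromatin domain chain over consecutive 5 kb windows
    hmm_window: int = 5000
    domain_stay_prob: float = 0.9
    domain_start_state: int | None = None  # None = random start per chromosome
    emission_means: tuple[float, float] = (-1.0, 1.0)
    emission_sds: tuple[float, float] = (0.5**0.5, 0.5**0.5)
    domain_resample_frac: float = 0.1  # per-stage fraction of windows re-simulated
    closed_in_domain_prob: float = 0.15  # P(stage-2-closed enhancer sits in a stage-2 domain)
    domain_margin: int = 5000
    # RNA model
    base_expr_mean: float = 500.0
    silent_expr_mean: float = 2.0
    active_boost: float = 0.75  # relative mean increase per truly active enhancer
    rna_dispersion: float = 0.1
    p_expressed_active: float = 0.95  # gene has >= 1 truly active enhancer
    p_expressed_marked: float = 0.5  # only primed/poised enhancers nearby
    p_expressed_none: float = 0.1
    promoter_flank: int = 1000

    def __post_init__(self) -> None:
        probs = np.asarray(self.initial_state_probs, dtype=float)
        trans = np.asarray(self.transition_matrix, dtype=float)
        if probs.shape != (4,) or not np.isclose(probs.sum(), 1.0):
            raise ValueError("initial_state_probs must be 4 probabilities summing to 1")
        if trans.shape != (4, 4) or not np.allclose(trans.sum(axis=1), 1.0):
            raise ValueError("transition_matrix must be 4x4 row-stochastic")
        if np.any(probs < 0) or np.any(trans < 0):
            raise ValueError("probabilities must be in [0, 1]")
        if not (0 < self.domain_stay_prob <= 1):
            raise ValueError("domain_stay_prob must be in (0, 1]")
        if any(sd <= 0 for sd in self.emission_sds):
            raise ValueError("emission SDs must be positive")
        for name in ("background_mean", "k4me1_fold", "k27ac_fold", "k27me3_fold"):
            if getattr(self, name) < 1 and "fold" in name:
                raise ValueError(f"{name} must be >= 1")

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(f"chr{i + 1}" for i in range(len(self.chrom_lengths)))


@dataclass
class TruthSet:
    """Ground truth behind one synthetic dataset."""

    genome: GenomeSpec
    genes: pd.DataFrame  # name, chrom, strand, txStart, txEnd, exonStarts, exonEnds, tss
    enhancers: pd.DataFrame  # id, chrom, start, end, target_gene + state_<stage> columns
    expression: pd.DataFrame  # per gene: exonic_length + class_<stage>, mean_<stage>
    domain_states: dict[str, np.ndarray]  # per stage: hidden 0/1 per 5 kb window
    domains: dict[str, DomainSet]
    config: SimulationConfig

    def enhancer_states(self, stage: str) -> pd.Series:
        return self.enhancers[f"state_{stage}"]

    def enhancer_regions(self) -> list[Region]:
        return [
            Region(str(c), int(s), int(e))
            for c, s, e in zip(
                self.enhancers["chrom"], self.enhancers["start"], self.enhancers["end"]
            )
        ]

    def promoter_intervals(self) -> dict[str, list[tuple[int, int]]]:
        flank = self.config.promoter_flank
        out: dict[str, list[tuple[int, int]]] = {}
        for _, g in self.genes.iterrows():
            out.setdefault(g["chrom"], []).append(
                (max(0, int(g["tss"]) - flank), int(g["tss"]) + flank)
            )
        return {c: sorted(v) for c, v in out.items()}


def simulate_genome(config: SimulationConfig) -> GenomeSpec:
    """Echo the configured chromosome layout as a validated GenomeSpec."""
    if len(config.chrom_lengths) == 0:
        raise ValueError("at least one chromosome required")
    return GenomeSpec(names=config.chrom_names, lengths=tuple(int(l) for l in config.chrom_lengths))


def _markov_chain(rng: np.random.Generator, n: int, stay: float, start: int | None = None) -> np.ndarray:
    states = np.empty(n, dtype=int)
    states[0] = rng.integers(0, 2) if start is None else start
    flips = rng.random(n - 1) >= stay if n > 1 else np.array([], dtype=bool)
    for i, flip in enumerate(flips):
        states[i + 1] = 1 - states[i] if flip else states[i]
    return states


def _simulate_domain_states(
    genome: GenomeSpec, config: SimulationConfig, seed_tag: str
) -> dict[str, np.ndarray]:
    """Per-stage hidden 0/1 state per 5 kb window, mostly shared across stages."""
    grid = make_windows(genome, config.hmm_window, config.hmm_window)
    rng = child_rng(config.seed, seed_tag)
    base = np.concatenate(
        [
            _markov_chain(rng, grid.n_windows(c), config.domain_stay_prob, config.domain_start_state)
            for c in genome.names
        ]
    )
    out: dict[str, np.ndarray] = {}
    block = 40
    for si, stage in enumerate(config.stages):
        states = base.copy()
        if si > 0 and config.domain_resample_frac > 0:
            n_blocks = max(1, int(round(config.domain_resample_frac * grid.n / block)))
            for _ in range(n_blocks):
                at = int(rng.integers(0, max(1, grid.n - block)))
                states[at : at + block] = _markov_chain(rng, block, config.domain_stay_prob)
        out[stage] = states
    return out


def _states_to_domainset(
    states: np.ndarray, genome: GenomeSpec, config: SimulationConfig, stage: str
) -> DomainSet:
    grid = make_windows(genome, config.hmm_window, config.hmm_window)
    rows = []
    offset = 0
    for chrom in genome.names:
        n = grid.n_windows(chrom)
        s = states[offset : offset + n]
        in_run = False
        for i, v in enumerate(s):
            if v == 1 and not in_run:
                run_start = i
                in_run = True
            if in_run and (v == 0 or i == n - 1):
                stop = i if v == 0 else i + 1
                rows.append((chrom, run_start * config.hmm_window, stop * config.hmm_window))
                in_run = False
        offset += n
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return DomainSet(frame=frame, stage=stage)


def _place_genes(genome: GenomeSpec, config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    lengths = np.asarray(genome.lengths, dtype=float)
    per_chrom = np.floor(config.n_genes * lengths / lengths.sum()).astype(int)
    per_chrom[0] += config.n_genes - per_chrom.sum()
    rows = []
    gene_no = 0
    for chrom, L, n in zip(genome.names, genome.lengths, per_chrom):
        placed_tss: list[int] = []
        for _ in range(n):
            for _attempt in range(500):
                body = int(rng.integers(2000, 10001))
                strand = "+" if rng.random() < 0.5 else "-"
                tss = int(rng.integers(config.promoter_flank + body, L - config.promoter_flank - body))
                j = bisect_left(placed_tss, tss)
                near = [placed_tss[k] for k in (j - 1, j) if 0 <= k < len(placed_tss)]
                if all(abs(tss - t) >= 6000 for t in near):
                    break
            else:
                raise RuntimeError("gene placement failed after bounded retries")
            insort(placed_tss, tss)
            tx_start, tx_end = (tss, tss + body) if strand == "+" else (tss - body, tss)
            n_ex = int(rng.integers(2, 6))
            cuts = np.sort(rng.random(2 * n_ex - 2))
            bounds = np.concatenate([[0.0], cuts, [1.0]])
            pts = tx_start + np.round(bounds * body).astype(int)
            exon_starts = [int(pts[2 * k]) for k in range(n_ex)]
            exon_ends = [max(int(pts[2 * k + 1]), exon_starts[k] + 1) for k in range(n_ex)]
            rows.append(
                {
                    "name": f"gene{gene_no:04d}",
                    "chrom": chrom,
                    "strand": strand,
                    "txStart": tx_start,
                    "txEnd": tx_end,
                    "exonStarts": exon_starts,
                    "exonEnds": exon_ends,
                    "tss": tss,
                }
            )
            gene_no += 1
    return pd.DataFrame(rows)


def _place_enhancers(
    genome: GenomeSpec,
    config: SimulationConfig,
    rng: np.random.Generator,
    genes: pd.DataFrame,
    states: np.ndarray,
    domains_stage2: DomainSet | None,
) -> pd.DataFrame:
    """Place enhancer intervals subject to TSS-distance, spacing and (for the
    marked-then-closed group) heterochromatin-domain co-placement constraints."""
    W = config.enhancer_width
    margin = config.domain_margin
    tss_by_chrom = {
        c: sorted(genes.loc[genes["chrom"] == c, "tss"].astype(int)) for c in genome.names
    }
    placed: dict[str, list[int]] = {c: [] for c in genome.names}  # sorted starts
    lengths = np.asarray(genome.lengths, dtype=float)
    chrom_probs = lengths / lengths.sum()

    stage2_idx = 1 if len(config.stages) > 1 else 0
    closing = (states[:, 0] != ENHANCER_STATES.index("closed")) & (
        states[:, stage2_idx] == ENHANCER_STATES.index("closed")
    )
    in_domain_flag = np.zeros(len(states), dtype=bool)
    if domains_stage2 is not None:
        in_domain_flag[closing] = rng.random(int(closing.sum())) < config.closed_in_domain_prob

    dom_ivs = (
        {c: domains_stage2.intervals(c) for c in genome.names}
        if domains_stage2 is not None
        else {c: [] for c in genome.names}
    )
    inner = {
        c: [(s + margin, e - margin - W) for s, e in dom_ivs[c] if e - s >= 2 * margin + W]
        for c in genome.names
    }

    def ok(chrom: str, start: int, need_in_domain: bool | None) -> bool:
        end = start + W
        ts = tss_by_chrom[chrom]
        j = bisect_left(ts, start)
        for k in (j - 1, j, j + 1):
            if 0 <= k < len(ts):
                t = ts[k]
                if start - config.min_tss_distance < t < end + config.min_tss_distance:
                    return False
        ps = placed[chrom]
        j = bisect_left(ps, start)
        for k in (j - 1, j):
            if 0 <= k < len(ps):
                if abs(start - ps[k]) < W + config.min_enhancer_gap:
                    return False
        if need_in_domain is True:
            return any(s + margin <= start and end <= e - margin for s, e in dom_ivs[chrom])
        if need_in_domain is False:
            return all(
                end + margin <= s or start >= e + margin for s, e in dom_ivs[chrom]
            )
        return True

    order = np.concatenate([np.flatnonzero(closing), np.flatnonzero(~closing)])
    out = [None] * len(states)
    for i in order:
        need = None
        if closing[i] and domains_stage2 is not None:
            need = bool(in_domain_flag[i])
        for _attempt in range(2000):
            if need is True:
                cands = [(c, iv) for c in genome.names for iv in inner[c]]
                if not cands:
                    raise RuntimeError("no heterochromatin domain large enough for placement")
                weights = np.array([iv[1] - iv[0] + 1 for _, iv in cands], dtype=float)
                c, iv = cands[rng.choice(len(cands), p=weights / weights.sum())]
                start = int(rng.integers(iv[0], iv[1] + 1))
            else:
                c = genome.names[rng.choice(len(genome.names), p=chrom_probs)]
                start = int(rng.integers(0, genome.sizes[c] - W))
            if ok(c, start, need):
                insort(placed[c], start)
                out[i] = (c, start)
                break
        else:
            raise RuntimeError("enhancer placement failed after bounded retries")

    chroms = [o[0] for o in out]
    starts = [o[1] for o in out]
    # associate each enhancer with the gene whose TSS is nearest (expression coupling)
    targets = []
    for c, s in zip(chroms, starts):
        ts = tss_by_chrom[c]
        mid = s + W / 2
        j = min(range(len(ts)), key=lambda k: abs(ts[k] - mid))
        sub = genes[(genes["chrom"] == c) & (genes["tss"] == ts[j])]
        targets.append(sub.iloc[0]["name"])
    frame = pd.DataFrame(
        {
            "id": [f"enh{i:04d}" for i in range(len(states))],
            "chrom": chroms,
            "start": starts,
            "end": [s + W for s in starts],
            "target_gene": targets,
            "in_stage2_domain": in_domain_flag,
        }
    )
    for si, stage in enumerate(config.stages):
        frame[f"state_{stage}"] = [ENHANCER_STATES[k] for k in states[:, si]]
    return frame


def simulate_truth(genome: GenomeSpec, config: SimulationConfig) -> TruthSet:
    """Place genes and enhancers, draw per-stage latent states and domains."""
    rng = child_rng(config.seed, "truth")
    genes = _place_genes(genome, config, rng)

    # latent enhancer states across stages
    n, S = config.n_enhancers, len(config.stages)
    probs = np.asarray(config.initial_state_probs)
    trans = np.asarray(config.transition_matrix)
    states = np.empty((n, S), dtype=int)
    states[:, 0] = rng.choice(4, size=n, p=probs)
    for s in range(1, S):
        for i in range(n):
            states[i, s] = rng.choice(4, p=trans[states[i, s - 1]])

    domain_states = _simulate_domain_states(genome, config, "domains")
    domains = {
        st: _states_to_domainset(domain_states[st], genome, config, st) for st in config.stages
    }
    stage2 = config.stages[1] if S > 1 else config.stages[0]
    enhancers = _place_enhancers(genome, config, rng, genes, states, domains[stage2])

    # expression truth per stage
    active_idx = ENHANCER_STATES.index("active")
    exonic = genes.apply(
        lambda g: sum(e - s for s, e in merge_intervals(list(zip(g["exonStarts"], g["exonEnds"])))),
        axis=1,
    )
    expr = pd.DataFrame({"exonic_length": exonic.to_numpy()}, index=genes["name"])
    mean_len = expr["exonic_length"].mean()
    for si, stage in enumerate(config.stages):
        n_active = (
            enhancers.loc[states[:, si] == active_idx, "target_gene"].value_counts()
        )
        counts = pd.Series(
            [int(n_active.get(g, 0)) for g in genes["name"]], index=genes["name"]
        )
        marked = enhancers.loc[states[:, si] != ENHANCER_STATES.index("closed"), "target_gene"]
        has_marked = pd.Series(
            [g in set(marked) for g in genes["name"]], index=genes["name"]
        )
        p = np.where(
            counts > 0,
            config.p_expressed_active,
            np.where(has_marked, config.p_expressed_marked, config.p_expressed_none),
        )
        expressed = rng.random(len(p)) < p
        mean = np.where(
            expressed,
            config.base_expr_mean
            * (expr["exonic_length"] / mean_len)
            * (1 + config.active_boost * counts),
            config.silent_expr_mean,
        )
        expr[f"class_{stage}"] = np.where(expressed, "expressed", "silent")
        expr[f"mean_{stage}"] = mean
        expr[f"n_active_{stage}"] = counts
    return TruthSet(
        genome=genome,
        genes=genes,
        enhancers=enhancers,
        expression=expr,
        domain_states=domain_states,
        domains=domains,
        config=config,
    )


def _draw_counts(
    rng: np.random.Generator, mean: np.ndarray, overdispersion: float | None
) -> np.ndarray:
    if overdispersion is None:
        return rng.poisson(mean).astype(float)
    r = 1.0 / overdispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p).astype(float)


def _fold_per_window(
    truth: TruthSet, grid, mark: str, stage: str, config: SimulationConfig
) -> np.ndarray:
    fold = np.ones(grid.n)

    def paint(chrom: str, start: int, end: int, f: float) -> None:
        lo, hi = grid.windows_overlapping(chrom, start, end)
        off = grid.chrom_slice(chrom).start
        fold[off + lo : off + hi] = np.maximum(fold[off + lo : off + hi], f)

    if mark in ("K4me3", "K4me1"):
        pf = config.promoter_k4me3_fold if mark == "K4me3" else config.promoter_k4me1_fold
        for chrom, ivs in truth.promoter_intervals().items():
            for s, e in ivs:
                paint(chrom, s, e, pf)
    state_fold = {
        "K4me1": {"active": config.k4me1_fold, "primed": config.k4me1_fold, "poised": config.k4me1_fold},
        "K27ac": {"active": config.k27ac_fold},
        "K27me3": {"poised": config.k27me3_fold},
        "K4me3": {},
    }[mark]
    states = truth.enhancer_states(stage)
    for (_, enh), st in zip(truth.enhancers.iterrows(), states):
        f = state_fold.get(st)
        if f:
            paint(enh["chrom"], int(enh["start"]), int(enh["end"]), f)
    return fold


def simulate_chip_counts(
    truth: TruthSet,
    genome: GenomeSpec,
    mark: str,
    stage: str,
    config: SimulationConfig,
    grid=None,
    depth_factors: dict[str, float] | None = None,
) -> CountMatrix:
    """Per-window ChIP replicate and input counts for one mark and stage.

    Input counts have the configured background mean; ChIP counts have mean
    background x fold(state at the window).  ``depth_factors`` scales the
    sequencing depth of individual samples (keys: replicate names or
    "input"); library normalization downstream undoes it in expectation.
    """
    if mark not in MARKS:
        raise ValueError(f"unknown mark {mark!r}; expected one of {MARKS}")
    if stage not in config.stages:
        raise ValueError(f"unknown stage {stage!r}")
    if grid is None:
        grid = make_windows(genome, 1000, 500)
    rng = child_rng(config.seed, f"chip:{mark}:{stage}")
    fold = _fold_per_window(truth, grid, mark, stage, config)
    depth_factors = depth_factors or {}
    data = {}
    for r in range(config.replicates.get(mark, 1)):
        name = f"{mark}_{stage}_rep{r + 1}"
        d = depth_factors.get(name, 1.0)
        data[name] = _draw_counts(rng, config.background_mean * fold * d, config.overdispersion)
    iname = f"input_{stage}"
    d = depth_factors.get("input", 1.0)
    data[iname] = _draw_counts(
        rng, np.full(grid.n, config.background_mean * d), config.overdispersion
    )
    frame = pd.DataFrame(data)
    totals = {c: float(frame[c].sum()) for c in frame.columns}
    return CountMatrix(grid=grid, data=frame, totals=totals, normalized=False)


def simulate_k9me2_track(
    genome: GenomeSpec,
    config: SimulationConfig,
    truth: TruthSet | None = None,
    stage: str | None = None,
) -> tuple[EnrichmentTrack, DomainSet, np.ndarray]:
    """Gaussian log2-enrichment emissions over a 5 kb tiling grid.

    Hidden states come from the TruthSet when given (so all marks share one
    ground truth), otherwise from a fresh two-state Markov chain.  Returns
    (track, true domains, hidden state per window).
    """
    grid = make_windows(genome, config.hmm_window, config.hmm_window)
    tag = f"k9me2:{stage or 'standalone'}"
    rng = child_rng(config.seed, tag)
    if truth is not None and stage is not None:
        states = truth.domain_states[stage]
        domains = truth.domains[stage]
    else:
        states = np.concatenate(
            [
                _markov_chain(rng, grid.n_windows(c), config.domain_stay_prob, config.domain_start_state)
                for c in genome.names
            ]
        )
        domains = _states_to_domainset(states, genome, config, stage or "")
    means = np.asarray(config.emission_means)[states]
    sds = np.asarray(config.emission_sds)[states]
    values = rng.normal(means, sds)
    track = EnrichmentTrack(grid=grid, values=values, mark="K9me2", stage=stage or "")
    return track, domains, states


def simulate_rnaseq(truth: TruthSet, config: SimulationConfig, stage: str) -> pd.Series:
    """Per-gene exonic read counts for one stage (negative binomial)."""
    rng = child_rng(config.seed, f"rna:{stage}")
    mean = truth.expression[f"mean_{stage}"].to_numpy(dtype=float)
    counts = _draw_counts(rng, mean, config.rna_dispersion)
    return pd.Series(counts, index=truth.expression.index, name=stage)
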