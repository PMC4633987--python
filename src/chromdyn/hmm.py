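"""Two-state Gaussian-emission HMM segmentation of H3K9me2 enrichment.

Broad dimethylation domains are modelled as the hidden states of a
first-order Markov chain over consecutive 5 kb windows, with per-state
Gaussian emissions on the log2 enrichment scale.  The model is fitted by
Baum-Welch expectation-maximization on the values of a single training
chromosome and domains are then decoded genome-wide with the exact
Viterbi algorithm, one chromosome at a time.

State 0 is the depleted state and state 1 the enriched state.  The
default initialization starts in the enriched state with probability 1,
stays in either state with probability 0.9 and emits N(-1, 0.5) /
N(+1, 0.5) (variances, not SDs).  After fitting, the state with the
larger mean is relabelled "enriched" to undo any label switching.

All recursions run in log space; Viterbi is exact (ties broken toward the
lower-numbered state).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .genome import WindowGrid
from .windows import CountMatrix, EnrichmentTrack

__all__ = [
    "HmmModel",
    "DomainSet",
    "default_model",
    "retain_covered_windows",
    "em_fit",
    "viterbi",
    "states_to_domains",
    "genome_fraction",
    "domain_overlap",
    "correlate_tracks",
    "enhancer_domain_overlap",
]

VARIANCE_FLOOR = 1e-3
DEPLETED, ENRICHED = 0, 1


@dataclass
class HmmModel:
    """Two-state Gaussian HMM: initial probs, transitions, emissions."""

    startprob: np.ndarray
    transmat: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    loglik_trace: list[float] = field(default_factory=list)
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.startprob = np.asarray(self.startprob, dtype=float)
        self.transmat = np.asarray(self.transmat, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        if self.startprob.shape != (2,) or self.transmat.shape != (2, 2):
            raise ValueError("model must have exactly two states")
        if not np.allclose(self.transmat.sum(axis=1), 1.0):
            raise ValueError("transition rows must sum to 1")
        if np.any(self.variances < VARIANCE_FLOOR):
            raise ValueError(f"variances must be >= {VARIANCE_FLOOR}")

    def log_emission(self, values: np.ndarray) -> np.ndarray:
        """(n, 2) log N(value; mean_k, var_k)."""
        v = np.asarray(values, dtype=float)[:, None]
        return -0.5 * (
            np.log(2 * np.pi * self.variances) + (v - self.means) ** 2 / self.variances
        )


def default_model() -> HmmModel:
    """The standard initialization: enriched start, 0.9 stay, emissions at +-1."""
    return HmmModel(
        startprob=np.array([0.0, 1.0]),
        transmat=np.array([[0.9, 0.1], [0.1, 0.9]]),
        means=np.array([-1.0, 1.0]),
        variances=np.array([0.5, 0.5]),
    )


def retain_covered_windows(count_matrices: list[CountMatrix]) -> np.ndarray:
    """Boolean mask of windows with >= 1 raw read in any sample of any stage.

    ``count_matrices`` holds the (un-normalized) K9me2 and input count
    tables for every stage, all on the same tiling grid.
    """
    if not count_matrices:
        raise ValueError("no count matrices supplied")
    grid = count_matrices[0].grid
    for cm in count_matrices[1:]:
        if cm.grid.n != grid.n:
            raise ValueError("count matrices are on different grids")
    mask = np.zeros(grid.n, dtype=bool)
    for cm in count_matrices:
        mask |= (cm.data.to_numpy() > 0).any(axis=1)
    return mask


def _log_forward(model: HmmModel, loge: np.ndarray) -> tuple[np.ndarray, float]:
    n = len(loge)
    with np.errstate(divide="ignore"):
        logpi = np.log(model.startprob)
        loga = np.log(model.transmat)
    alpha = np.empty((n, 2))
    alpha[0] = logpi + loge[0]
    for t in range(1, n):
        alpha[t] = logsumexp(alpha[t - 1][:, None] + loga, axis=0) + loge[t]
    return alpha, float(logsumexp(alpha[-1]))


def _log_backward(model: HmmModel, loge: np.ndarray) -> np.ndarray:
    n = len(loge)
    with np.errstate(divide="ignore"):
        loga = np.log(model.transmat)
    beta = np.zeros((n, 2))
    for t in range(n - 2, -1, -1):
        beta[t] = logsumexp(loga + loge[t + 1] + beta[t + 1], axis=1)
    return beta


def log_likelihood(model: HmmModel, values: np.ndarray) -> float:
    _, ll = _log_forward(model, model.log_emission(values))
    return ll


def em_fit(
    values: np.ndarray,
    init: HmmModel | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> HmmModel:
    """Baum-Welch fit of the two-state Gaussian HMM to one value sequence.

    Iterates until the relative log-likelihood improvement drops below
    ``tol`` or ``max_iter`` is reached.  Variances are floored at 1e-3;
    an (effectively) constant input returns the floored model with the
    ``degenerate`` flag set.  The fitted state with the larger mean is
    relabelled enriched.  The log-likelihood trace is recorded and is
    non-decreasing.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 10:
        raise ValueError("need at least 10 values to fit")
    model = init if init is not None else default_model()
    model = replace(model, loglik_trace=[])
    degenerate = bool(np.ptp(values) < 1e-12)

    trace: list[float] = []
    prev_ll = -np.inf
    for _ in range(max_iter):
        loge = model.log_emission(values)
        alpha, ll = _log_forward(model, loge)
        trace.append(ll)
        model = replace(model, loglik_trace=trace)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * abs(prev_ll):
            break
        prev_ll = ll
        beta = _log_backward(model, loge)

        log_gamma = alpha + beta - ll
        gamma = np.exp(log_gamma)

        with np.errstate(divide="ignore"):
            loga = np.log(model.transmat)
        # xi[i, j] summed over t, in log space
        log_xi_sum = np.full((2, 2), -np.inf)
        if len(values) > 1:
            terms = (
                alpha[:-1, :, None]
                + loga[None, :, :]
                + loge[1:, None, :]
                + beta[1:, None, :]
                - ll
            )
            log_xi_sum = logsumexp(terms, axis=0)
        xi_sum = np.exp(log_xi_sum)

        startprob = gamma[0] / gamma[0].sum()
        denom = gamma[:-1].sum(axis=0)[:, None]
        transmat = np.where(denom > 0, xi_sum / np.where(denom == 0, 1, denom), model.transmat)
        transmat = transmat / transmat.sum(axis=1, keepdims=True)
        weights = gamma.sum(axis=0)
        means = (gamma * values[:, None]).sum(axis=0) / weights
        variances = (gamma * (values[:, None] - means) ** 2).sum(axis=0) / weights
        variances = np.maximum(variances, VARIANCE_FLOOR)

        model = HmmModel(startprob, transmat, means, variances, trace, degenerate)

    # undo label switching: the larger-mean state is "enriched" (index 1)
    if model.means[ENRICHED] < model.means[DEPLETED]:
        perm = [1, 0]
        model = HmmModel(
            model.startprob[perm],
            model.transmat[np.ix_(perm, perm)],
            model.means[perm],
            model.variances[perm],
            model.loglik_trace,
            model.degenerate,
        )
    return model


def viterbi(model: HmmModel, values: np.ndarray) -> np.ndarray:
    """Exact maximum-probability joint state path for one chromosome."""
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("empty observation sequence")
    loge = model.log_emission(values)
    with np.errstate(divide="ignore"):
        logpi = np.log(model.startprob)
        loga = np.log(model.transmat)
    n = len(values)
    delta = np.empty((n, 2))
    back = np.zeros((n, 2), dtype=int)
    delta[0] = logpi + loge[0]
    for t in range(1, n):
        cand = delta[t - 1][:, None] + loga
        back[t] = np.argmax(cand, axis=0)
        delta[t] = cand[back[t], [0, 1]] + loge[t]
    path = np.empty(n, dtype=int)
    path[-1] = int(np.argmax(delta[-1]))
    for t in range(n - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


@dataclass
class DomainSet:
    """Enriched-state intervals for one stage, aligned to window boundaries."""

    frame: pd.DataFrame  # columns chrom, start, end
    stage: str = ""

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def total_bp(self) -> int:
        return int((self.frame["end"] - self.frame["start"]).sum())

    def intervals(self, chrom: str) -> list[tuple[int, int]]:
        sub = self.frame[self.frame["chrom"] == chrom]
        return list(zip(sub["start"].astype(int), sub["end"].astype(int)))


def states_to_domains(
    path: np.ndarray,
    grid: WindowGrid,
    retained: np.ndarray | None = None,
    stage: str = "",
) -> DomainSet:
    """Turn a decoded state path into enriched-domain intervals.

    The path is defined over the retained windows only (all windows when
    ``retained`` is None).  A domain spans from the start of the first to
    the end of the last retained window of a maximal enriched run, so a
    dropped window flanked by enriched neighbours is bridged into one
    domain.
    """
    if retained is None:
        retained = np.ones(grid.n, dtype=bool)
    idx = np.flatnonzero(retained)
    if len(idx) != len(path):
        raise ValueError("path length does not match number of retained windows")
    chroms = grid.frame["chrom"].to_numpy()
    starts = grid.frame["start"].to_numpy()
    ends = grid.frame["end"].to_numpy()
    rows = []
    run_start = None
    prev_i = None
    for p, i in zip(path, idx):
        boundary = prev_i is None or chroms[i] != chroms[prev_i]
        if run_start is not None and (boundary or p != ENRICHED):
            rows.append((chroms[prev_i], starts[run_start], ends[prev_i]))
            run_start = None
        if p == ENRICHED and run_start is None:
            run_start = i
        prev_i = i
    if run_start is not None:
        rows.append((chroms[prev_i], starts[run_start], ends[prev_i]))
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end"]).astype(
        {"start": int, "end": int}
    )
    return DomainSet(frame=frame, stage=stage)


def genome_fraction(path: np.ndarray) -> float:
    """Fraction of retained windows decoded as enriched."""
    path = np.asarray(path)
    if len(path) == 0:
        raise ValueError("no retained windows")
    return float(np.mean(path == ENRICHED))


def domain_overlap(domain_sets: dict[str, DomainSet]) -> pd.DataFrame:
    """Base-level Venn partition across stages.

    One row per non-empty stage combination; ``bp`` is the number of bases
    covered by exactly that combination of stages.  Rows partition the
    union, so their bp values sum to the union size exactly.
    """
    if len(domain_sets) < 2:
        raise ValueError("need at least two domain sets")
    stages = list(domain_sets)
    chroms = sorted({c for ds in domain_sets.values() for c in ds.frame["chrom"].unique()})
    cells: dict[tuple[str, ...], int] = {}
    for chrom in chroms:
        points = sorted(
            {p for ds in domain_sets.values() for iv in ds.intervals(chrom) for p in iv}
        )
        ivs = {st: domain_sets[st].intervals(chrom) for st in stages}
        for a, b in zip(points[:-1], points[1:]):
            members = tuple(
                st for st in stages if any(s <= a and b <= e for s, e in ivs[st])
            )
            if members:
                cells[members] = cells.get(members, 0) + (b - a)
    rows = [
        {"stages": "&".join(k), "n_stages": len(k), "bp": v} for k, v in sorted(cells.items())
    ]
    return pd.DataFrame(rows)


def correlate_tracks(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two paired enrichment vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need >= 3 paired values")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in one of the tracks")
    return float(np.corrcoef(a, b)[0, 1])


def enhancer_domain_overlap(regions: list, domains: DomainSet) -> tuple[float, np.ndarray]:
    """Fraction of regions sharing >= 1 base with any enriched domain.

    Returns (fraction, per-region boolean mask).
    """
    ivs = {c: domains.intervals(c) for c in domains.frame["chrom"].unique()}
    marked = np.array(
        [
            any(s < r.end and r.start < e for s, e in ivs.get(r.chrom, []))
            for r in regions
        ],
        dtype=bool,
    )
    frac = float(marked.mean()) if len(marked) else 0.0
    return frac, marked
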