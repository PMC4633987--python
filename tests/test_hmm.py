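"""Two-state Gaussian HMM: exact decoding, EM, domains and overlaps."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import chromdyn as cd
from chromdyn.genome import Region, merge_intervals
from chromdyn.hmm import (
    DEPLETED,
    ENRICHED,
    DomainSet,
    HmmModel,
    correlate_tracks,
    default_model,
    domain_overlap,
    em_fit,
    enhancer_domain_overlap,
    genome_fraction,
    log_likelihood,
    retain_covered_windows,
    states_to_domains,
    viterbi,
)

try:
    from hmmlearn.hmm import GaussianHMM

    HAVE_HMMLEARN = True
except Exception:  # pragma: no cover
    HAVE_HMMLEARN = False


def random_model(rng):
    start = rng.dirichlet([1.0, 1.0])
    trans = np.stack([rng.dirichlet([2.0, 2.0]) for _ in range(2)])
    means = np.sort(rng.normal(0.0, 2.0, 2))
    variances = rng.uniform(0.1, 2.0, 2)
    return HmmModel(start, trans, means, variances)


def brute_force_viterbi(model, values):
    """Enumerate all 2^n paths; return the max-log-prob path, ties broken
    lexicographically toward state 0 (matching argmax tie rules)."""
    loge = model.log_emission(values)
    with np.errstate(divide="ignore"):
        logpi = np.log(model.startprob)
        loga = np.log(model.transmat)
    best_lp, best_path = -np.inf, None
    for path in itertools.product([0, 1], repeat=len(values)):
        lp = logpi[path[0]] + loge[0, path[0]]
        for t in range(1, len(values)):
            lp += loga[path[t - 1], path[t]] + loge[t, path[t]]
        if lp > best_lp:
            best_lp, best_path = lp, path
    return best_lp, np.array(best_path)


def path_logprob(model, values, path):
    loge = model.log_emission(values)
    with np.errstate(divide="ignore"):
        logpi = np.log(model.startprob)
        loga = np.log(model.transmat)
    lp = logpi[path[0]] + loge[0, path[0]]
    for t in range(1, len(values)):
        lp += loga[path[t - 1], path[t]] + loge[t, path[t]]
    return lp


def sample_sequence(model, n, rng):
    states = np.empty(n, dtype=int)
    states[0] = rng.choice(2, p=model.startprob)
    for t in range(1, n):
        states[t] = rng.choice(2, p=model.transmat[states[t - 1]])
    values = rng.normal(model.means[states], np.sqrt(model.variances[states]))
    return states, values


class TestModel:
    def test_default_model_parameters(self):
        m = default_model()
        assert m.startprob.tolist() == [0.0, 1.0]
        assert np.allclose(np.diag(m.transmat), 0.9)
        assert m.means.tolist() == [-1.0, 1.0]
        assert m.variances.tolist() == [0.5, 0.5]

    def test_bad_transition_rows_rejected(self):
        with pytest.raises(ValueError):
            HmmModel(np.array([0.5, 0.5]), np.array([[0.9, 0.2], [0.1, 0.9]]),
                     np.zeros(2), np.ones(2))

    def test_variance_floor_enforced(self):
        with pytest.raises(ValueError):
            HmmModel(np.array([0.5, 0.5]), np.eye(2), np.zeros(2),
                     np.array([1e-9, 1.0]))

    def test_log_emission_closed_form(self):
        m = default_model()
        le = m.log_emission(np.array([1.0]))
        expected = -0.5 * (math.log(2 * math.pi * 0.5) + (1.0 - 1.0) ** 2 / 0.5)
        assert le[0, ENRICHED] == pytest.approx(expected)


class TestViterbi:
    def test_matches_exhaustive_enumeration(self, rng):
        """100 random (model, sequence) instances, n <= 12: the Viterbi path
        attains exactly the maximum over all 2^n paths."""
        for _ in range(100):
            model = random_model(rng)
            n = int(rng.integers(1, 13))
            values = rng.normal(0, 2, n)
            best_lp, _ = brute_force_viterbi(model, values)
            path = viterbi(model, values)
            assert path_logprob(model, values, path) == pytest.approx(best_lp, abs=1e-9)

    def test_obvious_sequence(self):
        m = default_model()
        path = viterbi(m, np.array([5.0, 5.0, -5.0, -5.0, 5.0]))
        assert path.tolist() == [ENRICHED, ENRICHED, DEPLETED, DEPLETED, ENRICHED]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            viterbi(default_model(), np.array([]))

    def test_zero_start_prob_respected(self):
        # startprob puts zero mass on depleted, so even a depleted-looking
        # first observation starts in the enriched state
        m = default_model()
        path = viterbi(m, np.array([-5.0]))
        assert path[0] == ENRICHED

    @pytest.mark.skipif(not HAVE_HMMLEARN, reason="hmmlearn unavailable")
    def test_cross_check_against_hmmlearn(self, rng):
        for _ in range(20):
            model = random_model(rng)
            # hmmlearn rejects exact zeros in startprob; keep strictly positive
            model = HmmModel(
                np.array([0.3, 0.7]), model.transmat, model.means, model.variances
            )
            values = rng.normal(0, 2, 200)
            ref = GaussianHMM(n_components=2, covariance_type="diag", init_params="")
            ref.startprob_ = model.startprob
            ref.transmat_ = model.transmat
            ref.means_ = model.means[:, None]
            ref.covars_ = model.variances[:, None]
            lp_ref, path_ref = ref.decode(values[:, None], algorithm="viterbi")
            path = viterbi(model, values)
            assert path_logprob(model, values, path) == pytest.approx(lp_ref, abs=1e-6)
            assert np.array_equal(path, path_ref)


class TestEmFit:
    def test_loglik_trace_nondecreasing(self, rng):
        _, values = sample_sequence(default_model(), 400, rng)
        model = em_fit(values)
        trace = np.array(model.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-8)

    def test_infinite_tol_single_update(self, rng):
        """tol=inf stops at the first convergence check after one update, and
        the recorded trace ends at the returned model's likelihood."""
        _, values = sample_sequence(default_model(), 200, rng)
        model = em_fit(values, tol=np.inf)
        assert len(model.loglik_trace) == 2
        assert log_likelihood(model, values) == pytest.approx(model.loglik_trace[-1])

    def test_parameter_recovery(self, rng):
        """n=5000 from the default generator: means within 0.1, stay
        probabilities within 0.05."""
        truth = default_model()
        _, values = sample_sequence(truth, 5000, rng)
        model = em_fit(values)
        assert np.allclose(model.means, truth.means, atol=0.1)
        assert np.allclose(np.diag(model.transmat), np.diag(truth.transmat), atol=0.05)

    def test_label_switching_corrected(self, rng):
        """Initializing with swapped means still yields larger mean at the
        enriched index."""
        init = HmmModel(
            np.array([0.5, 0.5]),
            np.array([[0.9, 0.1], [0.1, 0.9]]),
            np.array([1.0, -1.0]),  # deliberately swapped
            np.array([0.5, 0.5]),
        )
        _, values = sample_sequence(default_model(), 1000, rng)
        model = em_fit(values, init=init)
        assert model.means[ENRICHED] > model.means[DEPLETED]

    def test_constant_input_flagged_degenerate(self):
        model = em_fit(np.zeros(100))
        assert model.degenerate
        assert np.all(model.variances >= 1e-3)

    def test_variance_floor_applied(self, rng):
        # two exactly repeated values per state -> zero within-state variance
        values = np.tile([5.0, -5.0], 200)
        model = em_fit(values)
        assert np.all(model.variances >= 1e-3)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            em_fit(np.arange(5, dtype=float))

    @pytest.mark.skipif(not HAVE_HMMLEARN, reason="hmmlearn unavailable")
    def test_likelihood_competitive_with_hmmlearn(self, rng):
        """Our converged fit should reach a likelihood at least as good as an
        hmmlearn fit from the same initialization (up to small numerics)."""
        _, values = sample_sequence(default_model(), 1500, rng)
        ours = em_fit(values, tol=1e-8, max_iter=500)
        ref = GaussianHMM(
            n_components=2, covariance_type="diag", init_params="", n_iter=500, tol=1e-8
        )
        ref.startprob_ = np.array([0.1, 0.9])
        ref.transmat_ = np.array([[0.9, 0.1], [0.1, 0.9]])
        ref.means_ = np.array([[-1.0], [1.0]])
        ref.covars_ = np.array([[0.5], [0.5]])
        ref.fit(values[:, None])
        ll_ref = ref.score(values[:, None])
        assert log_likelihood(ours, values) >= ll_ref - 1e-3


class TestDomains:
    @pytest.fixture()
    def grid(self):
        return cd.make_windows(cd.GenomeSpec(("chr1",), (40_000,)), 5000, 5000)

    def test_basic_runs(self, grid):
        path = np.array([1, 1, 0, 1, 0, 0, 1, 1])
        ds = states_to_domains(path, grid)
        assert ds.frame[["start", "end"]].to_numpy().tolist() == [
            [0, 10_000], [15_000, 20_000], [30_000, 40_000],
        ]

    def test_gap_bridging_over_dropped_window(self, grid):
        retained = np.array([True, True, False, True, True, True, True, True])
        path = np.array([1, 1, 1, 0, 0, 0, 0])  # over retained windows only
        ds = states_to_domains(path, grid, retained)
        # enriched run covers windows 0,1,3 -> one domain spanning the gap
        assert ds.frame[["start", "end"]].to_numpy().tolist() == [[0, 20_000]]

    def test_chromosome_boundary_not_bridged(self):
        grid = cd.make_windows(cd.GenomeSpec(("c1", "c2"), (10_000, 10_000)), 5000, 5000)
        ds = states_to_domains(np.array([1, 1, 1, 1]), grid)
        assert ds.frame["chrom"].tolist() == ["c1", "c2"]
        assert ds.total_bp == 20_000

    def test_length_mismatch_rejected(self, grid):
        with pytest.raises(ValueError):
            states_to_domains(np.array([1, 1]), grid)

    def test_genome_fraction(self):
        assert genome_fraction(np.array([1, 1, 0, 0])) == 0.5
        with pytest.raises(ValueError):
            genome_fraction(np.array([]))

    def test_retain_covered_windows(self, grid, small_genome):
        g = cd.make_windows(cd.GenomeSpec(("chr1",), (20_000,)), 5000, 5000)
        data = pd.DataFrame({"a": [0.0, 1.0, 0.0, 0.0], "b": [0.0, 0.0, 2.0, 0.0]})
        cm = cd.CountMatrix(grid=g, data=data, totals={"a": 1.0, "b": 2.0})
        mask = retain_covered_windows([cm])
        assert mask.tolist() == [False, True, True, False]


def brute_force_venn(domain_sets, genome_length=1_000_000):
    """Per-base bitmask oracle over a single chromosome."""
    masks = {}
    for st, ds in domain_sets.items():
        m = np.zeros(genome_length, dtype=bool)
        for s, e in ds.intervals("chr1"):
            m[s:e] = True
        masks[st] = m
    stages = list(domain_sets)
    out = {}
    stacked = np.stack([masks[st] for st in stages])
    for combo_bits in range(1, 2 ** len(stages)):
        combo = tuple(st for i, st in enumerate(stages) if combo_bits >> i & 1)
        sel = np.ones(genome_length, dtype=bool)
        for i, st in enumerate(stages):
            sel &= stacked[i] if combo_bits >> i & 1 else ~stacked[i]
        if sel.sum():
            out["&".join(combo)] = int(sel.sum())
    return out


class TestVenn:
    def make_ds(self, intervals, stage):
        frame = pd.DataFrame(intervals, columns=["start", "end"])
        frame.insert(0, "chrom", "chr1")
        return DomainSet(frame=frame, stage=stage)

    def test_simple_partition(self):
        ds = {
            "a": self.make_ds([(0, 100)], "a"),
            "b": self.make_ds([(50, 150)], "b"),
        }
        venn = domain_overlap(ds).set_index("stages")["bp"]
        assert venn["a"] == 50
        assert venn["b"] == 50
        assert venn["a&b"] == 50
        assert venn.sum() == 150  # exactly the union size

    def test_matches_bitmask_oracle_random(self, rng):
        for _ in range(20):
            ds = {}
            for st in ("a", "b", "c"):
                starts = np.sort(rng.choice(np.arange(0, 9000, 100), 6, replace=False))
                ivs = [(int(s), int(s + rng.integers(1, 4) * 100)) for s in starts]
                merged = merge_intervals(ivs)
                ds[st] = self.make_ds(merged, st)
            venn = domain_overlap(ds)
            got = dict(zip(venn["stages"], venn["bp"]))
            expected = brute_force_venn(ds, genome_length=12_000)
            assert got == expected

    def test_partition_sums_to_union(self, rng):
        ds = {}
        for st in ("a", "b"):
            starts = np.sort(rng.choice(np.arange(0, 9000, 50), 10, replace=False))
            ivs = merge_intervals([(int(s), int(s) + 120) for s in starts])
            ds[st] = self.make_ds(ivs, st)
        venn = domain_overlap(ds)
        union = np.zeros(12_000, dtype=bool)
        for d in ds.values():
            for s, e in d.intervals("chr1"):
                union[s:e] = True
        assert venn["bp"].sum() == int(union.sum())

    def test_single_set_rejected(self):
        with pytest.raises(ValueError):
            domain_overlap({"a": self.make_ds([(0, 100)], "a")})


class TestCorrelation:
    def test_known_value(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert correlate_tracks(a, 2 * a + 1) == pytest.approx(1.0)
        assert correlate_tracks(a, -a) == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate_tracks(np.ones(5), np.arange(5.0))

    def test_shared_domains_closed_form(self, rng):
        """Two tracks sharing the same +-1 state signal with independent
        N(0, 0.5) noise have r = var_signal / (var_signal + var_noise)
        = 1 / 1.5 = 2/3 (verified within 3 SEs via the Fisher transform)."""
        n = 20_000
        states = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        a = states + rng.normal(0, math.sqrt(0.5), n)
        b = states + rng.normal(0, math.sqrt(0.5), n)
        r = correlate_tracks(a, b)
        z, z0 = np.arctanh(r), np.arctanh(2 / 3)
        assert abs(z - z0) <= 3 / math.sqrt(n - 3)


class TestEnhancerDomainOverlap:
    def make_ds(self, intervals):
        frame = pd.DataFrame(intervals, columns=["start", "end"])
        frame.insert(0, "chrom", "chr1")
        return DomainSet(frame=frame)

    def test_fraction_and_mask(self):
        ds = self.make_ds([(1000, 5000)])
        regions = [
            Region("chr1", 0, 1000),    # book-ended: no shared base
            Region("chr1", 999, 1001),  # one shared base
            Region("chr1", 2000, 2500), # inside
            Region("chr1", 6000, 7000), # outside
        ]
        frac, mask = enhancer_domain_overlap(regions, ds)
        assert mask.tolist() == [False, True, True, False]
        assert frac == 0.5

    def test_empty_regions(self):
        frac, mask = enhancer_domain_overlap([], self.make_ds([(0, 100)]))
        assert frac == 0.0 and len(mask) == 0

    def test_unknown_chromosome_not_marked(self):
        frac, _ = enhancer_domain_overlap([Region("chrX", 0, 100)], self.make_ds([(0, 100)]))
        assert frac == 0.0


class TestPipelineHmm:
    def test_recovered_emission_means(self, pipeline_result, default_sim):
        """Fitted emission means recover the generator's +-1 within 0.1."""
        for model in pipeline_result.hmm_models.values():
            assert model.means[ENRICHED] == pytest.approx(default_sim.emission_means[1], abs=0.1)
            assert model.means[DEPLETED] == pytest.approx(default_sim.emission_means[0], abs=0.1)

    def test_recovered_stay_probabilities(self, pipeline_result, default_sim):
        for model in pipeline_result.hmm_models.values():
            assert np.allclose(np.diag(model.transmat), default_sim.domain_stay_prob, atol=0.05)

    def test_decoding_accuracy(self, pipeline_result):
        assert pipeline_result.metrics["domain_base_accuracy"] > 0.9

    def test_genome_fraction_near_stationary(self, pipeline_result, default_sim):
        """The symmetric 0.9-stay chain has stationary enriched fraction 0.5;
        each stage's decoded fraction lies within 3 SDs, where the SD
        accounts for autocorrelated windows via the effective sample size
        n_eff = n (1-rho) / (1+rho), rho = 2 * stay - 1."""
        n = sum(default_sim.chrom_lengths) // default_sim.hmm_window
        rho = 2 * default_sim.domain_stay_prob - 1
        n_eff = n * (1 - rho) / (1 + rho)
        bound = 3 * math.sqrt(0.25 / n_eff)
        for frac in pipeline_result.genome_fractions.values():
            assert abs(frac - 0.5) <= bound

    def test_venn_sums_to_union(self, pipeline_result):
        venn = pipeline_result.domain_venn
        union = 0
        sets = pipeline_result.domain_sets
        chroms = {c for ds in sets.values() for c in ds.frame["chrom"].unique()}
        for chrom in chroms:
            ivs = [iv for ds in sets.values() for iv in ds.intervals(chrom)]
            union += sum(e - s for s, e in merge_intervals(ivs))
        assert int(venn["bp"].sum()) == union

    def test_stages_share_most_domains(self, pipeline_result, default_sim):
        """The generator resamples only ~10% of domain-state blocks per
        stage, so the all-stages Venn cell dominates the union."""
        venn = pipeline_result.domain_venn
        shared = venn.loc[venn["n_stages"] == len(default_sim.stages), "bp"].sum()
        assert shared / venn["bp"].sum() > 0.5
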