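# chromdyn

Window-based analysis of chromatin-state dynamics across cellular
differentiation stages, bundled with a synthetic-data generator that provides
known-answer inputs for every step.

During differentiation, enhancers move between regulatory states that are
readable from histone modifications: H3K4me1 marks enhancer chromatin
generally, H3K27ac distinguishes *active* enhancers, H3K27me3 marks *poised*
(Polycomb-repressed) ones, and enhancers with H3K4me1 alone are *primed*.
In parallel, broad domains of H3K9me2 dimethylation partition the genome into
heterochromatic and euchromatic territory that is largely stable between
stages. `chromdyn` implements the standard window-based analyses of these
signals:

- **Window enrichment** — ChIP and input tag counts in sliding 1 kb windows
  (500 bp step, 60 bp strand-aware tag shift), libraries scaled to the mean
  total, scored as `log2((chip + 8) / (input + 8))`, averaged across
  replicates. Windows at or above 1.5 log2 are called enriched and merged
  into regions (overlap-merge; book-ended windows stay separate); a region's
  score is the maximum over its windows.
- **Enhancer calling** — H3K4me1 regions that share no base with a promoter
  (TSS ± 1 kb, de-overlapped first-kept-wins) and are H3K4me3-depleted
  (region score < 1.0) are putative enhancers; each is classified active
  (H3K27ac ≥ 1.5), else poised (H3K27me3 ≥ 1.5), else primed. Dual-marked
  regions are active with an audit flag.
- **Gene linking** — RNA counts are normalized to library size and unique
  exonic length, binarized at the antimode of the bimodal log-scale
  distribution, and enhancers are assigned to their nearest promoter
  (midpoint-to-TSS, ≤ 500 kb) in two passes: active enhancers first, with
  their promoters withheld from the primed/poised pass.
- **Cross-stage dynamics** — a stage's enhancer repertoire is re-scored at
  fixed coordinates in later stages and placed in
  active/primed/poised/closed outcomes (H3K4me1 loss dominates), plus a
  presence matrix over the merged union repertoire and base-level Jaccard
  similarities between stages.
- **Heterochromatin domains** — a two-state Gaussian HMM over 5 kb-window
  H3K9me2 enrichment, fitted by Baum–Welch on one training chromosome and
  decoded genome-wide with exact Viterbi; enriched runs become domains, and
  stages are compared by an exact base-level Venn partition.

The generator simulates all of this forward — a latent four-state enhancer
Markov chain across stages, Poisson (optionally negative-binomial) window
counts, a two-state domain chain mostly shared between stages, and
negative-binomial RNA coupled to enhancer activity — so every analysis
result can be checked against ground truth.

## Worked example

```python
import chromdyn as cd

result = cd.run_pipeline(cd.SimulationConfig(seed=1))

print(result.state_fractions["stage1"])
```

```
        count  fraction
state
active    171  0.430730
primed    219  0.551637
poised      7  0.017632
```

397 enhancers are called at stage 1; the recovered state mix matches the
generator's configured (active, primed, poised) mix conditioned on non-closed
enhancers. Following the 219 stage-1 primed enhancers into stage 2:

```python
print(result.transition_tables["primed"].loc["stage2"])
```

13 of 219 (5.94%) become active — the generator's primed-to-active
transition probability is 4%, and the recovered fraction is within the
binomial noise of a 219-element sample. Of the 230 stage-1 enhancers that
are closed by stage 2, 17.4% fall inside a stage-2 H3K9me2 domain
(`result.closed_enhancer_domain_fraction`), against a generator placement
probability of 15%.

The HMM recovers the domain process without being told its parameters:

```python
m = result.hmm_models["stage1"]
print(m.means, m.transmat.diagonal())
```

```
[-0.98581236  0.97669773] [0.91897913 0.91100269]
```

against true emission means ±1 and stay probability 0.9; decoded states
agree with the latent domain states on 97.1% of windows
(`result.metrics["domain_base_accuracy"]`), and the decoded enriched
fractions per stage (0.482, 0.480, 0.518) sit at the chain's stationary
value 0.5. Expression rises with the number of linked active enhancers:

```python
from chromdyn.linking import expression_by_active_count
print(expression_by_active_count(result.links["stage1"], result.expression["stage1"]))
```

```
          n_genes           q1       median           q3
n_active
0             179     0.935153     2.685813   266.312338
1              80   544.618118   696.007995   906.259750
2              33   901.801079  1106.716391  1411.785756
3+              8  1519.344069  1674.992497  1837.282918
```

The same pipeline is available from the command line:

```bash
chromdyn run-all --seed 1 --out out/
```

which writes enrichment bedGraphs, enhancer BED/TSV tables, link and
transition tables, domain BEDs, fitted HMM parameters, the Venn partition
and a `manifest.json` with the seed and recovery metrics. Individual steps
(`simulate`, `enrich`, `call-enhancers`, `link`, `transitions`,
`k9domains`) operate on plain text files (BED, bedGraph, TSV) and can be
chained on real data.

## Reproduction

All randomness derives from a single integer seed (child streams are tagged
per subsystem, so results are independent of evaluation order). To
reproduce the numbers above and the headline quantities:

```bash
python scripts/acceptance.py --seed 1 --out acceptance.json
```

which runs the full pipeline (< 10 s, single core) and writes each reported
quantity as `{"value": ..., "n": ...}` — among them
`primed_to_active_fraction` 0.0594 (n = 219),
`closed_enhancer_in_domain_fraction` 0.1739 (n = 230),
`enhancer_state_recovery` 1.0 (n = 736) and
`domain_window_accuracy` 0.9708 (n = 6000). The test suite, including
oracle comparisons (exhaustive Viterbi enumeration, brute-force assignment
and interval arithmetic, hmmlearn cross-checks) runs with:

```bash
python -m pytest
```

See `docs/methods.md` for the model definitions, parameter values and
numerical choices.
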