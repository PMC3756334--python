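# stemward

Fossils preserve bones, teeth and shells; decay destroys muscles,
nerves and skin.  Phylogenies of fossil taxa are therefore inferred
from a systematically censored character sample, and the worry is not
just *less* resolution but *biased* placement: a fossil stripped of its
soft-part synapomorphies can slide down the tree, out of its crown
group and into the stem — **stemward slippage** — distorting divergence
dates and inferred evolutionary rates.

`stemward` implements the simulated-fossilization ("pseudoextinction")
experiment that quantifies this bias on neontological data.  Given a
morphological matrix whose characters are partitioned into **hard**
(biomineralized) and **soft** (non-biomineralized) anatomy, with a
designated outgroup, it runs two tests under maximum parsimony:

- **Node recovery** — delete the whole soft partition, re-search, and
  count how many clades of the original strict consensus survive,
  compared against a null of random character deletions of the same
  size: `r = |C(benchmark) ∩ C(test)| / |C(benchmark)|`, with the
  one-tailed rank p-value `p = (#{null ≤ r_sys} + 1)/(n + 1)`.
- **Taxon shift** — fossilize each taxon in turn (soft cells → `?`),
  re-search, and measure the change in its mean distance to the root
  over all most-parsimonious trees (`Δ = d_foss − d_orig`; negative =
  stemward).  Significance compares |Δ| with shifts from random
  deletions of the same number of that taxon's scored cells.

Everything needed to run the experiment end-to-end is included: NEXUS /
TNT matrix I/O with a hard/soft partition sidecar, the published
curation protocol (informativeness, taxonomic equivalents,
missing-data balancing, inclusion thresholds), a self-contained
parsimony engine (Fitch/Wagner scoring, random-addition + TBR search
with exact neighbor scoring, strict consensus, ACCTRAN patristic
distances), cross-dataset statistics (exact binomial tests, the
log-likelihood-ratio G test, dataset jackknife), and a synthetic-data
generator with planted, tunable taphonomic signal so the whole pipeline
is testable against known truth.  See `docs/methods.md` for the model
and its assumptions.

## Worked example

Generate a matrix with decay-biased signal (soft characters carry the
crownward synapomorphies), curate it, and run both tests:

```python
from stemward import (SyntheticSpec, generate_dataset, SearchSettings,
                      run_node_recovery, run_all_taxon_shifts, summarize_shifts)
from stemward.curation import curate

ds = generate_dataset(SyntheticSpec(n_taxa=10, n_hard=20, n_soft=20,
                                    signal_mode="decay_biased",
                                    homoplasy_rate=0.2, rng_seed=7))
matrix, reports, decision = curate(ds.matrix)

settings = SearchSettings(n_addition_replicates=3, hold_per_replicate=64,
                          max_trees=64)
res = run_node_recovery(matrix, "fossilization", n_reps=100,
                        settings=settings, rng_seed=1)
print(f"soft-deletion recovery: {res.recovery_index:.2f} "
      f"(null mean {res.null_indices.mean():.2f}), p = {res.p_value:.3f}")

shifts = run_all_taxon_shifts(matrix, n_reps=100, settings=settings, rng_seed=2)
summ = summarize_shifts(shifts, "fossilization")
print(f"taxa moved: {summ.moved}/{summ.n_taxa}, down {summ.moved_down}, "
      f"up {summ.moved_up}; significant {summ.significant} "
      f"({summ.significant_down} down)")
```

Output:

```
soft-deletion recovery: 0.50 (null mean 0.80), p = 0.079
taxa moved: 4/10, down 3, up 1; significant 2 (2 down)
```

Deleting this matrix's soft partition recovers 50% of the benchmark
consensus nodes where matched random deletions average 80% — the
fossilization filter destroys far more signal than its character count
alone explains, though a single 11-taxon matrix rarely reaches
significance on its own (p = 0.079; the pooled test across a suite of
matrices does, see the methods note).  Of the ten fossilized taxa, four
shift position; three of the four move toward the root, and both taxa
whose shift exceeds 95% of their random-deletion null move rootward —
the stemward-slippage signature.

## Command line

```sh
stemward simulate --n-matrices 20 --mode decay_biased --out-dir suite/
stemward run-all suite/ --profile desk --seed 1 --out-dir results/
stemward curate matrix.tnt --partition matrix.partition.csv --outgroup OUT --out curated.tnt
stemward stats --g-table 1071 965 1041 1083
```

`--profile paper` restores the published search effort (100 random
additions, hold 1000, max 10000 trees, 500 replicates); `desk` is the
reduced profile used throughout the tests.

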