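# Methods

## The experiment

`stemward` implements a simulated-fossilization experiment on
neontological morphological matrices.  Each matrix partitions its
characters into **hard** (biomineralized, readily fossilizable) and
**soft** (non-biomineralized) anatomy and names one outgroup taxon.
Two questions are asked of every matrix:

1. **Node recovery.**  Does deleting the entire soft partition degrade
   the inferred phylogeny more than deleting the same number of
   characters at random?  The benchmark is the strict consensus of the
   most-parsimonious trees (MPTs) for the full matrix.  The *node
   recovery index* of a perturbed matrix is the fraction of the
   benchmark's non-trivial clades that reappear in the perturbed
   consensus.  The systematic index (all soft characters deleted — or
   all hard characters, for the *inverse* control) is ranked against a
   null distribution of indices from random deletions of the same
   count.
2. **Taxon shift.**  When a single taxon is "fossilized" (its soft
   cells replaced by `?`), does it drift toward the root?  The taxon's
   position is its mean distance to the root over all MPTs, either in
   intervening nodes or in summed parsimony steps (patristic).  The
   shift `delta = d_perturbed − d_original` is compared in magnitude
   with shifts from replicates that blank the same number of that
   taxon's scored cells at random.  Negative delta = rootward
   ("down", stemward); positive = crownward ("up").

All permutation p-values use the rank convention
`p = (r + 1) / (n + 1)` with ties counted in `r`; 0 of 500 replicates
beyond the observed value gives p ≈ 0.002, 259 of 500 gives p ≈ 0.52.
Cross-dataset pooling adds *counts*, never averages fractions: the
pooled recovery is Σ recovered / Σ benchmark nodes, and the i-th pooled
null value combines every matrix's i-th replicate, preserving the
pairing of replicates across matrices.  Cross-dataset significance uses
exact binomial tests, a log-likelihood-ratio G test
(`G = 2 Σ O ln(O/E)`, χ² with 1 df, no continuity correction), and a
dataset-level jackknife (each matrix included with probability 0.5,
pooled comparison recomputed per resample).

## Parsimony engine

Tree length is the minimum number of state changes: Fitch set
operations for unordered characters, Farris interval operations for
ordered (additive) ones; `?` and inapplicable `-` are treated as the
full state alphabet; polymorphic cells as uncertainty sets.  Ordered
characters must carry contiguous state sets.

The heuristic search performs random-addition-sequence stepwise
insertion followed by tree-bisection-reconnection (TBR) swapping,
collecting *all* equally parsimonious trees up to the configured hold
and tree limits.  Every TBR neighbor is scored exactly via the
bisection decomposition `len(T′) = len(A) + len(B) + join(s_A(f),
s_B(g))`, where the per-edge directed state sets and component lengths
are computed once per bisection — parsimony length is invariant to
rooting, so each component may be treated as rooted at its attachment
edge.  The kernels are numba-compiled; correctness is checked against
full enumeration (`exhaustive_search`, ≤ 9 taxa) and an
assignment-enumeration brute force.

MPTs are kept **fully resolved with no branch collapsing**: trees
differing only across zero-length branches are distinct set members.
This makes node counting unambiguous and is required for the
root-distance metric.

Trees are rooted at the node where the outgroup attaches.  The clade
set of a tree is the outgroup-free side of each internal edge (sizes 2
to L−2); consequently a completely unresolved tree has an empty clade
set and node-recovery index 0.  A taxon's node distance to the root is
the number of clades containing it — the internal nodes strictly
between the terminal and the root, both endpoints excluded.  Patristic
distances use per-edge steps from an ACCTRAN resolution: per-character
Sankoff costs followed by a preorder single-state selection that takes
a change on the current (rootward) edge whenever an equally
parsimonious choice allows it; the per-edge steps provably sum to the
tree length (property-tested).

## Curation

Matrices are edited before analysis: parsimony-uninformative characters
removed (a character is informative when ≥ 2 states are each scored
unambiguously in ≥ 2 taxa); taxa flagged extinct removed; taxonomic
equivalents removed (rows identical, or identical up to MISSING
subsumption — the subsumed row goes, the first-listed of an identical
pair is kept, the outgroup never goes); missing data balanced between
partitions (if the partitions differ by ≥ 10 percentage points of
missing cells, taxa > 30% missing and then characters > 50% missing are
removed, iterating taxa-first until the gap closes or nothing removable
remains).  Inclusion requires ≥ 30 characters, ≥ 10 taxa, and a hard
fraction (|hard| / all characters) between 0.20 and 0.80, boundaries
inclusive.  The pipeline is idempotent and never alters retained cell
values.

## Synthetic data

The generator emulates the kind of compiled neontological matrices the
experiment needs, with known truth:

- **Tree**: Yule (uniform-split) topology over `n` ingroup taxa; one
  outgroup attached at the root carrying the ancestral state for every
  character.
- **Characters**: binary by default.  Each character receives one
  primary change on a parsimony-informative edge (both sides ≥ 2 taxa;
  a terminal-edge primary change would be an autapomorphy that curation
  deletes, systematically distorting the hard:soft ratio).
- **Signal modes**: *exchangeable* places both partitions' changes
  uniformly over informative edges — the calibration null, symmetric
  under partition relabelling.  *Decay-biased* places a fraction
  `crown_bias` (default 0.8) of soft changes on the **crown zone** and
  `deep_bias` (default 0.6) of hard changes on the **deep zone**.
  Zones are defined by clade size, the cladistic depth proxy: crown =
  edges subtending ≤ 3 taxa (cherries and near-cherries — numerous, so
  crown-biased signal is spread thin), deep = edges subtending ≥
  max(4, n/2) taxa (few, so root-biased signal is redundant).  Node
  depth itself is a poor zone covariate on Yule trees: both equal-count
  and depth-range terciles make the crown zone small, concentrating
  rather than spreading soft signal.
- **Homoplasy**: each character receives `Poisson(homoplasy_rate)`
  extra convergent changes placed uniformly over *all* ingroup edges,
  terminal edges included.  The default rate of 1.0 gives consistency
  indices near 0.5, typical of real morphological matrices.  Two
  things depend on realistic homoplasy: (i) autapomorphic convergence
  is what keeps sister taxa distinguishable — without it every cherry
  loses a taxon to taxonomic-equivalence curation; (ii) in
  near-noiseless data, deleting cells can only *release* a taxon
  rootward (it creates placement ties along the path to the root but
  never pulls the taxon crownward), so the random-missingness null
  becomes artificially one-sided.  Realistic conflicting signal
  restores magnitude symmetry (zero mean displacement) and balances the
  direction of substantive shifts, though a residual rootward lean in
  the sign of sub-node drifts remains (see Limitations).
- **Missingness**: cells are blanked independently per partition
  (default 10% in each, keeping partitions balanced through curation).

What the generator does *not* emulate: correlated character evolution,
ordered/multistate coding conventions of particular literatures,
non-random taxon sampling, polymorphism, and rate heterogeneity among
lineages.  Passing tests on this generator therefore demonstrate that
the pipeline detects the planted taphonomic asymmetry and is calibrated
under its null — not that any particular empirical dataset will show
the effect.

## Problem sizes and search effort

The published protocol (100 random additions, hold 1000, max 10000
trees, 500 replicates) is available as the `paper` profile.  The test
suite and the acceptance script run at desk scale, chosen to keep a
full run in minutes on one core while leaving the statistics
interpretable:

- search: 2–3 addition replicates, hold = max trees = 32–64;
- node-recovery calibration: 50 exchangeable matrices (15 ingroup taxa,
  30 + 30 characters), 100 random-deletion replicates;
- slippage recovery: 20 decay-biased matrices (10 ingroup taxa,
  20 + 20 characters, homoplasy 0.2, crown bias 0.8), 100 replicates,
  every ingroup taxon fossilized;
- the directional-symmetry check of the random null uses the taxon as
  the unit (the direction of its mean random shift): per-replicate
  directions within a taxon are strongly correlated, so a binomial
  interval over replicates would be invalid.

Truncating the MPT set at 32–64 trees slightly over-resolves consensus
trees relative to the untruncated strict consensus; the distortion is
identical for systematic and null conditions and measured effects were
unchanged at hold limits of 400.

## Numerical conventions

- A taxon "moved" when |delta| > 1e-9 (float noise in means over MPTs).
- Shift significance compares magnitudes only (two-sided in direction)
  at alpha = 0.05, per the protocol; a directional variant exists.
- Tie-breaks: insertion and swap moves take the first minimum in a
  deterministic enumeration order; trees are deduplicated by their
  bipartition sets.  Results depend only on the seeds recorded in the
  run manifest.
- Random character deletions that empty a partition or leave the matrix
  uninformative are kept, not redrawn (redrawing would bias the null);
  they score what they score (recovery recorded as 0 when no search is
  possible).

## Limitations

- Under random per-taxon cell deletion in exchangeable synthetic data,
  the *mean* root-distance displacement is approximately zero, but the
  *sign* of the per-taxon mean shift skews rootward: deleting cells
  mostly releases placement ties along the path to the root, producing
  many sub-0.1-node rootward drifts, while the rarer substantive
  repositionings (> 0.25 nodes) are direction-balanced.  Sign-based
  "moved down / moved up" tallies over this null therefore lean
  rootward even though the null carries no net displacement.  This is
  insensitive to search effort and to the generator's homoplasy and
  missingness levels within realistic ranges; empirical matrices, with
  their already-diffuse placements and richer character conflict,
  behave more symmetrically.  Directional conclusions in this package
  should therefore always be read against the measured random-null
  direction split, not against an assumed 50/50.
- The heuristic guarantees neither optimality nor MPT-set completeness;
  at desk scale both failure modes add symmetric noise to systematic
  and null conditions.  Oracle tests bound the optimality gap at small
  taxon counts (score equality with exhaustive search on 200 random
  matrices).
- Ordered characters are supported in scoring and search but not in
  ACCTRAN patristic distances.
- Taxonomic-equivalence removal uses strict cell equality (up to
  MISSING); polymorphism-aware subsumption is not implemented.
- The jackknife resamples datasets, not characters or taxa.
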