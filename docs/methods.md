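# Methods

This note documents the models, defaults, numerical choices and known
limitations of `gcmalign`. It covers design territory the API reference
does not: why the defaults are what they are, and what the tests do and do
not demonstrate.

## The merge model

The central object is the **alignment graph**: every column of every
subalignment is a node, and an edge accumulates one unit of support for
every pair of upper-case residues that a backbone column places together
(residue-pair granularity, not mere column co-occurrence — a match
witnessed by ten sequence pairs is stronger evidence than one witnessed by
a single pair). Residues map from a backbone to their home column through
the sequence's ungapped site index, which is invariant under gap placement;
this is also why all pair bookkeeping package-wide uses 0-based ungapped
site indices.

Edges between two columns of the *same* subalignment can arise (a backbone
may disagree with a subalignment's internal structure) and are recorded,
but clusters are forced valid afterwards: a cluster holding several columns
of one subalignment keeps, per offender, the column with the greatest edge
weight into the cluster (tie: lower column index) and evicts the rest into
singletons. The alternative — silently dropping intra-subalignment support —
would bias MCL's transition probabilities.

### Markov clustering

MCL operates on the column-stochastic matrix of the support graph with
self-loops. Defaults:

| parameter       | default            | rationale                                   |
|-----------------|--------------------|---------------------------------------------|
| inflation       | 2.0                | standard granularity for MCL                 |
| self-loop       | max incident weight | keeps attractors stable without drowning weak nodes |
| prune threshold | 1e-8               | sparsity guard; far below meaningful mass    |
| tolerance       | 1e-8               | matrix max-change convergence test           |
| max iterations  | 1000               | safety valve; non-convergence interprets the current matrix with a warning |

Clusters are read off as connected components of the converged matrix's
support. Isolated nodes (columns with no backbone evidence) become
singleton clusters and survive into the output as their own columns.

### Trace ordering

A valid trace must visit every subalignment's columns in increasing order.
The precedence digraph is built from *consecutive* column pairs only
(the full precedence relation is the transitive closure of these edges, so
cycle detection and topological sorting over them are equivalent and the
edge count stays linear in the total column count). While a strongly
connected component persists, one node is moved out of its cluster into a
singleton: the candidate maximizing cycle-supporting edges destroyed per
unit of support weight lost, with ties broken by the smallest
(subalignment, column). This greedy repair is this package's concrete
realization of conflict resolution "with minimal changes"; it makes no
optimality claim. Any deterministic ordering satisfying the trace
invariants is acceptable behavior, and the invariants are asserted after
ordering on every run.

## Decomposition and recursion

The dataset is split by centroid edge decomposition: recursively delete
the edge minimizing the larger side's leaf count. The target subset size is
⌈n/25⌉ (25 subsets by default). "Balanced" is interpreted as
minimize-the-larger-side; ties go to the edge met first in a deterministic
traversal from the lexicographically first leaf — the choice is about
reproducibility, not accuracy.

Subsets larger than the recursion threshold — default
max(backbone size, target subset size) — are aligned by a nested pipeline
run rather than the base aligner, because base aligners (and the trace
search) degrade past a few hundred sequences. A nested run inherits its
parent's strategy, derives its seed as a hash of (parent seed, subset
index), and runs its own resumable workdir. A depth cap (default 3) guards
against pathological trees; recursion also requires the subset to be a
proper subset of its parent's dataset, which guarantees termination.

## Base aligner

The built-in base aligner is guide-tree progressive profile–profile
alignment: k-mer NJ tree, then Gotoh affine-gap DP (numba-compiled) over
profile columns. Scoring: +1/−1 for nucleotides, BLOSUM62 for proteins;
gap open −4, gap extend −1 — conventional midpoint values. Gap penalties
are scaled by the occupancy (non-gap fraction) of the profile column being
skipped, the usual position-specific treatment; without it, insertion
columns from different lineages over-merge and accuracy collapses beyond
~100 sequences. A tiny deterministic index-keyed offset (1e-9) is added to
each pairwise distance so agglomeration never faces a tie and trees are
identical across processes.

The aligner's identity is deliberately pluggable: any external tool
satisfying the `{input} → {output}` FASTA subprocess contract can replace
it for subsets and backbones (an accurate external aligner is the intended
production choice; the built-in keeps the package self-contained). If the
external tool fails or is missing, the built-in takes over with a logged
warning rather than failing the run.

## Backbones

Defaults: 10 backbones of 200 rows. Each backbone draws
⌊backbone_size/k⌋ rows per subset (remainder to the first subsets),
uniformly without replacement, exhausting small subsets. 200 matches the
practical comfort zone of base aligners; users with many subsets should
raise `backbone_size` above the subset count (enforced) and may supply
their own backbones. Smaller backbones are better-aligned; several smaller
backbones usually beat one large one at equal total cost.

## Compression

`estimate_size` is the exact serialized FASTA byte count (wrap width 60).
Candidates are ranked by upper-case letter count (the quantity that
determines pairs lost — C(u,2) per dissolved column), leftmost first on
ties; the candidate list is recomputed after every dissolve (simplicity
over a lazy priority queue; compression is I/O-bound in practice anyway).
Shunting prefers left, then right, with the recursive domino pushing
intervening lower-case letters onward; a move blocked in both directions
for any row invalidates the whole dissolve. Lossless mode restricts
candidates to u ≤ 1. Decompression is not provided: sequences are always
recoverable (strip gaps, upcase) but dissolved columns are not.

## Error metrics

SPFP/SPFN are computed by column-wise counting (each column contributes
C(u,2) pairs; shared pairs are counted by bucketing a column's residues by
their column in the other alignment), never materializing the quadratic
pair set. Lower-case letters are excluded from pairs on *both* sides —
consistent with compression semantics, and it means scoring a compressed
alignment reflects only the homology it still asserts. An alignment with
zero pairs contributes 0 to its rate (a convention, chosen so degenerate
references do not produce NaNs).

## Task runtime

Tasks are JSON records named by a content hash of (type, inputs), so
re-enqueueing is naturally idempotent and a resumed run recognizes finished
work. Claiming renames `pending/x.json` → `running/x.json`; POSIX rename
atomicity is the whole locking story, so correctness requires a shared
filesystem with atomic rename (documented limitation — no fcntl locks, no
leases). Claims older than a timeout (default 300 s) are pushed back to
pending, recovering from workers that died mid-task; task outputs are
written atomically (temp file + rename) so a half-written output can never
be observed. Failed tasks retry up to 3 attempts, then fail the pipeline by
name.

Determinism: every task's output is a pure function of its recorded inputs
(seeds included), and the merge is orchestrated sequentially, so the final
alignment is byte-identical for any worker count and any
interruption/resume pattern with the same seed.

During graph building and assembly, subalignments pass through a
single-slot store; the instrumented high-water mark of concurrently loaded
subalignments is asserted to be 1 and recorded in `output/done.json`. The
merged alignment is written subalignment-by-subalignment (rows grouped by
subset), which is what makes the single-slot discipline possible.

## Synthetic data

The simulator evolves sequences down a Yule topology with exponential
branch lengths: uniform-replacement substitutions (probability
1 − exp(−rate·bl) per site), and Poisson indel events with geometric
lengths. Every residue carries a persistent site identifier; new insertions
enter a global column order adjacent to their lineage's left neighbor,
which keeps every lineage's site order a subsequence of the global order —
so the true alignment is exact by construction, and its restriction to any
taxon subset has exactly the restricted pair set (the property the merge
oracle test depends on).

Preset divergences were calibrated empirically at 40 taxa:
`16S-like` (substitution rate 0.18) targets ~0.2 average p-distance,
`rnasim-like` (0.47) targets ~0.4. Because tree depth grows with the taxon
count, realized p-distance rises with n at a fixed rate; the ~0.3
divergence regime used in the end-to-end comparisons corresponds to rate
0.2 at 200 taxa.

What the simulator does *not* emulate: rate heterogeneity across sites or
lineages, non-homogeneous substitution models, base composition bias,
fragmentary sequences, and alphabet-specific indel structure. Tests passing
on this generator demonstrate the machinery's correctness contracts
(conservation, trace validity, exactness under consistent evidence,
determinism), not biological-accuracy claims on real data.

## Problem sizes in the test suite

The test and acceptance runs use 16–200 taxa with root length 100,
3–10 backbones of 20–50 rows, and 200 random compression alignments up to
10×40 — sizes chosen so the full suite exercises every code path, including
recursion and multi-process runs, in a couple of minutes on one core.

## Known limitations

- The ordering heuristic is greedy; adversarial cluster structures may be
  split more than strictly necessary.
- MCL is run on the whole graph at once; with hundreds of subalignments of
  many thousands of columns the matrix squaring dominates runtime.
- The built-in aligner is a fallback, not a contender: for production
  accuracy plug in an external aligner for subsets and backbones.
- Rename-based locking assumes one shared POSIX filesystem; workers on
  filesystems without atomic rename (some network mounts) can race.
- Guide-tree adapters (external tree estimators) are subprocess hooks and
  are not exercised by the test suite.
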