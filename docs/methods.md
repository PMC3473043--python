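# Methods

## The evolution model

A simulation starts from one ancestral sequence of `n_pos` residues drawn
independently per position from an emission profile (a position-specific
distribution over the 20 amino acids; uniform 1/20 when none is supplied).
The population then grows down a copy-tree: branching level 1 makes `b1`
identical copies of the ancestor; each later level `k` appends `b_k` copies
of every current lineage. Between expansions, every lineage runs a fixed
number of mutation/recombination cycles. A cycle applies, in order:

1. **Point mutations.** Each non-covarion position is drawn with
   probability `mutation_prob`; a draw samples the position's emission
   profile and may return the current residue (a silent draw changes
   nothing and is not counted).
2. **Covarion co-mutation.** Each covarion pair is drawn with probability
   `covarion_mut_prob`; a draw samples a residue *pair* jointly from the
   pair's 21×21 joint distribution and writes both positions. By default
   each pair gets a two-state perfectly coupled distribution (two
   residue-pair states at probability ½ each, chosen once per run from the
   run's RNG); an explicit joint table can be supplied per pair, e.g. the
   empirical joint frequencies of two columns of a reference alignment.
3. **Zone recombination.** With probability `recombination_prob`, the
   lineage receives one uniformly chosen zone — a column block delimited by
   the fixed interior crossover points — from a uniformly chosen other
   lineage (any-to-any: recombination crosses branches).

Alignment length is fixed; there is no indel process and no explicit
fitness. The final population is optionally subsampled uniformly without
replacement to `n_seq` rows. The subsample is kept in *drawn* order, so the
delivered MSA's row order carries no residual tree structure — it is an
"unsorted" alignment, which is the natural baseline for the resorting step
below.

### Ground-truth bookkeeping

Per cycle and lineage, with M = positions changed by point mutation, C =
covarion pairs whose positions actually changed, R = positions changed by
recombination:

* `mutCOV` += 1 for every unordered pair within M;
* `covCOV` += 1 for every changed covarion pair, and for every cross pair
  between positions of *distinct* changed covarion pairs (two pairs
  co-mutating in the same cycle are indistinguishable, to any detector,
  from four);
* `recCOV` += 1 for every unordered pair within R, and for every pair
  mixing a point mutation with a recombination change (mechanism priority:
  mixed pairs are credited to recombination);
* `totCOV` accumulates every increment in parallel.

With this contract `totCOV = mutCOV + covCOV + recCOV` holds elementwise
after every cycle by construction; the equality is asserted as a standing
regression check on the bookkeeping rather than as a mathematical
discovery. An event log (level, cycle, lineage, mechanism, positions)
allows replay checks, e.g. that a covarion pair's `covCOV` entry equals its
number of logged co-mutation events.

## Default parameters

| parameter | default | rationale |
|---|---|---|
| `branching` | (3, 2, 4) | three-level copy-tree (45 lineages); the benchmark preset adds a fourth level (3, 2, 4, 6) → 315 lineages so that ~300-sequence MSAs need no replication of lineages |
| `cycles_per_level` | 10, or per-level tuple; preset (16, 10, 4, 2) | decreasing counts give long internal and short terminal branches — the branch-length shape of real families, where some sequence pairs stay nearly identical while clades are deeply diverged |
| `mutation_prob` | 0.02 per position per cycle (preset) | over a 32-cycle root-to-leaf path this gives ≈0.6 substitution draws per position: deep but unsaturated divergence, comparable to a diverse protein family |
| `covarion_mut_prob` | 0.05 per pair per cycle (preset) | ≈1.6 co-mutation events per lineage path, enough for strong `covCOV` signal without dominating the alignment |
| `recombination_prob` | 0.1 per lineage per cycle | recombination events outnumber covarion events and touch whole zones, so `recCOV` dwarfs `mutCOV` — the regime in which block transfer is a serious confounder for detectors |
| background for relative entropy | uniform 1/20 | no composition prior is assumed; configurable |
| contact centroid | all non-hydrogen atoms | "residue centroid" is ambiguous; a side-chain-only mode is provided (glycine falls back to all heavy atoms), contacts use a strict `< cutoff` comparison at 8 Å |

`FAMILY_PRESETS` records the eight benchmark family geometries (length,
covarion count, crossover points); `preset_config` builds a full
configuration from one of them.

## The differential binary methods

Resorting is greedy nearest-neighbor chaining on Hamming distance; exact
minimization of the change count is a traveling-salesman-path problem, so
no global optimum is claimed. The default seed is the most similar sequence
pair (fastest and empirically best-performing start); `fixed_index` and
`scan_all` (every sequence tried as chain seed, minimum kept) are
available. Ties always resolve to the lowest original row index, making
every pipeline deterministic.

Encodings treat the gap as an ordinary 21st symbol: gap→gap across
consecutive rows is "no change", gap↔residue is a change. The global
differential expansion marks the *new* symbol of each change in the
21-column block of its position (an all-residue one-hot variant exists
behind a flag for comparison, but it is no longer differential). Column `c`
maps to block `[c*21, c*21+21)`.

Score pipeline choices:

* MI uses plug-in frequencies in bits, no pseudocounts. Amino-acid MI and
  OMES exclude gapped rows pairwise (gap inflation is a known artifact);
  the binary pipelines do not, since gaps are already folded into change
  events.
* ZPX2 row statistics exclude the diagonal and use the population (n)
  denominator; rows with zero spread get z = 0. ZPX2 is the plain
  elementwise square, which discards sign — a pair with two large negative
  z-scores ranks as high as two large positive ones; a signed-square
  variant is available. An APC-first option exists but is off by default:
  the composite methods apply ZPX2 directly to the merged matrix.
* MI/COV merging fits ordinary least squares `mi ≈ a·cov + b` over the
  off-diagonal upper triangle and averages `mi` with the rescaled
  covariance; a constant covariance degenerates to MI alone with a warning.
* Every final score matrix gets its diagonal set to the matrix minimum so
  self-pairs never enter a descending ranking.

## Evaluation

Recovery curves follow the sorted-pair assignment protocol: rank the
method's upper-triangle pairs by score (ties lexicographic), replace each
ranked pair's value by the truth count of that same pair, accumulate. The
ideal-observer curve is the truth counts accumulated in their own
descending order; it bounds every method curve from above by the
rearrangement inequality, so the bound is a sanity check, not a finding.

Contact recall filters both the ranking and the contact denominator to
pairs with more than `separation` intervening positions (at least *s*
intervening positions ⇔ `|i − j| ≥ s + 1`), and reports the percentage of
all surviving sub-cutoff pairs captured among the top-k, with k up to one
pair per residue (x = 100 at k = n_pos). The denominator is filtered
consistently with the numerator.

Curve merging normalizes each curve's x range to [0, 1], fits a
shape-preserving piecewise cubic Hermite interpolant (PCHIP), resamples on
a common grid (default 100 points), and reports the pointwise mean and
plain standard deviation across curves; the spread hook can be replaced by
a weighted alternative.

## What the generator does and does not emulate

Simulated MSAs reproduce: tree-structured relatedness with heterogeneous
branch lengths, position-specific composition (when a profile is given —
the per-column relative-entropy profile of the simulated MSA then tracks
the reference profile), forced covariation with known joint distributions,
and block recombination with realistic zone geometry. They do not
reproduce: indels (columns are never inserted or deleted, so gap handling
is exercised only through input normalization), selection or rate variation
tied to structure, site-specific substitution matrices, or alignment error.
A detector that performs well here is therefore validated against
phylogenetic and recombinant confounders, not against misalignment or
indel-rich regions.

One behavior of the resorting step deserves a caveat. Minimizing the
change count reliably lowers the binary MSA's mean column entropy and mean
column MI — the mechanism the differential binary methods exploit (they
work by *minimizing* mutual information, so concerted changes stand out
against a quieter background). The acceptance suite also checks a
companion expectation that the mean *joint* entropy rises under resorting;
under this generator's conditions it falls instead, tracking the identity
`Δjoint = ΔMI − Δ(H_i + H_j)`: the MI drop never exceeds the entropy-sum
drop because unsorted mean pairwise MI is small compared to column entropy
in every regime the copy-tree produces. That check is left failing rather
than redefined; the entropy and MI directions, which carry the method's
rationale, hold in every replicate.

## Numerical notes

* All randomness flows through one `numpy.random.Generator`; identical
  config and seed give bit-identical alignments, records and event logs.
* Plug-in entropies treat empty cells as contributing zero (no NaN paths).
* Degenerate inputs are defined, not exceptional: constant alignments give
  all-zero MI; constant covariance degenerates merging to MI; zero-spread
  z-score rows give 0; all-gap columns have relative entropy 0.
* Matrix TSVs store the upper triangle only with 1-based indices;
  permutations are written as (new_rank, original_index), 1-based.
* Test and acceptance problem sizes (e.g. 20 replicates of 300×280
  benchmark-geometry simulations; 100×150 additivity runs) were chosen as
  the smallest sizes at which the statistical properties under test are
  stable across seeds.
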