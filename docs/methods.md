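# Methods

## Model and procedure

Given a multiple sequence alignment A of n taxa and l columns, a
reference phylogeny T is inferred by Neighbor-Joining (NJ) on a corrected
distance matrix: Jukes–Cantor, d = −(3/4)·ln(1 − (4/3)p), for DNA, and
the Kimura approximation, d = −ln(1 − p − 0.2p²), for proteins, where p
is the proportion of differing sites.  N pseudo-replicated alignments
PRA_1..PRA_N are drawn by resampling l columns with replacement, and a
tree T_t is inferred from each by the same distance + NJ pipeline.

Branch k of T is scored `100 · Σ_t w_t · 1[k ∈ B_t]`, with B_t the set of
non-trivial splits of T_t and w a weight vector with w_t ∈ [0, 1] and
Σ w_t = 1.  The five strategies differ only in w:

* **std** — uniform, 1/N; equals the classical Felsenstein percentage
  exactly (the uniform case is computed with the integer-count formula,
  so the equality is exact in floating point too).
* **ls** — w_t ∝ 1/ls_t, where the least-squares coefficient
  ls_t = Σ_{i<j} (d_t(i,j) − δ_t(i,j))² sums, over unordered pairs, the
  squared disagreement between the replicate's distance matrix and its
  tree's patristic distances.  Smaller ls means the replicate is closer
  to the space of additive (tree) metrics, so inversion orients the
  weight correctly.  An exactly additive replicate (ls = 0) is floored at
  ε = 10⁻¹² before inversion and so receives the maximal finite weight.
* **norm_ls** — ls is min–max normalized onto [0, 1] to accentuate
  differences, and w_t ∝ 1 − norm_ls_t.
* **sbs** — each replicate tree's overall robustness ss_t is the mean
  classical bootstrap support of its internal branches, estimated from
  Ns secondary resamples of PRA_t (two-level bootstrap); w_t ∝ ss_t.
* **norm_sbs** — w_t ∝ min–max normalized ss_t.

Any constant quality vector (including a degenerate normalization where
max = min) degrades gracefully to uniform weights, i.e. to the
traditional bootstrap.  Weight proportionality is linear in the quality
measure; this is the simplest scheme satisfying the range, sum and
monotonicity constraints (the same family used for weighting members of
clustering ensembles by diversity), and alternatives (e.g.
Normal-distribution or group weighting) are deliberately out of scope.

## Noise-robustness protocol

Two corruption models, applied to the original alignment without
realignment:

* **Strategy 1 (substitution)** — every non-gap character independently
  changes with probability NR to a uniformly chosen different symbol
  (1/3 per alternative nucleotide, 1/19 per alternative amino acid).
* **Strategy 2 (indel blocks)** — blocks with sizes drawn uniformly in
  [⌈n·l·NR/10⌉, ⌈n·l·NR/2⌉] are applied until ⌈n·l·NR⌉ characters are
  affected (the last block truncated to fit); each block is, with
  probability 1/2, an elimination (a contiguous run in one row
  overwritten with gaps — elimination masks in place rather than
  shifting the row, since deletions are expected to *introduce gaps*
  into the alignment) or an insertion (random characters into one row,
  gap columns added to all other rows to keep the alignment
  rectangular).
* **combined** — one of the two at full NR, chosen with probability 1/2
  per draw, so repeated draws mix the strategies 50/50.

Robustness of a support strategy is the least-squares bootstrap
deviation ls_bd = Σ_k (bs_k − bsn_k)², where bs are the noise-free
scores of the original tree's m branches and bsn the scores of the
*same* branches recomputed from replicates of the noisy alignment.  The
unnormalized sum (not a mean or root) is used; support tables at each
noise level are averages over `repeats` independently seeded runs, and
ls_bd is computed between the averaged tables.  Replicate streams are
keyed by repeat index only, never by noise level, so a level of 0
follows the identical random path as the baseline and yields ls_bd = 0
identically.

## Randomness and reproducibility

All randomness descends from one root seed through named substreams
(`numpy` `SeedSequence` spawn keys): primary replicate t uses
(primary, t), secondary replicate (t, s) uses (secondary, t, s), and
noise, simulation and repeat-derivation have their own namespaces.  Any
individual replicate can therefore be regenerated in isolation, and the
nested two-level design is exactly reproducible across platforms.  Q
matrix ties in NJ are broken by the lexicographically smallest
(row, column) pair, and negative NJ branch lengths are retained rather
than clamped — the LS coefficient measures the tree exactly as NJ
produced it.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| N | 100 | primary pseudo-replicates; classical bootstrap resolution is 100/N points |
| Ns | 100 | secondary replicates per primary (SBS kinds only); cost scales as N·Ns |
| repeats | 1 | independently seeded runs averaged into each support table |
| NR | — | noise fraction of characters (0–1) |
| saturation cap | 5.0 subst./site | distance assigned when a correction's log argument is ≤ 0, keeping LS and NJ finite |
| ε (LS floor) | 10⁻¹² | floor for ls_t = 0 before inversion |

Gap treatment in distances is pairwise deletion: sites with a gap or
ambiguity code in either sequence of a pair are skipped for that pair
only.  This is required for the indel-noise protocol, which introduces
gaps and still expects distances afterwards; complete-column deletion
would discard entire columns per indel and distort the comparison.

## Synthetic data generator

`simulate_alignment` draws a uniform random resolved topology (by
sequential random edge attachment), branch lengths uniform in
[0.02, 0.3] substitutions/site, and evolves i.i.d. sites from a uniform
root under the k-state symmetric substitution process (k = 4 or 20), so
the Jukes–Cantor correction is an exactly consistent estimator of DNA
path lengths (the Kimura protein correction is a close approximation for
the 20-state case).  Defaults in tests mirror a small mitochondrial-DNA
study: 12 taxa × 896 sites.

What the generator does *not* emulate: among-site rate variation,
base-composition bias, transition/transversion bias, realistic indel
histories, and alignment error.  Passing tests on this data demonstrate
the correctness and internal consistency of the machinery — not that any
weighting strategy is superior on real sequences.

## Numerical choices and degenerate inputs

* Distance saturation (p ≥ 3/4 for JC; 1 − p − 0.2p² ≤ 0 for Kimura) is
  capped at 5.0 rather than infinite, keeping downstream LS and NJ
  defined; a pair with zero comparable sites is an error.
* Support scores are kept at full precision internally and reported at
  one decimal; table comparisons (`compare_strategy_tables`) judge
  equality at that reporting precision.
* Splits are stored canonically as the side not containing the first
  taxon of the fixed taxon ordering, so split sets from different trees
  over the same taxa compare by plain set operations; the newick writer
  emits that anchor taxon first so the convention survives round trips.
* Branches of T absent from every replicate score 0 and stay in the
  table.
* Multiple repeats average support tables (rather than pooling all
  replicates into one larger set); averaging keeps N, and hence the
  per-run score resolution, fixed across configurations.

## Problem sizes used in validation

The automated checks run at deliberately modest scale: the NJ oracle
enumerates all topologies for up to 6 taxa; support properties use
6–12-taxon alignments of 200–900 columns with N ≤ 50 and Ns ≤ 50; the
robustness surrogate uses a 12 × 896 DNA alignment at 10% combined noise
with N = Ns = 50 averaged over 10 repeats.  These sizes were chosen so
the full suite completes in a few minutes while every property is still
exercised end to end.

## Known limitations

* Only distance-based NJ inference is implemented; weighting replicate
  trees from likelihood or parsimony inference (including the handling
  of multiple optimal trees per replicate) is out of scope, as are
  consensus-tree construction from weighted replicates and two-level
  p-value corrections.
* The robustness advantage of the normalized secondary bootstrap
  (smaller ls_bd than the traditional bootstrap) reproduces on some
  synthetic alignment realizations but reverses on others, even with
  many repeats — on clean simulated data the effect is
  realization-dependent and small relative to between-alignment
  variation, although normalized SBS consistently yields the larger sum
  of branch scores.  Conclusions about real data should not be drawn
  from the synthetic surrogate alone.
* Min–max normalization makes weights sensitive to the single best and
  worst replicate; a heavy-tailed quality distribution can concentrate
  weight and increase score variance.
* The indel-noise model takes NR as a fraction of all n·l characters
  and the block-size bounds n·l·NR/2 and n·l·NR/10 literally; at very
  large NR single blocks can exceed a row and are truncated (logged at
  debug level).
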