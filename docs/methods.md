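# Methods

## Model and coordinate frame

All statistics are computed in a query-anchored frame: the query record
defines the L columns, columns where the query is gapped are deleted from
every row at read time, and insertions relative to the query are discarded.
Every matrix is therefore L×L over the query's own positions, which is what
heat maps, trees and neighbor diagrams index. The query itself is kept as
row 0 of the alignment and participates in all counts; this makes the
"non-weighted" scheme coincide with a naive column count that includes the
query. Ambiguity codes (B, Z, X, J, U, O) are kept as literal characters:
the binary match/mismatch classification only needs equality to the query
residue, and an ambiguity code simply compares unequal.

The pairwise state space is deliberately coarse — match/mismatch to the
query rather than a 20×20 amino-acid pair model. This keeps counts dense at
realistic alignment depths and matches the 4-state frequency model the
scores are defined on; Potts-style direct-coupling models are a different
method family and out of scope.

## Frequencies, pseudocount, and weighting

For a column pair, rows gapped at either position are excluded. Each
remaining row contributes its weight to exactly one of the four joint
states; N_eff is the summed weight, and every frequency (joint and marginal)
is count/(N_eff + λ) with λ = 1. Marginals are computed from the same
pairwise-complete row subset as the joint counts — mixing subsets would
break the p(x,y) ≤ relationship with its marginals and allow negative MI
structurally rather than from rounding. Negative MI from floating-point
rounding is floored at 0.

Weight schemes and their defaults:

| scheme | weight per row | notes |
|---|---|---|
| none | 1 | naive counting |
| dissimilarity | 1 − seqid(row, query) | the query row itself weighs 0 |
| gap | 1 − gap fraction over the L query columns | |
| phylogeny | 1 / (cluster size at > 80 % identity) | strict inequality; threshold configurable |

Sequence identity uses mutually non-gap positions as the denominator.
Local-alignment-style inputs leave long gap runs; a full-length denominator
would systematically underestimate relatedness and inflate phylogeny cluster
counts. Two rows sharing no non-gap position have identity 0. The 80 %
clustering threshold sits mid-way in the 70–90 % band over which the
weighting is insensitive; it is strict (`>`) so that rows at exactly the
threshold remain separate, and a row always belongs to its own cluster, so
no weight is ever 0 or undefined under this scheme. A row with weight 0
(e.g. a query duplicate under dissimilarity) is retained and simply
contributes nothing — the frequency algebra needs no special case.

## Metrics and post-processing

Natural logarithms are used throughout; the 1/log 4 and 1/log 20
normalization factors make the normalized entropies base-independent, and
fixing the natural log pins down the raw (pre-normalization) MI scale in
nats for reproducibility.

- **MI** is min-max normalized over the off-diagonal entries only; the
  diagonal carries per-residue frequencies with different semantics and
  stays out of the normalization. A constant off-diagonal maps to all
  zeros.
- **MIp** applies the average product correction on the *raw* MI of the
  selected weighting variant — APC(a,b) = row-mean(a)·row-mean(b)/grand-mean
  with off-diagonal means — then floors negatives at 0, then min-max
  normalizes, in that printed order. If the grand mean is 0 the matrix is
  all-zero and passes through unchanged.
- **χ²** is evaluated literally on the pseudocounted frequencies (no ×N_eff
  count rescaling) and converted to the df = 1 cumulative probability via
  the chi-square CDF. The count-scaled OMES-style variant is available
  behind `scale_chi2_by_neff` (off by default): scaling changes where a
  fixed cumulative-probability cutoff bites, and the literal frequency form
  is the reference behaviour.
- **r** uses per-row similarity scores s_il — the PSSM log-odds of row l's
  residue at query position i. Position means and standard deviations are
  weighted by the same scheme weights as the covariance sum (mixing
  weighting regimes would bias the standardization) and use the population
  (1/N_eff) form. A position with zero score variance returns r = 0 for all
  its pairs rather than erroring: fully conserved columns carry no
  covariance signal and must not crash a pipeline. Values are clamped to
  [−1, 1] against rounding.
- **S** is the 4-state joint entropy normalized by 1/log 4.

Diagonals: weighted pseudocounted frequency of the query residue for
MI/MIp/χ²/r; for S, the 20-state entropy of the PSSM probability rows
normalized by 1/log 20.

Without a PSSM the tool degrades gracefully and labels the fallback in the
matrix metadata (`similarity_source`): r uses BLOSUM62 scores of
(query residue, observed residue), and the S diagonal uses 20-state weighted
column frequencies from the MSA itself. A profile-based PSSM remains the
preferred similarity source when available.

## Clustering

Scores become distances by d = 1 − score for MI/MIp/χ² (normalized or
probability-scaled, hence in [0, 1]) and for r after flooring negatives at
0. Joint entropy is used directly as the distance: S is small exactly for
jointly conserved (related) pairs, so 1 − S would invert the intended
geometry. Distances are clamped to [0, 1] and the diagonal forced to 0.

Complete linkage is implemented in-package as the direct O(L³)
agglomeration so the tie-break is fully specified: among pairs at the
minimal complete-linkage distance, the lowest pair of cluster ids (leaves
first, then creation order) merges first. This yields bit-identical trees
across platforms. Complete linkage is monotone, so merge heights never
decrease. The test suite checks height-multiset equality against scipy's
implementation; exact node ordering relative to other packages' internal
tie-breaking is deliberately not promised.

Newick export is ultrametric: each internal node sits at elevation
height/2, so a leaf branch is half its first merge height and an internal
branch is the elevation difference to the parent. Labels with Newick
metacharacters are quoted. `cut_clusters` keeps merges at or below the cut
height.

## Rendering

Heat maps use a diverging blue (0, no covariation) → white (0.5) → red
(1, complete covariation) palette; for joint entropy the palette is
reversed so 0 (complete joint conservation) renders red. Interactive zoom
is replaced by a rectangular region crop. Tree leaves read residue letter +
label ("E171" style) and are colored by a fixed, configurable hydropathy
classing: hydrophobic {A,V,L,I,M,F,W,C}, polar {S,T,N,Q,Y,G,P,H}, positive
{K,R}, negative {D,E}. Circular diagrams are plain SVG with the focus
residue and its neighbors on a circle and chords whose width and opacity
scale with the score; node order follows descending score. All rendering is
deterministic. Matrices export as a '#'-metadata + tab-separated dialect at
6 decimal places, chosen so write→read round trips are stable at 1e-6.

## Synthetic data

The generator emulates exactly the covariation structure the metrics
measure: couplings are planted in match/mismatch space, not in 20-letter
sequence space. Each homolog mutates each position away from the query
independently at the background rate (mutated residues drawn uniformly from
the 19 non-query residues); for a coupled pair, with probability equal to
the coupling strength one shared draw decides the match state of both
columns, otherwise the columns mutate independently. Phylogenetic
redundancy is planted as blocks of near-copies of a fresh parent homolog;
gaps are inserted per cell at a fixed rate (the query row stays gap-free).
The returned alignment has 1 query row + `n_seqs` homologs + the cluster
rows. The companion fixture PSSM uses BLOSUM62 score columns for the query
residues and observed column frequencies (largest-remainder rounding to
integer percentages) as the probability part.

Default study conditions for the planted-signal benchmark: 200 homologs ×
50 columns, one pair coupled at 0.9, background mutation rate 0.3, no
clusters or gaps — a depth and divergence regime typical of a
database-search alignment after redundancy reduction. What passing these
tests shows is that the statistics recover a strong pairwise dependency and
that phylogeny weighting suppresses redundancy artifacts; what they do not
show is performance on real alignments, which add phylogenetic tree
structure (not just flat clusters), indel patterns correlated with
structure, and indirect (chained) couplings the 4-state metrics cannot
disentangle.

## Numerical choices and problem sizes

0·log 0 terms are skipped in every entropy/MI sum; chi-square terms with
zero expected frequency are skipped. Empty pair subsets (N_eff = 0) yield
zero scores rather than errors. The matrix builder evaluates all pairs via
weighted indicator-matrix products, which matches the naive per-pair
evaluation to ≤1e-10 (tested) and keeps the end-to-end suite and the
validation script in the hundreds-of-rows × tens-of-columns regime at
seconds of runtime: oracle comparisons use ≤12-row × ≤8-column alignments
where exhaustive evaluation is exact and fast, the recovery benchmark uses
20 replicates at 200 × 50, and the end-to-end run uses 100 × 60.

## Known limitations

- The 4-state model cannot separate direct from indirect couplings; MIp's
  background correction helps but is not a substitute for inverse-covariance
  or Potts approaches.
- Phylogeny weighting uses flat identity clusters, not a tree; deep,
  balanced phylogenies are only approximately corrected.
- The PSSM reader targets the standard ASCII dialect of profile search
  output (two header lines, 40 integer columns, trailing statistics block);
  exotic variants may need pre-conversion.
- Stockholm input is reduced to the query frame immediately; per-column
  annotations are not carried through.
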