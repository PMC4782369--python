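# coevol

Residue coevolution analysis from a multiple sequence alignment (MSA).

Groups of residues that fold or function together leave a correlated
substitution signal in the alignments of their homologs. `coevol` quantifies
that signal for every pair of query positions, producing symmetric L×L score
matrices, a complete-linkage residue dendrogram, heat maps, and circular
neighbor diagrams — the standard desk workflow for spotting active sites,
binding residues and functional motifs without relying on single-residue
conservation alone.

## The model

The alignment is *query-anchored*: the first (or named) record defines the L
columns; columns where the query is gapped are discarded. Every aligned
residue is classified by a binary state — equal (X) or unequal (!X) to the
query residue at that position — so a column pair (i, j) has four joint
states. With per-sequence weights *w*<sub>l</sub> and rows non-gapped at both
positions, the weighted counts *c*(s) give pseudocounted frequencies

> p(s) = c(s) / (N_eff + λ),  N_eff = Σ<sub>l</sub> w<sub>l</sub>,  λ = 1.

Four pairwise metrics are computed from these frequencies:

- **MI** — mutual information Σ<sub>x</sub>Σ<sub>y</sub> p(x,y) log [p(x,y) / (p<sub>i</sub>(x) p<sub>j</sub>(y))], min-max normalized to [0, 1];
- **MIp** — MI minus the average product correction APC(a,b) = MI(a,·)·MI(b,·)/MI̅, which removes the background signal a promiscuous column shares with all partners; negatives floored at 0, then min-max normalized;
- **χ²** — Σ (p(x,y) − p<sub>i</sub>(x)p<sub>j</sub>(y))² / (p<sub>i</sub>(x)p<sub>j</sub>(y)), reported as the df = 1 chi-square cumulative probability;
- **r** — weighted Pearson correlation of per-row PSSM similarity scores at the two positions (BLOSUM62 fallback without a PSSM);

and the conservation measure

- **S** — joint Shannon entropy of the four states, normalized by 1/log 4 (low S = jointly conserved).

Each metric is available under four weighting schemes: **none** (w = 1),
**dissimilarity** (w = 1 − identity to the query), **gap** (w = 1 − gap
fraction), and **phylogeny** (w<sub>a</sub> = 1/|{b : seqid(a,b) > 80 %}|, so
a clade of near-duplicates counts once in aggregate). Matrix diagonals carry
the weighted query-residue frequency (MI/MIp/χ²/r) or 20-state positional
entropies from the PSSM probability rows (S).

For clustering, scores become distances by d = 1 − score (negative r floored
at 0 first; S used directly as the distance), and residues are merged by
complete linkage with deterministic tie-breaking.

## Worked example

```bash
# synthetic 31-row, 10-column alignment with columns 1 and 5 coupled at 0.9
coevol simulate --n-seqs 30 --length 10 --couple 1:5:0.9 --seed 7 \
    --fasta-out msa.fa --pssm-out msa.pssm
coevol compute --msa msa.fa --pssm msa.pssm --metric mip \
    --weighting phylogeny -o mip.tsv
coevol neighbors --matrix mip.tsv --residue 2 --cutoff 0.3 --svg-out n.svg
```

The `neighbors` call prints the partners of residue 2 (1-based; column 1 of
the simulation) scoring at least 0.3:

```
6	1.000000
```

Residue 6 is column 5 of the simulation — the planted coupled partner — and
its MIp score of 1.000000 is the maximum of the min-max-normalized matrix:
the pair carries the strongest coevolution signal in the alignment, and no
other residue clears the cutoff. `coevol cluster --matrix mip.tsv --msa
msa.fa --newick-out t.nwk --tree-png t.png` then merges those two residues
first in the dendrogram, and `coevol heatmap --matrix mip.tsv -o h.png`
renders the matrix with the blue (0) → white (0.5) → red (1) palette.

Custom residue numbering (PDB-style, with insertion codes) can be supplied as
a two-column TSV via `--numbering`; all outputs then use those labels.

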