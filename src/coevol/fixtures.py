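"""Synthetic alignment generator with planted covariation.

Generates query-anchored alignments whose columns covary in match/mismatch
space — exactly the 4-state structure the metrics measure.  Each homolog row
mutates away from the query independently per position at a background rate;
a coupled column pair shares a single per-row mutation draw with probability
equal to the coupling strength, so at coupling 1 the two columns' match
indicators are identical across rows.  Phylogenetic redundancy is planted as
clusters of near-copies of a parent homolog, and gapping as per-cell gap
insertion.  Everything is reproducible from the seed.

The generator also writes a PSI-BLAST-style ASCII PSSM whose score columns
are BLOSUM62 columns for the query residues and whose probability part is
the observed column frequencies, enabling Pearson-r and entropy tests
without running any database search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from .errors import InputError
from .msa_io import GAP, PSSM_ALPHABET, Alignment

AA = PSSM_ALPHABET  # 20 standard residues


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic alignment.

    ``n_seqs`` counts homolog rows (the query row is added on top);
    ``phylo_clusters`` adds (size, within_rate) blocks of near-copies of a
    fresh parent homolog.
    """

    n_seqs: int = 200
    length: int = 50
    coupled_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    background_mutation_rate: float = 0.3
    phylo_clusters: list[tuple[int, float]] = field(default_factory=list)
    gap_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_seqs < 1 or self.length < 2:
            raise InputError("need n_seqs >= 1 and length >= 2")
        seen: set[int] = set()
        for i, j, c in self.coupled_pairs:
            if not (0 <= i < self.length and 0 <= j < self.length) or i == j:
                raise InputError(f"invalid coupled pair ({i}, {j})")
            if i in seen or j in seen:
                raise InputError("coupled positions must be distinct across pairs")
            seen.update((i, j))
            if not 0 <= c <= 1:
                raise InputError(f"coupling strength {c} outside [0, 1]")
        for rate in (self.background_mutation_rate, self.gap_rate):
            if not 0 <= rate <= 1:
                raise InputError(f"rate {rate} outside [0, 1]")
        for size, rate in self.phylo_clusters:
            if size < 1 or not 0 <= rate <= 1:
                raise InputError("invalid phylo cluster")


def _mutate(query: str, i: int, rng: np.random.Generator) -> str:
    """Uniform draw from the 19 residues unequal to the query at i."""
    while True:
        c = AA[rng.integers(20)]
        if c != query[i]:
            return c


def generate_msa(spec: SyntheticSpec) -> Alignment:
    """Generate the alignment described by ``spec`` (query at row 0)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    L = spec.length
    query = "".join(AA[k] for k in rng.integers(20, size=L))
    coupled_pos = {i for i, j, _ in spec.coupled_pairs} | {
        j for _, j, _ in spec.coupled_pairs
    }

    def make_homolog() -> list[str]:
        row = list(query)
        for p in range(L):
            if p in coupled_pos:
                continue
            if rng.random() < spec.background_mutation_rate:
                row[p] = _mutate(query, p, rng)
        for i, j, c in spec.coupled_pairs:
            if rng.random() < c:
                # one shared draw decides the match state of both columns
                if rng.random() < spec.background_mutation_rate:
                    row[i] = _mutate(query, i, rng)
                    row[j] = _mutate(query, j, rng)
            else:
                for p in (i, j):
                    if rng.random() < spec.background_mutation_rate:
                        row[p] = _mutate(query, p, rng)
        return row

    rows = [list(query)]
    row_ids = ["query"]
    for k in range(spec.n_seqs):
        rows.append(make_homolog())
        row_ids.append(f"hom{k + 1}")
    for ci, (size, within_rate) in enumerate(spec.phylo_clusters):
        parent = make_homolog()
        for k in range(size):
            member = list(parent)
            for p in range(L):
                if rng.random() < within_rate:
                    member[p] = _mutate(query, p, rng)
            rows.append(member)
            row_ids.append(f"clu{ci + 1}_{k + 1}")
    if spec.gap_rate > 0:
        for row in rows[1:]:  # query row stays gap-free
            for p in range(L):
                if rng.random() < spec.gap_rate:
                    row[p] = GAP
    return Alignment(
        query_id="query",
        query_seq=query,
        rows=["".join(r) for r in rows],
        row_ids=row_ids,
    )


def write_fixture_pssm(aln: Alignment, out: str | Path) -> None:
    """Write an NCBI-dialect ASCII PSSM derived from the alignment itself.

    Score columns are BLOSUM62 rows for each query residue; the probability
    part is the integer-rounded percentage of each residue in the column
    (largest-remainder rounding so every row sums to 100).
    """
    b62 = substitution_matrices.load("BLOSUM62")
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position",
        "            " + "   ".join(AA) + "   " + "   ".join(AA),
    ]
    chars = aln.char_matrix()
    for i in range(aln.length):
        qi = aln.query_seq[i]
        scores = [int(b62[qi, aa]) for aa in AA]
        col = chars[:, i]
        counts = np.array([(col == aa).sum() for aa in AA], dtype=float)
        total = counts.sum()
        if total == 0:
            pct = [0] * 20
        else:
            exact = counts / total * 100.0
            floor = np.floor(exact).astype(int)
            rem = exact - floor
            short = 100 - floor.sum()
            for k in np.argsort(-rem)[: int(short)]:
                floor[k] += 1
            pct = floor.tolist()
        fields = (
            [f"{i + 1:5d} {qi}"]
            + [f"{s:3d}" for s in scores]
            + [f"{p:4d}" for p in pct]
            + ["  0.50", " 0.10"]
        )
        lines.append(" ".join(fields))
    lines += [
        "",
        "                      K         Lambda",
        "Standard Ungapped    0.1337     0.3176",
        "",
    ]
    Path(out).write_text("\n".join(lines))
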