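"""Per-sequence weights for covariance counting.

Four schemes:

``none``
    every row counts 1 (the naive column count, query included);
``dissimilarity``
    w_l = 1 - seqid(row_l, query), so near-duplicates of the query count
    little;
``gap``
    w_l = 1 - (fraction of gap characters in row_l over the query frame);
``phylogeny``
    w_a = 1 / |{b : seqid(row_a, row_b) > threshold}| with the row itself in
    its own cluster, so a clade of k near-identical sequences contributes a
    summed weight of 1 regardless of k.  The default threshold is 0.80,
    the midpoint of the 70-90 % range over which the weighting is insensitive
    to the precise value.

Sequence identity is counted over mutually non-gap positions: PSI-BLAST-style
local alignments leave long gap runs, and a full-length denominator would
systematically underestimate relatedness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .msa_io import GAP, Alignment

SCHEMES = ("none", "dissimilarity", "gap", "phylogeny")

#: Identity threshold defining a phylogeny cluster (strict inequality).
PHYLO_IDENTITY_THRESHOLD = 0.80


@dataclass
class WeightVector:
    scheme: str
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.scheme not in SCHEMES:
            raise InputError(f"unknown weighting scheme {self.scheme!r}")
        if np.any(self.weights < 0):
            raise InputError("weights must be non-negative")

    def __len__(self) -> int:
        return len(self.weights)

    @classmethod
    def ones(cls, n: int) -> "WeightVector":
        return cls("none", np.ones(n))


def percent_identity(seq_a: str, seq_b: str) -> float:
    """Fractional identity over mutually non-gap positions.

    Returns 0 when the two rows share no non-gap position.
    """
    if len(seq_a) != len(seq_b):
        raise InputError("sequences must have equal aligned length")
    a = np.frombuffer(seq_a.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(seq_b.encode("ascii"), dtype=np.uint8)
    gap = ord(GAP)
    both = (a != gap) & (b != gap)
    denom = int(both.sum())
    if denom == 0:
        return 0.0
    return float(((a == b) & both).sum()) / denom


def _pairwise_identity(aln: Alignment) -> np.ndarray:
    """(n, n) identity matrix over mutually non-gap positions."""
    chars = aln.char_matrix().view(np.uint32)  # U1 -> codepoints
    gap = ord(GAP)
    ng = chars != gap
    n = aln.n_rows
    pid = np.empty((n, n))
    for a in range(n):
        both = ng[a] & ng
        denom = both.sum(axis=1)
        match = ((chars[a] == chars) & both).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            row = np.where(denom > 0, match / np.maximum(denom, 1), 0.0)
        pid[a] = row
    return pid


def compute_weights(
    aln: Alignment,
    scheme: str,
    phylo_threshold: float = PHYLO_IDENTITY_THRESHOLD,
) -> WeightVector:
    """Compute one weight per alignment row under the chosen scheme."""
    if aln.n_rows == 0:
        raise InputError("empty alignment")
    if scheme == "none":
        w = np.ones(aln.n_rows)
    elif scheme == "dissimilarity":
        w = np.array(
            [1.0 - percent_identity(row, aln.query_seq) for row in aln.rows]
        )
    elif scheme == "gap":
        L = aln.length
        w = np.array([1.0 - row.count(GAP) / L for row in aln.rows])
    elif scheme == "phylogeny":
        pid = _pairwise_identity(aln)
        cluster_sizes = (pid > phylo_threshold).sum(axis=1)
        # a row is always >threshold-identical to itself (identity 1),
        # except an all-gap row whose self-identity is 0 by convention
        cluster_sizes = np.maximum(cluster_sizes, 1)
        w = 1.0 / cluster_sizes
    else:
        raise InputError(f"unknown weighting scheme {scheme!r}")
    return WeightVector(scheme=scheme, weights=w)


def export_weights_tsv(aln: Alignment, wv: WeightVector, path) -> None:
    """Write row_id<TAB>weight lines for inspection."""
    with open(path, "w") as fh:
        fh.write(f"# scheme\t{wv.scheme}\n")
        for rid, w in zip(aln.row_ids, wv.weights):
            fh.write(f"{rid}\t{w:.6f}\n")
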