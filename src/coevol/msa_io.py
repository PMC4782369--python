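"""Alignment, PSSM and residue-numbering input.

The column frame is *query-anchored*: the first (or named) record defines the
columns, and every column where the query carries a gap is deleted from all
rows.  All downstream matrices are therefore L x L over the query's own
positions, where L is the gap-free query length.

Supported inputs
----------------
* aligned FASTA / Stockholm (via Bio.AlignIO),
* NCBI PSI-BLAST ASCII PSSM (the ``-out_ascii_pssm`` dialect),
* an optional headerless two-column TSV mapping position index to a custom
  residue label (PDB-style numbering with insertion codes).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio import AlignIO

from .errors import FormatError, InputError, ResidueLookupError

GAP = "-"

#: Canonical 20-letter amino-acid alphabet in NCBI PSSM column order.
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"


@dataclass
class Alignment:
    """A query-anchored multiple sequence alignment.

    ``rows[0]`` is always the (gap-free) query itself, so naive column counts
    include the query sequence.  Every row has length ``L == len(query_seq)``.
    """

    query_id: str
    query_seq: str
    rows: list[str]
    row_ids: list[str]

    def __post_init__(self) -> None:
        L = len(self.query_seq)
        if GAP in self.query_seq:
            raise InputError("query sequence must be gap-free after reduction")
        for rid, row in zip(self.row_ids, self.rows):
            if len(row) != L:
                raise InputError(
                    f"row {rid!r} has length {len(row)}, expected {L}"
                )
        if len(self.rows) != len(self.row_ids):
            raise InputError("rows and row_ids must have equal length")

    @property
    def length(self) -> int:
        return len(self.query_seq)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def char_matrix(self) -> np.ndarray:
        """Rows as an (n_rows, L) array of single characters."""
        return np.array([list(r) for r in self.rows], dtype="U1")

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rid, row in zip(self.row_ids, self.rows):
                fh.write(f">{rid}\n{row}\n")


@dataclass
class PSSMProfile:
    """PSI-BLAST position-specific scoring matrix for the query.

    ``scores`` are the integer log-odds columns (one row per query position,
    columns in :data:`PSSM_ALPHABET` order); ``probs`` is the probability
    part, i.e. the printed integer percentages divided by 100.
    """

    scores: np.ndarray  # (L, 20) int
    probs: np.ndarray  # (L, 20) float in [0, 1]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.scores.shape != self.probs.shape or self.scores.shape[1] != 20:
            raise FormatError("PSSM scores/probs must both be L x 20")
        sums = self.probs.sum(axis=1)
        # integer percentages round to within 2 points of 100
        if np.any(np.abs(sums - 1.0) > 0.02 + 1e-12):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise FormatError(
                f"PSSM probability row {bad + 1} sums to {sums[bad]:.3f}"
            )

    @property
    def length(self) -> int:
        return self.scores.shape[0]


@dataclass
class ResidueNumbering:
    """Residue labels for the L query positions (default "1".."L")."""

    labels: list[str]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise InputError("residue labels must be unique")

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, i: int) -> str:
        return self.labels[i]

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ResidueLookupError(f"unknown residue label {label!r}") from None

    @classmethod
    def default(cls, L: int) -> "ResidueNumbering":
        return cls([str(i + 1) for i in range(L)])


def read_alignment(
    path: str | Path,
    format: str = "fasta",
    query_id: Optional[str] = None,
) -> Alignment:
    """Read an aligned FASTA or Stockholm file into the query-anchored frame.

    The query is the record named by ``query_id`` if given, otherwise the
    first record.  Columns where the query has a gap are deleted from every
    row; residues are uppercased.  The query is placed at row 0 (moved there
    if ``query_id`` names a later record).
    """
    if format not in ("fasta", "stockholm"):
        raise InputError(f"unsupported alignment format {format!r}")
    try:
        msa = AlignIO.read(str(path), format)
    except ValueError as exc:
        msg = str(exc)
        if "equal length" in msg or "length" in msg.lower():
            raise FormatError(f"malformed {format} alignment: {msg}") from exc
        raise InputError(f"could not read alignment: {msg}") from exc
    records = [(rec.id, str(rec.seq).upper()) for rec in msa]
    if not records:
        raise InputError(f"empty alignment file: {path}")
    lengths = {len(seq) for _, seq in records}
    if len(lengths) != 1:
        raise FormatError("alignment records have unequal lengths")

    if query_id is None:
        q_idx = 0
    else:
        try:
            q_idx = [rid for rid, _ in records].index(query_id)
        except ValueError:
            raise ResidueLookupError(
                f"query id {query_id!r} not found in alignment"
            ) from None
    records.insert(0, records.pop(q_idx))

    q_id, q_seq = records[0]
    keep = [i for i, c in enumerate(q_seq) if c != GAP]
    row_ids = [rid for rid, _ in records]
    rows = ["".join(seq[i] for i in keep) for _, seq in records]
    return Alignment(query_id=q_id, query_seq=rows[0], rows=rows, row_ids=row_ids)


_PSSM_ROW = re.compile(r"^\s*(\d+)\s+([A-Za-z*])\s+(-?\d.*)$")


def read_pssm(path: str | Path, expected_length: Optional[int] = None) -> PSSMProfile:
    """Parse an NCBI PSI-BLAST ASCII PSSM (``-out_ascii_pssm`` dialect).

    Layout: two header lines, a column-header line, then one data row per
    query position (index, residue, 20 integer log-odds, 20 integer
    percentages, two trailing information statistics), then a K/lambda block
    which is ignored.  Percentages are converted to fractions.
    """
    scores: list[list[int]] = []
    probs: list[list[float]] = []
    indices: list[int] = []
    with open(path) as fh:
        for line in fh:
            m = _PSSM_ROW.match(line)
            if not m:
                continue
            fields = m.group(3).split()
            if len(fields) < 40:
                raise FormatError(
                    f"PSSM data row {m.group(1)} has {len(fields)} numeric "
                    "fields, expected at least 40"
                )
            try:
                # 20 integer log-odds + 20 integer percentages; the trailing
                # information/weight statistics are ignored
                row_scores = [int(x) for x in fields[:20]]
                row_pcts = [int(x) for x in fields[20:40]]
            except ValueError as exc:
                raise FormatError(f"non-numeric PSSM cell in row {m.group(1)}") from exc
            indices.append(int(m.group(1)))
            scores.append(row_scores)
            probs.append([v / 100.0 for v in row_pcts])
    if not scores:
        raise FormatError(f"no PSSM data rows found in {path}")
    if indices != list(range(1, len(indices) + 1)):
        raise FormatError("PSSM position indices are not consecutive from 1")
    if expected_length is not None and len(scores) != expected_length:
        raise FormatError(
            f"PSSM has {len(scores)} positions, expected {expected_length}"
        )
    return PSSMProfile(scores=np.array(scores, dtype=int), probs=np.array(probs))


def apply_numbering(aln: Alignment, path: Optional[str | Path] = None) -> ResidueNumbering:
    """Build the residue numbering for an alignment.

    Without a file, positions are labeled "1".."L".  With a file, every one
    of the L positions must be mapped (numbering is total): the file is a
    headerless TSV of ``index<TAB>label`` lines with 1-based indices.
    """
    L = aln.length
    if path is None:
        return ResidueNumbering.default(L)
    mapping: dict[int, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise InputError(f"numbering line {ln}: expected 2 tab-separated fields")
            try:
                idx = int(parts[0])
            except ValueError:
                raise InputError(f"numbering line {ln}: non-integer index {parts[0]!r}") from None
            if idx in mapping:
                raise InputError(f"numbering index {idx} given twice")
            mapping[idx] = parts[1]
    if set(mapping) != set(range(1, L + 1)):
        raise InputError(
            f"numbering must cover exactly positions 1..{L}; got {len(mapping)} entries"
        )
    return ResidueNumbering([mapping[i] for i in range(1, L + 1)])
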