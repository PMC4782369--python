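"""Shared fixtures: tiny hand-built alignments and random-alignment factories."""

import numpy as np
import pytest

from coevol import Alignment, SyntheticSpec, generate_msa, write_fixture_pssm, read_pssm

AA20 = "ARNDCQEGHILKMFPSTWYV"


def make_alignment(rows, query=None, ids=None):
    """Alignment from raw row strings; row 0 is the query unless given."""
    if query is None:
        query = rows[0]
    if ids is None:
        ids = [f"s{k}" for k in range(len(rows))]
    return Alignment(query_id=ids[0], query_seq=query, rows=list(rows), row_ids=ids)


def random_alignment(rng, n_rows=None, length=None, gap_rate=0.1):
    """Small random alignment (query at row 0, query gap-free)."""
    n_rows = n_rows or int(rng.integers(2, 13))
    length = length or int(rng.integers(2, 9))
    query = "".join(AA20[k] for k in rng.integers(20, size=length))
    rows = [query]
    for _ in range(n_rows - 1):
        row = [
            "-" if rng.random() < gap_rate else AA20[rng.integers(20)]
            for _ in range(length)
        ]
        rows.append("".join(row))
    return make_alignment(rows, query=query)


@pytest.fixture
def toy_aln():
    """4 columns, 5 rows incl. query, one gap."""
    return make_alignment(["ACDE", "ACDE", "ACDF", "AC-E", "GCDE"])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_msa_with_pssm(tmp_path):
    """Synthetic 30-row, 12-column alignment plus its fixture PSSM."""
    spec = SyntheticSpec(
        n_seqs=29, length=12, coupled_pairs=[(2, 7, 0.9)],
        background_mutation_rate=0.3, gap_rate=0.05, seed=11,
    )
    aln = generate_msa(spec)
    pssm_path = tmp_path / "fixture.pssm"
    write_fixture_pssm(aln, pssm_path)
    return aln, read_pssm(pssm_path, expected_length=aln.length)
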