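"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive quantities by the most naive method
possible (double loops over columns and row pairs, dense matrices) so they
share no code path with the implementations they check.
"""

from __future__ import annotations

import itertools
import random
import string

import pytest

from gcmalign.msa import Alignment


def brute_force_pairs(aln: Alignment) -> set:
    """Homologous pairs by a double loop over columns and row pairs."""
    sites = {}
    for rid in aln.row_ids:
        row = aln.row(rid)
        counter = -1
        per_col = {}
        for col, ch in enumerate(row):
            if ch != "-":
                counter += 1
                per_col[col] = (counter, ch)
        sites[rid] = per_col
    pairs = set()
    for col in range(aln.length):
        for ra, rb in itertools.combinations(aln.row_ids, 2):
            a = sites[ra].get(col)
            b = sites[rb].get(col)
            if a and b and a[1].isupper() and b[1].isupper():
                ea, eb = (ra, a[0]), (rb, b[0])
                pairs.add((ea, eb) if ea <= eb else (eb, ea))
    return pairs


def random_alignment(
    rng: random.Random,
    n_rows: int,
    n_cols: int,
    alphabet: str = "ACGT",
    p_gap: float = 0.3,
    p_lower: float = 0.15,
) -> Alignment:
    """A random gapped matrix with mixed case; rows guaranteed non-empty."""
    ids = [f"r{i}" for i in range(n_rows)]
    rows = {}
    for rid in ids:
        while True:
            cells = []
            for _ in range(n_cols):
                u = rng.random()
                if u < p_gap:
                    cells.append("-")
                else:
                    ch = rng.choice(alphabet)
                    cells.append(ch.lower() if rng.random() < p_lower else ch)
            if any(c != "-" for c in cells):
                break
        rows[rid] = "".join(cells)
    return Alignment(ids, rows)


def random_regap(
    rng: random.Random, aln: Alignment, p_gap: float = 0.3,
    p_lower: float = 0.15,
) -> Alignment:
    """A different random alignment of the same underlying sequences."""
    rows = {}
    width = 0
    for rid in aln.row_ids:
        residues = aln.ungapped(rid)
        cells = []
        for ch in residues:
            while rng.random() < p_gap:
                cells.append("-")
            cells.append(ch.lower() if rng.random() < p_lower else ch)
        rows[rid] = cells
        width = max(width, len(cells))
    return Alignment(
        aln.row_ids,
        {rid: "".join(cells) + "-" * (width - len(cells))
         for rid, cells in rows.items()},
    )


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240917)
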