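"""Conservative lossy (and lossless) alignment compression.

Very large merged alignments are dominated by gap characters: most columns
hold letters from only a few sequences.  Compression shortens the alignment
by *dissolving* columns: each letter in the dissolved column is demoted to
lower-case (it no longer asserts homology) and shunted sideways into the
nearest gap in its row, dominoing any intervening lower-case letters along;
a move that would displace an upper-case letter is invalid.  Dissolving a
column with at most one upper-case letter destroys no homologous pair, so
restricting to such columns gives *lossless* compression; beyond that the
procedure is lossy but conservative, dissolving the emptiest columns first
until a target serialized size is reached or no valid move remains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .msa import GAP, Alignment

FASTA_WRAP = 60


@dataclass
class CompressionReport:
    columns_dissolved: int
    pairs_lost: int
    size_before: int
    size_after: int
    lossless: bool


def estimate_size(alignment: Alignment, wrap_width: int = FASTA_WRAP) -> int:
    """Exact on-disk FASTA size in bytes, as written by ``write_fasta``.

    Per row: ``'>' + id + '\\n'`` plus the body (L characters) wrapped into
    ``ceil(L / wrap_width)`` newline-terminated lines.
    """
    total = 0
    L = alignment.length
    body_lines = math.ceil(L / wrap_width)
    for rid in alignment.row_ids:
        total += 1 + len(rid) + 1 + L + body_lines
    return total


def dissolve_column(alignment: Alignment, col: int) -> tuple[Alignment, bool]:
    """Dissolve one column, if every letter in it can be shunted aside.

    Each residue is demoted to lower-case and moved toward the nearest gap
    in its row — leftward first; intervening lower-case letters shift one
    step further in the same direction (the domino).  A chain that runs
    into an upper-case letter is blocked; rightward is then tried.  If any
    residue is blocked both ways, nothing changes and ``moved`` is False;
    otherwise the emptied column is deleted.
    """
    L = alignment.length
    if not 0 <= col < L:
        raise IndexError(f"column {col} out of range")
    # Plan: per row with a letter in `col`, the gap position absorbing its
    # chain, or None if the row is gapped there.
    plans: dict[str, tuple[str, int]] = {}  # rid -> (direction, gap index)
    for rid, row in alignment.rows():
        if row[col] == GAP:
            continue
        dest = None
        for j in range(col - 1, -1, -1):
            if row[j] == GAP:
                dest = ("L", j)
                break
            if row[j].isupper():
                break
        if dest is None:
            for j in range(col + 1, L):
                if row[j] == GAP:
                    dest = ("R", j)
                    break
                if row[j].isupper():
                    break
        if dest is None:
            return alignment, False
        plans[rid] = dest
    new_rows: dict[str, str] = {}
    for rid, row in alignment.rows():
        if rid not in plans:
            new_rows[rid] = row[:col] + row[col + 1 :]
            continue
        cells = list(row)
        demoted = cells[col].lower()
        direction, g = plans[rid]
        if direction == "L":
            # shift (g, col) left one step; demoted letter lands at col-1
            cells[g:col] = cells[g + 1 : col] + [demoted]
        else:
            cells[col + 1 : g + 1] = [demoted] + cells[col + 1 : g]
        del cells[col]
        new_rows[rid] = "".join(cells)
    return Alignment(alignment.row_ids, new_rows), True


def compress(
    alignment: Alignment,
    size_threshold_bytes: int,
    lossless_only: bool = False,
) -> tuple[Alignment, CompressionReport]:
    """Dissolve columns, emptiest first, until the size threshold is met.

    At each step the column with the fewest upper-case letters (tie:
    leftmost) that admits a valid dissolve is removed; in lossless mode only
    columns with ≤1 upper-case letter are candidates, which provably
    preserves the homologous pair set.  Stops when the serialized size
    reaches the threshold or no candidate can move.
    """
    size_before = estimate_size(alignment)
    current = alignment
    dissolved = 0
    pairs_lost = 0
    while estimate_size(current) > size_threshold_bytes:
        candidates = sorted(
            range(current.length), key=lambda c: (current.upper_count(c), c)
        )
        if lossless_only:
            candidates = [c for c in candidates if current.upper_count(c) <= 1]
        moved = False
        for c in candidates:
            u = current.upper_count(c)
            nxt, ok = dissolve_column(current, c)
            if ok:
                current = nxt
                dissolved += 1
                pairs_lost += u * (u - 1) // 2
                moved = True
                break
        if not moved:
            break
    report = CompressionReport(
        columns_dissolved=dissolved,
        pairs_lost=pairs_lost,
        size_before=size_before,
        size_after=estimate_size(current),
        lossless=pairs_lost == 0,
    )
    return current, report
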