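"""Alignment data model with homology-bearing case semantics, plus FASTA I/O.

The central container is :class:`Alignment`, a rectangular gapped character
matrix.  Character state matters:

* **upper-case letter** — an aligned residue; two upper-case residues in the
  same column are asserted homologous,
* **lower-case letter** — an unaligned residue (e.g. demoted by lossy
  compression); it carries sequence content but no homology claim,
* ``'-'`` — a gap.

Site indices used throughout the package are 0-based positions over the
*ungapped* residues of each sequence, so pair sets survive column insertion
and removal unchanged.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence as TypingSequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

GAP = "-"

NUCLEOTIDE_LETTERS = frozenset("ACGTURYSWKMBDHVN")
AMINO_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWYBXZJUO*")


class FastaFormatError(ValueError):
    """Raised on malformed FASTA input."""


@dataclass(frozen=True)
class Sequence:
    """An unaligned, gap-free sequence with a unique id."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")
        if GAP in self.residues or "." in self.residues:
            raise ValueError(f"sequence {self.id!r} contains gap characters")

    def __len__(self) -> int:
        return len(self.residues)


class Alignment:
    """A multiple sequence alignment: ordered rows of equal-length gapped strings.

    Rows are addressable by id; row order is preserved from construction
    (and hence from input file order).
    """

    __slots__ = ("row_ids", "_rows")

    def __init__(self, row_ids: TypingSequence[str], rows: dict[str, str]):
        row_ids = list(row_ids)
        if not row_ids:
            raise ValueError("alignment must have at least one row")
        if len(set(row_ids)) != len(row_ids):
            raise ValueError("duplicate row ids in alignment")
        lengths = {len(rows[r]) for r in row_ids}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        self.row_ids: list[str] = row_ids
        self._rows: dict[str, str] = {r: rows[r] for r in row_ids}

    # -- basic container protocol ------------------------------------------

    @property
    def length(self) -> int:
        return len(self._rows[self.row_ids[0]])

    @property
    def n_rows(self) -> int:
        return len(self.row_ids)

    def row(self, row_id: str) -> str:
        return self._rows[row_id]

    def rows(self) -> Iterator[tuple[str, str]]:
        for r in self.row_ids:
            yield r, self._rows[r]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return self.row_ids == other.row_ids and self._rows == other._rows

    def __repr__(self) -> str:
        return f"<Alignment {self.n_rows} rows x {self.length} columns>"

    # -- derived views -----------------------------------------------------

    def ungapped(self, row_id: str) -> str:
        """The raw input sequence of a row: gaps stripped, case folded up."""
        return self._rows[row_id].replace(GAP, "").upper()

    def sequences(self) -> list[Sequence]:
        return [Sequence(r, self.ungapped(r)) for r in self.row_ids]

    def column(self, col: int) -> list[str]:
        return [self._rows[r][col] for r in self.row_ids]

    def site_to_column(self, row_id: str) -> list[int]:
        """For each ungapped site of ``row_id``, the alignment column holding it."""
        return [i for i, c in enumerate(self._rows[row_id]) if c != GAP]

    def upper_count(self, col: int) -> int:
        return sum(1 for c in self.column(col) if c.isupper())

    def drop_all_gap_columns(self) -> "Alignment":
        keep = [
            i
            for i in range(self.length)
            if any(self._rows[r][i] != GAP for r in self.row_ids)
        ]
        if len(keep) == self.length:
            return self
        rows = {r: "".join(self._rows[r][i] for i in keep) for r in self.row_ids}
        return Alignment(self.row_ids, rows)


def from_sequences(sequences: Iterable[Sequence]) -> Alignment:
    """A trivial 'alignment' stacking equal-length sequences without gaps.

    Only valid when all sequences have identical length (e.g. duplicates).
    """
    seqs = list(sequences)
    return Alignment([s.id for s in seqs], {s.id: s.residues for s in seqs})


# ---------------------------------------------------------------------------
# Homologous pairs
# ---------------------------------------------------------------------------

#: A homology pair: frozenset-free canonical form — the two (row_id, site)
#: endpoints sorted, so the pair is unordered and hashable.
Pair = tuple[tuple[str, int], tuple[str, int]]


def _canonical(a: tuple[str, int], b: tuple[str, int]) -> Pair:
    return (a, b) if a <= b else (b, a)


def homologous_pairs(alignment: Alignment) -> set[Pair]:
    """All homologous residue pairs asserted by an alignment.

    For every column, every unordered pair among its *upper-case* residues is
    a pair; lower-case residues and gaps assert nothing.  Endpoints are
    (row_id, ungapped_site_index).
    """
    pairs: set[Pair] = set()
    site_counters = {r: -1 for r in alignment.row_ids}
    for col in range(alignment.length):
        members: list[tuple[str, int]] = []
        for r in alignment.row_ids:
            c = alignment.row(r)[col]
            if c == GAP:
                continue
            site_counters[r] += 1
            if c.isupper():
                members.append((r, site_counters[r]))
        for a, b in itertools.combinations(members, 2):
            pairs.add(_canonical(a, b))
    return pairs


def restrict(alignment: Alignment, keep_ids: Iterable[str]) -> Alignment:
    """Restrict to a subset of rows, dropping columns that become all-gap.

    Preserves row order and character case.  The homologous pair set of the
    result equals the input's pairs filtered to ``keep_ids`` (site indices are
    ungapped, hence stable under column removal).
    """
    keep = set(keep_ids)
    unknown = keep - set(alignment.row_ids)
    if unknown:
        raise KeyError(f"unknown row ids: {sorted(unknown)}")
    ids = [r for r in alignment.row_ids if r in keep]
    sub = Alignment(ids, {r: alignment.row(r) for r in ids})
    return sub.drop_all_gap_columns()


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------


def _parse_fasta_records(path: Path) -> list[tuple[str, str]]:
    records: list[tuple[str, str]] = []
    with open(path) as fh:
        for title, body in SimpleFastaParser(fh):
            rid = title.split()[0] if title.split() else ""
            if not rid:
                raise FastaFormatError(f"{path}: empty record header")
            records.append((rid, body.replace(" ", "")))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records")
    ids = [r for r, _ in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise FastaFormatError(f"{path}: duplicate record ids {dup}")
    for rid, body in records:
        if "." in body:
            raise FastaFormatError(
                f"{path}: record {rid!r} uses '.'; only '-' gaps are supported"
            )
        if not body:
            raise FastaFormatError(f"{path}: record {rid!r} is empty")
    return records


def read_fasta(path: str | Path, aligned: bool) -> Alignment | list[Sequence]:
    """Read FASTA.

    With ``aligned=True`` returns an :class:`Alignment`, preserving case and
    gaps verbatim (lower-case letters encode unaligned residues).  With
    ``aligned=False`` returns a list of :class:`Sequence`; gaps are rejected
    and lower-case input is upcased, since raw input carries no homology
    semantics.
    """
    path = Path(path)
    records = _parse_fasta_records(path)
    if aligned:
        lengths = {len(body) for _, body in records}
        if len(lengths) != 1:
            raise FastaFormatError(
                f"{path}: unequal record lengths {sorted(lengths)} in aligned FASTA"
            )
        return Alignment([r for r, _ in records], dict(records))
    seqs = []
    for rid, body in records:
        if GAP in body:
            raise FastaFormatError(
                f"{path}: record {rid!r} contains gaps but aligned=False"
            )
        seqs.append(Sequence(rid, body.upper()))
    return seqs


def write_fasta(
    data: Alignment | Iterable[Sequence],
    path: str | Path,
    wrap_width: int = 60,
) -> None:
    """Write FASTA deterministically, preserving case, wrapping at ``wrap_width``."""
    if wrap_width < 1:
        raise ValueError("wrap_width must be positive")
    if isinstance(data, Alignment):
        items = list(data.rows())
    else:
        items = [(s.id, s.residues) for s in data]
    with open(path, "w") as fh:
        for rid, body in items:
            fh.write(f">{rid}\n")
            for i in range(0, len(body), wrap_width):
                fh.write(body[i : i + wrap_width] + "\n")


def assert_letters_conserved(
    alignment: Alignment, sequences: Iterable[Sequence]
) -> None:
    """Check that upcased-degapped rows equal the given input sequences exactly."""
    expected = {s.id: s.residues.upper() for s in sequences}
    if set(expected) != set(alignment.row_ids):
        raise AssertionError("alignment rows do not cover the input ids")
    for rid in alignment.row_ids:
        got = alignment.ungapped(rid)
        if got != expected[rid]:
            raise AssertionError(
                f"letters not conserved for {rid!r}: {got!r} != {expected[rid]!r}"
            )
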