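"""Subset alignment and backbone construction.

Subsets produced by the decomposition are aligned with a *base aligner* —
any tool or callable mapping unaligned sequences to an alignment over
exactly those ids.  Backbones are small alignments spanning all subsets:
each draws an equal-sized random sample from every subalignment and
realigns it; they are the evidence that later links subalignment columns in
the merge graph.

The built-in base aligner is a guide-tree progressive profile–profile
aligner with affine gap penalties (Gotoh recurrences, numba-compiled).  It
is deliberately plain — match/mismatch for nucleotides, BLOSUM62 for
proteins — because the merge machinery, not the base aligner, is the point;
any external aligner can be substituted via :class:`ExternalAlignerAdapter`.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence as TypingSequence

import numpy as np
from numba import njit

from .guidetree import GuideTree, build_fallback_tree
from .msa import (
    GAP,
    NUCLEOTIDE_LETTERS,
    Alignment,
    Sequence,
    assert_letters_conserved,
)

logger = logging.getLogger(__name__)

DEFAULT_NUM_BACKBONES = 10
DEFAULT_BACKBONE_SIZE = 200
DEFAULT_GAP_OPEN = -4.0
DEFAULT_GAP_EXTEND = -1.0

#: BaseAligner contract: unaligned sequences in, alignment over those ids out.
BaseAligner = Callable[[TypingSequence[Sequence]], Alignment]


# ---------------------------------------------------------------------------
# Backbone sampling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BackboneSample:
    """Rows chosen for one backbone: (subset_index, row_id) pairs."""

    members: tuple[tuple[int, str], ...]

    def row_ids(self) -> list[str]:
        return [rid for _, rid in self.members]


def sample_backbones(
    subalignments: TypingSequence[Alignment] | TypingSequence[TypingSequence[str]],
    num_backbones: int = DEFAULT_NUM_BACKBONES,
    backbone_size: int = DEFAULT_BACKBONE_SIZE,
    seed: int = 0,
) -> list[BackboneSample]:
    """Draw equal-sized random row samples from every subalignment.

    Per backbone, each subset contributes ``backbone_size // num_subsets``
    rows (the remainder goes to the first subsets, one extra row each),
    sampled uniformly without replacement; a subset smaller than its quota
    contributes all of its rows.  Deterministic per seed; backbones are
    sampled independently.  Accepts either alignments or bare row-id lists
    (sampling needs only the ids, so no subalignment has to be resident).
    """
    k = len(subalignments)
    if k < 2:
        raise ValueError("need at least two subalignments to build backbones")
    if backbone_size < k:
        raise ValueError(
            f"backbone_size {backbone_size} smaller than subset count {k}"
        )
    if num_backbones < 1:
        raise ValueError("num_backbones must be >= 1")
    base, rem = divmod(backbone_size, k)
    rng = random.Random(seed)
    samples = []
    for _ in range(num_backbones):
        members: list[tuple[int, str]] = []
        for si, sub in enumerate(subalignments):
            quota = base + (1 if si < rem else 0)
            ids = sub.row_ids if isinstance(sub, Alignment) else list(sub)
            if len(ids) <= quota:
                chosen = list(ids)
            else:
                chosen = rng.sample(ids, quota)
            members.extend((si, rid) for rid in sorted(chosen))
        samples.append(BackboneSample(tuple(members)))
    return samples


def align_backbone(
    sample: BackboneSample,
    subalignments: TypingSequence[Alignment],
    aligner: BaseAligner,
) -> Alignment:
    """Degap the sampled rows and realign them with the base aligner."""
    seqs = []
    for si, rid in sample.members:
        sub = subalignments[si]
        if rid not in sub.row_ids:
            raise KeyError(f"backbone row {rid!r} not in subalignment {si}")
        seqs.append(Sequence(rid, sub.ungapped(rid)))
    aln = aligner(seqs)
    if set(aln.row_ids) != {s.id for s in seqs}:
        raise AssertionError("base aligner did not cover exactly the sampled ids")
    assert_letters_conserved(aln, seqs)
    return aln


# ---------------------------------------------------------------------------
# Built-in progressive profile aligner
# ---------------------------------------------------------------------------

_NT_ALPHABET = "ACGT"
_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def _substitution_matrix(alphabet: str) -> np.ndarray:
    if alphabet == _NT_ALPHABET:
        s = np.full((4, 4), -1.0, dtype=np.float32)
        np.fill_diagonal(s, 1.0)
        return s
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    n = len(alphabet)
    s = np.zeros((n, n), dtype=np.float32)
    for i, a in enumerate(alphabet):
        for j, b in enumerate(alphabet):
            s[i, j] = blosum[a][b]
    return s


def _pick_alphabet(sequences: TypingSequence[Sequence]) -> str:
    letters = {c for s in sequences for c in s.residues.upper()}
    return _NT_ALPHABET if letters <= NUCLEOTIDE_LETTERS else _AA_ALPHABET


def _profile(alignment: Alignment, index: dict[str, int], n_letters: int) -> np.ndarray:
    """Per-column letter frequencies; gaps and unknown letters add no mass."""
    prof = np.zeros((alignment.length, n_letters), dtype=np.float32)
    for _, row in alignment.rows():
        for col, ch in enumerate(row):
            li = index.get(ch.upper(), -1)
            if li >= 0:
                prof[col, li] += 1.0
    prof /= alignment.n_rows
    return prof


@njit(cache=True)
def _gotoh_pointers(M, occ_a, occ_b, gap_open, gap_extend):  # pragma: no cover
    # Affine-gap profile DP.  Gap penalties are scaled by the occupancy
    # (non-gap fraction) of the column being skipped, so opening a gap
    # opposite an already-gappy profile column is cheap — the usual
    # position-specific treatment in profile alignment.
    L1, L2 = M.shape
    NEG = np.float32(-1e30)
    H = np.empty((L1 + 1, L2 + 1), dtype=np.float32)
    E = np.empty((L1 + 1, L2 + 1), dtype=np.float32)
    F = np.empty((L1 + 1, L2 + 1), dtype=np.float32)
    # ptr codes for H: 0 = diagonal, 1 = from E (gap in first profile),
    # 2 = from F (gap in second profile)
    ptrH = np.zeros((L1 + 1, L2 + 1), dtype=np.uint8)
    ptrE = np.zeros((L1 + 1, L2 + 1), dtype=np.uint8)  # 0: opened, 1: extended
    ptrF = np.zeros((L1 + 1, L2 + 1), dtype=np.uint8)
    H[0, 0] = 0.0
    E[0, 0] = NEG
    F[0, 0] = NEG
    for j in range(1, L2 + 1):
        step = occ_b[j - 1]
        if j == 1:
            E[0, j] = gap_open * step
        else:
            E[0, j] = E[0, j - 1] + gap_extend * step
        H[0, j] = E[0, j]
        F[0, j] = NEG
        ptrH[0, j] = 1
        ptrE[0, j] = 0 if j == 1 else 1
    for i in range(1, L1 + 1):
        step = occ_a[i - 1]
        if i == 1:
            F[i, 0] = gap_open * step
        else:
            F[i, 0] = F[i - 1, 0] + gap_extend * step
        H[i, 0] = F[i, 0]
        E[i, 0] = NEG
        ptrH[i, 0] = 2
        ptrF[i, 0] = 0 if i == 1 else 1
        for j in range(1, L2 + 1):
            e_open = H[i, j - 1] + gap_open * occ_b[j - 1]
            e_ext = E[i, j - 1] + gap_extend * occ_b[j - 1]
            if e_open >= e_ext:
                E[i, j] = e_open
                ptrE[i, j] = 0
            else:
                E[i, j] = e_ext
                ptrE[i, j] = 1
            f_open = H[i - 1, j] + gap_open * occ_a[i - 1]
            f_ext = F[i - 1, j] + gap_extend * occ_a[i - 1]
            if f_open >= f_ext:
                F[i, j] = f_open
                ptrF[i, j] = 0
            else:
                F[i, j] = f_ext
                ptrF[i, j] = 1
            diag = H[i - 1, j - 1] + M[i - 1, j - 1]
            best = diag
            code = 0
            if E[i, j] > best:
                best = E[i, j]
                code = 1
            if F[i, j] > best:
                best = F[i, j]
                code = 2
            H[i, j] = best
            ptrH[i, j] = code
    return H[L1, L2], ptrH, ptrE, ptrF


def _traceback(ptrH, ptrE, ptrF, L1: int, L2: int) -> list[tuple[int, int]]:
    """Column pairing from Gotoh pointers; (-1) marks a gap on that side."""
    ops: list[tuple[int, int]] = []
    i, j = L1, L2
    state = 0  # 0=H, 1=E, 2=F
    while i > 0 or j > 0:
        if state == 0:
            state = ptrH[i, j]
            if state == 0:
                ops.append((i - 1, j - 1))
                i -= 1
                j -= 1
        elif state == 1:
            ops.append((-1, j - 1))
            nxt = ptrE[i, j]
            j -= 1
            state = 0 if nxt == 0 else 1
        else:
            ops.append((i - 1, -1))
            nxt = ptrF[i, j]
            i -= 1
            state = 0 if nxt == 0 else 2
    ops.reverse()
    return ops


def _merge_alignments(
    a: Alignment,
    b: Alignment,
    sub_matrix: np.ndarray,
    index: dict[str, int],
    gap_open: float,
    gap_extend: float,
) -> Alignment:
    pa = _profile(a, index, sub_matrix.shape[0])
    pb = _profile(b, index, sub_matrix.shape[0])
    M = (pa @ sub_matrix) @ pb.T
    occ_a = pa.sum(axis=1).astype(np.float32)
    occ_b = pb.sum(axis=1).astype(np.float32)
    _, ptrH, ptrE, ptrF = _gotoh_pointers(
        M.astype(np.float32), occ_a, occ_b,
        np.float32(gap_open), np.float32(gap_extend),
    )
    ops = _traceback(ptrH, ptrE, ptrF, a.length, b.length)
    rows: dict[str, str] = {}
    for rid, row in a.rows():
        rows[rid] = "".join(GAP if i < 0 else row[i] for i, _ in ops)
    for rid, row in b.rows():
        rows[rid] = "".join(GAP if j < 0 else row[j] for _, j in ops)
    return Alignment(list(a.row_ids) + list(b.row_ids), rows)


def builtin_progressive_align(
    sequences: TypingSequence[Sequence],
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    seed: int = 0,
    guide: GuideTree | None = None,
) -> Alignment:
    """Progressive profile–profile alignment along a k-mer distance guide tree.

    Deterministic for a fixed seed; output rows upcased-degapped equal the
    inputs exactly.  Scoring: +1/−1 (nucleotide) or BLOSUM62 (protein);
    affine gaps (default open −4, extend −1).
    """
    seqs = list(sequences)
    if not seqs:
        raise ValueError("no sequences to align")
    if len(seqs) == 1:
        return Alignment([seqs[0].id], {seqs[0].id: seqs[0].residues.upper()})
    alphabet = _pick_alphabet(seqs)
    index = {c: i for i, c in enumerate(alphabet)}
    sub_matrix = _substitution_matrix(alphabet)
    if guide is None:
        guide = build_fallback_tree(seqs, seed=seed)
    by_id = {s.id: s for s in seqs}

    tree = guide.dendropy_tree

    def align_node(node) -> Alignment:
        children = node.child_nodes()
        if not children:
            s = by_id[node.taxon.label]
            return Alignment([s.id], {s.id: s.residues.upper()})
        acc = align_node(children[0])
        for child in children[1:]:
            acc = _merge_alignments(
                acc, align_node(child), sub_matrix, index, gap_open, gap_extend
            )
        return acc

    result = align_node(tree.seed_node)
    # Restore input row order for reproducible output files.
    result = Alignment(
        [s.id for s in seqs], {rid: result.row(rid) for rid in result.row_ids}
    )
    assert_letters_conserved(result, seqs)
    return result


# ---------------------------------------------------------------------------
# External aligner adapter
# ---------------------------------------------------------------------------


@dataclass
class ExternalAlignerAdapter:
    """Subprocess contract: ``{input}`` unaligned FASTA → ``{output}`` aligned FASTA.

    Any external aligner honoring the contract may be configured (the
    canonical choice for subsets and backbones is an accurate aligner such
    as ``mafft --localpair``).  If the tool is unavailable or fails, the
    built-in progressive aligner takes over with a logged warning.
    """

    name: str
    command_template: str
    workdir: Path

    def __call__(self, sequences: TypingSequence[Sequence]) -> Alignment:
        import shlex
        import subprocess
        import tempfile

        from .msa import read_fasta, write_fasta

        self.workdir.mkdir(parents=True, exist_ok=True)
        with tempfile.TemporaryDirectory(dir=self.workdir) as tmp:
            inp = Path(tmp) / "in.fasta"
            out = Path(tmp) / "out.fasta"
            write_fasta(sequences, inp)
            cmd = self.command_template.format(input=str(inp), output=str(out))
            try:
                proc = subprocess.run(
                    shlex.split(cmd), capture_output=True, text=True
                )
                ok = proc.returncode == 0 and out.is_file()
            except FileNotFoundError:
                ok = False
            if not ok:
                logger.warning(
                    "external aligner %r unavailable or failed; "
                    "falling back to the built-in progressive aligner",
                    self.name,
                )
                return builtin_progressive_align(sequences)
            aln = read_fasta(out, aligned=True)
            assert isinstance(aln, Alignment)
            return aln
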