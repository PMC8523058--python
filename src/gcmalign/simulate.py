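"""Synthetic sequence evolution with a known true alignment.

Sequences evolve down a random birth-process tree: i.i.d. substitutions
(uniform replacement — Jukes–Cantor-like for nucleotides, uniform over the
20 amino acids for proteins), plus insertion/deletion events drawn as a
Poisson process along each branch with geometric event lengths.  Every
residue carries a persistent site identifier from its creation, so the true
alignment — one column per surviving site, globally ordered consistently
with every lineage — is known exactly.  This yields unaligned inputs plus
their ground-truth alignment at any divergence level, which is what every
stage of the pipeline is tested against.

Presets emulate the divergence regimes of classic benchmark collections:
``16S-like`` targets an average p-distance near 0.2 (conserved rRNA),
``rnasim-like`` near 0.4 (deep simulated RNA evolution).
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, replace

import dendropy

from .guidetree import GuideTree
from .msa import Alignment, Sequence

_NT = "ACGT"
_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SimConfig:
    n_taxa: int = 50
    root_length: int = 100
    substitution_rate: float = 0.3  # per site per unit branch length
    insertion_rate: float = 0.02   # events per site per unit branch length
    deletion_rate: float = 0.02
    indel_length_p: float = 0.5    # geometric success prob; mean length 1/p
    branch_scale: float = 0.12     # mean branch length (exponential)
    alphabet: str = _NT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 1 or self.root_length < 1:
            raise ValueError("n_taxa and root_length must be >= 1")
        if min(self.substitution_rate, self.insertion_rate,
               self.deletion_rate, self.branch_scale) < 0:
            raise ValueError("rates must be non-negative")
        if not 0 < self.indel_length_p <= 1:
            raise ValueError("indel_length_p must be in (0, 1]")


#: Divergence presets named for the benchmark regimes they emulate.
PRESETS: dict[str, SimConfig] = {
    "16S-like": SimConfig(substitution_rate=0.18, branch_scale=0.12,
                          insertion_rate=0.03, deletion_rate=0.03),
    "rnasim-like": SimConfig(substitution_rate=0.47, branch_scale=0.12,
                             insertion_rate=0.05, deletion_rate=0.05),
}


def preset_config(name: str, **overrides) -> SimConfig:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    return replace(PRESETS[name], **overrides)


@dataclass
class _Lineage:
    sites: list[int]            # persistent site ids, in sequence order
    chars: dict[int, str] = field(default_factory=dict)


def _random_topology(n: int, rng: random.Random) -> dict[int, list[int]]:
    """Birth-process (Yule) topology: children lists keyed by node id; leaves
    are nodes with no children.  Node 0 is the root."""
    children: dict[int, list[int]] = {0: []}
    leaves = [0]
    next_id = 1
    while len(leaves) < n:
        i = rng.randrange(len(leaves))
        parent = leaves.pop(i)
        kids = [next_id, next_id + 1]
        next_id += 2
        children[parent] = kids
        for k in kids:
            children[k] = []
        leaves.extend(kids)
    return children


def simulate(config: SimConfig) -> tuple[Alignment, list[Sequence], GuideTree]:
    """Evolve sequences; return (true alignment, unaligned sequences, tree).

    Deterministic for a fixed config (including seed).
    """
    rng = random.Random(config.seed)
    alphabet = config.alphabet
    children = _random_topology(config.n_taxa, rng)
    branch_len = {
        node: (rng.expovariate(1.0 / config.branch_scale)
               if config.branch_scale > 0 else 0.0)
        for node in children if node != 0
    }

    global_order: list[int] = list(range(config.root_length))
    next_site = config.root_length
    root = _Lineage(sites=list(range(config.root_length)))
    for s in root.sites:
        root.chars[s] = rng.choice(alphabet)

    def evolve(parent: _Lineage, bl: float) -> _Lineage:
        nonlocal next_site, global_order
        child = _Lineage(sites=list(parent.sites),
                         chars=dict(parent.chars))
        # substitutions
        p_sub = 1.0 - math.exp(-config.substitution_rate * bl)
        for s in child.sites:
            if rng.random() < p_sub:
                cur = child.chars[s]
                others = [c for c in alphabet if c != cur]
                child.chars[s] = rng.choice(others)
        # deletions
        n_del = _poisson(rng, config.deletion_rate * bl * len(child.sites))
        for _ in range(n_del):
            if len(child.sites) <= 1:
                break
            length = min(_geometric(rng, config.indel_length_p),
                         len(child.sites) - 1)
            start = rng.randrange(len(child.sites) - length + 1)
            for s in child.sites[start : start + length]:
                del child.chars[s]
            del child.sites[start : start + length]
        # insertions
        n_ins = _poisson(rng, config.insertion_rate * bl * max(1, len(child.sites)))
        for _ in range(n_ins):
            length = _geometric(rng, config.indel_length_p)
            pos = rng.randrange(len(child.sites) + 1)
            new_ids = list(range(next_site, next_site + length))
            next_site += length
            # Place new sites in the global order right after the left
            # neighbor in this lineage (or before the first site / at the
            # end when there is no neighbor), preserving the invariant that
            # every lineage's site order is a subsequence of global_order.
            if pos > 0:
                anchor = global_order.index(child.sites[pos - 1]) + 1
            elif child.sites:
                anchor = global_order.index(child.sites[0])
            else:
                anchor = len(global_order)
            global_order[anchor:anchor] = new_ids
            child.sites[pos:pos] = new_ids
            for s in new_ids:
                child.chars[s] = rng.choice(alphabet)
        return child

    lineages: dict[int, _Lineage] = {0: root}
    order = [0]
    i = 0
    while i < len(order):
        node = order[i]
        for kid in children[node]:
            lineages[kid] = evolve(lineages[node], branch_len[kid])
            order.append(kid)
        i += 1

    leaf_nodes = [n for n in order if not children[n]]
    labels = {node: f"t{k + 1}" for k, node in enumerate(leaf_nodes)}

    surviving = set()
    for node in leaf_nodes:
        surviving.update(lineages[node].sites)
    columns = [s for s in global_order if s in surviving]
    col_index = {s: i for i, s in enumerate(columns)}

    rows: dict[str, str] = {}
    sequences: list[Sequence] = []
    for node in leaf_nodes:
        lin = lineages[node]
        cells = ["-"] * len(columns)
        for s in lin.sites:
            cells[col_index[s]] = lin.chars[s]
        label = labels[node]
        rows[label] = "".join(cells)
        sequences.append(Sequence(label, "".join(lin.chars[s] for s in lin.sites)))
    true_alignment = Alignment([labels[n] for n in leaf_nodes], rows)

    tree = _to_dendropy(children, branch_len, labels)
    return true_alignment, sequences, GuideTree(tree)


def _to_dendropy(
    children: dict[int, list[int]],
    branch_len: dict[int, float],
    labels: dict[int, str],
) -> dendropy.Tree:
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    nodes: dict[int, dendropy.Node] = {0: tree.seed_node}
    stack = [0]
    while stack:
        nid = stack.pop()
        for kid in children[nid]:
            dn = dendropy.Node()
            dn.edge.length = branch_len[kid]
            nodes[nid].add_child(dn)
            nodes[kid] = dn
            stack.append(kid)
        if not children[nid]:
            taxon = ns.new_taxon(labels[nid])
            nodes[nid].taxon = taxon
    return tree


def _poisson(rng: random.Random, lam: float) -> int:
    if lam <= 0:
        return 0
    # Knuth's method; lambdas here are small (events per branch).
    L = math.exp(-lam)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= L:
            return k
        k += 1


def _geometric(rng: random.Random, p: float) -> int:
    if p >= 1.0:
        return 1
    u = rng.random()
    return max(1, math.ceil(math.log(1.0 - u) / math.log(1.0 - p)))


def measure_pdistance(alignment: Alignment) -> tuple[float, float]:
    """Average and maximum pairwise p-distance (normalized Hamming).

    Per pair of rows: the fraction of columns where both have a letter (any
    case) and the letters differ, case-insensitively.  Pairs with no
    comparable site are skipped.
    """
    ids = alignment.row_ids
    if len(ids) < 2:
        raise ValueError("p-distance needs at least two rows")
    dists = []
    rows = [alignment.row(r).upper() for r in ids]
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            comparable = mismatch = 0
            for a, b in zip(rows[i], rows[j]):
                if a != "-" and b != "-":
                    comparable += 1
                    if a != b:
                        mismatch += 1
            if comparable:
                dists.append(mismatch / comparable)
    if not dists:
        raise ValueError("no comparable residue pairs")
    return sum(dists) / len(dists), max(dists)
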