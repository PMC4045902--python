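"""Intergenome distances, sequence distances, neighbor joining and consensus.

Two distance surfaces feed the same tree machinery:

* the shared-variant intergenome distance ``D_ij = (N_s - |i ∩ j|) / N_s``
  over variant *locations* (chrom, pos) only, where ``N_s`` is the variant
  count of the genome with the fewer variants — allele-agnostic by design,
  which makes the measure robust to uneven depth of coverage across
  sequencing platforms; and
* the Kimura two-parameter (K2P) distance over aligned sequences.

Trees are built by Saitou–Nei neighbor joining with deterministic
tie-breaking, and summarized by majority-rule extended consensus with
per-edge occurrence counts as support.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .formats_io import SiteKey

__all__ = [
    "Node",
    "Tree",
    "parse_newick",
    "DistanceResult",
    "DistanceMatrix",
    "intergenome_distance",
    "per_chromosome_distance_matrices",
    "restrict_to_flagged",
    "flagged_distance_matrix",
    "k2p_distance",
    "neighbor_joining",
    "majority_consensus",
    "collapse_zero_length",
    "bootstrap_tree",
    "bipartitions",
]


# ---------------------------------------------------------------------------
# Tree structure and newick


@dataclass
class Node:
    name: Optional[str] = None
    length: Optional[float] = None
    support: Optional[float] = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class Tree:
    """An (implicitly unrooted) tree; the root is a basal multifurcation."""

    root: Node

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.root.leaves()]

    def to_newick(self, include_support: bool = True) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                s = node.name or ""
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if include_support and node.support is not None:
                    s += (
                        str(int(node.support))
                        if float(node.support).is_integer()
                        else f"{node.support:g}"
                    )
            if node.length is not None:
                s += f":{node.length:.6g}"
            return s

        return fmt(self.root) + ";"


def parse_newick(text: str) -> Tree:
    """Parse a newick string (names, branch lengths, internal support labels)."""
    s = text.strip()
    if not s.endswith(";"):
        raise ValueError("newick string must end with ';'")
    s = s[:-1]
    pos = 0

    def parse_node() -> Node:
        nonlocal pos
        node = Node()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            node.children.append(parse_node())
            while pos < len(s) and s[pos] == ",":
                pos += 1
                node.children.append(parse_node())
            if pos >= len(s) or s[pos] != ")":
                raise ValueError(f"unbalanced parentheses at offset {pos}")
            pos += 1
        # label (leaf name, or internal support)
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        label = s[start:pos].strip()
        if label:
            if node.is_leaf:
                node.name = label
            else:
                try:
                    node.support = float(label)
                except ValueError:
                    node.name = label
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",():;":
                pos += 1
            node.length = float(s[start:pos])
        return node

    root = parse_node()
    if pos != len(s):
        raise ValueError(f"trailing characters in newick at offset {pos}")
    return Tree(root)


def bipartitions(tree: Tree) -> dict[frozenset, Node]:
    """Non-trivial bipartitions of an unrooted tree.

    Each internal edge splits the leaves in two; the split is keyed by the
    side that excludes the lexicographically smallest leaf, so keys are
    comparable across trees with the same leaf set.
    """
    all_leaves = frozenset(tree.leaf_names())
    ref = min(all_leaves)
    out: dict[frozenset, Node] = {}

    def walk(node: Node) -> frozenset:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(walk(c) for c in node.children))
        side = below if ref not in below else all_leaves - below
        if 1 < len(side) < len(all_leaves) - 1:
            out[side] = node
        return below

    for c in tree.root.children:
        walk(c)
    return out


# ---------------------------------------------------------------------------
# Intergenome shared-variant distance


@dataclass(frozen=True)
class DistanceResult:
    """One pairwise shared-variant distance with its ingredients."""

    pair: tuple[str, str]
    n_small: int
    n_large: int
    shared: int
    distance: float


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def to_phylip(self) -> str:
        lines = [f"    {len(self.labels)}"]
        for lab, row in zip(self.labels, self.values):
            lines.append(
                f"{lab[:10]:<10}" + "  ".join(f"{x:.6f}" for x in row)
            )
        return "\n".join(lines) + "\n"


def intergenome_distance(
    variants_i: Iterable[SiteKey],
    variants_j: Iterable[SiteKey],
    labels: tuple[str, str] = ("i", "j"),
) -> DistanceResult:
    """D = (N_s − shared)/N_s over variant locations of two genomes.

    N_s is the size of the smaller variant set; the formula is symmetric
    when the sets tie.  Raises on an empty smaller set (undefined division).
    """
    si, sj = set(variants_i), set(variants_j)
    n_small, n_large = min(len(si), len(sj)), max(len(si), len(sj))
    if n_small == 0:
        raise ValueError("intergenome distance undefined for an empty variant set")
    shared = len(si & sj)
    return DistanceResult(
        pair=labels,
        n_small=n_small,
        n_large=n_large,
        shared=shared,
        distance=(n_small - shared) / n_small,
    )


def _pairwise_matrix(genomes: Mapping[str, set]) -> DistanceMatrix:
    labels = list(genomes)
    n = len(labels)
    m = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            d = intergenome_distance(
                genomes[labels[a]], genomes[labels[b]], (labels[a], labels[b])
            ).distance
            m[a, b] = m[b, a] = d
    return DistanceMatrix(labels, m)


def per_chromosome_distance_matrices(
    genomes: Mapping[str, set],
    contigs: Optional[Sequence[str]] = None,
) -> list[tuple[str, DistanceMatrix]]:
    """One shared-variant distance matrix per contig (default: 22 autosomes).

    A contig on which any genome has no variants is skipped with a warning.
    """
    if len(genomes) < 3:
        raise ValueError("need at least 3 genomes")
    if contigs is None:
        contigs = [str(c) for c in range(1, 23)]
    out = []
    for contig in contigs:
        restricted = {
            g: {s for s in sites if s.chrom == contig} for g, sites in genomes.items()
        }
        if any(len(v) == 0 for v in restricted.values()):
            warnings.warn(f"contig {contig}: empty variant set for some genome; skipped")
            continue
        out.append((contig, _pairwise_matrix(restricted)))
    return out


def restrict_to_flagged(variants: Iterable[SiteKey], flagged_sites: set) -> set:
    """Subset of variant locations that carry a disease-gene (OMIM-like) flag."""
    return set(variants) & set(flagged_sites)


def flagged_distance_matrix(
    genomes: Mapping[str, set], flagged_sites: set
) -> DistanceMatrix:
    """Pairwise distances restricted, per pair, to flagged locations present
    in either genome of the pair; pairs with an empty restricted smaller set
    are skipped with a warning (distance left at 0)."""
    flagged = set(flagged_sites)
    labels = list(genomes)
    n = len(labels)
    m = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            fa = genomes[labels[a]] & flagged
            fb = genomes[labels[b]] & flagged
            keep = fa | fb
            ra, rb = genomes[labels[a]] & keep, genomes[labels[b]] & keep
            if min(len(ra), len(rb)) == 0:
                warnings.warn(
                    f"pair ({labels[a]},{labels[b]}): no flagged variants; skipped"
                )
                continue
            m[a, b] = m[b, a] = intergenome_distance(ra, rb).distance
    return DistanceMatrix(labels, m)


# ---------------------------------------------------------------------------
# K2P sequence distance

_PURINES = {"A", "G"}
_VALID = {"A", "C", "G", "T"}


def k2p_distance(seq_a: str, seq_b: str, undefined_value: float = 10.0) -> float:
    """Kimura two-parameter distance between two aligned sequences.

    d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q) with P, Q the transition and
    transversion proportions over pairwise-complete ACGT sites (pairwise
    deletion of ambiguous sites).  When a log argument is non-positive the
    distance is saturated and ``undefined_value`` is returned with a warning.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    n = ti = tv = 0
    for a, b in zip(seq_a, seq_b):
        if a not in _VALID or b not in _VALID:
            continue
        n += 1
        if a != b:
            if (a in _PURINES) == (b in _PURINES):
                ti += 1
            else:
                tv += 1
    if n == 0:
        raise ValueError("no comparable ACGT sites")
    P, Q = ti / n, tv / n
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        warnings.warn("K2P distance undefined (saturated); reporting configured value")
        return undefined_value
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k2p_matrix(seqs: Mapping[str, str]) -> DistanceMatrix:
    labels = list(seqs)
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = k2p_distance(seqs[labels[i]], seqs[labels[j]])
    return DistanceMatrix(labels, m)


# ---------------------------------------------------------------------------
# Neighbor joining


def neighbor_joining(matrix: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor joining.

    Q-criterion ties are broken by the lowest (row, column) index pair, so
    the result is deterministic for a given label order.  Negative branch
    lengths are retained.  The returned tree is unrooted, represented with a
    basal trifurcation.
    """
    labels = list(matrix.labels)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = matrix.values.astype(float).copy()
    nodes: list[Node] = [Node(name=lab) for lab in labels]

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        # Q[i,j] = (m-2) d_ij - r_i - r_j
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # deterministic argmin: first (i,j) in row-major order at the minimum
        flat = np.argmin(q)
        i, j = divmod(int(flat), m)
        if i > j:
            i, j = j, i
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        nodes[i].length = li
        nodes[j].length = lj
        parent = Node(children=[nodes[i], nodes[j]])
        # distances from new node to the rest
        dnew = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        d_next = np.empty((m - 1, m - 1))
        d_next[:-1, :-1] = d[np.ix_(keep, keep)]
        d_next[-1, :-1] = d_next[:-1, -1] = dnew[keep]
        d_next[-1, -1] = 0.0
        d = d_next
        nodes = [nodes[k] for k in keep] + [parent]

    # resolve the final three nodes with the three-point formulas
    (d01, d02, d12) = (d[0, 1], d[0, 2], d[1, 2])
    nodes[0].length = 0.5 * (d01 + d02 - d12)
    nodes[1].length = 0.5 * (d01 + d12 - d02)
    nodes[2].length = 0.5 * (d02 + d12 - d01)
    return Tree(Node(children=nodes))


# ---------------------------------------------------------------------------
# Majority-rule extended consensus


def _compatible(a: frozenset, b: frozenset) -> bool:
    # splits keyed relative to a common reference leaf: compatible iff
    # nested or disjoint
    return a <= b or b <= a or not (a & b)


def majority_consensus(trees: Sequence[Tree], extended: bool = True) -> Tree:
    """Majority-rule (extended) consensus with occurrence counts as support.

    Includes every bipartition present in more than half the input trees,
    then — in the extended (PHYLIP Consense default) variant — greedily adds
    the remaining bipartitions in decreasing frequency order when compatible
    with all those already included.  Support = number of input trees
    containing the bipartition.
    """
    if not trees:
        raise ValueError("no trees")
    leaf_sets = [frozenset(t.leaf_names()) for t in trees]
    if len(set(leaf_sets)) != 1:
        raise ValueError("consensus requires identical leaf sets")
    all_leaves = leaf_sets[0]
    counts: dict[frozenset, int] = {}
    for t in trees:
        for split in bipartitions(t):
            counts[split] = counts.get(split, 0) + 1
    n_trees = len(trees)
    # deterministic order: frequency desc, then by sorted member tuple
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], sorted(kv[0])))
    included: list[tuple[frozenset, int]] = []
    for split, c in ordered:
        if 2 * c > n_trees:
            included.append((split, c))
        elif extended and all(_compatible(split, s) for s, _ in included):
            included.append((split, c))

    # build tree from the laminar family of included splits
    root = Node()
    clade_nodes: dict[frozenset, Node] = {frozenset(all_leaves): root}
    for split, c in sorted(included, key=lambda kv: -len(kv[0])):
        parent_key = min(
            (k for k in clade_nodes if split < k or k == frozenset(all_leaves)),
            key=len,
        )
        node = Node(support=c)
        clade_nodes[parent_key].children.append(node)
        clade_nodes[split] = node
    for leaf in sorted(all_leaves):
        parent_key = min((k for k in clade_nodes if leaf in k), key=len)
        clade_nodes[parent_key].children.append(Node(name=leaf))
    return Tree(root)


def collapse_zero_length(tree: Tree, tol: float = 1e-12) -> Tree:
    """Collapse internal edges of length ≤ tol into multifurcations.

    A zero-length internal edge carries no grouping signal (NJ resolves
    ties arbitrarily), so replicate trees are collapsed before consensus.
    """

    def rebuild(node: Node) -> list[Node]:
        if node.is_leaf:
            return [node]
        children: list[Node] = []
        for c in node.children:
            children.extend(rebuild(c))
        if node.length is not None and node.length <= tol:
            return children  # splice grandchildren into the parent
        return [Node(name=node.name, length=node.length, support=node.support,
                     children=children)]

    new_children: list[Node] = []
    for c in tree.root.children:
        new_children.extend(rebuild(c))
    return Tree(Node(children=new_children))


# ---------------------------------------------------------------------------
# Bootstrap


def bootstrap_tree(
    alignment: Mapping[str, str],
    n_reps: int,
    seed: int,
) -> Tree:
    """Bootstrap consensus: resample alignment columns with replacement,
    build a K2P neighbor-joining tree per replicate, and return the
    majority-rule extended consensus with replicate counts as support."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    names = list(alignment)
    seqs = [alignment[n] for n in names]
    L = len(seqs[0])
    if L == 0:
        raise ValueError("alignment has zero length")
    if any(len(s) != L for s in seqs):
        raise ValueError("ragged alignment")
    rng = np.random.default_rng(seed)
    reps = []
    arr = np.array([list(s) for s in seqs])
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        res = arr[:, cols]
        boot = {n: "".join(row) for n, row in zip(names, res)}
        reps.append(collapse_zero_length(neighbor_joining(k2p_matrix(boot))))
    return majority_consensus(reps)
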