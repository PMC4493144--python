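"""Neighbour-joining trees, nonparametric bootstrap and tree-based assignment.

The agglomeration is Saitou & Nei's: at each step join the pair minimising

    Q(i, j) = (n - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k)

with branch lengths from the standard three-point formulas.  Ties in Q are
broken by the lowest (row, col) index pair of the working matrix, so repeated
runs are bit-identical.  Negative branch-length estimates are clamped to zero
with no length transfer; the clamped total is logged.

Bootstrap supports are column-resampling supports for the bipartitions of the
*original-data* tree (one phenogram annotated with percentages, not a
majority-rule consensus).  The RNG stream is documented and deliberately
simple so an independent recount can consume the same index stream: a single
``numpy.random.default_rng(seed)`` generator draws, replicate by replicate,
``L`` column indices via ``rng.integers(0, L, size=L)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .distances import (
    DistanceMatrix,
    P_DISTANCE,
    UndefinedDistanceError,
    build_distance_matrix,
)
from .seqio import Alignment, SequenceRecord

logger = logging.getLogger(__name__)

#: Default cap substituted for K2P-saturated pairs when building trees.
DEFAULT_SATURATION_CAP = 5.0

AMBIGUOUS_BETWEEN_CLUSTERS = "ambiguous-between-clusters"


class TreeError(ValueError):
    pass


@dataclass
class Node:
    """Tree node; ``length`` is the branch above the node (None at the root)."""

    name: str | None = None
    length: float | None = None
    support: float | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out: list[Node] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.name for l in self.leaves())  # type: ignore[misc]

    def walk(self) -> Iterable["Node"]:
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass(frozen=True)
class Bipartition:
    """A split of the leaf set induced by an internal edge.

    Canonical form: the block containing the lexicographically smallest leaf
    is ``side_a``.
    """

    side_a: tuple[str, ...]
    side_b: tuple[str, ...]

    @classmethod
    def from_blocks(cls, a: Iterable[str], b: Iterable[str]) -> "Bipartition":
        a, b = sorted(a), sorted(b)
        if not a or not b:
            raise ValueError("bipartition blocks must be non-empty")
        if min(a) > min(b):
            a, b = b, a
        return cls(tuple(a), tuple(b))


class PhyloTree:
    """Unrooted tree stored with a trifurcating top node."""

    def __init__(self, root: Node):
        if len(root.children) < 3 and not root.is_leaf:
            # permit the degenerate rooted form only if it came from parsing;
            # NJ construction always produces a trifurcation.
            pass
        self.root = root
        names = [l.name for l in root.leaves()]
        if len(names) != len(set(names)) or any(n is None for n in names):
            raise TreeError("leaf labels must be unique and non-empty")
        self._leaf_names = frozenset(names)  # type: ignore[arg-type]

    @property
    def leaf_names(self) -> frozenset[str]:
        return self._leaf_names

    def _canonical(self, block: frozenset[str]) -> frozenset[str]:
        """Represent a split by the block NOT containing the smallest leaf."""
        anchor = min(self._leaf_names)
        return self._leaf_names - block if anchor in block else block

    def internal_nodes(self) -> list[Node]:
        """Non-root internal nodes; each owns one internal edge of the tree."""
        return [
            n for n in self.root.walk() if n is not self.root and not n.is_leaf
        ]

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each as its canonical block."""
        n = len(self._leaf_names)
        out = set()
        for node in self.internal_nodes():
            block = node.leaf_names()
            if 2 <= len(block) <= n - 2:
                out.add(self._canonical(block))
        return out

    def bipartition_objects(self) -> set[Bipartition]:
        return {
            Bipartition.from_blocks(b, self._leaf_names - b)
            for b in self.bipartitions()
        }

    def edge_blocks(self) -> list[frozenset[str]]:
        """Every leaf block induced by every edge (both orientations)."""
        blocks: list[frozenset[str]] = []
        for node in self.root.walk():
            if node is self.root:
                continue
            b = node.leaf_names()
            blocks.append(b)
            blocks.append(self._leaf_names - b)
        return blocks

    def supports(self) -> dict[frozenset[str], float]:
        return {
            self._canonical(n.leaf_names()): n.support
            for n in self.internal_nodes()
            if n.support is not None
        }

    def total_length(self) -> float:
        return sum(
            n.length for n in self.root.walk() if n.length is not None
        )


def nj_build(dm: DistanceMatrix) -> PhyloTree:
    """Build the neighbour-joining tree for a distance matrix.

    On an additive (tree-metric) input the generating topology and branch
    lengths are recovered exactly (up to numerical round-off).
    """
    n = len(dm)
    if n < 3:
        raise TreeError(f"need at least 3 taxa for NJ (got {n})")
    if not np.isfinite(dm.matrix).all():
        raise TreeError("distance matrix contains non-finite entries")

    D = dm.matrix.astype(float).copy()
    nodes: list[Node] = [Node(name=lab) for lab in dm.labels]
    clamped_total = 0.0

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # argmin on the flattened row-major array -> lowest (row, col) tie-break
        flat = int(np.argmin(Q))
        i, j = divmod(flat, m)
        if i > j:  # cannot happen for symmetric Q, but keep the invariant explicit
            i, j = j, i
        d_ij = D[i, j]
        li = 0.5 * d_ij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d_ij - li
        if li < 0:
            clamped_total += -li
            li = 0.0
        if lj < 0:
            clamped_total += -lj
            lj = 0.0
        nodes[i].length = li
        nodes[j].length = lj
        parent = Node(children=[nodes[i], nodes[j]])
        d_new = 0.5 * (D[i, :] + D[j, :] - d_ij)
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.pad(D[np.ix_(keep, keep)], ((0, 1), (0, 1)))
        D[-1, :-1] = d_new[keep]
        D[:-1, -1] = d_new[keep]
        nodes = [nodes[k] for k in keep] + [parent]

    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lengths = [
        (d01 + d02 - d12) / 2.0,
        (d01 + d12 - d02) / 2.0,
        (d02 + d12 - d01) / 2.0,
    ]
    for node, l in zip(nodes, lengths):
        if l < 0:
            clamped_total += -l
            l = 0.0
        node.length = l
    if clamped_total > 0:
        logger.info(
            "NJ clamped negative branch lengths totalling %.6g subs/site",
            clamped_total,
        )
    return PhyloTree(Node(children=list(nodes)))


def _resampled_alignment(alignment: Alignment, idx: np.ndarray) -> Alignment:
    codes = alignment.to_codes()[:, idx]
    # rebuild records from resampled codes
    inv = np.array(list("ACGT" + "-RYSWKMBDHVN"), dtype="U1")
    recs = [
        SequenceRecord(rid, "".join(inv[codes[k]]))
        for k, rid in enumerate(alignment.ids)
    ]
    return Alignment(recs)


def bootstrap_supports(
    alignment: Alignment,
    model: str = P_DISTANCE,
    n_reps: int = 1000,
    seed: int = 0,
    saturation_cap: float = DEFAULT_SATURATION_CAP,
) -> PhyloTree:
    """NJ tree of *alignment* with bootstrap supports on its internal edges.

    Each replicate resamples ``alignment.length`` columns with replacement and
    rebuilds the NJ tree; an internal edge's support is 100 x the fraction of
    successful replicate trees containing its bipartition.  Replicates with an
    undefined pair (no comparable sites) are skipped with a warning; more than
    50% skipped is an error.  Fixed seed -> bit-identical output.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    dm = build_distance_matrix(alignment, model, saturation_cap=saturation_cap)
    tree = nj_build(dm)
    targets = tree.bipartitions()
    counts: dict[frozenset[str], int] = {b: 0 for b in targets}

    rng = np.random.default_rng(seed)
    L = alignment.length
    skipped = 0
    for _ in range(n_reps):
        idx = rng.integers(0, L, size=L)
        rep_aln = _resampled_alignment(alignment, idx)
        try:
            rep_dm = build_distance_matrix(rep_aln, model, saturation_cap=saturation_cap)
        except UndefinedDistanceError as exc:
            skipped += 1
            logger.warning("bootstrap replicate skipped: %s", exc)
            continue
        rep_biparts = nj_build(rep_dm).bipartitions()
        for b in targets & rep_biparts:
            counts[b] += 1
    effective = n_reps - skipped
    if skipped * 2 > n_reps:
        raise TreeError(
            f"{skipped}/{n_reps} bootstrap replicates skipped (undefined distances)"
        )
    for node in tree.internal_nodes():
        block = tree._canonical(node.leaf_names())
        if block in counts:
            node.support = 100.0 * counts[block] / effective
    return tree


def _newick_node(node: Node) -> str:
    if node.is_leaf:
        body = node.name or ""
    else:
        label = "" if node.support is None else f"{node.support:g}"
        body = "(" + ",".join(_newick_node(c) for c in node.children) + ")" + label
    if node.length is None:
        return body
    return f"{body}:{node.length:.10g}"


def to_newick(tree: PhyloTree) -> str:
    """Newick text with branch lengths and supports as internal-node labels."""
    return _newick_node(tree.root) + ";"


@dataclass(frozen=True)
class TreeAssignment:
    """Outcome of placing one query on the tree."""

    query_id: str
    species: str | None
    flag: str | None = None
    candidates: tuple[str, ...] = ()


def assign_by_tree(
    tree: PhyloTree,
    reference_species: Mapping[str, str],
    query_ids: Iterable[str],
) -> dict[str, TreeAssignment]:
    """Assign queries to the species of their smallest enclosing reference clade.

    For each query, over all edge-induced leaf blocks containing the query and
    at least one reference, take the smallest; if every reference in all
    minimal blocks belongs to one species, assign it, otherwise flag
    ``ambiguous-between-clusters`` (the query sits between reference clusters).
    """
    query_ids = list(query_ids)
    missing = [q for q in query_ids if q not in tree.leaf_names]
    if missing:
        raise TreeError(f"queries absent from tree: {missing}")
    ref_ids = set(reference_species)
    blocks = tree.edge_blocks()
    out: dict[str, TreeAssignment] = {}
    for q in query_ids:
        best_size: int | None = None
        species: set[str] = set()
        for block in blocks:
            if q not in block:
                continue
            refs_in = block & ref_ids
            if not refs_in:
                continue
            if best_size is None or len(block) < best_size:
                best_size = len(block)
                species = {reference_species[r] for r in refs_in}
            elif len(block) == best_size:
                species |= {reference_species[r] for r in refs_in}
        if best_size is None:
            out[q] = TreeAssignment(q, None, flag="no-reference-in-tree")
        elif len(species) == 1:
            out[q] = TreeAssignment(q, next(iter(species)))
        else:
            out[q] = TreeAssignment(
                q,
                None,
                flag=AMBIGUOUS_BETWEEN_CLUSTERS,
                candidates=tuple(sorted(species)),
            )
    return out
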