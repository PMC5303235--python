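"""Difference-count phylogenetics: concatenation, p-distances, NJ, bootstrap.

Homologous fragments are concatenated per taxon; pairwise distances are
plain difference counts (p-distances) over sites passing the deletion
filter; trees are built by Neighbor-Joining, which is consistent on
additive matrices; internal-edge support comes from column bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import encode
from .errors import ParameterError

COMPLETE_DELETION = "complete_deletion"
PAIRWISE_DELETION = "pairwise_deletion"


@dataclass
class ConcatAlignment:
    """A concatenated multiple alignment: equal-length rows over A,C,G,T,N,-."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ParameterError("one row per taxon required")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ParameterError(f"rows have unequal lengths: {sorted(lengths)}")
        if len(set(self.taxa)) != len(self.taxa):
            raise ParameterError("duplicate taxon names")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @classmethod
    def concatenate(cls, taxa: list[str], fragments: list[list[str]]) -> "ConcatAlignment":
        """Concatenate per-taxon aligned fragments (outer list: fragments)."""
        rows = ["".join(parts) for parts in zip(*fragments)]
        return cls(taxa, rows)

    def _matrix(self) -> np.ndarray:
        mat = np.zeros((len(self.rows), self.n_columns), dtype=np.uint8)
        for i, r in enumerate(self.rows):
            mat[i] = encode(r.replace("-", "N").replace("?", "N"))
        return mat

    def subset_columns(self, idx: np.ndarray) -> "ConcatAlignment":
        rows = ["".join(r[j] for j in idx) for r in self.rows]
        return ConcatAlignment(self.taxa, rows)


def pairwise_differences(
    aln: ConcatAlignment, mode: str = COMPLETE_DELETION
) -> tuple[np.ndarray, np.ndarray | int]:
    """Symmetric matrix of pairwise difference counts plus sites used.

    ``complete_deletion`` drops every column with N or a gap in any taxon
    first (one shared site count); ``pairwise_deletion`` drops per pair
    (matrix of site counts).
    """
    if len(aln.taxa) < 2:
        raise ParameterError("need at least two taxa")
    mat = aln._matrix()
    known = mat <= 3
    n = len(aln.taxa)
    if mode == COMPLETE_DELETION:
        usable = known.all(axis=0)
        n_sites = int(usable.sum())
        if n_sites == 0:
            raise ParameterError("no usable sites under complete deletion")
        sub = mat[:, usable]
        D = np.zeros((n, n), dtype=np.int64)
        for i in range(n):
            for j in range(i + 1, n):
                d = int((sub[i] != sub[j]).sum())
                D[i, j] = D[j, i] = d
        return D, n_sites
    if mode == PAIRWISE_DELETION:
        D = np.zeros((n, n), dtype=np.int64)
        S = np.zeros((n, n), dtype=np.int64)
        for i in range(n):
            for j in range(i + 1, n):
                ok = known[i] & known[j]
                s = int(ok.sum())
                if s == 0:
                    raise ParameterError(f"no usable sites for pair ({aln.taxa[i]}, {aln.taxa[j]})")
                d = int((mat[i, ok] != mat[j, ok]).sum())
                D[i, j] = D[j, i] = d
                S[i, j] = S[j, i] = s
        np.fill_diagonal(S, aln.n_columns)
        return D, S
    raise ParameterError(f"unknown deletion mode {mode!r}")


def p_distance_matrix(
    aln: ConcatAlignment, mode: str = COMPLETE_DELETION, jukes_cantor: bool = False
) -> np.ndarray:
    """Fraction-of-differing-sites matrix (optionally Jukes-Cantor corrected)."""
    D, sites = pairwise_differences(aln, mode)
    P = D / np.maximum(sites, 1) if isinstance(sites, np.ndarray) else D / sites
    if jukes_cantor:
        arg = 1.0 - 4.0 * P / 3.0
        if (arg <= 0).any():
            raise ParameterError("p-distance too large for Jukes-Cantor correction")
        P = -0.75 * np.log(arg)
    np.fill_diagonal(P, 0.0)
    return P


@dataclass
class TreeNode:
    name: str = ""
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for c, _ in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PhyloTree:
    """An unrooted tree, stored with a trifurcating root; supports on internal edges."""

    root: TreeNode
    taxa: list[str]

    def bipartitions(self) -> dict[frozenset, TreeNode]:
        """Non-trivial splits, each keyed by the side excluding the first taxon
        (alphabetically) so that the two orientations of a split coincide."""
        anchor = min(self.taxa)
        full = set(self.taxa)
        out: dict[frozenset, TreeNode] = {}

        def walk(node: TreeNode) -> None:
            for child, _ in node.children:
                if not child.is_leaf:
                    below = set(child.leaves())
                    side = frozenset(full - below if anchor in below else below)
                    if 2 <= len(side) <= len(full) - 2:
                        out[side] = child
                    walk(child)

        walk(self.root)
        return out

    def to_newick(self, with_support: bool = True) -> str:
        def fmt(node: TreeNode, length: float | None) -> str:
            if node.is_leaf:
                s = node.name
            else:
                inner = ",".join(fmt(c, ln) for c, ln in node.children)
                label = (
                    f"{node.support:g}" if with_support and node.support is not None else ""
                )
                s = f"({inner}){label}"
            return s if length is None else f"{s}:{length:g}"

        return fmt(self.root, None) + ";"


def nj_tree(distances: np.ndarray, taxa: list[str]) -> PhyloTree:
    """Neighbor-Joining with the standard Q criterion.

    Negative intermediate branch lengths are clamped to zero, the deficit
    shifted to the sister edge (preserving the pair's summed length).
    Requires a symmetric, non-negative matrix with a zero diagonal and at
    least three taxa.
    """
    D = np.asarray(distances, dtype=float)
    n = len(taxa)
    if n < 3:
        raise ParameterError("NJ requires at least three taxa")
    if D.shape != (n, n):
        raise ParameterError("distance matrix does not match the taxon list")
    if not np.allclose(D, D.T) or (np.diag(D) != 0).any() or (D < 0).any():
        raise ParameterError("distance matrix must be symmetric, non-negative, zero-diagonal")

    nodes: list[TreeNode] = [TreeNode(name=t) for t in taxa]
    edge_len: dict[int, float] = {}
    D = D.copy()
    active = list(range(n))
    children: dict[int, list[tuple[int, float]]] = {}
    next_id = n
    store: dict[int, TreeNode] = {i: nodes[i] for i in range(n)}

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        ii, jj = np.unravel_index(np.argmin(Q), Q.shape)
        a, b = active[ii], active[jj]
        dij = D[a, b]
        la = 0.5 * dij + (r[ii] - r[jj]) / (2 * (m - 2))
        lb = dij - la
        if la < 0:
            la, lb = 0.0, dij
        elif lb < 0:
            la, lb = dij, 0.0
        parent = TreeNode()
        parent.children = [(store[a], la), (store[b], lb)]
        store[next_id] = parent
        # distances from the new node to the remaining ones
        newD = np.zeros_like(D[0])
        for c in active:
            if c in (a, b):
                continue
            newD[c] = 0.5 * (D[a, c] + D[b, c] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[next_id, : next_id] = newD[: next_id]
        D[: next_id, next_id] = newD[: next_id]
        active = [c for c in active if c not in (a, b)] + [next_id]
        next_id += 1

    # resolve the final three nodes into the trifurcating root
    x, y, z = active
    lx = max(0.0, 0.5 * (D[x, y] + D[x, z] - D[y, z]))
    ly = max(0.0, 0.5 * (D[x, y] + D[y, z] - D[x, z]))
    lz = max(0.0, 0.5 * (D[x, z] + D[y, z] - D[x, y]))
    root = TreeNode()
    root.children = [(store[x], lx), (store[y], ly), (store[z], lz)]
    return PhyloTree(root=root, taxa=list(taxa))


def bootstrap_support(
    aln: ConcatAlignment,
    reps: int = 500,
    seed: int = 0,
    mode: str = COMPLETE_DELETION,
) -> tuple[PhyloTree, dict[frozenset, float]]:
    """Column bootstrap on the NJ tree of the full alignment.

    Resamples alignment columns with replacement, rebuilds the NJ tree per
    replicate, and reports for each internal edge of the full-data tree the
    fraction of replicates containing its bipartition.  Deterministic given
    ``seed``.  Degenerate alignments with no resolved splits (e.g. all
    sequences identical) return empty supports.
    """
    if reps < 1:
        raise ParameterError("reps must be >= 1")
    P = p_distance_matrix(aln, mode)
    tree = nj_tree(P, aln.taxa)
    if not P.any():
        return tree, {}
    splits = tree.bipartitions()
    if not splits:
        return tree, {}
    counts = {s: 0 for s in splits}
    rng = np.random.default_rng(seed)
    ncol = aln.n_columns
    for _ in range(reps):
        idx = rng.integers(0, ncol, size=ncol)
        sub = aln.subset_columns(idx)
        try:
            Pr = p_distance_matrix(sub, mode)
        except ParameterError:  # replicate with no usable sites
            continue
        rep_splits = nj_tree(Pr, aln.taxa).bipartitions()
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    supports = {s: c / reps for s, c in counts.items()}
    for s, node in splits.items():
        node.support = supports[s]
    return tree, supports


def robinson_foulds(t1: PhyloTree, t2: PhyloTree) -> int:
    """Unweighted RF distance (symmetric difference of non-trivial splits)."""
    s1, s2 = set(t1.bipartitions()), set(t2.bipartitions())
    return len(s1 ^ s2)
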