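"""Rooted ultrametric phylogenies: parsing, covariance, branching times.

The central objects are :class:`Phylogeny` (a rooted tree with branch
lengths in millions of years), :class:`PhyloCovariance` (the tip-by-tip
expected covariance of a trait evolving by Brownian motion on that tree)
and :class:`BranchingTimes` (sorted internal-node depths with the
internode intervals ``g_k`` used by the diversification-slowdown
statistic).

Newick/NEXUS I/O is delegated to :mod:`dendropy`; everything downstream
of parsing (covariance construction, Pagel's lambda transform, branching
time extraction, ultrametricity checks) is computed here.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "PhyloCovariance",
    "BranchingTimes",
    "TreeError",
    "TreeParseError",
    "UltrametricityError",
    "read_tree",
    "read_trees",
    "lambda_transform",
]


class TreeError(ValueError):
    """A tree violates a structural requirement."""


class TreeParseError(TreeError):
    """The Newick/NEXUS source could not be parsed."""


class UltrametricityError(TreeError):
    """Tip depths differ by more than the allowed tolerance."""


@dataclass(frozen=True)
class PhyloCovariance:
    """Expected trait covariance among tips under Brownian motion.

    ``matrix[i, j]`` is the root-to-MRCA path length shared by tips
    ``taxa[i]`` and ``taxa[j]``; the diagonal holds root-to-tip depths.
    Units are those of the branch lengths (My for the shipped trees).
    """

    matrix: np.ndarray
    taxa: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "taxa", tuple(self.taxa))
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("covariance matrix must be square")
        if m.shape[0] != len(self.taxa):
            raise ValueError("taxa count does not match matrix dimension")
        if not np.allclose(m, m.T, rtol=0, atol=1e-10 * max(1.0, np.abs(m).max())):
            raise ValueError("covariance matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def lambda_transform(self, lam: float, upper: float = 1.0) -> "PhyloCovariance":
        """Pagel's lambda: scale off-diagonal covariances by ``lam``.

        ``lam = 1`` leaves the Brownian covariance intact; ``lam = 0``
        removes all shared history (a star tree with the original tip
        depths). Diagonals are never modified.
        """
        if not (0.0 <= lam <= upper):
            raise ValueError(f"lambda={lam} outside [0, {upper}]")
        out = self.matrix * lam
        np.fill_diagonal(out, np.diag(self.matrix))
        return PhyloCovariance(out, self.taxa)

    def reorder(self, taxa: Sequence[str]) -> "PhyloCovariance":
        """Return the covariance restricted/permuted to the given taxa."""
        index = {t: i for i, t in enumerate(self.taxa)}
        missing = [t for t in taxa if t not in index]
        if missing:
            raise KeyError(f"taxa not in covariance: {missing}")
        idx = np.array([index[t] for t in taxa])
        return PhyloCovariance(self.matrix[np.ix_(idx, idx)], tuple(taxa))


def lambda_transform(C: PhyloCovariance, lam: float, upper: float = 1.0) -> PhyloCovariance:
    """Functional alias for :meth:`PhyloCovariance.lambda_transform`."""
    return C.lambda_transform(lam, upper=upper)


@dataclass(frozen=True)
class BranchingTimes:
    """Internal-node depths of an ultrametric tree, sorted root-first.

    For a binary tree with ``n`` tips there are ``n - 1`` depths; a
    ``k``-way polytomy contributes ``k - 1`` coincident depths so the
    bookkeeping (and the gamma statistic) stays defined on imperfectly
    resolved trees. ``intervals[k-2]`` is ``g_k``, the duration during
    which the reconstructed tree had exactly ``k`` lineages
    (``k = 2..n``); the intervals sum to the root age.
    """

    depths: np.ndarray
    n_tips: int

    def __post_init__(self) -> None:
        d = np.sort(np.asarray(self.depths, dtype=float))[::-1]
        object.__setattr__(self, "depths", d)
        if len(d) != self.n_tips - 1:
            raise ValueError(
                f"expected {self.n_tips - 1} internal depths for {self.n_tips} tips, got {len(d)}"
            )
        if len(d) and d[-1] < -1e-12:
            raise ValueError("negative node depth")

    @property
    def root_age(self) -> float:
        return float(self.depths[0])

    @property
    def intervals(self) -> np.ndarray:
        """Internode intervals g_k for k = 2..n (length n - 1)."""
        d = self.depths
        return np.concatenate([d[:-1] - d[1:], d[-1:]])

    @classmethod
    def from_intervals(cls, intervals: Sequence[float]) -> "BranchingTimes":
        g = np.asarray(intervals, dtype=float)
        if np.any(g < 0):
            raise ValueError("internode intervals must be nonnegative")
        # depth of the k-th node from the present is the tail sum of g
        depths = np.cumsum(g[::-1])[::-1]
        return cls(depths, n_tips=len(g) + 1)


class Phylogeny:
    """A rooted tree with branch lengths, stored as parent-pointer arrays.

    Nodes are indexed in preorder (root = 0), so every parent precedes
    its children. Tips carry unique non-empty labels; branch lengths are
    nonnegative and interpreted in millions of years.
    """

    def __init__(
        self,
        parent: Sequence[int],
        branch_lengths: Sequence[float],
        labels: Sequence[str | None],
    ) -> None:
        self.parent = np.asarray(parent, dtype=int)
        self.branch_lengths = np.asarray(branch_lengths, dtype=float)
        self.labels = list(labels)
        self._validate()

    # -- construction ------------------------------------------------

    def _validate(self) -> None:
        n = len(self.parent)
        if not (len(self.branch_lengths) == len(self.labels) == n):
            raise TreeError("parent, branch_lengths and labels must have equal length")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1 or roots[0] != 0:
            raise TreeError("exactly one root required, at index 0")
        if np.any(self.parent[1:] >= np.arange(1, n)):
            raise TreeError("nodes must be in preorder (parents before children)")
        if np.any(self.branch_lengths < 0):
            raise TreeError("negative branch length")
        self._children: list[list[int]] = [[] for _ in range(n)]
        for i in range(1, n):
            self._children[self.parent[i]].append(i)
        self._tip_idx = np.array(
            [i for i in range(n) if not self._children[i]], dtype=int
        )
        tips = [self.labels[i] for i in self._tip_idx]
        if any(t is None or t == "" for t in tips):
            raise TreeError("every tip must carry a non-empty label")
        if len(set(tips)) != len(tips):
            dupes = sorted({t for t in tips if tips.count(t) > 1})
            raise TreeError(f"duplicate tip labels: {dupes}")
        if self.depth <= 0:
            raise TreeError("tree depth must be positive")

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent, blen, labels = [], [], []
        for nd in nodes:
            parent.append(-1 if nd.parent_node is None else index[id(nd.parent_node)])
            blen.append(0.0 if nd.edge.length is None else float(nd.edge.length))
            if nd.taxon is not None:
                labels.append(nd.taxon.label)
            else:
                labels.append(nd.label)
        return cls(parent, blen, labels)

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=taxa)
        nodes = [dendropy.Node() for _ in range(len(self.parent))]
        tree.seed_node = nodes[0]
        for i in range(1, len(self.parent)):
            nodes[self.parent[i]].add_child(nodes[i])
            nodes[i].edge.length = float(self.branch_lengths[i])
        for i in self._tip_idx:
            nodes[i].taxon = taxa.new_taxon(self.labels[i])
        return tree

    # -- basic geometry ----------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self._tip_idx)

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self._tip_idx]

    def node_depths(self) -> np.ndarray:
        depth = np.zeros(len(self.parent))
        for i in range(1, len(self.parent)):
            depth[i] = depth[self.parent[i]] + self.branch_lengths[i]
        return depth

    def tip_depths(self) -> np.ndarray:
        return self.node_depths()[self._tip_idx]

    @property
    def depth(self) -> float:
        d = np.zeros(len(self.parent))
        for i in range(1, len(self.parent)):
            d[i] = d[self.parent[i]] + self.branch_lengths[i]
        return float(d.max()) if len(d) else 0.0

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        td = self.tip_depths()
        return bool(np.abs(td - td.mean()).max() <= rtol * td.mean())

    def check_ultrametric(self, rtol: float = 1e-6) -> None:
        td = self.tip_depths()
        dev = np.abs(td - td.mean())
        worst = int(dev.argmax())
        if dev[worst] > rtol * td.mean():
            raise UltrametricityError(
                f"tree is not ultrametric within rtol={rtol}: tip "
                f"{self.tip_labels[worst]!r} at depth {td[worst]:.6g} vs mean {td.mean():.6g}"
            )

    # -- derived objects ---------------------------------------------

    def vcv(self) -> PhyloCovariance:
        """Brownian-motion tip covariance: shared root-to-MRCA path lengths."""
        if self.depth <= 0:
            raise TreeError("zero-depth tree has a degenerate covariance")
        n = self.n_tips
        depth = self.node_depths()
        tip_pos = {int(t): k for k, t in enumerate(self._tip_idx)}
        C = np.zeros((n, n))
        # postorder accumulation of descendant tip sets; pairs of tips in
        # different child subtrees share exactly this node's depth
        desc: dict[int, list[int]] = {}
        for i in range(len(self.parent) - 1, -1, -1):
            kids = self._children[i]
            if not kids:
                desc[i] = [tip_pos[i]]
                C[tip_pos[i], tip_pos[i]] = depth[i]
                continue
            sets = [desc.pop(k) for k in kids]
            for a in range(len(sets)):
                for b in range(a + 1, len(sets)):
                    C[np.ix_(sets[a], sets[b])] = depth[i]
                    C[np.ix_(sets[b], sets[a])] = depth[i]
            desc[i] = [t for s in sets for t in s]
        return PhyloCovariance(C, tuple(self.tip_labels))

    def branching_times(self, rtol: float = 1e-6) -> BranchingTimes:
        """Internal-node depths measured from the root of an ultrametric tree.

        A node with ``k`` children contributes ``k - 1`` coincident
        depths, so polytomies behave like zero-length internodes.
        """
        self.check_ultrametric(rtol=rtol)
        depth = self.node_depths()
        T = self.tip_depths().mean()
        out: list[float] = []
        for i in range(len(self.parent)):
            k = len(self._children[i])
            if k:
                out.extend([T - depth[i]] * (k - 1))
        return BranchingTimes(np.array(out), n_tips=self.n_tips)

    # -- editing & I/O -----------------------------------------------

    def drop_tips(self, labels: Sequence[str]) -> "Phylogeny":
        """Return a tree with the named tips (and orphaned internals) removed."""
        labels = set(labels)
        missing = labels - set(self.tip_labels)
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        tree = self.to_dendropy()
        keep = [t for t in tree.taxon_namespace if t.label not in labels]
        tree.retain_taxa(keep)
        # collapse the root's single child if pruning left a knee
        tree.suppress_unifurcations()
        return Phylogeny.from_dendropy(tree)

    def write_newick(self) -> str:
        return self.to_dendropy().as_string(
            schema="newick", suppress_rooting=True
        ).strip()


def _get_dendropy_trees(source, fmt: str) -> dendropy.TreeList:
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        data = Path(str(source)).read_text()
    elif hasattr(source, "read"):
        data = source.read()
    else:
        data = str(source)
    try:
        return dendropy.TreeList.get(
            data=data, schema=fmt, preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise TreeParseError(f"could not parse {fmt} source: {exc}") from exc


def read_trees(source, format: str = "newick") -> list[Phylogeny]:
    """Read every tree in a Newick or NEXUS source (file path, stream or text).

    NEXUS TRANSLATE tables, quoted labels and square-bracket comments are
    handled by the parser; non-TREES blocks are ignored.
    """
    fmt = format.lower()
    if fmt not in {"newick", "nexus"}:
        raise ValueError(f"unknown tree format: {format!r}")
    trees = _get_dendropy_trees(source, fmt)
    if not trees:
        raise TreeParseError("source contains no trees")
    return [Phylogeny.from_dendropy(t) for t in trees]


def read_tree(source, format: str = "newick", index: int = 0) -> Phylogeny:
    """Read one tree (by position) from a Newick or NEXUS source."""
    trees = read_trees(source, format=format)
    if not (0 <= index < len(trees)):
        raise IndexError(f"tree index {index} out of range ({len(trees)} trees)")
    return trees[index]
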