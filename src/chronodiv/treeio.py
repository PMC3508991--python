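"""Chronogram input/output and branching-time extraction.

A *chronogram* is a rooted, binary, ultrametric tree whose branch lengths
are in absolute time (Ma here).  Every downstream analysis in this package
consumes either a single chronogram or an ordered sample of them (e.g. a
Bayesian posterior), and works with node *ages* measured backward from the
present: tips sit at age 0 and the crown node at the crown age.

Parsing and serialisation are delegated to :mod:`dendropy`; this module
adds validation (ultrametricity, binary-ness, unique labels), the shared
time-direction convention, and the derived vectors (branching times,
branch lengths) the diversification statistics are built on.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass
from typing import Iterable

import dendropy
import numpy as np

__all__ = [
    "TreeError",
    "Chronogram",
    "TreeSample",
    "BranchingTimes",
    "read_trees",
    "write_trees",
    "branching_times",
    "branch_lengths",
    "drop_taxa",
    "DEFAULT_ULTRAMETRICITY_RTOL",
]

#: Relative tolerance (fraction of root depth) for the ultrametricity check.
#: Dating software prints rounded decimals, so exact equality is never met.
DEFAULT_ULTRAMETRICITY_RTOL = 1e-6


class TreeError(ValueError):
    """Raised for invalid trees (non-ultrametric, polytomies, bad labels...)."""


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------


@dataclass
class Chronogram:
    """A validated rooted binary ultrametric tree with ages in Ma.

    Wraps a :class:`dendropy.Tree`.  Use :meth:`from_dendropy` /
    :meth:`from_newick` so the invariants (unique tip labels, >= 3 tips,
    non-negative branch lengths, binary nodes, ultrametricity within
    tolerance) are checked on construction.
    """

    tree: dendropy.Tree
    ultrametricity_rtol: float = DEFAULT_ULTRAMETRICITY_RTOL

    # -- construction -------------------------------------------------------

    @classmethod
    def from_dendropy(
        cls,
        tree: dendropy.Tree,
        *,
        rtol: float = DEFAULT_ULTRAMETRICITY_RTOL,
        resolve_polytomies: bool = False,
        seed: int | None = None,
        require_ultrametric: bool = True,
    ) -> "Chronogram":
        tree = tree.clone(depth=1)
        if resolve_polytomies:
            _resolve_polytomies(tree, seed=seed)
        obj = cls(tree=tree, ultrametricity_rtol=rtol)
        obj.validate(require_ultrametric=require_ultrametric)
        return obj

    @classmethod
    def from_newick(
        cls,
        newick: str,
        *,
        rtol: float = DEFAULT_ULTRAMETRICITY_RTOL,
        resolve_polytomies: bool = False,
        seed: int | None = None,
        require_ultrametric: bool = True,
    ) -> "Chronogram":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except dendropy.utility.error.DataParseError as exc:
            raise TreeError(
                f"unparseable newick (non-unique labels or bad syntax): {exc}"
            ) from exc
        return cls.from_dendropy(
            tree,
            rtol=rtol,
            resolve_polytomies=resolve_polytomies,
            seed=seed,
            require_ultrametric=require_ultrametric,
        )

    # -- basic properties ----------------------------------------------------

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def crown_age(self) -> float:
        """Root depth, i.e. the maximum root-to-tip path length in Ma."""
        return max(self._node_depths().values())

    # -- validation ----------------------------------------------------------

    def validate(self, *, require_ultrametric: bool = True) -> None:
        labels = []
        for leaf in self.tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise TreeError("tree has an unlabeled tip")
            labels.append(leaf.taxon.label)
        if len(set(labels)) != len(labels):
            raise TreeError("tip labels are not unique")
        if len(labels) < 3:
            raise TreeError(f"need >= 3 tips, got {len(labels)}")
        for node in self.tree.preorder_node_iter():
            nch = len(node.child_nodes())
            if nch not in (0, 2):
                raise TreeError(
                    "tree is not strictly binary (polytomy or unifurcation); "
                    "use resolve_polytomies=True to randomly resolve"
                )
            if node.parent_node is not None:
                if node.edge.length is None:
                    raise TreeError("missing branch length")
                if node.edge.length < 0:
                    raise TreeError(f"negative branch length {node.edge.length}")
        if require_ultrametric and not self.is_ultrametric():
            raise TreeError(
                "tree is not ultrametric within tolerance "
                f"(rtol={self.ultrametricity_rtol})"
            )

    def is_ultrametric(self, rtol: float | None = None) -> bool:
        rtol = self.ultrametricity_rtol if rtol is None else rtol
        depths = [
            d for node, d in self._node_depths().items() if node.is_leaf()
        ]
        depth = max(depths)
        if depth == 0:
            return False
        return (depth - min(depths)) <= rtol * depth

    # -- derived quantities --------------------------------------------------

    def _node_depths(self) -> dict[dendropy.Node, float]:
        depths: dict[dendropy.Node, float] = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                depths[node] = 0.0
            else:
                depths[node] = depths[node.parent_node] + node.edge.length
        return depths

    def node_ages(self) -> dict[dendropy.Node, float]:
        """Age (Ma before present) of every node; tips clamped to >= 0."""
        depths = self._node_depths()
        present = max(d for n, d in depths.items() if n.is_leaf())
        return {n: max(present - d, 0.0) for n, d in depths.items()}

    # -- serialisation -------------------------------------------------------

    def as_newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()


@dataclass
class TreeSample:
    """An ordered collection of chronograms with a shared tip set."""

    trees: list[Chronogram]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.trees:
            raise TreeError("empty tree sample")
        ref = frozenset(self.trees[0].tip_labels)
        for i, t in enumerate(self.trees):
            if frozenset(t.tip_labels) != ref:
                raise TreeError(
                    f"tree {i} tip set differs from the first tree's tip set"
                )

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)


@dataclass
class BranchingTimes:
    """Ages of the n-1 internal nodes of an n-tip chronogram, descending.

    ``ages[0]`` is the crown age; internode interval g_k (the span during
    which exactly k lineages exist, k = 2..n) is ``ages[k-2] - ages[k-1]``
    with age 0 appended for the present.
    """

    ages: np.ndarray
    n: int
    crown_age: float

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        if len(self.ages) != self.n - 1:
            raise TreeError(
                f"expected {self.n - 1} node ages for {self.n} tips, "
                f"got {len(self.ages)}"
            )
        if np.any(np.diff(self.ages) > 0):
            raise TreeError("node ages must be sorted descending")
        if np.any(self.ages < 0) or np.any(self.ages > self.crown_age * (1 + 1e-12)):
            raise TreeError("node ages must lie within [0, crown_age]")

    def internode_intervals(self) -> np.ndarray:
        """g_k for k = 2..n (length n-1); g_n ends at the present."""
        bounds = np.concatenate([self.ages, [0.0]])
        return -np.diff(bounds)

    def total_weighted_length(self) -> float:
        """T = sum_k k * g_k, the total lineage-time below the crown node."""
        k = np.arange(2, self.n + 1, dtype=float)
        return float(np.sum(k * self.internode_intervals()))


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------


def read_trees(
    path: str,
    format: str = "newick",
    *,
    rtol: float = DEFAULT_ULTRAMETRICITY_RTOL,
    resolve_polytomies: bool = False,
    seed: int | None = None,
    require_same_taxa: bool = True,
    require_ultrametric: bool = True,
) -> TreeSample:
    """Read one or more chronograms from a Newick or NEXUS file.

    Parameters
    ----------
    format:
        ``"newick"`` or ``"nexus"``.
    require_same_taxa:
        If True (the default), all trees must share a tip-label set, as a
        posterior sample must.
    """
    if format not in ("newick", "nexus"):
        raise ValueError(f"unsupported format {format!r}")
    tl = dendropy.TreeList.get(path=path, schema=format, preserve_underscores=True)
    if len(tl) == 0:
        raise TreeError(f"no trees found in {path}")
    trees = [
        Chronogram.from_dendropy(
            t,
            rtol=rtol,
            resolve_polytomies=resolve_polytomies,
            seed=seed,
            require_ultrametric=require_ultrametric,
        )
        for t in tl
    ]
    if not require_same_taxa and len(trees) > 1:
        # bypass the shared-tip-set check of TreeSample
        sample = TreeSample.__new__(TreeSample)
        sample.trees = trees
        sample.source = path
        return sample
    return TreeSample(trees=trees, source=path)


def write_trees(sample: TreeSample | Chronogram, path: str, format: str = "newick") -> None:
    """Write chronogram(s) to Newick or NEXUS."""
    if isinstance(sample, Chronogram):
        trees = [sample]
    elif isinstance(sample, TreeSample):
        trees = sample.trees
    else:
        raise TypeError("write_trees expects a Chronogram or TreeSample")
    tl = dendropy.TreeList()
    for c in trees:
        t = c.tree.clone(depth=1)
        t.migrate_taxon_namespace(tl.taxon_namespace)
        tl.append(t)
    tl.write(path=path, schema=format, suppress_rooting=True, unquoted_underscores=True)


# small wrapper kept simple: most callers write a single tree
def write_tree(chrono: Chronogram, path: str, format: str = "newick") -> None:
    chrono.tree.write(
        path=path, schema=format, suppress_rooting=True, unquoted_underscores=True
    )


# ---------------------------------------------------------------------------
# derived vectors
# ---------------------------------------------------------------------------


def branching_times(chrono: Chronogram) -> BranchingTimes:
    """Extract the n-1 internal-node ages, sorted descending (crown first).

    Ages are measured backward from the present (tips at age 0).  Ties are
    kept in in-file node order; the gamma statistic depends only on the
    multiset of ages, so tie order is immaterial downstream.
    """
    if not chrono.is_ultrametric():
        raise TreeError("branching times require an ultrametric tree")
    ages = chrono.node_ages()
    internal = [a for n, a in ages.items() if not n.is_leaf()]
    arr = np.array(sorted(internal, reverse=True), dtype=float)
    n = chrono.n_tips
    return BranchingTimes(ages=arr, n=n, crown_age=float(arr[0]))


def branch_lengths(chrono: Chronogram, include_root_edge: bool = False) -> np.ndarray:
    """All edge lengths in Ma; 2n-2 values (root edge excluded by default)."""
    out = []
    for node in chrono.tree.preorder_node_iter():
        if node.parent_node is None:
            if include_root_edge and node.edge.length:
                out.append(float(node.edge.length))
            continue
        out.append(float(node.edge.length))
    return np.asarray(out, dtype=float)


def drop_taxa(chrono: Chronogram, labels: Iterable[str]) -> Chronogram:
    """Prune the given tips (e.g. outgroups) and return a new chronogram."""
    drop = set(labels)
    keep = [t for t in chrono.tip_labels if t not in drop]
    missing = drop - set(chrono.tip_labels)
    if missing:
        warnings.warn(f"drop-list taxa not in tree: {sorted(missing)}")
    if len(keep) < 3:
        raise TreeError("fewer than 3 tips would remain after pruning")
    taxa = [
        t for t in chrono.tree.taxon_namespace if t.label in set(keep)
    ]
    pruned = chrono.tree.extract_tree_with_taxa(taxa=taxa)
    pruned = dendropy.Tree.get(
        data=pruned.as_string(schema="newick"), schema="newick",
        preserve_underscores=True,
    )
    _collapse_root_unifurcation(pruned)
    return Chronogram.from_dendropy(pruned, rtol=chrono.ultrametricity_rtol)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _collapse_root_unifurcation(tree: dendropy.Tree) -> None:
    """Re-seed the tree at the first bifurcation, absorbing root edges."""
    while len(tree.seed_node.child_nodes()) == 1:
        child = tree.seed_node.child_nodes()[0]
        child.parent_node = None
        child.edge.length = None
        tree.seed_node = child


def _resolve_polytomies(tree: dendropy.Tree, seed: int | None = None) -> None:
    poly = any(
        len(n.child_nodes()) > 2 for n in tree.preorder_node_iter()
    )
    if poly:
        warnings.warn("randomly resolving polytomies with zero-length edges")
        tree.resolve_polytomies(rng=random.Random(seed))
        for node in tree.preorder_node_iter():
            if node.parent_node is not None and node.edge.length is None:
                node.edge.length = 0.0
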