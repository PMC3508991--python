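"""Event-cost dispersal-vicariance ancestral-range reconstruction.

Classic DIVA parsimony: ancestral ranges are subsets of a fixed area set;
at a speciation node a single-area range is inherited by both daughters
(duplication, cost 0) while a widespread range splits into two nonempty
disjoint subsets covering it (vicariance, cost 0); along a branch each
area gained costs 1 dispersal event and each area lost costs 1 local-
extinction event.  Ancestral ranges are capped at ``max_areas`` (two in
the default configuration); terminal ranges are exempt, as is usual in
S-DIVA practice.

The reconstruction is exact: a bottom-up dynamic program over the allowed
range states (for 8 areas and max two, C(8,1)+C(8,2)=36 states) with a
top-down pass that yields, for every internal node, every range occurring
in at least one minimum-cost full reconstruction together with its
multiplicity (the number of optimal reconstructions containing it).

S-DIVA averages these per-node solutions over a tree sample (e.g. a
Bayesian posterior): for each clade of a reference tree, the optimal
ranges of the matching node in every sample tree containing that clade
are accumulated — each tree contributing unit mass split across its
optimal ranges — and normalised into relative probabilities, alongside
the fraction of trees containing the clade.

Our branch/node cost factorisation (transition cost = symmetric
difference along branches, free duplication/vicariance at nodes) is
equivalent to the classical single-step DIVA optimisation on binary
trees; the brute-force oracle in the test suite pins these semantics.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .treeio import Chronogram, TreeSample

__all__ = [
    "RangeAssignmentError",
    "DivaReconstruction",
    "SDivaSummary",
    "validate_ranges",
    "read_range_table",
    "write_range_table",
    "diva_optimize",
    "sdiva_summarize",
]

DEFAULT_AREAS = ("A", "B", "C", "D", "E", "F", "G", "H")


class RangeAssignmentError(ValueError):
    """Raised for invalid taxon -> area-set tables."""


# ---------------------------------------------------------------------------
# range tables
# ---------------------------------------------------------------------------


def validate_ranges(
    ranges: Mapping[str, Iterable[str]],
    areas: Sequence[str] = DEFAULT_AREAS,
    tips: Iterable[str] | None = None,
) -> dict[str, frozenset[str]]:
    """Normalise and validate a taxon -> area-set mapping."""
    area_set = set(areas)
    out: dict[str, frozenset[str]] = {}
    for taxon, r in ranges.items():
        fs = frozenset(r)
        if not fs:
            raise RangeAssignmentError(f"empty range for taxon {taxon!r}")
        bad = fs - area_set
        if bad:
            raise RangeAssignmentError(
                f"taxon {taxon!r} has areas outside the area set: {sorted(bad)}"
            )
        out[taxon] = fs
    if tips is not None:
        missing = set(tips) - set(out)
        if missing:
            raise RangeAssignmentError(
                f"tips without a range assignment: {sorted(missing)}"
            )
    return out


def read_range_table(path: str, areas: Sequence[str] = DEFAULT_AREAS) -> dict[str, frozenset[str]]:
    """Read a TSV of ``taxon<TAB>areas`` with areas as concatenated letters
    (e.g. ``CE`` = areas C and E)."""
    out: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise RangeAssignmentError(f"malformed range line: {line!r}")
            taxon, letters = parts
            if taxon in out:
                raise RangeAssignmentError(f"duplicate taxon {taxon!r}")
            out[taxon] = frozenset(letters)
    return validate_ranges(out, areas=areas)


def write_range_table(ranges: Mapping[str, frozenset[str]], path: str) -> None:
    with open(path, "w") as fh:
        for taxon in sorted(ranges):
            fh.write(f"{taxon}\t{''.join(sorted(ranges[taxon]))}\n")


# ---------------------------------------------------------------------------
# DIVA dynamic program
# ---------------------------------------------------------------------------


@dataclass
class DivaReconstruction:
    """Exact DIVA solution for one tree.

    ``node_ranges`` maps each internal node's clade (frozenset of tip
    labels) to a dict of optimal ancestral ranges -> multiplicity (the
    number of minimum-cost full reconstructions containing that range at
    that node).  ``min_cost`` is the total dispersal+extinction count of
    an optimal reconstruction.
    """

    node_ranges: dict[frozenset, dict[frozenset, float]]
    min_cost: float
    root_clade: frozenset


class _DivaMachine:
    """Precomputed state space and cost tables for one (areas, max_areas)."""

    def __init__(self, areas: Sequence[str], max_areas: int,
                 extra_tip_masks: Iterable[int] = ()):
        self.areas = tuple(areas)
        na = len(areas)
        self.bit = {a: 1 << i for i, a in enumerate(areas)}
        internal = [
            m for m in range(1, 1 << na) if bin(m).count("1") <= max_areas
        ]
        extra = sorted(set(extra_tip_masks) - set(internal))
        self.states = internal + extra          # internal states first
        self.n_internal = len(internal)
        self.index = {m: i for i, m in enumerate(self.states)}
        ns = len(self.states)
        sm = np.array(self.states)
        # transition (branch) cost: popcount of symmetric difference
        xor = sm[:, None] ^ sm[None, :]
        self.tc = np.vectorize(lambda v: bin(v).count("1"))(xor).astype(float)
        # node cost: NC[r, c1, c2] = min over splits (d1, d2) of R of
        # tc[d1, c1] + tc[d2, c2]
        self.nc = np.full((self.n_internal, ns, ns), np.inf)
        for ri in range(self.n_internal):
            r = self.states[ri]
            for d1, d2 in self._splits(r):
                i1, i2 = self.index[d1], self.index[d2]
                cand = self.tc[i1][:, None] + self.tc[i2][None, :]
                np.minimum(self.nc[ri], cand, out=self.nc[ri])

    def _splits(self, r: int):
        """Allowed daughter-range pairs at a node with range r."""
        bits = [b for b in (1 << i for i in range(len(self.areas))) if r & b]
        if len(bits) == 1:
            yield r, r                     # duplication within a single area
            return
        # vicariance: disjoint nonempty subsets covering r (ordered pairs)
        for size in range(1, len(bits)):
            for combo in combinations(bits, size):
                d1 = 0
                for b in combo:
                    d1 |= b
                yield d1, r ^ d1

    def mask(self, rng: frozenset[str]) -> int:
        m = 0
        for a in rng:
            m |= self.bit[a]
        return m

    def unmask(self, m: int) -> frozenset[str]:
        return frozenset(a for a in self.areas if m & self.bit[a])


def diva_optimize(
    tree: Chronogram | dendropy.Tree,
    ranges: Mapping[str, Iterable[str]],
    max_areas: int = 2,
    areas: Sequence[str] | None = None,
) -> DivaReconstruction:
    """Exact minimum-cost DIVA reconstruction on one binary rooted tree.

    Only the topology matters (event costs ignore branch lengths).  The
    returned multiplicities count, for every internal node and range, the
    optimal full reconstructions (assignments of ranges to all internal
    nodes) in which that node carries that range.
    """
    dtree = tree.tree if isinstance(tree, Chronogram) else tree
    tips = [l.taxon.label for l in dtree.leaf_node_iter()]
    missing = set(tips) - set(ranges)
    if missing:
        raise RangeAssignmentError(
            f"tips without a range assignment: {sorted(missing)}"
        )
    if areas is None:
        used = sorted(set().union(*(frozenset(ranges[t]) for t in tips)))
        areas = tuple(used)
    ranges = validate_ranges(ranges, areas=areas, tips=tips)

    machine = _DivaMachine(
        areas, max_areas,
        extra_tip_masks=[_mask_of(ranges[t], areas) for t in tips],
    )
    ni, ns = machine.n_internal, len(machine.states)

    up_cost: dict[dendropy.Node, np.ndarray] = {}
    up_cnt: dict[dendropy.Node, np.ndarray] = {}
    clades: dict[dendropy.Node, frozenset] = {}

    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            clades[node] = frozenset([node.taxon.label])
            cost = np.full(ns, np.inf)
            cnt = np.zeros(ns)
            ti = machine.index[machine.mask(ranges[node.taxon.label])]
            cost[ti] = 0.0
            cnt[ti] = 1.0
            up_cost[node] = cost
            up_cnt[node] = cnt
            continue
        ch = node.child_nodes()
        if len(ch) != 2:
            raise ValueError("DIVA requires a strictly binary rooted tree")
        x, y = ch
        clades[node] = clades[x] | clades[y]
        # A[r, c1, c2] = nc[r, c1, c2] + up_x[c1] + up_y[c2]
        a = machine.nc + up_cost[x][None, :, None] + up_cost[y][None, None, :]
        flat = a.reshape(ni, -1)
        cost = flat.min(axis=1)
        cnt = np.zeros(ns)
        cxy = up_cnt[x][:, None] * up_cnt[y][None, :]
        for ri in range(ni):
            if not np.isfinite(cost[ri]):
                continue
            opt = np.isclose(a[ri], cost[ri])
            cnt[ri] = float(np.sum(cxy[opt]))
        full_cost = np.full(ns, np.inf)
        full_cost[:ni] = cost
        up_cost[node] = full_cost
        up_cnt[node] = cnt

    root = dtree.seed_node
    min_cost = float(np.min(up_cost[root][: machine.n_internal]))

    # top-down pass: down[v][c] = best cost of the rest of the tree given
    # node v carries state c (and the count of such partial optima)
    down_cost: dict[dendropy.Node, np.ndarray] = {
        root: np.concatenate([np.zeros(ni), np.full(ns - ni, np.inf)])
    }
    down_cnt: dict[dendropy.Node, np.ndarray] = {
        root: np.concatenate([np.ones(ni), np.zeros(ns - ni)])
    }
    node_ranges: dict[frozenset, dict[frozenset, float]] = {}

    for node in dtree.preorder_node_iter():
        if node.is_leaf():
            continue
        x, y = node.child_nodes()
        # marginal multiplicities at this node
        tot = down_cost[node] + up_cost[node]
        opt = np.isclose(tot, min_cost)
        marg = {}
        for ri in np.nonzero(opt)[0]:
            mult = down_cnt[node][ri] * up_cnt[node][ri]
            if mult > 0:
                marg[machine.unmask(machine.states[ri])] = float(mult)
        node_ranges[clades[node]] = marg
        # push down to children
        for child, sib in ((x, y), (y, x)):
            if child.is_leaf():
                continue
            # cost for child state c: min over parent state r, sib state cs
            # careful with argument order of nc: nc[r, c_x, c_y]
            if child is x:
                a = (
                    machine.nc
                    + down_cost[node][: ni][:, None, None]
                    + up_cost[sib][None, None, :]
                )  # shape (ni, ns(child), ns(sib))
                red_axis = (0, 2)
                cnt_outer = down_cnt[node][:ni][:, None, None] * up_cnt[sib][None, None, :]
            else:
                a = (
                    machine.nc
                    + down_cost[node][: ni][:, None, None]
                    + up_cost[sib][None, :, None]
                )  # shape (ni, ns(sib), ns(child))
                red_axis = (0, 1)
                cnt_outer = down_cnt[node][:ni][:, None, None] * up_cnt[sib][None, :, None]
            c_cost = a.min(axis=red_axis)
            c_cnt = np.zeros(ns)
            for ci in range(ns):
                if not np.isfinite(c_cost[ci]):
                    continue
                if child is x:
                    sl = a[:, ci, :]
                    co = cnt_outer[:, 0, :]
                else:
                    sl = a[:, :, ci]
                    co = cnt_outer[:, :, 0]
                optm = np.isclose(sl, c_cost[ci])
                c_cnt[ci] = float(np.sum(co[optm]))
            down_cost[child] = c_cost
            down_cnt[child] = c_cnt

    return DivaReconstruction(
        node_ranges=node_ranges, min_cost=min_cost, root_clade=clades[root]
    )


def _mask_of(rng: frozenset[str], areas: Sequence[str]) -> int:
    m = 0
    for i, a in enumerate(areas):
        if a in rng:
            m |= 1 << i
    return m


# ---------------------------------------------------------------------------
# S-DIVA averaging over a tree sample
# ---------------------------------------------------------------------------


@dataclass
class SDivaSummary:
    """Per-clade relative probabilities of ancestral ranges over a sample.

    ``clade_probs`` maps each internal clade (frozenset of tip labels) of
    the reference tree to a dict range -> probability summing to 1;
    ``clade_support`` gives the fraction of sample trees containing the
    clade.  Clades absent from every sample tree get support 0 and no
    probabilities.
    """

    clade_probs: dict[frozenset, dict[frozenset, float]]
    clade_support: dict[frozenset, float]
    n_trees: int
    weighting: str


def sdiva_summarize(
    sample: TreeSample,
    ranges: Mapping[str, Iterable[str]],
    max_areas: int = 2,
    reference: Chronogram | None = None,
    weighting: str = "multiplicity",
    areas: Sequence[str] | None = None,
) -> SDivaSummary:
    """S-DIVA: average per-node DIVA solutions over a tree sample.

    For each internal clade of the reference tree (default: the first
    tree of the sample), every sample tree containing that exact clade
    contributes one unit of mass, split across the clade's optimal ranges
    in that tree — proportionally to reconstruction multiplicity
    (``weighting="multiplicity"``) or equally (``weighting="uniform"``,
    since published S-DIVA versions differ here) — and the accumulated
    mass is normalised into relative probabilities.
    """
    if weighting not in ("multiplicity", "uniform"):
        raise ValueError("weighting must be 'multiplicity' or 'uniform'")
    if reference is None:
        reference = sample.trees[0]
    if frozenset(reference.tip_labels) != frozenset(sample.trees[0].tip_labels):
        raise ValueError("reference and sample must share a tip set")

    ref_clades = [
        frozenset(l.taxon.label for l in node.leaf_iter())
        for node in reference.tree.preorder_internal_node_iter()
    ]
    acc: dict[frozenset, dict[frozenset, float]] = {c: {} for c in ref_clades}
    containing: dict[frozenset, int] = {c: 0 for c in ref_clades}

    for chrono in sample:
        recon = diva_optimize(chrono, ranges, max_areas=max_areas, areas=areas)
        for clade in ref_clades:
            sol = recon.node_ranges.get(clade)
            if not sol:
                continue
            containing[clade] += 1
            if weighting == "multiplicity":
                tot = sum(sol.values())
                shares = {r: m / tot for r, m in sol.items()}
            else:
                shares = {r: 1.0 / len(sol) for r in sol}
            slot = acc[clade]
            for r, s in shares.items():
                slot[r] = slot.get(r, 0.0) + s

    probs: dict[frozenset, dict[frozenset, float]] = {}
    support: dict[frozenset, float] = {}
    for clade in ref_clades:
        m = containing[clade]
        support[clade] = m / len(sample)
        probs[clade] = (
            {r: v / m for r, v in acc[clade].items()} if m else {}
        )
    return SDivaSummary(
        clade_probs=probs,
        clade_support=support,
        n_trees=len(sample),
        weighting=weighting,
    )
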