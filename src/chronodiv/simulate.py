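"""Synthetic chronograms, posterior-like tree samples and range histories.

Every analysis stage in this package is tested against data with known
ground truth.  This module generates it:

* ultrametric crown-group chronograms under a constant-rate pure-birth
  (Yule) process, a two-rate pure-birth process with one global rate shift,
  or a constant birth-death process, conditioned on a fixed number of
  extant tips;
* random pruning of tips to a stated sampling fraction (the incomplete-
  sampling scenario the MCCR test corrects for);
* posterior-like tree samples obtained by jittering node ages (and
  optionally perturbing the topology) of a base tree;
* geographic-range evolution along the branches of a tree by
  continuous-time area gain (dispersal) and loss (local extinction).

Conventions
-----------
Pure-birth trees conditioned on ``n`` tips are generated through their
internode intervals: with ``k`` lineages the waiting time is exponential
with hazard ``k * lambda(age)``, for ``k = 2..n`` *including* the final,
right-censored interval from the last divergence to the present
(equivalently: grow until the (n+1)-th birth and cut at that event).
This is the construction under which the gamma statistic's null has mean
0 and unit variance.  The two-rate model draws the same intervals backward
from the present with a piecewise hazard (rate ``lambda2`` at ages younger
than the shift, ``lambda1`` older), which is exactly the process the
two-rate likelihood downstream describes.

All randomness flows from a single root seed through
:class:`numpy.random.SeedSequence` child streams, so identical configs
produce bit-identical serialised trees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np

from .treeio import BranchingTimes, Chronogram, TreeSample

__all__ = [
    "SimConfig",
    "AreaSimConfig",
    "SimulationError",
    "SimulatedTree",
    "simulate_tree",
    "prune_to_sample",
    "simulate_tree_sample",
    "simulate_ranges",
    "RangeSimulation",
]

DEFAULT_AREAS = ("A", "B", "C", "D", "E", "F", "G", "H")

MAX_RETRIES = 10_000


class SimulationError(RuntimeError):
    """Raised when a conditioned simulation cannot be realised."""


@dataclass
class SimConfig:
    """Parameters of the tree simulator.

    ``model`` is one of ``yule1`` (constant-rate pure birth), ``yule2``
    (pure birth with a single global rate shift from ``lambda1`` to
    ``lambda2`` at ``shift_time`` Ma before present) or ``birthdeath``
    (constant speciation ``lambda1`` and extinction ``mu``).  ``n_total``
    is the number of extant species the clade is conditioned to contain
    (~70 for the study system); ``sample_n`` the number retained after
    uniform pruning (65 sampled species, >90% coverage).
    """

    model: str = "yule1"
    lambda1: float = 0.2
    lambda2: float | None = None
    mu: float | None = None
    shift_time: float | None = None
    n_total: int = 70
    sample_n: int | None = None   # e.g. 65 of ~70 described species
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("yule1", "yule2", "birthdeath"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.lambda1 <= 0:
            raise ValueError("lambda1 must be > 0")
        if self.model == "yule2":
            if self.lambda2 is None or self.lambda2 <= 0:
                raise ValueError("yule2 requires lambda2 > 0")
            if self.shift_time is None or self.shift_time <= 0:
                raise ValueError("yule2 requires shift_time > 0")
        if self.model == "birthdeath":
            if self.mu is None or self.mu < 0:
                raise ValueError("birthdeath requires mu >= 0")
        if self.n_total < 3:
            raise ValueError("n_total must be >= 3")
        if self.sample_n is not None and self.sample_n > self.n_total:
            raise ValueError("sample_n must be <= n_total")


@dataclass
class AreaSimConfig:
    """Parameters of the range-evolution simulator.

    ``dispersal_rate`` and ``extinction_rate`` are total per-lineage event
    rates (events/lineage/Ma); on an event the gained/lost area is drawn
    uniformly.  A lineage's range never empties (the last area is
    loss-protected) and never exceeds ``max_range_size``.
    """

    areas: tuple[str, ...] = DEFAULT_AREAS
    root_range: frozenset[str] = frozenset({"E"})
    dispersal_rate: float = 0.05
    extinction_rate: float = 0.05
    max_range_size: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        self.root_range = frozenset(self.root_range)
        if not self.root_range:
            raise ValueError("root_range must be nonempty")
        if not self.root_range <= set(self.areas):
            raise ValueError("root_range must be a subset of areas")
        if self.dispersal_rate < 0 or self.extinction_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.max_range_size < 1:
            raise ValueError("max_range_size must be >= 1")


@dataclass
class SimulatedTree:
    """A simulated chronogram plus its ground truth."""

    chronogram: Chronogram
    node_ages: np.ndarray          # descending, crown first (ground truth)
    params: dict = field(default_factory=dict)

    def branching_times(self) -> BranchingTimes:
        return BranchingTimes(
            ages=self.node_ages,
            n=self.chronogram.n_tips,
            crown_age=float(self.node_ages[0]),
        )


# ---------------------------------------------------------------------------
# internode-interval sampling
# ---------------------------------------------------------------------------


def _yule1_ages(n: int, lam: float, rng: np.random.Generator) -> np.ndarray:
    """Node ages of an n-tip constant-rate pure-birth tree.

    g_k ~ Exp(k*lam) for k = 2..n; ages accumulate backward from the
    present (the final interval g_n separates the youngest divergence from
    the present).
    """
    k = np.arange(2, n + 1)
    g = rng.exponential(1.0 / (k * lam))
    # backward from the present: youngest node at g_n, next at g_n+g_{n-1},
    # ..., crown at g_2+...+g_n
    ages = np.cumsum(g[::-1])
    return ages[::-1].copy()  # descending: crown first


def _yule2_ages(
    n: int, lam1: float, lam2: float, shift: float, rng: np.random.Generator
) -> np.ndarray:
    """Node ages under a single global rate shift at `shift` Ma.

    Intervals are drawn backward from the present with piecewise hazard
    k*lambda(age): lambda2 at ages < shift, lambda1 at ages >= shift.
    Retries until the crown age exceeds the shift age.
    """
    for _ in range(MAX_RETRIES):
        ages = np.empty(n - 1)
        a = 0.0
        for i, k in enumerate(range(n, 1, -1)):  # k = n .. 2
            e = rng.exponential(1.0)
            if a < shift:
                h2 = k * lam2 * (shift - a)
                if e <= h2:
                    a += e / (k * lam2)
                else:
                    a = shift + (e - h2) / (k * lam1)
            else:
                a += e / (k * lam1)
            ages[i] = a
        if ages[-1] > shift:  # crown older than the shift
            return ages[::-1].copy()
    raise SimulationError(
        f"crown age never exceeded shift_time={shift} after {MAX_RETRIES} tries"
    )


def _topology_from_ages(
    ages_desc: np.ndarray, labels: Sequence[str], rng: np.random.Generator
) -> Chronogram:
    """Random-join topology over the given node ages (Yule/coalescent shape)."""
    n = len(ages_desc) + 1
    ns = dendropy.TaxonNamespace()
    lineages: list[tuple[dendropy.Node, float]] = []
    for lab in labels:
        taxon = dendropy.Taxon(label=lab)
        ns.add_taxon(taxon)
        node = dendropy.Node(taxon=taxon)
        lineages.append((node, 0.0))
    for age in ages_desc[::-1]:  # youngest first
        i, j = rng.choice(len(lineages), size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        (na, aa) = lineages[i]
        (nb, ab) = lineages[j]
        parent = dendropy.Node()
        parent.add_child(na)
        na.edge.length = age - aa
        parent.add_child(nb)
        nb.edge.length = age - ab
        lineages[i] = (parent, float(age))
        del lineages[j]
    root, _ = lineages[0]
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=root)
    return Chronogram.from_dendropy(tree)


# ---------------------------------------------------------------------------
# birth-death forward simulation
# ---------------------------------------------------------------------------


class _BDLineage:
    __slots__ = ("parent", "birth", "end", "children", "node")

    def __init__(self, parent, birth):
        self.parent = parent
        self.birth = birth
        self.end = None
        self.children = []


def _simulate_birthdeath(
    n_total: int, lam: float, mu: float, rng: np.random.Generator
) -> np.ndarray | None:
    """One forward birth-death history conditioned on n_total survivors.

    Starts from two crown lineages; stops at the first event time after
    the extant count reaches n_total (so the final interval is fully
    elapsed, matching the pure-birth construction when mu = 0).  Returns
    the reconstructed (extinct-pruned) tree or None if the clade died.
    """
    root = _BDLineage(None, 0.0)
    c1, c2 = _BDLineage(root, 0.0), _BDLineage(root, 0.0)
    root.children = [c1, c2]
    root.end = 0.0
    extant = [c1, c2]
    t = 0.0
    total = lam + mu
    max_events = 200 * n_total + 1000
    for _ in range(max_events):
        k = len(extant)
        if k == 0:
            return None
        dt = rng.exponential(1.0 / (k * total))
        t += dt
        if k == n_total:
            present = t  # cut at the moment of the next (uncommitted) event
            return _reconstruct_bd(root, extant, present)
        idx = int(rng.integers(k))
        lin = extant[idx]
        if rng.random() < lam / total:
            lin.end = t
            a, b = _BDLineage(lin, t), _BDLineage(lin, t)
            lin.children = [a, b]
            extant[idx] = a
            extant.append(b)
        else:
            lin.end = t
            extant.pop(idx)
    return None


def _reconstruct_bd(root: _BDLineage, extant: list, present: float):
    """Prune extinct lineages, returning the reconstructed-tree skeleton.

    A lineage that split at time ``end`` contributes an internal node at
    age ``present - end`` when at least two of its descendant lineages
    have extant descendants; unifurcations collapse (the edge spans the
    pruned segment automatically, since edges are derived from node ages).
    """
    for lin in extant:
        lin.end = present

    def build(lin: _BDLineage):
        if not lin.children:
            return ("LEAF", None, 0.0) if lin.end == present else None
        subs = [build(c) for c in lin.children]
        subs = [s for s in subs if s is not None]
        if not subs:
            return None
        if len(subs) == 1:
            return subs[0]
        return ("NODE", subs, present - lin.end)

    top = build(root)
    if top is None or top[0] == "LEAF":
        return None
    return top, present


def _bd_to_chronogram(top) -> tuple[Chronogram, np.ndarray]:
    """Materialise the reconstructed birth-death history as a Chronogram."""
    ns = dendropy.TaxonNamespace()
    ages: list[float] = []
    idx = [0]

    def mk(node) -> tuple[dendropy.Node, float]:
        kind, payload, age = node   # age = present - split time (0 at leaves)
        if kind == "LEAF":
            idx[0] += 1
            taxon = dendropy.Taxon(label=f"t{idx[0]}")
            ns.add_taxon(taxon)
            return dendropy.Node(taxon=taxon), 0.0
        ages.append(age)
        parent = dendropy.Node()
        for sub in payload:
            child, child_age = mk(sub)
            parent.add_child(child)
            child.edge.length = age - child_age
        return parent, age

    root_node, _root_age = mk(top)
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=root_node)
    chrono = Chronogram.from_dendropy(tree)
    return chrono, np.array(sorted(ages, reverse=True))


def simulate_tree(config: SimConfig) -> SimulatedTree:
    """Simulate one ultrametric chronogram conditioned on ``n_total`` tips.

    Returns the tree together with the true node ages and parameters, so
    tests can verify extraction code exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    n = config.n_total
    labels = [f"t{i + 1}" for i in range(n)]
    params = {
        "model": config.model,
        "lambda1": config.lambda1,
        "lambda2": config.lambda2,
        "mu": config.mu,
        "shift_time": config.shift_time,
        "n_total": n,
        "seed": config.seed,
    }
    if config.model == "yule1":
        ages = _yule1_ages(n, config.lambda1, rng)
        chrono = _topology_from_ages(ages, labels, rng)
    elif config.model == "yule2":
        ages = _yule2_ages(
            n, config.lambda1, config.lambda2, config.shift_time, rng
        )
        chrono = _topology_from_ages(ages, labels, rng)
    else:  # birthdeath
        result = None
        for _ in range(MAX_RETRIES):
            result = _simulate_birthdeath(n, config.lambda1, config.mu, rng)
            if result is not None:
                break
        if result is None:
            raise SimulationError(
                f"birth-death clade died before reaching {n} survivors "
                f"in {MAX_RETRIES} attempts"
            )
        top, _present = result
        chrono, ages = _bd_to_chronogram(top)
    params["crown_age"] = float(ages[0])
    return SimulatedTree(chronogram=chrono, node_ages=ages, params=params)


# ---------------------------------------------------------------------------
# pruning (incomplete sampling)
# ---------------------------------------------------------------------------


def prune_to_sample(chrono: Chronogram, sample_n: int, seed: int = 0) -> Chronogram:
    """Retain a uniformly random subset of ``sample_n`` tips.

    Models incomplete taxon sampling (e.g. 65 of ~70 described species).
    Degree-2 nodes created by pruning are suppressed, so the result is
    again a valid binary chronogram.
    """
    n = chrono.n_tips
    if sample_n > n:
        raise ValueError("sample_n exceeds tip count")
    if sample_n < 3:
        raise ValueError("sample_n must be >= 3")
    if sample_n == n:
        return Chronogram.from_dendropy(chrono.tree, rtol=chrono.ultrametricity_rtol)
    rng = np.random.default_rng(seed)
    labels = sorted(chrono.tip_labels)
    keep = set(rng.choice(labels, size=sample_n, replace=False).tolist())
    from .treeio import drop_taxa  # local import avoids cycle at module load

    return drop_taxa(chrono, [t for t in labels if t not in keep])


# ---------------------------------------------------------------------------
# posterior-like tree samples
# ---------------------------------------------------------------------------


def jitter_tree_sample(
    base: Chronogram,
    n_trees: int,
    jitter_sd: float = 0.05,
    nni_prob: float = 0.0,
    seed: int = 0,
) -> TreeSample:
    """Posterior-like replicates of ``base`` by node-age jitter.

    Each internal node age is multiplied by an independent mean-1
    lognormal factor with standard deviation ``jitter_sd``; parent-child
    age order is then restored top-down (child ages clamped to the parent
    age), which keeps every replicate ultrametric.  With ``nni_prob`` > 0,
    each internal edge is swapped with that probability (a nearest-
    neighbour interchange) before re-clamping.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + jitter_sd**2)) if jitter_sd > 0 else 0.0
    trees = []
    for _ in range(n_trees):
        t = base.tree.clone(depth=1)
        if nni_prob > 0:
            _random_nni(t, nni_prob, rng)
        # ages of the base tree
        chron = Chronogram.__new__(Chronogram)
        chron.tree = t
        chron.ultrametricity_rtol = base.ultrametricity_rtol
        ages = chron.node_ages()
        new_age: dict[dendropy.Node, float] = {}
        for node in t.preorder_node_iter():
            if node.is_leaf():
                new_age[node] = 0.0
                continue
            a = ages[node]
            if sigma > 0:
                a *= math.exp(rng.normal(-0.5 * sigma**2, sigma))
            if node.parent_node is not None:
                a = min(a, new_age[node.parent_node])
            new_age[node] = a
        for node in t.preorder_node_iter():
            if node.parent_node is not None:
                node.edge.length = new_age[node.parent_node] - new_age[node]
        trees.append(Chronogram.from_dendropy(t, rtol=base.ultrametricity_rtol))
    return TreeSample(trees=trees, source="jittered sample")


def _random_nni(tree: dendropy.Tree, prob: float, rng: np.random.Generator) -> None:
    """Swap a child of each eligible internal node with its sibling subtree."""
    internal = [
        n
        for n in tree.preorder_node_iter()
        if (not n.is_leaf()) and n.parent_node is not None
    ]
    for node in internal:
        if rng.random() >= prob:
            continue
        parent = node.parent_node
        sibs = [c for c in parent.child_nodes() if c is not node]
        if not sibs or node.is_leaf():
            continue
        sib = sibs[0]
        child = node.child_nodes()[int(rng.integers(len(node.child_nodes())))]
        # swap `child` and `sib`
        node.remove_child(child)
        parent.remove_child(sib)
        node.add_child(sib)
        parent.add_child(child)


def simulate_tree_sample(
    config: SimConfig,
    n_trees: int,
    jitter_sd: float = 0.05,
    nni_prob: float = 0.0,
) -> tuple[SimulatedTree, TreeSample]:
    """Simulate a base chronogram and a jittered posterior-like sample."""
    sim = simulate_tree(config)
    child_seed = int(np.random.SeedSequence(config.seed).spawn(2)[1].generate_state(1)[0] % (2**31))
    sample = jitter_tree_sample(
        sim.chronogram, n_trees, jitter_sd=jitter_sd, nni_prob=nni_prob,
        seed=child_seed,
    )
    return sim, sample


# ---------------------------------------------------------------------------
# range evolution
# ---------------------------------------------------------------------------


@dataclass
class RangeSimulation:
    """Tip ranges plus the true range at every internal node (by clade)."""

    tip_ranges: dict[str, frozenset[str]]
    node_ranges: dict[frozenset, frozenset[str]]   # clade tip-set -> true range
    root_range: frozenset[str]


def simulate_ranges(chrono: Chronogram, config: AreaSimConfig) -> RangeSimulation:
    """Evolve geographic ranges along the tree by area gain/loss events.

    Dispersal adds one uniformly chosen absent area (blocked at
    ``max_range_size``); local extinction removes one uniformly chosen
    present area (blocked when only one remains).  The range at every
    internal node is recorded as ground truth for reconstruction tests.
    """
    rng = np.random.default_rng(config.seed)
    areas = list(config.areas)

    def evolve(r: frozenset[str], duration: float) -> frozenset[str]:
        r = set(r)
        t = 0.0
        while True:
            gain = config.dispersal_rate if len(r) < config.max_range_size else 0.0
            loss = config.extinction_rate if len(r) > 1 else 0.0
            total = gain + loss
            if total <= 0:
                return frozenset(r)
            t += rng.exponential(1.0 / total)
            if t >= duration:
                return frozenset(r)
            if rng.random() < gain / total:
                absent = [a for a in areas if a not in r]
                r.add(absent[int(rng.integers(len(absent)))])
            else:
                present = sorted(r)
                r.discard(present[int(rng.integers(len(present)))])

    tip_ranges: dict[str, frozenset[str]] = {}
    node_ranges: dict[frozenset, frozenset[str]] = {}
    state: dict[dendropy.Node, frozenset[str]] = {}
    clades: dict[dendropy.Node, frozenset] = {}
    for node in chrono.tree.postorder_node_iter():
        if node.is_leaf():
            clades[node] = frozenset([node.taxon.label])
        else:
            clades[node] = frozenset().union(*(clades[c] for c in node.child_nodes()))
    for node in chrono.tree.preorder_node_iter():
        if node.parent_node is None:
            state[node] = frozenset(config.root_range)
        else:
            state[node] = evolve(state[node.parent_node], node.edge.length)
        if node.is_leaf():
            tip_ranges[node.taxon.label] = state[node]
        else:
            node_ranges[clades[node]] = state[node]
    return RangeSimulation(
        tip_ranges=tip_ranges,
        node_ranges=node_ranges,
        root_range=frozenset(config.root_range),
    )
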