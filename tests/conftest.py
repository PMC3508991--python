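import itertools

import numpy as np
import pytest

import chronodiv as cd


@pytest.fixture
def three_tip():
    """((A:1,B:1):1,C:2); — crown age 2, node ages [2, 1]."""
    return cd.Chronogram.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def comb5():
    """5-tip comb with equal internode intervals of 1 Ma (ages 4,3,2,1)."""
    nwk = "((((A:1,B:1):1,C:2):1,D:3):1,E:4);"
    return cd.Chronogram.from_newick(nwk)


@pytest.fixture
def yule_tree():
    return cd.simulate_tree(cd.SimConfig(model="yule1", lambda1=0.25, n_total=40, seed=11))


# ---------------------------------------------------------------------------
# independent oracles (coded separately from the package implementations)
# ---------------------------------------------------------------------------


def gamma_oracle(ages_desc):
    """Pybus-Harvey gamma via literal double-loop formula expansion."""
    ages = sorted(ages_desc, reverse=True)
    n = len(ages) + 1
    bounds = ages + [0.0]
    g = {k: bounds[k - 2] - bounds[k - 1] for k in range(2, n + 1)}
    T = sum(j * g[j] for j in range(2, n + 1))
    outer = 0.0
    for i in range(2, n):
        outer += sum(k * g[k] for k in range(2, i + 1))
    num = outer / (n - 2) - T / 2.0
    den = T * (1.0 / (12.0 * (n - 2))) ** 0.5
    return num / den


def yule_lnL_oracle(ages_desc, rate_of_age):
    """Pure-birth log-likelihood as a direct sum of exponential log-densities.

    ``rate_of_age(a)`` gives the per-lineage speciation rate at age ``a``;
    intervals crossing a rate change are scored piecewise by splitting at
    the discontinuity (caller passes breakpoints via closure or the rate
    function is constant).  The final interval is censored.
    """
    ages = sorted(ages_desc, reverse=True)
    n = len(ages) + 1
    bounds = ages + [0.0]
    lnL = 0.0
    for k in range(2, n + 1):
        hi, lo = bounds[k - 2], bounds[k - 1]
        # integrate hazard k*rate over [lo, hi] by fine trapezoid on the
        # piecewise-constant rate (midpoint sampling on a fine grid)
        m = 4000
        edges = np.linspace(lo, hi, m + 1)
        mids = (edges[:-1] + edges[1:]) / 2
        hazard_int = k * float(np.sum([rate_of_age(a) for a in mids]) * (hi - lo) / m)
        lnL -= hazard_int
        if k < n:  # observed event at age lo
            lnL += np.log(k * rate_of_age(lo))
    return lnL


def yule_lnL_oracle_exact(ages_desc, lam1, lam2, shift):
    """Exact two-rate pure-birth log-likelihood (piecewise closed form)."""
    ages = sorted(ages_desc, reverse=True)
    n = len(ages) + 1
    bounds = ages + [0.0]
    lnL = 0.0
    for k in range(2, n + 1):
        hi, lo = bounds[k - 2], bounds[k - 1]
        w1 = max(0.0, hi - max(lo, shift))
        w2 = (hi - lo) - w1
        lnL -= k * (lam1 * w1 + lam2 * w2)
        if k < n:
            lnL += np.log(k * (lam1 if lo >= shift else lam2))
    return lnL


def diva_bruteforce(dtree, tip_ranges, areas, max_areas):
    """Exhaustive-enumeration DIVA oracle.

    Enumerates every assignment of ranges (nonempty subsets of ``areas``
    of size <= max_areas) to the internal nodes; the cost of an
    assignment sums, over nodes, the cheapest split of the node's range
    into daughter starting ranges followed by per-branch symmetric-
    difference events.  Returns (min cost, {root range: multiplicity},
    per-node optimal range sets).
    """
    area_list = list(areas)
    na = len(area_list)
    bit = {a: 1 << i for i, a in enumerate(area_list)}
    states = [m for m in range(1, 1 << na) if bin(m).count("1") <= max_areas]

    def popcount(v):
        return bin(v).count("1")

    def splits(r):
        bits = [b for b in (1 << i for i in range(na)) if r & b]
        if len(bits) == 1:
            return [(r, r)]
        out = []
        for size in range(1, len(bits)):
            for combo in itertools.combinations(bits, size):
                d1 = 0
                for b in combo:
                    d1 |= b
                out.append((d1, r ^ d1))
        return out

    split_cache = {r: splits(r) for r in states}

    internals = [n for n in dtree.preorder_node_iter() if not n.is_leaf()]
    tips = {n: 0 for n in dtree.leaf_node_iter()}
    for n in tips:
        m = 0
        for a in tip_ranges[n.taxon.label]:
            m |= bit[a]
        tips[n] = m

    def node_cost(r, c1, c2):
        return min(
            popcount(d1 ^ c1) + popcount(d2 ^ c2) for d1, d2 in split_cache[r]
        )

    best_cost = None
    root_mult = {}
    node_opt = {id(n): {} for n in internals}
    for assign in itertools.product(states, repeat=len(internals)):
        amap = {id(n): s for n, s in zip(internals, assign)}
        cost = 0
        for n, s in zip(internals, assign):
            c1, c2 = n.child_nodes()
            m1 = tips[c1] if c1.is_leaf() else amap[id(c1)]
            m2 = tips[c2] if c2.is_leaf() else amap[id(c2)]
            cost += node_cost(s, m1, m2)
        if best_cost is None or cost < best_cost:
            best_cost = cost
            root_mult = {}
            node_opt = {id(n): {} for n in internals}
        if cost == best_cost:
            r = assign[internals.index(dtree.seed_node)]
            root_mult[r] = root_mult.get(r, 0) + 1
            for n, s in zip(internals, assign):
                node_opt[id(n)][s] = node_opt[id(n)].get(s, 0) + 1

    def unmask(m):
        return frozenset(a for a in area_list if m & bit[a])

    per_node = {}
    for n in internals:
        clade = frozenset(l.taxon.label for l in n.leaf_iter())
        per_node[clade] = {unmask(s): c for s, c in node_opt[id(n)].items()}
    return best_cost, {unmask(r): c for r, c in root_mult.items()}, per_node
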