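"""Tree-shape diversification statistics and diagnostics.

Implements the constant-rate (CR) test through the Pybus-Harvey gamma
statistic, its Monte-Carlo correction for incomplete taxon sampling (the
MCCR test), lineage-through-time curves for single trees and posterior
samples, interval-based species-birth rates (new species per lineage per
fixed time bin), and the cumulative-density diagnostic of branch lengths
fitted against constant- vs variable-rate expectations.

The gamma statistic
-------------------
With internode intervals ``g_k`` (the span during which exactly k
lineages exist, k = 2..n) and ``T = sum_k k*g_k``::

    gamma = ( mean_i sum_{k<=i} k*g_k  -  T/2 ) / ( T * sqrt(1/(12(n-2))) )

for i = 2..n-1.  Under a constant-rate pure-birth process gamma is
asymptotically standard normal; negative values indicate branching
concentrated near the root (slowdown), positive values branching toward
the present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .treeio import BranchingTimes, Chronogram, TreeError, TreeSample, branching_times

__all__ = [
    "GammaResult",
    "MCCRResult",
    "LTTCurve",
    "IntervalRates",
    "BranchLengthCDF",
    "gamma_statistic",
    "mccr_test",
    "ltt_curve",
    "mltt",
    "interval_rates",
    "branch_length_cdf",
]


# ---------------------------------------------------------------------------
# gamma / CR test
# ---------------------------------------------------------------------------


@dataclass
class GammaResult:
    """Gamma statistic with p-values under the standard-normal null.

    ``p_value`` is the lower-tail mass Phi(gamma) — the convention under
    which a significant *slowdown* gives a small p (and a tip-ward shift a
    p near 1).  Upper-tail and two-sided versions are also reported so no
    tail is silently flipped.
    """

    gamma: float
    p_value: float       # Phi(gamma), lower tail
    p_upper: float       # 1 - Phi(gamma)
    p_two_sided: float
    n: int
    crown_age: float


def gamma_statistic(bt: BranchingTimes) -> GammaResult:
    """Constant-rate (CR) test statistic from branching times.

    Requires n >= 4 (the 1/(n-2) normalisation and the interior sum are
    degenerate below that).
    """
    n = bt.n
    if n < 4:
        raise TreeError("gamma statistic requires n >= 4 tips")
    g = bt.internode_intervals()              # g_2 .. g_n
    k = np.arange(2, n + 1, dtype=float)
    weighted = k * g
    T = float(weighted.sum())
    if T <= 0:
        raise TreeError("degenerate tree: zero total weighted length")
    partial = np.cumsum(weighted)             # sum_{k<=i} k g_k at i = 2..n
    inner_mean = partial[:-1].mean()          # i = 2..n-1
    gamma = (inner_mean - T / 2.0) / (T * np.sqrt(1.0 / (12.0 * (n - 2))))
    p_lower = float(stats.norm.cdf(gamma))
    return GammaResult(
        gamma=float(gamma),
        p_value=p_lower,
        p_upper=1.0 - p_lower,
        p_two_sided=float(2.0 * stats.norm.sf(abs(gamma))),
        n=n,
        crown_age=bt.crown_age,
    )


# ---------------------------------------------------------------------------
# MCCR test
# ---------------------------------------------------------------------------


@dataclass
class MCCRResult:
    """Monte-Carlo CR test against a null of incompletely sampled trees."""

    observed_gamma: float
    null_gammas: np.ndarray
    critical_value_5pct: float       # lower 5th percentile of the null
    p_lower: float                   # fraction of null <= observed
    p_upper: float                   # fraction of null >= observed
    outside_95: bool                 # observed outside the null's central 95%
    n_total: int
    sample_n: int
    reps: int


def mccr_test(
    bt: BranchingTimes,
    n_total: int,
    reps: int = 1000,
    seed: int = 0,
) -> MCCRResult:
    """MCCR test: gamma null from pure-birth trees pruned to the sampling
    fraction actually achieved (``bt.n`` of ``n_total`` species).

    The null simulates constant-rate pure-birth trees with ``n_total``
    tips, prunes each uniformly at random to ``bt.n`` tips, and computes
    gamma; incomplete sampling shifts this null below N(0,1).  The
    speciation rate is irrelevant (gamma is invariant to time scaling).
    """
    if n_total < bt.n:
        raise ValueError("n_total must be >= number of sampled tips")
    if reps < 100:
        raise ValueError("reps must be >= 100")
    from .simulate import SimConfig, prune_to_sample, simulate_tree

    ss = np.random.SeedSequence(seed)
    null = np.empty(reps)
    for i, child in enumerate(ss.spawn(reps)):
        s1, s2 = (int(x % (2**31)) for x in child.generate_state(2))
        sim = simulate_tree(
            SimConfig(model="yule1", lambda1=1.0, n_total=n_total,
                      sample_n=None, seed=s1)
        )
        if bt.n < n_total:
            pruned = prune_to_sample(sim.chronogram, bt.n, seed=s2)
            sub_bt = branching_times(pruned)
        else:
            sub_bt = sim.branching_times()
        null[i] = gamma_statistic(sub_bt).gamma
    obs = gamma_statistic(bt).gamma
    lo, hi = np.percentile(null, [2.5, 97.5])
    return MCCRResult(
        observed_gamma=obs,
        null_gammas=null,
        critical_value_5pct=float(np.percentile(null, 5.0)),
        p_lower=float(np.mean(null <= obs)),
        p_upper=float(np.mean(null >= obs)),
        outside_95=bool(obs < lo or obs > hi),
        n_total=n_total,
        sample_n=bt.n,
        reps=reps,
    )


# ---------------------------------------------------------------------------
# lineage-through-time curves
# ---------------------------------------------------------------------------


@dataclass
class LTTCurve:
    """Step function of lineage count vs age (descending to the present)."""

    times: np.ndarray          # ages in Ma, descending, last entry 0
    lineage_counts: np.ndarray  # counts just after each time; 2 .. n

    def at_age(self, age: float) -> int:
        """Lineage count at a given age (between crown age and 0)."""
        counts = self.lineage_counts[self.times >= age]
        return int(counts[-1]) if len(counts) else int(self.lineage_counts[-1])


def ltt_curve(tree: Chronogram | BranchingTimes) -> LTTCurve:
    """Lineage-through-time curve of one chronogram."""
    bt = tree if isinstance(tree, BranchingTimes) else branching_times(tree)
    times = np.concatenate([bt.ages, [0.0]])
    counts = np.concatenate([np.arange(2, bt.n + 1), [bt.n]])
    return LTTCurve(times=times, lineage_counts=counts)


def mltt(sample: TreeSample, k: int, seed: int = 0) -> list[LTTCurve]:
    """LTT curves for ``k`` trees drawn without replacement from a sample."""
    if k > len(sample):
        raise ValueError("k exceeds the sample size")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(sample), size=k, replace=False)
    return [ltt_curve(sample.trees[int(i)]) for i in idx]


# ---------------------------------------------------------------------------
# interval-based species-birth rates
# ---------------------------------------------------------------------------


@dataclass
class IntervalRates:
    """New-species counts and per-lineage birth rates in fixed time bins.

    Bins of width ``delta_t`` are tiled from the crown age toward the
    present (the youngest bin may be truncated at age 0).  ``delta_n`` is
    the number of branching events in each bin — the crown divergence
    itself creates the two initial lineages and is not a birth, so the
    counts sum to n-2.  ``rate = delta_n / n_start`` where ``n_start`` is
    the lineage count at the bin's older edge; ``rate_per_ma`` divides by
    the bin's actual width.
    """

    bin_edges: np.ndarray     # older edges, descending; length = #bins + 1 incl. 0
    delta_n: np.ndarray
    n_start: np.ndarray
    rate: np.ndarray
    rate_per_ma: np.ndarray
    delta_t: float


def interval_rates(
    bt: BranchingTimes, delta_t: float = 0.9, anchor: str = "crown"
) -> IntervalRates:
    """Species-birth counts per fixed time interval (default 0.9 Ma).

    ``anchor`` places the bin grid: ``"crown"`` (default) starts the
    oldest bin edge exactly at the crown age; ``"present"`` tiles from
    age 0 upward so the oldest bin may be truncated instead.
    """
    if delta_t <= 0:
        raise ValueError("delta_t must be > 0")
    if anchor not in ("crown", "present"):
        raise ValueError("anchor must be 'crown' or 'present'")
    crown = bt.crown_age
    if anchor == "crown":
        edges_old = np.arange(crown, 0.0, -delta_t)
        edges = np.concatenate([edges_old, [0.0]])
    else:  # grid anchored at the present; oldest (truncated) bin ends at crown
        interior = np.arange(delta_t, crown, delta_t)[::-1]
        edges = np.concatenate([[crown], interior, [0.0]])
    events = bt.ages[1:]                       # crown divergence excluded
    nbins = len(edges) - 1
    delta_n = np.zeros(nbins, dtype=int)
    n_start = np.zeros(nbins, dtype=int)
    for b in range(nbins):
        old, young = edges[b], edges[b + 1]
        # event at exactly the older edge belongs to the older (previous) bin
        delta_n[b] = int(np.sum((events < old) & (events >= young)))
        n_start[b] = 1 + int(np.sum(bt.ages >= old))
    widths = edges[:-1] - edges[1:]
    rate = delta_n / n_start
    return IntervalRates(
        bin_edges=edges,
        delta_n=delta_n,
        n_start=n_start,
        rate=rate,
        rate_per_ma=rate / widths,
        delta_t=delta_t,
    )


# ---------------------------------------------------------------------------
# branch-length cumulative density
# ---------------------------------------------------------------------------


@dataclass
class BranchLengthCDF:
    """Cumulative branch-length frequencies vs fitted rate models.

    Branch lengths are binned into equal-width classes over (0, max]; the
    empirical cumulative frequency is compared against a maximum-
    likelihood single-exponential CDF (the constant-rate expectation) and
    a two-component exponential mixture (a heavier-tailed variable-rates
    surrogate).  ``classification`` is "variable" when the mixture has the
    lower AIC, else "constant".
    """

    class_edges: np.ndarray        # upper class boundaries, ascending
    cumulative_freq: np.ndarray
    fitted_constant_cdf: np.ndarray
    fitted_variable_cdf: np.ndarray
    delta_aic_exp_vs_alt: float    # AIC(exponential) - AIC(mixture)
    classification: str
    exp_rate: float
    mixture_params: dict


def _fit_exp_mixture(x: np.ndarray, max_iter: int = 500, tol: float = 1e-12):
    """ML fit of w*Exp(r1) + (1-w)*Exp(r2) by EM with deterministic init."""
    med = np.median(x)
    lo, hi = x[x <= med], x[x > med]
    r1 = 1.0 / max(np.mean(hi), 1e-12)    # slow component (long branches)
    r2 = 1.0 / max(np.mean(lo), 1e-12)
    w = 0.5
    ll_old = -np.inf
    for _ in range(max_iter):
        l1 = np.log(w) + np.log(r1) - r1 * x
        l2 = np.log1p(-w) + np.log(r2) - r2 * x
        m = np.maximum(l1, l2)
        ll = float(np.sum(m + np.log(np.exp(l1 - m) + np.exp(l2 - m))))
        resp = 1.0 / (1.0 + np.exp(l2 - l1))   # P(component 1 | x)
        s1 = resp.sum()
        s2 = len(x) - s1
        if s1 < 1e-9 or s2 < 1e-9:
            break
        w = s1 / len(x)
        r1 = s1 / float(np.sum(resp * x))
        r2 = s2 / float(np.sum((1 - resp) * x))
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    l1 = np.log(w) + np.log(r1) - r1 * x
    l2 = np.log1p(-w) + np.log(r2) - r2 * x
    m = np.maximum(l1, l2)
    ll = float(np.sum(m + np.log(np.exp(l1 - m) + np.exp(l2 - m))))
    return {"w": float(w), "rate1": float(r1), "rate2": float(r2)}, ll


def branch_length_cdf(lengths: np.ndarray, n_classes: int = 10) -> BranchLengthCDF:
    """Cumulative-density diagnostic over equal-width branch-length classes."""
    x = np.asarray(lengths, dtype=float)
    x = x[x > 0]
    if len(x) < 10:
        raise ValueError("need at least 10 positive branch lengths")
    n_distinct = len(np.unique(x))
    if n_distinct < n_classes:
        warnings.warn(
            f"only {n_distinct} distinct lengths; widening to {n_distinct} classes"
        )
        n_classes = max(n_distinct, 2)
    edges = np.linspace(0.0, float(x.max()), n_classes + 1)[1:]
    cum = np.array([np.mean(x <= e) for e in edges])
    cum[-1] = 1.0

    # constant-rate fit: single exponential, ML rate = 1/mean
    rate = 1.0 / x.mean()
    ll_exp = float(len(x) * np.log(rate) - rate * x.sum())
    aic_exp = 2 * 1 - 2 * ll_exp

    mix, ll_mix = _fit_exp_mixture(x)
    aic_mix = 2 * 3 - 2 * ll_mix

    delta = aic_exp - aic_mix
    cdf_exp = 1.0 - np.exp(-rate * edges)
    cdf_mix = mix["w"] * (1 - np.exp(-mix["rate1"] * edges)) + (
        1 - mix["w"]
    ) * (1 - np.exp(-mix["rate2"] * edges))
    return BranchLengthCDF(
        class_edges=edges,
        cumulative_freq=cum,
        fitted_constant_cdf=cdf_exp,
        fitted_variable_cdf=cdf_mix,
        delta_aic_exp_vs_alt=float(delta),
        classification="variable" if delta > 0 else "constant",
        exp_rate=float(rate),
        mixture_params=mix,
    )
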