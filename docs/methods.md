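# Methods notes

This note records the models implemented in `chronodiv`, the numerical
and design choices that were genuinely open, what the simulators do and
do not emulate, and the problem sizes the test suite and acceptance
script use. It states no empirical result that the tests or
`scripts/acceptance.py` do not themselves compute.

## Time convention and tree validation

All modules measure node ages backward from the present: tips at age 0,
the crown node at the crown age (Ma). Ultrametricity is checked as
(max − min root-to-tip depth) ≤ rtol × depth with rtol = 1e-6 by
default — dating software prints rounded decimals, so exact equality is
never met; the tolerance is configurable per tree. Polytomies are
rejected by default because every downstream likelihood assumes binary
trees; an optional seeded zero-length random resolution is provided with
a warning. Outgroups are handled by an explicit drop-list pruned before
analysis; the default analysis is ingroup-only, with the drop-list
exposed so both variants can be run.

Node-age ties are kept in in-file order; γ depends only on the multiset
of ages, so tie order cannot change it (property-tested).

## The γ / CR / MCCR machinery

γ follows the standard constant-rates-test form (see README). Three
p-values are always reported — Φ(γ), 1 − Φ(γ) and two-sided — with
`p_value` bound to the lower-tail Φ(γ) convention used in the
comparative literature when testing for slowdowns. Reporting all three
avoids silently flipping tails when the interesting signal is, as here,
an *upshift* (γ > 0). Minimum n is 4; n = 3 is rejected (the 1/(n−2)
normalisation and interior sum are degenerate).

The MCCR null simulates constant-rate pure-birth trees at the described
species number (`n_total`, default 70) and prunes each uniformly to the
sampled count. The simulation rate is fixed at 1/Ma: γ is invariant to
time scaling, so the null does not depend on it.

## Pure-birth simulator conditioned on n

Trees conditioned on n tips are generated through their internode
intervals: with k lineages the waiting time has hazard k·λ(age), for
k = 2..n *including* the final censored interval from the youngest
divergence to the present — equivalently, the process is grown until the
(n+1)-th birth and cut at that event. This is the construction under
which γ has null mean 0 and unit variance; stopping exactly at the n-th
birth would set g_n = 0 and bias γ upward. Topology is built by uniform
random joins (the Yule labelled-history distribution).

The single-shift (two-rate) simulator draws the same intervals backward
from the present with a piecewise hazard: rate λ2 at ages younger than
the shift, λ1 older. This is exactly the process the two-rate likelihood
describes, and it realises the shift at a fixed age before the present —
something a naive forward simulation cannot target because the present
is unknown until the simulation ends. Histories whose crown age does not
exceed the shift age are rejected and redrawn (capped at 10,000 tries).

The birth–death simulator runs forward from two crown lineages and stops
at the first event time after the extant count reaches n (so the final
interval is fully elapsed and the μ = 0 case coincides with the
pure-birth construction, which the tests check distributionally on γ).
Extinct lineages are pruned and the reconstructed tree returned;
all-extinct histories are redrawn, capped at 10,000 tries. This "stop at
first passage through n" conditioning is the simple-sampling scheme; it
is adequate for the null/recovery experiments here and is not a
general-purpose sampler of the fully conditioned birth–death
distribution.

Posterior-like samples multiply each internal node age by an independent
mean-1 lognormal factor (SD = `jitter_sd`) and restore parent–child
order top-down, keeping every replicate ultrametric; the crown age
carries one factor, so its coefficient of variation ≈ `jitter_sd`.
Optional NNI moves perturb topology at a per-edge probability. The
sample emulates the *spread* of a Bayesian posterior, not its
correlation structure: jitter is independent across nodes and trees,
whereas MCMC posteriors correlate ages along paths and across samples.
Passing recovery tests therefore shows robustness to independent dating
noise, not to systematic calibration error.

Range histories evolve by continuous-time events along branches: total
per-lineage gain rate `dispersal_rate` (uniform over absent areas,
blocked at `max_range_size`) and loss rate `extinction_rate` (uniform
over present areas, blocked when one area remains, so a range never
empties). True ranges at every internal node are recorded.

## Rate-model fitting

Likelihoods condition on the crown age and right-censor the final
interval. Alternative conditionings (on n; no censoring) differ by
data-independent constants, so ΔAIC between the models here is
unaffected — but absolute log-likelihood values are only comparable
across implementations sharing the exact same conditioning, and we do
not promise to match any particular external program's printed lnL.

For the two-rate model, the conditional MLEs given a shift age s are
closed-form: λ̂ᵢ = (events in epoch i)/(lineage-time in epoch i). The
profile log-likelihood over s is, within every inter-event interval, a
convex function of the epoch-1 lineage-time (its stationary point is a
minimum), so the continuous supremum always sits at an observed
branching time. The default candidate set — the observed branching
times, with the boundary convention that an event at exactly s belongs
to the older epoch — is therefore exhaustive, and the optional
midpoint/grid candidates exist only as cross-checks (the tests assert
they never improve the optimum). Degenerate candidates with all events
on one side are skipped; if none remain the fit falls back to the
constant-rate solution with a warning. Equal-AIC ties in model
comparison go to the model with fewer parameters; the report flags
ΔAIC > 4 (a conventional substantial-support bar) but exposes deltas and
Akaike weights so users can apply their own threshold, since no single
operational cutoff is canonical.

A constant birth–death fit (Nee-style reconstructed-process likelihood,
parametrised by net rate r and relative extinction a, optimised by
Nelder–Mead from the pure-birth start point) is available behind the
model list; it shares the conditioning above and reduces to pure birth
at a = 0.

## Interval-based birth rates

Bins of width Δt (default 0.9 Ma) are tiled from the crown age toward
the present by default (`anchor="present"` tiles from 0 instead; the
choice is not dictated by any standard, so both are exposed). "Newly
appearing species" are branching events — the crown divergence creates
the two initial lineages and is not a birth — so counts sum to n − 2 for
every tree and every Δt (property-tested). An event exactly on a bin
edge belongs to the older bin, consistently with the lineage count
`n_start` evaluated at the bin's older edge. `rate = Δn/n_start`;
`rate_per_ma` divides by the bin's actual width (the youngest bin may be
truncated). Note the discretisation bias of Δn/n_start/Δt as an
estimator of λ is (e^{λΔt} − 1)/(λΔt); at λΔt ≈ 0.27 (λ = 0.3, Δt = 0.9)
this is ≈ +15%, which is why the recovery experiments use Δt = 0.3
(bias ≈ +5%) while the pipeline default stays at the conventional 0.9
for descriptive plots.

## Branch-length cumulative density

Branch lengths are binned into ten equal-width classes over (0, max];
the empirical cumulative frequency is compared against a
maximum-likelihood single exponential (the constant-rate expectation)
and a two-component exponential mixture fitted by EM with a
deterministic median-split initialisation (≤500 iterations, tolerance
1e-12). The mixture is a *surrogate* for "variable rates": it is the
simplest heavier-tailed alternative within the same family, chosen
because the literature invoking this diagnostic does not pin down a
specific variable-rates CDF. Classification is by plain AIC (mixture
penalised 2 extra parameters); the signed ΔAIC is reported so users can
demand a stronger margin. Fewer than ten distinct lengths widen the
classes with a warning.

## DIVA / S-DIVA

Semantics: at a node, a single-area range duplicates into both daughters
at cost 0; a widespread range splits into two nonempty disjoint subsets
covering it at cost 0; along a branch each gained area costs 1 and each
lost area costs 1 (symmetric-difference transition cost). This
branch/node factorisation is equivalent to the classical single-step
DIVA optimisation on binary trees; the brute-force enumeration oracle in
the test suite pins the semantics exactly (cost, optimal root set, and
per-node multiplicities). Ancestral ranges are capped at `max_areas`
(default two); terminal ranges are exempt from the cap, matching S-DIVA
practice. The DP runs over all allowed range states with a top-down
counting pass, so multiplicities are exact counts of minimum-cost full
reconstructions, not samples.

S-DIVA matches clades across trees by unordered tip-set identity (the
only defensible reading of per-node averaging over a posterior). Each
sample tree containing a clade contributes one unit of mass split across
that clade's optimal ranges — by multiplicity share (default) or equally
(`weighting="uniform"`), since published S-DIVA versions differ in their
tie handling — and mass is normalised over containing trees; clade
support is the containing fraction. Clades absent from every tree get
support 0 and no probabilities.

## Problem sizes used by tests and the acceptance script

Chosen to mirror the study's scale where it matters (n = 65 of ~70
species for γ/MCCR; n = 200 for shift recovery where asymptotics are the
point) while keeping the whole suite fast: 2000 trees for γ-null
calibration; 1000 paired replicates for the MCCR shift; 200 two-rate +
500 constant-rate trees for model selection (the constant-rate
false-positive check uses the study's n = 65, which the criterion left
open); 100 random instances for the likelihood oracle; 200 random
instances (≤6 tips, ≤4 areas) for DIVA-vs-brute-force; 100 experiments
× 50-tree samples for S-DIVA recovery with 4 areas, root range {A} and
dispersal = loss = 0.05 events/lineage/Ma on 10-tip λ = 0.3 trees
(crown ≈ 6 Ma, hence ≈ 0.3 events per root-to-tip path — "moderate"
rates fixed a priori); 500 trees for interval-count conservation; 200
replicates per class for the branch-length-CDF discrimination.

## Known limitations

- The birth–death simulator's first-passage conditioning and the
  pure-birth cut-at-(n+1)-th-birth convention are stated choices, not
  the unique conditioned distributions.
- The two-rate model assumes one global instantaneous shift; clade-local
  shifts, multi-shift and density-dependent models are out of scope.
- DIVA is parsimony: no branch-length information, no rate estimates,
  and cost-symmetric dispersal; DEC-style likelihood models are out of
  scope.
- Absolute log-likelihoods are conditioning-dependent (see above);
  only ΔAIC within this package is interpretation-safe.
- The range simulator's per-lineage event rates are range-size-
  independent; real dispersal likely scales with range size and
  distance, neither of which is modelled.
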