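# chronodiv

Diversification-rate and historical-biogeography analyses on
time-calibrated phylogenies (chronograms), built for clade-scale studies
such as the paleotropical fern genus *Lepisorus*: a crown group of ~70
species whose dated phylogeny shows branching concentrated toward the
present, consistent with a recent increase in speciation rate, and whose
species ranges across eight areas of endemism (Africa through East Asia)
can be traced back with dispersal–vicariance parsimony.

The package answers two questions about such a clade:

1. **Has the diversification rate changed through time?**
   via the Pybus–Harvey γ statistic and constant-rate (CR) test, its
   Monte-Carlo correction for incomplete taxon sampling (MCCR),
   lineage-through-time (LTT/MLTT) curves, species-birth counts per fixed
   time interval, a cumulative branch-length density diagnostic, and
   maximum-likelihood comparison (AIC) of one-rate vs two-rate pure-birth
   models with shift-point estimation.
2. **Where did the clade and its subclades live?**
   via exact event-cost dispersal–vicariance reconstruction (DIVA) on
   single trees and statistical averaging over a posterior tree sample
   (S-DIVA), with ancestral ranges capped at a configurable size
   (default two areas).

A ground-truth simulator (constant-rate, single-shift and birth–death
chronograms conditioned on a fixed tip count; random pruning; jittered
posterior-like tree samples; continuous-time range evolution) makes every
stage testable without external data.

## The statistics

With internode intervals $g_k$ (the time during which exactly $k$
lineages exist, $k = 2..n$) and $T = \sum_k k\,g_k$:

$$\gamma = \frac{\tfrac{1}{n-2}\sum_{i=2}^{n-1}\sum_{k=2}^{i} k\,g_k \; - \; T/2}{T\sqrt{1/(12(n-2))}}$$

is asymptotically standard normal under a constant-rate pure-birth
process; $\gamma > 0$ means branching concentrated toward the present.
The MCCR test replaces the normal null with γ values from simulated
trees pruned to the empirical sampling fraction.

Model fits condition on the crown age: each observed interval
contributes $\ln(k\lambda) - k\lambda g_k$ and the final interval is
right-censored. The constant-rate MLE is
$\hat\lambda = (n-2)/\sum_k k\,g_k$; the two-rate model switches from
$\lambda_1$ to $\lambda_2$ at a shift age $t_s$, whose profile
likelihood is maximised exactly over the observed branching times.

DIVA assigns each ancestral node a range (a set of areas): vicariant
splits and within-area duplication are free, each area gained along a
branch costs one dispersal and each area lost one extinction; the
reconstruction minimising total events is found by exact dynamic
programming, enumerating *all* co-optimal ranges per node.

## Worked example

Simulate a 65-tip chronogram whose speciation rate jumps from 0.12 to
0.5 /lineage/Ma at 4 Ma (a stand-in for a dated consensus tree), then
test it:

```bash
$ divpipe simulate --model yule2 --lambda1 0.12 --lambda2 0.5 \
    --shift-time 4 --n-total 65 --seed 42 --out demo.nwk \
    --ranges-out demo_ranges.tsv
wrote 65-tip yule2 tree to demo.nwk

$ divpipe gamma --tree demo.nwk
{
 "crown_age": 18.900486171917322,
 "gamma": 3.3917554014209736,
 "n": 65,
 "p_two_sided": 0.0006944640584231631,
 "p_upper": 0.00034723202921160823,
 "p_value": 0.9996527679707884
}

$ divpipe fitmodels --tree demo.nwk
...
 "best": "yule2rate",
 "daic_two_vs_one": 19.525465085348287,
 "yule2rate": {
  "lambda1": 0.10165293626512328,
  "lambda2": 0.4744686584244341,
  "t_shift": 4.0559144911982745
 }
```

γ = 3.39 with `p_value` (the lower-tail convention, Φ(γ)) near 1 flags
branching concentrated toward the present; the two-rate model beats the
one-rate model by ΔAIC ≈ 19.5 and recovers the simulated shift
(λ̂₁ ≈ 0.10, λ̂₂ ≈ 0.47, t̂ ≈ 4.06 Ma). The same library calls are
available in Python (`chronodiv.gamma_statistic`,
`chronodiv.compare_models`, ...), and `divpipe run --config FILE` chains
every stage — γ/MCCR, model selection, LTT/MLTT, interval rates,
branch-length CDF, DIVA/S-DIVA — into one reproducible report with
optional figures.

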