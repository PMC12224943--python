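# synspread

Connectome-based modelling of directionally biased pathological protein
spread, for systems neuroscientists studying prion-like propagation (e.g.
misfolded α-synuclein after striatal fibril injection in mouse) on the
mesoscale brain connectome.

## The model

Regional pathology burdens `X(t)` on a directed, weighted connectome
`C = {c_ij}` (projection strength from region *i* to region *j*) evolve under
linear dynamics combining network spread with global amplification/clearance:

```
dX/dt = (α I − β L̂) X,          X(0) = X0
L̂    = diag(columnsum(Ĉ)) − Ĉ
Ĉ    = (1 − s)·Cᵀ + s·C
```

with closed-form solution `X̂(t) = exp((α I − β L̂) t) · X0`. The parameters
are

* `α` — net amplification (+) / clearance (−) rate per month,
* `β` — global diffusivity per month,
* `γ` — seed scaling: `X0` is `γ` at the injected region(s), 0 elsewhere,
* `s` — directionality in `[0, 1]`: 0 fully anterograde, 1 fully retrograde,
  intermediate values mix both transport directions.

Regional gene expression `g` can modulate the connectome before mixing:
`G·C` (outgoing / presynaptic effect), `C·G` (incoming / postsynaptic
effect), or `G·C·G` (combined), with `G = diag(g)`.

Parameters are fitted by maximising Lin's concordance correlation coefficient
(CCC) between `log10` observed and predicted burdens over regions with
nonzero observation, averaged over the observation times ("Ave. CCC"):

```
argmin over (α, β, γ, s)  of  Σ_t [ 1 − CCC(log10 X(t), log10 X̂(t)) ]
```

CCC penalises scale and location disagreement (unlike Pearson's r), which
makes the seed scaling `γ` identifiable. Around this core the package
provides connectome perturbation analyses (uniform/permutation nulls, random
and strength-ordered edge removal, key-subnetwork extraction), genome-wide
per-gene screening with permutation bootstraps, over-representation and
depth-1 key-driver statistics, and a synthetic-data generator that emulates
the statistical structure of real studies so every stage is testable
offline.

## Worked example

```python
from synspread import (SyntheticConfig, synth_bundle, fit_spread_model,
                       FitConfig, key_connectome)

# simulate a 40-region bilateral study observed at 3 and 6 months
# post-injection with 0.3 dex multiplicative observation noise
bundle = synth_bundle(SyntheticConfig(n_genes=0, rng_seed=7))
fit = fit_spread_model(bundle.pathology, bundle.connectome,
                       bundle.seed_spec.seeded_regions,
                       FitConfig(n_starts=8, rng_seed=1))
```

prints (via the session shown in `fit.parameters` / `fit.ccc_per_time`):

```
alpha       : +0.357 per month   (truth +0.30)
beta        : 0.431 per month    (truth 0.50)
gamma       : 0.186             (truth 0.20)
s           : 0.815             (truth 0.80)
CCC at 3 MPI: 0.906
CCC at 6 MPI: 0.906
Ave. CCC    : 0.906
```

The fitted `s = 0.815` recovers the predominantly retrograde transport the
generator used (`s = 0.8`) despite the observation noise, and Ave. CCC ≈ 0.91
is the noise-limited ceiling for this noise level. On a study whose dynamics
were generated from a planted key subnetwork, thresholding to the strongest
5% of entries barely changes the fit:

```
full connectome Ave. CCC : 0.962  (s = 0.814)
top-5% key subnetwork    : 80 of 1600 entries, Ave. CCC 0.959
```

A command-line pipeline wraps the same functionality:

```
synspread simulate   --outdir sim --seed 3 --n-regions 40
synspread fit-global --connectome sim/connectome.tsv \
    --pathology sim/pathology.tsv --seed-regions sim/seed_regions.txt \
    --outdir fit --seed 1
```

`fit-global` also reports the fixed-directionality comparisons (fully
anterograde `s = 0`, unbiased `s = 0.5`, fully retrograde `s = 1`) next to
the free fit. Further subcommands: `fit-genes`, `null-sweep`,
`key-connectome`, `enrich`, `kda`.

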