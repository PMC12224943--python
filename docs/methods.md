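# Methods

## The spread model

Pathology is a nonnegative scalar field on a directed, weighted region-level
connectome `C`, with `c_ij` the axonal projection strength from region *i*
to region *j*. Two processes act at the early disease stage modelled here:

1. **Network spread.** Pathology moves between structurally connected
   regions. At the cellular level transport can be anterograde
   (pre- to post-synaptic, along axon direction), retrograde, or a mixture.
   The directionality parameter `s ∈ [0, 1]` blends the connectome with its
   transpose, `Ĉ = (1 − s)·Cᵀ + s·C` (0 fully anterograde, 1 fully
   retrograde), and spread is generated by the column-sum graph Laplacian
   `L̂ = diag(columnsum(Ĉ)) − Ĉ` scaled by a global diffusivity `β ≥ 0`
   (per month).
2. **Amplification and clearance.** Templated misfolding creates new
   pathology and degradation removes it; their net effect is a single
   exponential rate `α` (positive: net amplification).

Together, `dX/dt = (α I − β L̂) X` with `X(0) = X0`, where `X0` carries the
seed scaling `γ ∈ (0, 1]` at the injected region(s). The closed-form
solution is the matrix exponential `X̂(t) = exp((α I − β L̂) t)·X0`.
Degeneration is deliberately not modelled: it is negligible at the 3–6 month
horizon the model targets.

Structural consequences used as tests throughout: columns of `L̂` sum to
zero, so total pathology is conserved when `α = 0` and grows exactly as
`e^{αt}` otherwise; `−β L̂` is Metzler, so solutions stay nonnegative;
predictions from `(C, s)` and `(Cᵀ, 1 − s)` coincide; and the flow obeys the
semigroup property.

### Gene modulation

Regional expression of a single gene `g` (diagonal matrix `G`) rescales the
connectome before mixing: `G·C` scales a region's efferent edges (outgoing /
presynaptic effect), `C·G` its afferent edges (incoming / postsynaptic), and
`G·C·G` both (combined). The mixed matrix and Laplacian are rebuilt from the
modulated connectome. Expression vectors are divided by their mean before
modulation (switchable via `gene_normalization`): because `β` is refit per
gene, only the vector's shape matters for the outgoing and incoming effects,
but the combined effect is quadratic in overall scale, and a common
normalisation keeps fitted diffusivities comparable across genes. A uniform
expression vector is exactly absorbed into `β` (by `c` for outgoing or
incoming, `c²` for combined), so a flat gene reproduces the global model — a
useful null.

## Fitting

The objective is Lin's concordance correlation coefficient between `log10`
burdens, `CCC = 2 cov(x, y) / (var(x) + var(y) + (mean x − mean y)²)` with
population (1/n) moments, summed as `Σ_t (1 − CCC_t)` over observation
times. Only regions with nonzero, finite observed burden enter (observations
span roughly three orders of magnitude, hence the log scale and the
structural zeros below the detection limit); predicted values at those
regions are floored at `1e-12` before the log. CCC rather than Pearson's r
is essential: it degrades under any location or scale shift, which makes
`γ` identifiable.

Optimisation is bounded multi-start local search (L-BFGS-B with numerical
gradients). Practical boxes `α ∈ [−5, 5]` and `β ∈ [0, 20]` stand in for the
unbounded constraints; `γ ∈ [1e-6, 1]`, `s ∈ [0, 1]`. Because `L̂(s)` is
affine in `s`, the two endpoint Laplacians are precomputed once per fit. A
seeded Latin hypercube supplies `8 × n_starts` (minimum 32) probe points,
each costing one loss evaluation; local optimisation starts from the best
`n_starts` probes (default 20), which is markedly more robust per unit cost
than optimising from raw draws. Ties across starts break by lowest loss,
then earliest start index; fits are bit-reproducible given the seed. A
prediction that overflows the exponential maps to a large finite sentinel
loss, and a fit whose every start fails reports `status="failed"` with no
parameters — genome-wide screens continue past such genes and report them.

The model is packaged as a scikit-learn style estimator
(`NetworkSpreadModel`): constructor arguments are stored verbatim,
`fit(X)` consumes the `(n_times, n_regions)` burden matrix, fitted state
lives in trailing-underscore attributes, and `get_params` / `set_params` /
`clone` follow the sklearn contract, so the model composes with sklearn
model-selection tooling. `fit_spread_model` is a thin functional wrapper.

## Perturbation and key-subnetwork analyses

Null connectomes (i.i.d. uniform entries; permutations of the real weights)
test whether observed spread follows the measured graph. Edge removal —
random, weakest-first, or strongest-first — and key-connectome extraction
(keep the `ceil(f·n²)` strongest entries) localise which connections carry
the signal. All fraction-based counts use the full `n²` entry universe
including the dynamically inert diagonal; this convention reproduces the
printed counts 3362 (2% of 410²) and 1077 (8% of 116²). Removal counts use
the complement rule `n² − ceil((1−f)·n²)` so removing `1−f` and keeping `f`
partition the universe consistently. Weight ties break by (row, column)
lexicographic order — stable and seed-independent. Replicate seeds derive as
`master_seed + replicate_index`; per-replicate fit failures are recorded,
never fatal, and Ave. CCC percentiles are computed over successes only.

## Gene screening

Each gene is fitted independently in each requested effect mode; genes whose
Ave. CCC strictly exceeds the unmodulated global model's (computed once per
dataset) are candidate contributors to regional selective vulnerability, and
the top N among them (ties by gene id) form the candidate set. The screen is
order-independent and embarrassingly parallel. The permutation bootstrap
refits a gene B times with its region assignment permuted (value multiset
preserved); the actual Ave. CCC's percentile against this null counts ties
as exceeded, and a constant vector — whose null is degenerate — is flagged
rather than called significant. A per-gene Pearson correlation between
expression and raw burdens (same nonzero-observation mask) serves as the
connectome-free comparison model.

## Enrichment and key-driver statistics

Over-representation uses the one-sided upper-tail hypergeometric test with
markers intersected with the declared background universe (default: the
screened gene set), fold enrichment `(k/n)/(K/N)`, and Bonferroni (explicit
family size allowed) or Benjamini–Hochberg adjustment. Key-driver analysis
is depth-1 and direction-blind: each node's undirected neighborhood
(excluding the node) is tested for candidate enrichment against all network
nodes with the same hypergeometric tail — an exact, assumption-free
substitute for the chi-like score some KDA implementations use — followed by
BH FDR across nodes and a 0.05 call threshold. The within-effect wiring test
compares, per effect, the count of directed key-driver→key-driver edges
landing on the same effect against the independence expectation
`total × (|KD_effect| − 1)/(|KD_any| − 1)` (a source cannot target itself)
in a two-cell chi-square with 1 df; expected cells sum to the observed total
by construction. The well-assay score
`(r_treated − r_background)/(r_control − r_background)` with
`r = pathology density / neuron-marker area` is invariant to common
rescaling of the densities and undefined when the control does not exceed
background.

## Synthetic data

The generator produces studies with the statistical structure the analysis
assumes, so every stage is testable without downloads:

* **Connectome** — directed, zero diagonal, Bernoulli(density = 0.25) edge
  mask, log-normal weights with `σ_ln = 1.7` (±2σ spans roughly a 1–1000×
  weight range, the heavy-tailed spread of real mesoscale projection
  strengths). Optional bilateral structure mirrors left/right hemispheres
  with contralateral blocks attenuated (×0.3) relative to ipsilateral ones.
  Matrices are normalised to unit maximum column strength, the usual
  network-diffusion convention (only relative weights are meaningful); this
  places the diffusion relaxation on the same timescale as `1/β`, so `β` is
  identifiable from observations a few months apart.
* **Pathology** — the forward model evaluated exactly at the true parameters
  (defaults `α = 0.3`, `β = 0.5`, `γ = 0.2`, `s = 0.8`, times {3, 6}
  months), multiplied by `10^(σZ)` with `σ = 0.3` dex (multiplicative noise,
  additive on the log10 scale the loss uses), then truncated at a detection
  floor of `1e-4` producing structural zeros. The default seed region is the
  highest-total-strength region, a deterministic stand-in for injection into
  a highly connected deep-gray structure. Positive observed burdens span
  more than two orders of magnitude under these defaults.
* **Planted key subnetwork** — for thresholding analyses, non-key entries of
  the sampled matrix are attenuated (×0.05) so the strongest 5% of entries
  carry ≈99% of total weight, and the dynamics are generated from the key
  edges alone. The plant is meaningful only under this concentration: if
  distractor edges carried substantial weight the full matrix would describe
  different dynamics and no thresholding analysis could preserve the fit.
* **Gene screens** — decoy genes are i.i.d. log-normal (σ = 0.5) across
  regions; each planted gene's vector is the one actually used to modulate
  the connectome when generating its paired dataset.
* **Regulatory networks** — scale-free-ish directed graphs; planted hubs are
  wired so ~80% of a 15-neighbor neighborhood falls in the candidate set.

Desk-scale defaults are 40 regions, 2 time points and ~50 genes; sizes are
configuration fields, so full-scale profiles (hundreds of regions,
thousands of genes) are reachable by overriding them. All generators are
pure functions of their seed.

### What the synthetic data does not emulate

The generator draws edges independently (no community or hub structure
beyond hemisphere blocks), uses spatially independent expression and noise
(real gene expression and measurement error are spatially correlated), and
makes the forward model exactly correct up to observation noise. Passing
tests therefore demonstrate that the pipeline recovers what it assumes —
correctness of the machinery, identifiability under realistic noise and
sparsity — not that the model is adequate for any particular real dataset.
Real-data effect sizes (per-gene Ave. CCC gains, null percentiles) depend on
the real connectome and atlas and are not reproduced here.

## Numerical choices and limitations

* Matrix exponentials are computed dense (`scipy.linalg.expm`), stepping
  through sorted times via the semigroup property; adequate to a few hundred
  regions.
* The independent ODE oracle integrates the same generator with an explicit
  high-order Runge–Kutta method (rtol `1e-10`); closed-form and integrated
  solutions agree to relative `1e-6` on instances up to 50 regions.
* Column-sum-zero checks use tolerance `1e-10` relative to the largest
  column strength; tiny negative round-off in predictions (> −1e-12) is
  clipped to zero.
* Acceptance-style experiments use scaled problem sizes chosen as desk-scale
  study conditions: 50 noisy-recovery replicates, 100 null replicates per
  null family, a 51-gene screen with a 100-draw bootstrap.
* Known limitations: no degeneration/atrophy term, no cell-type-density
  covariates, group-averaged burdens only (no per-animal hierarchy), and
  expression is baseline (pre-injection) — disease-stage expression changes
  are outside the model.
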