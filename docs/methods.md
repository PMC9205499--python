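# Methods

## Model

`netdnv` tests, gene by gene, whether the count of damaging de novo variants
(DNVs) observed in a trio cohort exceeds the mutational background, while
borrowing strength across genes that interact in a protein–protein
interaction (PPI) network.

**Latent labels.** Each gene *i* has a label S_i ∈ {−1, +1} (non-risk /
risk). On an undirected network G = (V, E) with degrees d_i and weights
w_i = √d_i, the joint prior is a nearest-neighbor Gibbs measure

    P(S | θ0) ∝ exp{ h Σ_i I₁(S_i)
                     + τ0 Σ_{<i,j>∈E} (w_i + w_j) I₋₁(S_i) I₋₁(S_j)
                     + τ1 Σ_{<i,j>∈E} (w_i + w_j) I₁(S_i) I₁(S_j) }.

`h` sets the marginal association rate of an isolated gene
(P = sigmoid(h)); τ0 and τ1 ≥ 0 reward edges whose endpoints agree on the
null / risk label respectively. The √degree weighting lets hub genes exert
(and receive) proportionally more prior influence. The full conditional of
one label is exactly logistic,

    logit P(S_i = +1 | S_{N_i}) = h + τ1 X_i1 − τ0 X_i0,
    X_is = Σ_{k∈N_i} (w_i + w_k) I_s(S_k),

which the test suite verifies against brute-force normalization of the joint
measure on all small networks. In no-network mode all w_i = 0 and the model
collapses to an independent two-group mixture.

**Counts.** Given the label, the DNV count of gene *i* in N trios is
Poisson: Y_i | S_i = −1 ~ Pois(2 N μ_i) and Y_i | S_i = +1 ~ Pois(2 N μ_i γ),
where μ_i is the per-gene mutability for the damaging variant class (per
haploid genome per generation, taken as known input) and γ ≥ 1 is a single
shared relative risk. One variant class is modeled; per-class relative risks
are out of scope.

## Estimation

The marginal likelihood is intractable, so the hyperparameters are estimated
by maximizing the pseudo conditional likelihood

    PCLK = Π_i f(Y_i | S_i, γ) · P(S_i | S_{N_i}, θ0)

with a blockwise ascent (one iteration = three steps):

1. **θ0 given S** — the conditional is a logistic regression of I(S_i = +1)
   on (1, X_i1, −X_i0). A ridge penalty λ(h² + τ0² + τ1²) keeps the maximum
   finite when the labels are separable. Solved by damped Newton–Raphson
   (backtracking line search) with an active-set treatment of the τ ≥ 0
   bounds; covariate columns that are identically zero (no-network mode) are
   dropped and their τ reported as 0. With λ = 0 and separated labels the
   fit raises an error instead of returning a diverged iterate.
2. **S given (θ0, γ)** — one iterated-conditional-modes sweep in fixed
   lexicographic gene order with immediate updates. Each gene takes the
   state maximizing emission × own conditional × the product of its
   neighbors' conditionals re-evaluated at the candidate state; ties resolve
   to −1.
3. **γ given S** — closed form γ̂ = Σ_{S_i=1} Y_i / Σ_{S_i=1} 2 N μ_i,
   clipped below at 1 (γ < 1 would contradict the model's reading of risk
   genes). If no gene is labeled +1, γ keeps its previous value and a
   warning flag is set.

Iteration stops when the labels are unchanged over a sweep **and** the
maximum relative change of (h, τ0, τ1, γ) is below `tol` (default 1e−4), or
after `max_iter` = 100 iterations (then `converged=False` is returned, not an
exception). The PCLK is traced per iteration; steps 2–3 increase it by
construction and step 1 maximizes a penalized version of its prior factor,
so the trace is non-decreasing up to tolerance-level wiggle — monitored by a
test rather than assumed.

Defaults and rationale:

- `lambda_ridge = 0.1`. Small enough to leave the three coefficients
  essentially unpenalized at n ≥ a few hundred genes (the fit on true labels
  moves by < 0.05 between λ = 0 and λ = 0.1) while guaranteeing existence.
  Sensitivity over λ ∈ {0.01, 0.1, 1} is part of the test surface.
- Initial labels: S_i = +1 where the exact Poisson upper-tail p-value of
  Y_i is < 0.01, else −1. Alternatives: a user-supplied seed-gene list, or
  `n_random_starts` sparse random starts keeping the best final PCLK —
  useful because coordinate ascent can stop in local maxima.
- γ init = e³, the low end of the relative-risk range the method targets.
- τ ≥ 0 is enforced by default (the prior reads the τs as affinities); an
  `nonneg=False` flag exposes the unconstrained fit for cross-checks.

## Posterior inference and FDR control

At the fitted (θ̂0, γ̂) a systematic-sweep Gibbs sampler draws S | Y; the
local fdr q_i = P(S_i = −1 | Y) is estimated by averaging the
full-conditional probability of the null state at update time
(Rao-Blackwellized — unbiased for the same marginal as the indicator
frequency but with visibly smaller Monte-Carlo variance at the default 5,000
sweeps / 2,000 burn-in; guidance minimum 2,000 sweeps / 1,000 burn-in).
The sampler is bit-reproducible given a seed.

Since global FDR equals the expected local fdr over the rejection set, genes
are sorted by q ascending (ties broken by gene identifier) and the m
smallest are rejected, with m the largest s whose running mean of the s
smallest q values is ≤ α. One stated description of this rule sorts q
"descending"; with the cumulative-mean criterion only the ascending
convention rejects the most likely risk genes and controls FDR, so ascending
is implemented and the discrepancy is noted here rather than silently
resolved. Reported candidate genes must additionally carry at least
`min_count` = 1 observed DNV, because network coupling alone can pull in
zero-count genes that are not actionable as sequencing findings.

## Network construction

Edge lists follow the STRING convention (integer confidence 0–1000; 400 =
medium, 950 ≈ highest). Filtering keeps edges with score ≥ threshold
(a `strict` flag switches to >, needed because seed-neighbor expansion uses
"score > 950"). The seed subnetwork is: seed genes plus their direct
neighbors connected by an edge scoring > 950, intersected with the genes
present in the count data; by default the induced subgraph keeps **all**
base-network edges among retained genes (whether only high-confidence edges
should survive is genuinely ambiguous, so a flag exposes the stricter
alternative). Gene identifiers are opaque case-sensitive strings; no
symbol/alias resolution is attempted. All sweep and output orders are
lexicographic for reproducibility.

## Synthetic-data generator

A replicate consists of:

- **Network**: Barabási–Albert preferential attachment on `n_genes` nodes
  (or any user edge list). The attachment parameter defaults to m = 1.
  This is a deliberate calibration to the study conditions: with √degree
  weights and h = −4, denser attachment makes the prior supercritical — at
  m = 5 a single Gibbs draw percolates to *every* gene being a risk gene for
  any τ1 ≥ 0.1, leaving no null genes, so FDR and power would be undefined.
  At m = 1 the τ1 grid 0.1–0.9 yields risk fractions of roughly 2–44%,
  bracketing the sparse-risk regime (roughly 3–18% of genes) the reference
  design reports. The cost is a tree topology, which under-represents the
  cliques and triangles of real PPI networks; an edge-list input path
  preserves fidelity when a real network is available.
- **Mutabilities**: log10 μ ~ Normal(−5.7, 0.6) truncated to
  [1e−8, 1e−4], giving null expected counts of order 0.01–0.1 per gene at
  cohort sizes of a few thousand trios — the rare-DNV regime. Real
  mutabilities correlate with gene length and sequence context; the
  generator treats them as exchangeable, so tests say nothing about
  length-driven confounding.
- **Labels**: one Gibbs draw from the MRF prior (default 5,000 sweeps,
  2,000 burn-in, from the all-null state).
- **Counts**: independent Poisson draws given the labels, γ = e^β.

Defaults: h = −4, τ0 = 0 (the reference design varies only h and τ1 and
never states τ0), τ1 = 0.5, β = 3.5, N = 5,000, 100 replicates. All
randomness flows from one seed through named substreams (network,
mutability, labels, counts, posterior sampler), and the truth substreams do
not depend on N or β — so replicate truths are paired across cohort-size and
effect-size grids, which removes most between-setting Monte-Carlo variance
from power comparisons.

The study harness scores each method per replicate with
power = TP / #true risk genes and FDP = FP / max(1, #rejections), and
reports across-replicate means and standard errors. Built-in comparators:
the network-coupled model, the same model with all weights zero, and the
exact Poisson upper-tail test with Benjamini–Hochberg adjustment. A
replicate where a fit fails is recorded with a failure flag (metrics NaN),
never dropped silently.

What passing these simulations does *not* show: robustness to a misspecified
network (edges unrelated to truth), to mutability error, or to relative risk
varying across genes — the generator draws from the fitted model's own
family.

## Enrichment preflight

Before trusting network coupling, check that the candidate genes are more
interconnected than chance: observed within-set edge count versus
`n_perm` uniform same-size gene sets, p = (1 + #{null ≥ obs}) / (1 + n_perm)
(add-one estimator, so p > 0 always), with the null's 95th percentile as the
baseline curve over top-k ranked genes. The sampling pool defaults to all
network nodes; a flag restricts it to genes with count data, because the
pool choice changes the null and should be explicit. Degree-preserving
rewiring nulls are not implemented.

## Numerical choices and degenerate inputs

- Sigmoids are evaluated with ±35 logit guards; log-sigmoids via log1p.
- Poisson pmf/sf come from scipy; no hand-rolled tail sums outside tests.
- Sweep order is lexicographic everywhere (ICM, Gibbs, file output).
- Empty networks, isolated genes (w = √0 = 0), all-null label vectors, and
  zero-count risk sets (γ̂ clipped to 1) are all defined, tested paths.
- Gibbs kernels are numba-compiled; sub-seeds are derived from numpy
  `SeedSequence` and masked below 2³¹.

## Known limitations

- Results depend on the chosen network and its confidence threshold; the
  package provides no way to rank candidate networks.
- The method targets early-onset disorders with a strong DNV signal; for
  small relative risks or small cohorts the label update can stay all-null
  (a "weak signal" warning is emitted) and the estimates are unreliable.
- Point estimates of hyperparameters ignore their uncertainty (no fully
  Bayesian treatment), and coordinate ascent can stop in local maxima —
  hence the seed-gene and multi-start initialization options.
- A single γ shared across genes loses power when relative risk differs by
  variant class or gene.
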