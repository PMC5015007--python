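# Methods

## The model

For every unordered pair of human proteins *(i, j)* the true physical
interaction status `Z_ij ∈ {0,1}` is a latent variable, as is the
self-activation status `X_i ∈ {0,1}` of each protein; both carry
independent Bernoulli priors, `Pr[Z_ij=1] = ρ` and `Pr[X_i=1] = r`.
Observed evidence is modelled conditionally on `(Z, X)`:

* **Y2H.** A yeast two-hybrid replicate reports positive if at least one
  of three mechanisms fires: a true interaction (probability `α_I` when
  `Z_ij=1`), self-activation (`α_S` per self-activating partner), or an
  unknown process (`α_U`):

  `Pr[Y_ij=1 | Z, X] = 1 − (1−α_I)^Z_ij (1−α_S)^(X_i+X_j) (1−α_U)`.

  The exponent `X_i + X_j` treats each self-activating partner as an
  independent trigger; an alternative reading collapses it to the
  indicator `1[X_i+X_j>0]` and is available through the
  `self_activation="indicator"` switch (both readings appear in the
  literature; the exponent form is the package default because it is the
  form the complete likelihood factorizes in).

* **MPC.** A pull-down complex for bait *k* captures each 1-step
  neighbour of the bait (under the current `Z` graph) with probability
  `ψ1` and each 2-step neighbour with `ψ2`.  Observed members at distance
  ≥ 3 (or unreachable) receive a fixed background capture probability
  `ψ_bg = 10⁻³` and unobserved distant proteins contribute no factor:
  this keeps the likelihood finite and local without a product over the
  whole proteome.  `ψ_bg` is a nuisance constant, not estimated.

* **Literature.** Two report channels H and L are Bernoulli filters of
  the truth with true/false positive rates `(γ1, γ0)` and `(β1, β0)`;
  identifiability under label switching is restored by enforcing
  `rate_pos > rate_neg` after each M-step.

* **Cross-organism transfer.** Orthologous pairs in another organism have
  their own latent state `(Z*, X*)` with their own Y2H/MPC evidence,
  coupled to the human state by
  `Pr[Z*=1|Z] = φ1^Z φ0^(1−Z)` and `Pr[X*=1|X] = λ1^X λ0^(1−X)`.
  A joint sequence identity for a pair of ortholog pairs is defined as
  the geometric mean of the two pairwise identities.  The default
  transfer parameterization is constant (identity-independent), matching
  the factorized likelihood; a logistic variant
  `expit(logit(φ_c) + slope·(J−0.5))`, monotone in identity, is exposed
  on `transfer_prob` for sensitivity analyses but is not used by the
  sampler.

Self-pairs (homodimers) are excluded throughout; evidence on `i = j` is
dropped with a logged warning.

## Inference

Parameters are estimated by Monte Carlo EM.  The E-step runs a
systematic-scan Gibbs sampler over all latent variables; each `Z_ij` is
resampled from its full conditional, which combines the prior, the pair's
Y2H replicate counts, both literature channels, transfer factors to its
starred counterparts, and the complex factors of every bait whose 1-/2-step
neighbourhood the toggle can change.  That last set is exactly the baits
equal or adjacent to `i` or `j`; the sampler maintains an adjacency matrix
and a common-neighbour-count matrix so the neighbourhood class of any
(bait, protein) entry is an O(1) lookup and an edge toggle costs O(n).

The M-step maximizes the Monte Carlo Q-function.  Components with
conjugate Bernoulli structure (ρ, r, γ, β, φ, λ) use closed-form ratio
estimators of the expected counts; `(α_I, α_S, α_U)` are maximized jointly
and `ψ1, ψ2` coordinate-wise by greedy hill climbing with step halving
from 0.1 down to 10⁻⁴, accepting only improving moves.  All components
are clipped to `[10⁻⁶, 1−10⁻⁶]` to keep the Gibbs conditionals proper.

Iteration stops when `diff`, the maximum absolute componentwise change in
θ, falls below the tolerance (default 0.01), or at `max_iter`.  Retained
sample counts grow linearly across EM iterations (default
`100·(1+iteration)` after a 50-sweep burn-in, the standard
increasing-precision MCEM practice; the schedule is a parameter).  The
default initialization is weakly informative and interior: ρ=0.005,
r=10⁻⁴, α_I=0.5, α_S=0.3, α_U=0.01, ψ1=0.7, ψ2=0.3, and (0.7, 0.05) for
every report/transfer rate pair.  The chain is warm-started across EM
iterations; final posteriors `Pr[Z_ij=1 | all evidence]` come from a
fresh scoring chain at the fitted θ.

Per-source parameter overrides are honoured by the reference likelihood
(`ppibayes.likelihood`); the sampler assumes shared parameters and
refuses overrides rather than silently ignoring them.

`exact_posterior` enumerates all latent configurations through the
reference likelihood (capped at 20 binary variables) and is the
brute-force oracle for the sampler in the test suite; the two code paths
share no inference code.

## Network, modules, enrichment

Pairs with posterior strictly greater than τ = 0.8 form the
high-confidence network, weighted by the posterior; proteins with no kept
edge are dropped (a flag retains them).  SCAN clusters the network using
the structural similarity
`σ(u,v) = |Γ(u)∩Γ(v)| / sqrt(|Γ(u)||Γ(v)|)` over closed neighbourhoods:
a node is a core if at least μ = 2 neighbours are ε-similar, clusters are
the structure-reachable sets grown from cores in sorted node order
(making the output independent of edge order), and unclustered nodes
adjacent to ≥ 2 clusters are hubs, the rest outliers.  Posterior edge
weights deliberately play no role in σ — module detection is purely
topological.

ε is selected by sweeping a grid (default 0.05–0.95, step 0.01) and
maximizing the similarity-based modularity
`Q_S = Σ_s [IS_s/TS − (DS_s/(2TS))²]`, the similarity-weighted analogue of
Newman modularity `Q_N = Σ_s [l_s/L − (d_s/(2L))²]`; ties break toward the
smallest ε.  Hubs and outliers enter both formulas as singleton modules so
that every partition covers the graph.

Each module of size *n* with *m* intrinsically disordered proteins
(IDPs: longest continuous disordered region strictly greater than 40 aa)
is tested against the clustered network background (*N* proteins, *M*
IDPs) with the hypergeometric upper tail
`p = Σ_{i=m}^{min(n,M)} C(M,i)C(N−M,n−i)/C(N,n)`; the background is the
clustered network rather than the full universe because modules are drawn
from it.  Raw p-values are compared with α = 0.05 (no multiplicity
correction by default; Benjamini–Hochberg is available behind a flag).
Hub composition uses the module-induced subgraph: a hub is a node with
strictly more than 5 neighbours inside the module.

## The simulator

The generator draws ground truth and all four evidence types from the
model itself: `Z ~ Bernoulli(ρ)` (optionally with planted dense
communities at an elevated within-community edge probability), Y2H
replicates through the three-mechanism response, complexes by independent
capture of 1-/2-step neighbours of baits drawn uniformly from proteins
with at least one true neighbour, literature channels as Bernoulli
filters, and starred organisms by one-ortholog-per-protein transfer with
identities uniform on [0.3, 1.0] (a range that spans the informative part
of the logistic transfer curve).  Disorder annotations plant an elevated
IDP frequency (default 0.9) inside designated communities against a
background rate of 0.375, giving the enrichment stage a known positive
control; IDP lengths are uniform on 41–300 aa, non-IDP on 0–40 aa.

Default generating parameters take published integrated-corpus estimates
where such estimates exist (ρ=0.014, r=8.9×10⁻⁵, α_I=0.933, α_S=0.852,
α_U=0.007, ψ1=0.738–0.809 depending on corpus — the default uses 0.809 —
ψ2=0.788) and plausible interior values for the unreported report and
transfer rates (γ=(0.8, 0.01), β=(0.7, 0.02), φ=λ=(0.7, 0.05)).
Everything is seeded; identical configuration and seed give byte-identical
output files.

What the simulator does *not* emulate: the heavy-tailed degree
distribution of real interactomes, study-specific coverage biases,
correlated errors between databases, and contamination of complexes by
abundant sticky proteins (`ψ_bg` exists in the likelihood but distant
contaminants are not generated).  Passing tests therefore demonstrate
correctness of the inference under the model's own assumptions, not
robustness to their violation on real data.

## Problem sizes and numerical choices

The bundled studies use 500 proteins (124 750 pairs, full evidence) for
parameter recovery and the evidence-integration comparison, a 220-protein
network with eight planted 14-member communities (two IDP-rich) for the
end-to-end pipeline, and 4-protein instances for exact-enumeration
cross-checks; the EM schedule for these studies is burn-in 30 with
60 + 40·iteration retained sweeps (capped at 300) and 300 scoring sweeps.
Log-space guards clip probabilities at 10⁻¹² before taking logs, and
conditional log-odds beyond ±35 are treated as certain.  Degenerate ratio
estimators (for example a channel whose sampled `Z` values are all 1)
fall back to clipping at `1−10⁻⁶`; components with no supporting evidence
keep their previous value, so single-source fits leave the other
components at their initialization.

## Known limitations

* The complete likelihood treats complexes as independent given `Z`;
  repeated pull-downs of the same bait are modelled as independent draws.
* Posterior scores for pairs with no evidence shrink to ρ; at realistic ρ
  they can never pass τ = 0.8, so recall is bounded by evidence coverage.
* The Gibbs sampler assumes shared parameters across sources; per-source
  rates are representable in the data model but not learned.
* `Q_S` normalization follows the similarity-weighted Newman form; other
  normalizations of the degree term would shift the curve but rarely the
  argmax.
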