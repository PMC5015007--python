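# ppibayes

Hierarchical Bayesian integration of heterogeneous protein–protein
interaction (PPI) evidence into per-pair interaction confidences, with
downstream module detection and disorder enrichment.

High-throughput interaction data are noisy and heterogeneous: yeast
two-hybrid (Y2H) screens suffer self-activation artefacts, mass-spec
pull-downs (MPC) report complexes rather than direct contacts, literature
curation has its own false positive and negative rates, and much of what we
know about human proteins is transferred from orthologs in other
organisms.  `ppibayes` treats the true interaction status of each human
pair as a latent Bernoulli variable `Z_ij` and models every evidence type
conditionally on it:

* Y2H replicate: `Pr[Y=1 | Z,X] = 1 − (1−α_I)^Z (1−α_S)^(X_i+X_j) (1−α_U)`,
  where `X_i` flags self-activating proteins;
* pull-down complex for bait *k*:
  `ψ1^|n¹∩C| (1−ψ1)^|n¹∖C| ψ2^|n²∩C| (1−ψ2)^|n²∖C|` over the bait's 1- and
  2-step neighbourhoods under `Z`;
* literature channels: `Pr[report=1 | Z] = γ1^Z γ0^(1−Z)` (and `β` for the
  second channel);
* ortholog transfer: `Pr[Z*=1 | Z] = φ1^Z φ0^(1−Z)`, with starred organisms
  carrying their own Y2H/MPC evidence.

Parameters θ = {ρ, r, α_I, α_S, α_U, ψ1, ψ2, γ1, γ0, β1, β0, φ1, φ0,
λ1, λ0} are estimated by Monte Carlo EM with a Gibbs-sampling E-step and a
hybrid closed-form / hill-climbing M-step.  Pairs with posterior
`Pr[Z_ij=1 | evidence] > 0.8` form a weighted high-confidence network,
which is clustered by SCAN with the threshold ε chosen by maximizing
similarity-based modularity `Q_S`; each module is then tested for
enrichment of intrinsically disordered proteins (IDPs, disordered region
longer than 40 aa) with the hypergeometric upper tail.  See
`docs/methods.md` for the full model, estimation details, and limitations.

A seeded simulator generates ground truth and all four evidence types
from the same generative model (with optional planted communities and
planted IDP enrichment), so every stage of the pipeline is testable
without external databases.

## Worked example

```python
from ppibayes import (ParameterVector, simulate_dataset, fit,
                      threshold_network, select_epsilon,
                      DisorderAnnotation, test_modules)
from ppibayes.mcem import MCEMSchedule
from ppibayes.simulate import SimulationConfig

cfg = SimulationConfig(n_proteins=220,
                       community_sizes=(14,) * 8, n_idp_communities=2,
                       rho_within=0.7, seed=23)
sim = simulate_dataset(cfg)

res = fit(sim.evidence, seed=5,
          schedule=MCEMSchedule(burnin=30, base=60, step=40, cap=300,
                                score_samples=300))
print(res.converged, round(res.theta_hat.alpha_I, 3))

net = threshold_network(res.posterior, tau=0.8)
grid = [round(0.05 + 0.01 * k, 2) for k in range(91)]
best_eps, parts, qn, qs = select_epsilon(net, grid)
part = parts[grid.index(best_eps)]
print(best_eps, part.n_modules())

ann = DisorderAnnotation.from_frame(sim.disorder)
sig = [r for r in test_modules(part, ann, alpha=0.05) if r.significant]
print([(r.module, r.n, r.m, round(r.p_value, 6)) for r in sig])
```

Output (default generating parameters for the unlisted components):

```
True 0.936
0.36 15
[(1, 15, 14, 0.000291), (2, 23, 19, 0.000639)]
```

The fit converges and recovers the Y2H true-interaction mechanism rate
near its generating value of 0.933; the thresholded network clusters into
15 modules at the `Q_S`-optimal ε = 0.36; and exactly the two modules that
recover the planted IDP-rich communities (14/15 and 19/23 members
disordered) test significant at α = 0.05.

The same pipeline is available from the shell:

```bash
ppibayes simulate --seed 3 --config run.cfg --out sim/
ppibayes fit      --seed 5 --evidence sim/ --out fit/
ppibayes score    --posteriors fit/posteriors.tsv --tau 0.8 --out net/
ppibayes cluster  --edges net/edges.tsv --out clus/
ppibayes enrich   --modules clus/modules.tsv --edges net/edges.tsv \
                  --disorder sim/disorder.tsv --out enr/
ppibayes show-config
```

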