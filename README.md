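# stratmix

Reconstruction of social contact matrices fully stratified by **age,
neighborhood socio-economic position (SEP), and education level** from
partially stratified survey data, with the downstream epidemic analyses
that such matrices enable: basic reproduction number and group
contributions, final-size attack rates, and type-reproduction numbers for
targeted control strategies.

## The problem

Contact surveys record the age, municipality, and education level of each
*participant*, but for the people they met only an age (often a range, or
missing). A transmission model stratified by socio-economic group needs
the full matrix `M̂_{s,t}` of mean contacts between strata
`s = (age i, SEP v, education d)` — 14 non-empty strata once children
(0–14), who are all classified middle-low education, are accounted for.

`stratmix` reconstructs the set of matrices compatible with the observed
data in three steps:

1. **Age matrix.** Estimate the 4×4 age-mixing matrix `M` and correct it
   for reciprocity, `M^rec_ij = (N_i M_ij + N_j M_ji) / 2N_i`, so total
   contact volumes balance (`N_i M^rec_ij = N_j M^rec_ji`).
2. **Intermediate matrix.** Estimate the 14×4 matrix `M̄_{(i,v,d),j}`
   stratified on the participant side only, and rescale it cell-wise so
   its population-weighted aggregation reproduces `M^rec` exactly.
3. **Expansion.** In total-contact units the unknown 14×14 matrix
   decomposes into 10 independent blocks (one per unordered age pair),
   each a transportation polytope: nonnegative tables with fixed row and
   column margins given by `M̄^rec`. The free coordinates — assortativity
   parameters `q ∈ (0,1)` — are sampled uniformly to produce an ensemble
   of matrices, every one of which satisfies reciprocity, aggregation,
   and positivity exactly. The leading coordinate of each block sweeps it
   from its minimal to its maximal cross-level contact volume, so the
   ensemble spans the full assortativity range the data allow.

Mixing along SEP or education is summarized by aggregating a matrix to
2×2 and taking the trace of its row-normalized form: the **assortativity
index** `α ∈ (0, 2)`, with `α = 2` fully assortative (diagonal), `α = 1`
proportional mixing, and `α = 0` fully disassortative (empty diagonal).

For epidemics, a stratified SIR model with force of infection
`λ_s = β σ_s Σ_t M̂_{s,t} I_t / N_t` yields the next-generation matrix
`K_{s,t} = (β σ_s / γ) M̂_{t,s}` with `R0 = ρ(K)`; per-group elasticity
contributions to `R0`; final-size attack rates; and the
type-reproduction number `T_g` from which the critical immunization
fraction `1 − 1/T_g` of a target group `g` and the overall control
effort `(1 − 1/T_g)·N_g/N` follow.

A synthetic-data module generates populations, ground-truth expanded
matrices with controllable assortativity, and surveys that *discard* the
contacts' socio-economic labels — so the whole pipeline is testable
against a known truth without restricted survey data.

## Worked example

```python
import numpy as np
from stratmix import (
    GroundTruthConfig, make_population, make_truth_matrix,
    simulate_survey, sample_ensemble, EpidemicParams,
    attack_rates, calibrate_beta, build_ngm, type_reproduction,
    child_reduced_sigma,
)
from stratmix.matrices import AgeContactMatrix, reciprocity_correct
from stratmix.synthetic import run_reconstruction, truth_assortativity
from stratmix.groups import GROUP_KEYS

# a known world: moderate assortativity along both social dimensions
cfg = GroundTruthConfig(w_sep=0.3, w_edu=0.3, seed=1)
pop = make_population(cfg)
base = reciprocity_correct(AgeContactMatrix(cfg.base_age_matrix), pop)
truth = make_truth_matrix(pop, base, cfg.w_sep, cfg.w_edu)

# a survey that hides the contacts' SEP and education
survey = simulate_survey(truth, pop, n_per_stratum=2000, seed=1)
ds, M_rec, bar_rec = run_reconstruction(survey, seed=2)

# the ensemble of expanded matrices compatible with the survey
matrices, summary = sample_ensemble(bar_rec, pop, n=500, seed=3)
print(f"true assortativity: {truth_assortativity(truth)}")
print(f"ensemble alpha_sep range: [{summary.alpha_sep.min():.3f}, {summary.alpha_sep.max():.3f}]")
print(f"ensemble alpha_edu range: [{summary.alpha_edu.min():.3f}, {summary.alpha_edu.max():.3f}]")
print(f"R0 inflation vs homogeneous mixing: "
      f"{100*(summary.eigen_ratio.min()-1):.2f}% to {100*(summary.eigen_ratio.max()-1):.2f}%")

# epidemic analysis of one ensemble member at R0 = 1.5, infectious
# period 3 days, children half as susceptible
sigma, gamma = child_reduced_sigma(0.5), 1/3
hat = matrices[0]
beta = calibrate_beta(hat, sigma, gamma, 1.5)
params = EpidemicParams(beta, gamma, sigma, 1.5)
z = attack_rates(hat, params)
K = build_ngm(hat, params)
high_sep = tuple(k for k in GROUP_KEYS if k.sep == "high")
res = type_reproduction(K, high_sep, pop)
print(f"attack rate, young adults with low SEP and high education: {100*z[3]:.1f}%")
print(f"targeting the high-SEP group: T_g = {res.t_g:.3f}, "
      f"critical fraction {100*res.critical_fraction:.1f}%, "
      f"overall effort {100*res.overall_effort:.1f}%")
```

prints

```
true assortativity: {'sep': 1.2356425421232986, 'edu': 1.2407554861872319}
ensemble alpha_sep range: [0.962, 1.789]
ensemble alpha_edu range: [0.934, 1.573]
R0 inflation vs homogeneous mixing: 1.69% to 3.71%
attack rate, young adults with low SEP and high education: 56.6%
targeting the high-SEP group: T_g = 1.751, critical fraction 42.9%, overall effort 29.6%
```

Both true assortativity values fall inside the reconstructed ranges: the
survey, which never reveals the contacts' socio-economic attributes,
still pins mixing down to an identifiable band. Heterogeneous mixing
raises `R0` relative to the age-only (homogeneous) expansion for every
ensemble member. Under this particular mixing realization, immunizing
42.9% of the high-SEP group — 29.6% of the whole population — is enough
to halt an epidemic with `R0 = 1.5`.

## Command line

The same pipeline is scriptable:

```bash
stratmix all --out-dir runs/demo --seed 0            # simulate → … → control
stratmix validate --matrix runs/demo/expand/expanded_example.csv \
    --population runs/demo/survey/population.csv --kind expanded \
    --intermediate runs/demo/matrices/intermediate_rec.csv
```

`all` chains `simulate`, `preprocess`, `matrices`, `expand` (1,000-matrix
ensemble by default), `epidemic` (attack rates and `R0` contributions,
median and 2.5/97.5 percentiles across the ensemble, for the homogeneous
and reduced-child-susceptibility scenarios) and `control`
(type-reproduction feasibility, success probability, and effort ranges
for SEP, education, and joint targets). Every stage accepts a YAML config
(`--config`) and writes metadata sidecars with seeds and input hashes.

## Layout

```
src/stratmix/
  groups.py      strata, age bounds, population table
  preprocess.py  survey loading, truncation, age imputation, SEP split,
                 crude means with bootstrap CIs
  matrices.py    age matrix, intermediate matrix, reciprocity corrections
  expansion.py   block solvers, q-parameterized ensembles, assortativity
  epidemic.py    SIR, NGM, elasticities, attack rates, type reproduction
  synthetic.py   population/truth/survey generators, recovery harness
  validate.py    standalone matrix constraint validation
  io.py          matrix CSV + metadata round-tripping
  cli.py         the `stratmix` command
docs/methods.md  model assumptions, parameter defaults, design notes
```
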