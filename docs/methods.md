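# Methods

## Strata

The population is stratified by age group (0–14, 15–24, 25–64, 65+),
neighborhood socio-economic position (SEP: low / high), and education
level (middle-low / high). Education is an individual attribute; SEP is
an area attribute attached to a participant through the building-weighted
mean SEP index of their municipality of residence, dichotomized at a
median. Children are all classified middle-low education, so two of the
sixteen nominal strata are empty and the analysis runs on 14 strata in a
fixed canonical order (age-major, SEP low before high, education
middle-low before high).

## Survey preprocessing

* **Contact-age reports** may be an exact age-group label, a year range
  (possibly spanning two groups, e.g. "0-18"), an open range ("70+"), a
  single year, or missing. Ranges lying inside one group resolve
  immediately; genuinely ambiguous or missing reports are imputed from
  the empirical age distribution of age-known contacts of participants in
  the same age group — restricted to the groups a reported range overlaps
  and renormalized. If a participant age group has no age-known contacts
  at all, the pooled distribution over all participants is used and a
  warning is logged; a range with zero empirical mass falls back to
  uniform weights over the range. Imputation conserves each participant's
  contact count and never assigns a group outside a reported range.
* **Truncation.** Individual contact counts are heavy-tailed; effective
  counts are capped at 50 contacts per participant. When a participant
  exceeds the cap, the first 50 contacts in file order are retained — a
  deterministic, auditable rule — and dropped rows remain in the table
  flagged `retained=False`. The cap applies to all downstream analyses
  (crude means and matrix estimation alike); a different cap, or
  effectively none (`--cap 10000`), is one flag away.
* **SEP split.** Municipality-level SEP is the resident-weighted mean of
  building-level SEP indices. The low/high threshold is the median over
  the municipality-level values (one value per municipality in the
  table); municipalities at or below the median are low. A
  participant-weighted median was considered and rejected: it forces a
  ~50/50 participant split regardless of the population's actual SEP
  composition, which contradicts a generator (or survey design) whose
  low/high sampling fractions differ.
* **Crude group means** are per-stratum means of effective counts with
  95% percentile-bootstrap confidence intervals over 1,000 resamples of
  participants (resampling within stratum, independently per stratum).
  Empty strata are reported with n = 0 and null means.

## Matrix estimation

The raw age matrix `M_ij` is the mean number of retained contacts that a
participant in age group `i` reports with age group `j`. Reciprocity is
enforced by `M^rec_ij = (N_i M_ij + N_j M_ji) / 2N_i` with census
populations `N_i`; this is the unique correction that preserves the total
contact volume while making `N_i M^rec_ij` symmetric. No participant
re-weighting toward census demography is applied — demography enters only
through the `N_i` in the correction — and no weekday/weekend adjustment
is made.

The intermediate matrix `M̄_{(i,v,d),j}` is the analogous per-stratum
estimate (14×4). Its reciprocity adjustment multiplies all subgroup
entries of each (participant-age, contact-age) cell by
`M^rec_ij / A_ij`, where `A_ij` is the population-weighted aggregate of
the raw entries: the minimal change that makes aggregation to `M^rec`
exact while preserving the within-cell contact proportions across
(SEP, education) subgroups. Zero aggregate mass in a cell whose target is
positive is an error rather than silently filled.

## Expansion to the full matrix

In total-contact units `T_{s,t} = N_s M̂_{s,t}`, reciprocity makes `T`
symmetric and aggregation fixes, for every unordered age pair `(i, j)`,
the row sums `R_a = N_a M̄^rec_{a,j}` (subgroups `a` of `i`) and column
sums `C_b = N_b M̄^rec_{b,i}` of the corresponding block. Each of the 10
blocks is therefore a transportation polytope — symmetric tables for the
four same-age blocks — and blocks are mutually independent. Degrees of
freedom: `m(m-1)/2` for a symmetric `m×m` block, `(m-1)(n-1)` otherwise;
55 in total for the 14-strata layout.

Each block's solution set is parameterized by coordinates `q ∈ [0,1]`
over an ordered canonical basis of margin-preserving directions:

1. the **SEP tilt**, **education tilt**, and **joint tilt** — directions
   of the form `T0 ∘ (S − u_a − v_b)`, where `T0` is the independence
   table (`R_a C_b / ΣR`), `S` indicates cross-level cells, and the
   offsets `u, v` solve a small linear system zeroing the margins.
   Weighting by `T0` makes these multiplicative mass transfers: a single
   tilt coordinate moves the block from its minimal to its maximal
   cross-level contact volume (verified against per-block linear programs
   in the test suite's brute-force checks for 2×2 blocks, and against LP
   bounds during development);
2. pairwise ±1 exchange matrices (symmetrized on diagonal blocks),
   Gram-Schmidt-orthogonalized against the tilts, completing the basis.
   Numerically vanishing tilts (e.g. the education tilt of blocks
   involving children, who have a single education level) are dropped
   before completion, so the basis dimension always equals the null-space
   dimension.

Coordinates are drawn **sequentially**: each `q_k` is uniform over the
exact feasibility interval of its direction conditional on the
coordinates already fixed. Every draw therefore satisfies positivity and
the margins exactly — no rejection step is needed beyond a numerical
safeguard — and the per-capita matrix `M̂_{s,t} = T_{s,t}/N_s` assembled
from the 10 blocks satisfies reciprocity, aggregation, and positivity to
better than 1e-9 relative (validated per matrix). An affine
box-with-rejection parameterization around the independence table was
implemented first and discarded: its accepted draws concentrate tightly
around proportional mixing (a 500-draw ensemble spanned barely a third of
the feasible assortativity interval), which defeats the purpose of
exploring the mixing patterns the data cannot distinguish.

A reproducible ensemble (`sample_ensemble`, default 10,000 matrices,
1,000 in the CLI pipeline) records for each member the assortativity
index along both social dimensions and the dominant-eigenvalue ratio
against the homogeneous expansion.

## Assortativity index

A 14×14 matrix is aggregated to 2×2 along one dimension by summing
contacted strata sharing a level and averaging participant strata sharing
a level with population weights. The index is the trace of the
row-normalized aggregate: 2 for a diagonal matrix, 1 for rows
proportional to contacted-group size, 0 for an empty diagonal. It is
invariant to positive rescaling and depends only on contact proportions.

One compositional subtlety is worth stating explicitly. The homogeneous
expansion (contacts proportional to subgroup size *within each age
group*) scores exactly 1 in the SEP dimension, whose low/high composition
is the same in every age group, but about 1.04 in the education
dimension: children are all middle-low education, ages mix assortatively,
and the education composition of a group's contacts therefore varies with
the group's own age mix. This is a real property of proportional mixing
under compositional heterogeneity, not an artifact; ensemble comparisons
in the education dimension should be read against the homogeneous
expansion's own index value, which the pipeline computes, rather than
against 1.

## Epidemic model

A stratified SIR model with force of infection
`λ_s = β σ_s Σ_t M̂_{s,t} I_t/N_t`; parameters:

* `γ` — recovery rate, default 1/3 per day (3-day infectious period);
* `β` — transmission rate per contact per day, calibrated per matrix so
  that `ρ(K) = R0`, default target `R0 = 1.5`;
* `σ_s` — relative susceptibility in [0, 1], default 1 everywhere; the
  reduced-child-susceptibility scenario sets 0.5 for the 0–14 strata and
  recalibrates `β`.

The next-generation matrix is `K_{s,t} = (β σ_s/γ) M̂_{t,s}` (column =
infector; the transpose convention changes nothing spectrally). Derived
quantities:

* **Elasticity contributions**: `e_{s,t} = v_s K_{s,t} w_t / (ρ ⟨v,w⟩)`
  with `w, v` the right/left dominant eigenvectors; a group's
  contribution to `R0` is its infector-side (column) sum, and
  contributions sum to 1 analytically. The infector-side attribution is a
  convention; the symmetric-case equality and the sum-to-one identity are
  the invariants enforced.
* **Attack rates**: the multigroup final-size system
  `z_s = 1 − exp(−(βσ_s/γ) Σ_t M̂_{s,t} z_t)`, solved by damped
  fixed-point iteration (damping 0.5) from `z = 1`, tolerance 1e-12, cap
  10,000 iterations — converging to the nontrivial branch. Agreement with
  the long-horizon ODE limit to 1e-4 per group is part of the test suite.
* **Type-reproduction numbers**: with `P` the projection onto a target
  set `g`, control through `g` is feasible iff `ρ((I−P)K) < 1`, and then
  `T_g = ρ(P K (I − (I−P)K)^{-1})`. A singular linear system is reported
  as infeasible, not raised. Immunizing a fraction `1 − 1/T_g` of `g` at
  t = 0 (moved from S to R) prevents outbreak growth — verified
  dynamically. The overall effort is `(1 − 1/T_g)·N_g/N`.
* **ODE integration**: adaptive RK45 (`scipy.integrate.solve_ivp`),
  absolute tolerance 1e-9·N, integrating in 200-day chunks until total
  prevalence falls below 1e-9·N; conservation `S+I+R = N` is enforced to
  1e-6·N.

The control report recalibrates `β` per ensemble matrix, evaluates every
target in the SEP-only, education-only, and SEP×education partitions, and
summarizes success probability (feasible fraction of the ensemble) and
effort quantiles over the feasible subset.

## Synthetic data

The generator emulates the structure of a national contact survey:

* **Population** (default 8.7 million): age shares 0.15/0.12/0.53/0.20,
  SEP split 31/69 low/high in every age group, education split 69/31
  middle-low/high among ages 15+ (children all middle-low). The largest
  stratum is then high-SEP × middle-low-education adults. Splits are
  applied independently, so the SEP marginal is exact by construction.
* **Ground truth mixing**: within each age-pair block, total contact
  volume from a reciprocity-corrected base age matrix is distributed by a
  bilinear convex combination of four size-proportional kernels —
  unrestricted, same-SEP, same-education, same-both — with weights built
  from `w_sep, w_edu ∈ [0,1]`. `w = 0` gives proportional mixing in that
  dimension; `w = 1` removes all cross-level contacts (index exactly 2);
  the index is strictly increasing in between. The default base age
  matrix has strong child-child and adult-adult mixing and row sums of
  roughly 6–13 daily contacts, the broad shape of European contact
  surveys.
* **Survey**: participant counts default to 4,462 (3,552 adults plus 910
  minors) allocated proportionally to stratum population; the recovery
  validation uses 2,000 per stratum. Contact counts are Poisson around
  the truth row sum (a negative-binomial shape parameter is available for
  overdispersion, off by default); contact strata are categorical over
  the truth row. Public files carry only the contact's age group, masked
  to missing with probability 0.19; the contacts' true strata and the
  participants' true SEP labels go to a sidecar file the pipeline never
  reads. Municipalities (40, six buildings each) draw building SEP
  indices around two well-separated modes (35 and 65, s.d. 4), so the
  median split recovers the intended labels with probability ≈ 1; the
  mislabeling rate is reported regardless.
* **Recovery harness**: simulate → preprocess → estimate → expand, then
  report the ensemble [min, max] assortativity range per dimension,
  whether it contains the truth, the RMSE of the adjusted intermediate
  matrix against the truth aggregate, and the SEP mislabeling rate.

What passing recovery does and does not show: the generator draws
contact counts from the same family the estimator assumes (independent
reports, no household clustering, no panel-wave or weekday structure, no
reporting bias), so recovery demonstrates the internal consistency of the
reconstruction — margins estimated well, ensemble spanning the truth —
not robustness to the reporting artifacts of real surveys. Equal
per-stratum allocation (used in the validation) is deliberately
non-representative; the resulting aggregation bias in the intermediate
matrix is visible as an RMSE that grows with assortativity yet stays well
inside the reconstructed assortativity band.

## Numerical conventions

Reciprocity and aggregation checks use relative tolerance 1e-9 on
total-contact scales. Spectral radii are `max |eig|` of dense 14×14
matrices. Dominant eigenvectors are sign-normalized to positive sums.
Ties at the SEP median classify as low. All stochastic operations take
explicit integer seeds; identical seeds give byte-identical outputs
(ensemble summaries, survey files), and stage metadata records seeds and
input hashes.

## Limitations

* The two-dimensional SES×SEP expansion is identified only up to the
  ensemble: the data constrain, but do not determine, within-age mixing
  across socio-economic groups.
* The SIR model has no severity, vaccination dynamics, waning, or
  time-varying behavior; "control" is a static immunity fraction at t=0.
* Education of children is structurally middle-low; analyses of targeting
  the high-education group therefore exclude children by construction.
* Survey covariates (household size, wave, weekday) are carried through
  but unused by the estimators; regression-based contact-rate analyses
  are out of scope.
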