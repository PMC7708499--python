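# Methods

## The problem

Sanctuary-housed chimpanzees with atypical early lives (wild-caught, or
predominantly housed without conspecifics during their first five years)
interact with group mates through several qualitatively different channels.
A single edge type — grooming alone, or everything summed into one score —
hides which channels are affected by whom.  The package therefore treats a
group's social structure as a 4-layer multiplex network over the same seven
individuals, one layer per interaction type ordered from low- to high-level
sociability:

| layer | definition | directed? |
|---|---|---|
| stationary vicinity (SV) | beyond arm's reach, within 5 m planar distance, at most one height level apart, not interacting | no |
| affiliative behaviour (AFF) | play, socio-sexual, embrace, follow, ... (grooming excluded) | yes |
| allogrooming (GRM) | cleaning/manipulating a partner's hair or body | yes |
| passive close proximity (PCP) | within an arm's reach, not otherwise interacting | no |

The four states are mutually exclusive per dyad and scan: a grooming pair is
not simultaneously "in proximity", but each animal may hold different states
with different partners at the same scan.

## From scans to indices

The observational unit is one individual's state at one instantaneous scan
(2-minute intervals inside 20-minute sessions; we fix 10 scans per session,
the count implied by that duration and interval).  For an ordered dyad
(A, B),

    index(A -> B, layer) = (# scans the dyad is credited with that layer)
                         / (# scans A and B had access to each other)

Access means both could reach the shared outdoor space — including scans
where one sat indoors and was not visible; it excludes scans where either
was separated (management or veterinary reasons).  Access, not visibility,
defines the denominator, so dyads with different co-presence histories stay
comparable.  SV is computed only from mapped positions: scans without
positions contribute to the denominator but never to SV counts.  Arm's-reach
annotations are taken as the union over both directions (observers record
the pair once).  Directed behaviours count once per scan per direction;
mutual grooming credits both directions.

For multiplex analytics every layer is rescaled by its maximum index across
*both* groups ("weighted" values): each layer then spans [0, 1] and no layer
dominates spectral measures purely by scale.  Model analyses use the raw
proportions.

## Multilayer measures

Layers are directed and weighted; diagonals are zero.  All spectral
computations symmetrise a layer as (A + Aᵀ)/2 — the Laplacian-spectrum
machinery needs a symmetric operator — while densities, strengths and the
dyadic models keep direction.

* **Density**: fraction of possible directed edges with positive weight;
  multiplex density pools the four layers (168 possible edges for a 7-node
  4-layer multiplex).
* **Edge overlap**: Jaccard fraction of shared directed edges between two
  layers' supports (a `min`-normalised variant is available; the choice is a
  convention, stated here because the original raw matrices are not public).
  Global overlap is |intersection| / |union| over all four layers.
* **Von Neumann entropy** of a layer: Shannon entropy (base 2) of the
  symmetrised Laplacian eigenvalues rescaled to unit sum.  Closed forms used
  as tests: a single-edge graph has 0 bits; the complete graph K_n has
  log2(n-1) bits; the value is invariant to multiplying all weights by a
  constant.
* **Quantum Jensen-Shannon distance** between layers: with density operators
  rho = L/tr(L), D = sqrt( h((rho_a+rho_b)/2) - (h(rho_a)+h(rho_b))/2 ),
  a semimetric in [0, 1], zero iff the rescaled Laplacians coincide.
* **Structural reducibility**: Ward agglomerative clustering on the pairwise
  JSD matrix fixes the merge order; following it, the two most similar
  layers are aggregated (summed — entropy's scale invariance makes sum vs
  mean immaterial, which a test asserts) and the relative entropy
  q = 1 - mean(h(layer)) / h(full aggregate) is recorded from L layers down
  to 1 (where q = 0 by construction).  A curve maximal at L layers means no
  layer is redundant.
* **Eigenvector centrality** per layer (and for the aggregate): leading
  eigenvector of the symmetrised matrix, max-normalised to 1.
  **Versatility** couples the four layers through the NL x NL
  supra-adjacency matrix (symmetrised layers on diagonal blocks, a uniform
  categorical coupling omega on every replica pair's diagonal); the leading
  supra-eigenvector's replica entries are summed per node and max-normalised.
  omega defaults to 1.0 and is exposed (`--omega`); rankings are stable over
  a wide omega range but the coupling used by the original software is not
  published.  Dense ranks (ties share a rank) are reported per ring — each
  layer, the aggregate, the multiplex — with rings ordered greedily by
  Spearman correlation starting from the multiplex ring.

## Dyadic mixed models

One row per ordered within-group dyad (N(N-1) per group; 84 for two groups
of seven).  The response is a layer index or the sum of the four
("aggregated"); fixed effects are the three sender->receiver combination
factors — origin (wild/captive), infant housing (with/without), sex (M/F) —
each with four levels and references captive->captive, with->with, F->F.
Random effects: a group intercept, and sender nested within group.

* Full vs null (intercept + same random effects) is a likelihood-ratio test
  on maximum-likelihood fits (chi-squared, 9 df).  The solver is statsmodels
  `MixedLM`; because index responses are numerically tiny the response is
  standardised internally (all reported statistics are scale-invariant;
  estimates are rescaled back), and both fits are polished against the
  profiled ML likelihood so optimizer slack cannot inflate the statistic —
  on reference data the resulting statistic matches lme4 to four decimals.
* Marginal (Type III) F tests per factor use the REML fit with
  Satterthwaite denominator degrees of freedom.  The df machinery is
  implemented here: the variance estimates are polished against the
  profiled REML criterion, the covariance of the variance parameters comes
  from a numerical observed-information matrix, each multi-df test is
  decomposed into independent 1-df contrasts whose Satterthwaite dfs are
  combined as in the standard mixed-model ANOVA approach.  When the
  information matrix is singular (variance components on the boundary) the
  residual df is used and flagged.
* Post hoc: all pairwise level contrasts per factor (Tukey family),
  z = estimate/SE, Holm-Bonferroni adjusted within the factor's family of
  six.
* Collinearity: generalised VIF per factor via the determinant formula on
  the predictor correlation matrix, reported as GVIF^(1/(2 df)) squared;
  values match R's `car::vif` to machine precision on reference data.
* Degenerate cases: constant responses and unobserved factor levels are
  flagged (never raised); singular random-effect fits are reported with a
  flag rather than silently simplified.

## The synthetic generator

No raw observation data are deposited, so the generator is a first-class
module that emulates the sampling design: groups x sessions x 10 scans; per
session each individual is absent (no access) with probability `p_absent`;
optionally indoors-but-present with `p_indoor` (default 0).  For every
unordered dyad and scan one of seven exclusive latent states is drawn
(none, SV, PCP, AFF/GRM in either direction) with probabilities

    p(layer, A->B) = base_rate(layer) x multipliers(origin, housing, sex combos),

symmetric layers averaging the two directions, and the vector renormalised
(with a warning) if it exceeds 1.  Because dyads and scans are independent,
every index is an unbiased binomial estimate of its planted probability —
recovery checks are closed-form (3-binomial-SE bands).

Default base rates (SV 0.12, PCP 0.04, GRM 0.02, AFF 0.01 per dyad-scan) are
order-of-magnitude choices reflecting that vicinity is common and directed
affiliation rare, reproducing the published pattern of dense SV/PCP layers
and sparser grooming/affiliative layers; the study reports no per-scan
rates, so these are configurable, not estimates.

Two rendering modes share the latent-state sampler:

* **state** — records carry behaviours and arm's-reach sets only; SV exists
  in the latent log, whose `indices_from_log` is the reference
  index computation.  Used for large recovery simulations.
* **spatial** — every visible individual also receives a planar position on
  a 1-metre lattice and a height level (0-4), solved per scan by constraint
  backtracking so that the geometric pipeline recovers the sampled states
  exactly: interacting dyads within 1 m (the arm's-reach radius adopted
  here; the protocol records arm's reach categorically), SV dyads at 2-5 m
  within one height level, "none" dyads beyond 5 m or two or more levels
  apart.  Under per-dyad independence roughly 1% of scans sample patterns
  with no geometric embedding at all (e.g. one animal interacting with four
  partners that are pairwise non-associating); such scans are redrawn from
  the same distribution and counted (`n_geometry_redraws`), so spatial-mode
  data are conditioned on embeddability — a deliberate, measured bias that
  leaves the record-vs-latent agreement exact.

What the generator does **not** emulate: temporal autocorrelation and
movement, triadic dependence (an individual may interact with several
partners at one scan), dominance/agonism, observer error.  Passing tests
therefore certify the estimators and the pipeline, not ethological realism.

## Problem sizes and numerical choices

Analyses and tests run at sizes chosen to make Monte-Carlo bands tight while
staying desk-scale: recovery uses 5 000 co-access scans per dyad over 50
seeds; model operating characteristics use 20 seeds (detection, x3 planted
multiplier, 50 sessions), 200 seeds (null rejection rate at alpha = 0.05,
25 sessions) and 50 seeds (power ordering, x2 multiplier, 20 sessions); the
worked example simulates 120 sessions per group.  Spectral tolerances: 1e-9
against closed forms; eigenvalues below -1e-10 raise, smaller negatives are
clipped to 0.  All logarithms are base 2.  Every stochastic component draws
from a single seeded generator in documented order (roster, absences,
dyad-state vectors per sorted dyad, geometry), so identical configurations
reproduce byte-identical artifacts.

## Known limitations

* Two groups give the group-level random effect almost no information; its
  variance is often estimated at the boundary (flagged as `singular`), and
  inference leans on the sender-within-group term — the same limitation the
  original design faces.
* Published group-specific values (edge overlaps, JSD magnitudes, F/z/p
  values) depend on the unpublished raw matrices and are treated as
  qualitative orderings, not reproduction targets.
* The spatial solver is a constructive heuristic: it guarantees any layout
  it returns is consistent, but may redraw a feasible-but-hard pattern;
  at the default rates this affects of the order of 1% of scans.
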