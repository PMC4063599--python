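# Methods

This note documents the models, statistics and design choices behind
`fluxcap`, in the spirit of a methods appendix: what is computed, under which
assumptions, with which defaults, and what the synthetic benchmark does and
does not establish.

## Flux-capacity model

The core object is the linear program

max c·v  subject to  S·v = 0,  v_min ≤ v ≤ v_max,

with S the compartmentalized stoichiometric matrix (rows are
compartment-specific species; the same base compound in two compartments is
two rows).  The steady-state constraint makes every internal species'
production and consumption balance, which is exactly why metabolite levels
are outside the model — the package's purpose is to relate the flux side to
independently measured levels, not to predict them.

For a metabolic function the objective is a unit coefficient on its declared
terminal reaction.  If a terminal product has no consumer or exporter
anywhere in the network, a demand reaction draining the terminal products in
stoichiometric ratio is synthesized at solve time, so the objective is never
trivially zero for a structurally intact pathway.  Non-pathway reactions stay
active: a capacity is the maximum flux the pathway can carry *within the
whole network*.  Only the optimum is used downstream; no parsimony or
secondary objective is applied, and any optimal vertex is accepted.

Solver: `scipy.optimize.linprog` (HiGHS) is the stateless reference path.
The permutation null solves hundreds of thousands of LPs that differ only in
column bounds and objective, so the batch solver keeps one persistent GLPK
problem (`swiglpk`) and re-solves from a warm basis, falling back to a fresh
standard basis on numerical failure.  Both paths are cross-checked against
each other, against cobrapy on a toy model, and against a brute-force
vertex-enumeration oracle on networks with ≤ 8 reactions (tolerance 1e-6).
Feasibility/optimality tolerances are solver defaults (~1e-9); capacities
with magnitude below 1e-9 are reported as exactly 0.

## Expression integration (E-flux)

GPR rules are evaluated with AND → minimum (an enzyme complex is limited by
its scarcest subunit) and OR → sum (isozymes act additively).  A gene absent
from a slice contributes *no evidence*: it is dropped from its parent node,
and an all-absent rule leaves the reaction unconstrained.  The alternative —
treating missing genes as zero expression — is available
(`missing_gene_mode="zero"`) but not default: absence of a measurement should
not force zero flux.

Activities are normalized per condition × time slice by the maximal activity
among constrained reactions and scaled to a global cap `v_cap` (default
1000 flux units; the LP is homogeneous, so the choice only sets the scale).
Slice-wise normalization makes bounds invariant to any common rescaling of
the expression values — appropriate for relative expression data — and keeps
each LP well-scaled.  Reversible constrained reactions get symmetric bounds
(−upper, +upper): expression caps the magnitude, thermodynamics keeps the
directionality pattern.  Exchange reactions are never expression-constrained.

## Permutation null, z-scores, classification

The null asks how much of an observed capacity is explained by the multiset
of expression-derived bounds alone, rather than by their placement on the
network: the constrained upper-bound magnitudes are permuted uniformly among
the constrained reactions (exchanges and unconstrained reactions untouched;
each reaction re-imposes its own reversibility on the magnitude it
receives).  Permutations are drawn independently per condition and time
point — 100 repetitions by default (the smallest count at which the sample
sd of the null is reasonably stable; repetitions ≥ 2 is enforced) — from
per-cell RNG substreams derived by counter from one master seed, so any cell
is reproducible in isolation and results do not depend on evaluation order.

z = (observed − null mean) / max(null sd, floor), with
floor = 1e-8 · (1 + |null mean|).  The floor prevents infinite z on
permutation-invariant cells (e.g. all constrained bounds equal); such cells
are flagged degenerate and get z = 0 when observed and null mean agree to
within the floor.

Per condition, the summary statistic is the *signed mean* of z over retained
time points; a sustainer requires mean z > 2, a modulator mean z < −2
(strict inequalities; configurable, as is a mean-|z| summary — the signed
mean is default because the classification must carry a direction).  A
pathway is differential when classified in at least one but not all
conditions: a shift appearing in every condition indistinguishably is a
property of the pathway, not a response.

Classification uses all time points by default; the first-hour exclusion
(below) applies to CV computation.  `pipeline.sensitivity_exclusion`
re-labels from the same z grid at any exclusion depth and reports agreement
with the full-grid labelling, which is how robustness of the classification
to the early transient is assessed — no LP is re-solved, because z itself
does not depend on the exclusion window.

## Metabolite roles and groupings

Within one function, a species consumed by some pathway reaction and
produced by none is a substrate; produced and never consumed, a product;
both, an intermediate.  Stoichiometric signs are taken as written — function
definitions declare the catalytic direction.  Initial substrates attach to
the declared first reaction(s), final products to the terminal reaction.
Cofactors (a user-supplied base-compound list, e.g. ATP/ADP/NAD(P)H/CoA/
phosphate) are excluded before any role or topology statistic.  Roles are
evaluated at the compartment-instance level and lifted to base compounds by
"any instance qualifies", because the measured data are compartment-agnostic
— each compartment instance of a mapped compound receives an identical copy
of the measured profile.

Groupings per condition collect measured base compounds holding a role in at
least one pathway of each class.  A pathway counts for a condition when it
carries the label there *and* passes the global differential filter.  The
in-X and in-non-X groups are disjoint by default (a compound participating
in both an X and a non-X pathway counts as in-X only), which keeps the
rank-sum comparison between independent-membership samples well-defined; an
overlapping mode exists behind a flag.

## Variability statistics

CV = sample standard deviation (n−1 denominator — the conventional estimator
for short series) over mean, per condition, after dropping the first six
time points: the first hour after the perturbation carries the strongest
transient and would otherwise dominate the variability estimate.  Cells with
fewer than two retained points or non-positive mean are flagged undefined
with a reason, never silently dropped; a sd at round-off level (≤ 1e-12 of
the mean) is snapped to CV = 0.  The same exclusion window is applied to
capacity-profile CVs for comparability.

Rank-sum tests are one-sided ("group CVs lower than reference"); the exact
null distribution is used when the smaller sample has ≤ 8 members and the
data are tie-free, otherwise the normal approximation with tie correction.
Samples with fewer than two members yield NA with a reason code.  The grid
crosses three categorizations (any role / products / substrates) with six
comparisons (modulator, sustainer, differential — each vs all measured
metabolites and vs its complement) per condition; significance is marked at
α = 0.05 per test with no multiple-testing correction for the headline
calls, and a Benjamini–Hochberg column is emitted alongside for
transparency.

One calibration property is worth stating explicitly: the "vs all measured"
comparisons include the group inside the reference sample, which makes them
conservative under the null (empirical size ≈ 0.02–0.03 at α = 0.05 in the
package's calibration harness), while the complement-group comparisons are
exactly sized (≈ 0.05).  This is structural to how the comparison is defined,
not an implementation artifact; both families are checked in the acceptance
suite in their respective directions.

## Synthetic benchmark

The generator emulates the targeted study design: 8 environmental
conditions (labelled as light/temperature regimes, with the temperature-
stress arm as the affected subset) × 22 time points over 0–24 h, six of them
inside the first hour; 20 linear pathways of 4 gene-associated reactions,
each with its own import and demand, an ATP/ADP couple on the first step, a
shared hub substrate on the second (so connectivity varies), a second
initial substrate on every fourth pathway and an occasional byproduct;
occasional OR- and AND-type GPRs.  Expression is log-normal noise (log-sd
0.3) around a flat baseline, with all genes of 4 planted-up pathways
multiplied and of 4 planted-down pathways divided by 5 in the affected
conditions.

Two sizing choices matter and were fixed at design time:

* **Constrained background.**  90 independent gene-associated chains of 6
  reactions bring the expression-constrainable pool to 620 reactions — the
  scale of a genome-scale mapping (~600 constrainable reactions).  The pool
  size is not cosmetic: the permutation null redistributes the planted
  down-regulated bounds, and in a small pool this contamination fattens the
  null's lower tail enough to mask down-regulated pathways.  A Monte Carlo
  of the min-over-chain capacity statistic shows recovery of down-planted
  pathways (|z| > 2) requires a pool of roughly ≥ 500 constrained reactions
  at these effect and noise levels.
* **No persistent per-gene baselines.**  All expression variation is
  temporal noise around a common baseline, as for per-gene-normalized
  relative expression.  Persistent per-gene level differences would give
  neutral pathways persistent capacity offsets that do not average out over
  time and would inflate the false-positive rate of the mean-z rule.

Metabolite series are generated at the base-compound level for 65 mappable
compounds (plus unmappable extras at a configurable fraction, default 0.2,
emulating incomplete dictionaries).  Substrates of planted pathways get a
low CV tier (0.05), everything else 0.3, each jittered per compound by
exp(N(0, 0.15)) so CVs are non-degenerate; on the retained window the
realized CV equals the target exactly by construction (the noise vector is
standardized).  The first six points carry a transient excursion of
deterministic shape and random sign, so the exclusion rule is exercised.
Values are clamped positive at 5% of the compound's level (only relevant
inside the excluded window in practice).

What passing tests show — and what they do not: the benchmark establishes
that the pipeline recovers planted capacity and variability structure at
realistic sizes and that its statistics are calibrated under the null.  It
does not emulate circadian structure, autocorrelated measurement noise,
compartment-specific metabolite pools, kinetic coupling between fluxes and
levels, or the breadth of real expression distributions; agreement on the
benchmark is therefore necessary, not sufficient, for trust on real data.

## Problem sizes used in the test and acceptance runs

The acceptance surface runs the study conditions in full: 20 pathways,
8 conditions × 22 time points, 100 permutations per cell (≈ 3.5 × 10^5 LPs;
about two minutes with the warm-started GLPK backend).  Metabolite-side
replicate studies (grid-row stability, null calibration) re-draw measurement
noise against a fixed classification — the grid's randomness is entirely on
the metabolite side, so re-running the LP null per replicate would add cost
but no information.  Unit tests use a 6-pathway, 3-condition configuration
of the same generator.

## Known limitations

* Pathway ordering is declared, not inferred; roles follow the declared
  direction and do not account for reversible operation of pathway steps.
* The E-flux mapping treats transcript abundance as a proxy for enzyme
  capacity; post-transcriptional regulation is only implicitly handled by
  constraining maxima rather than enforcing minima.
* The null permutes bounds within one condition × time slice; temporal
  dependence of the null across time points is not modelled.
* `connectivity_stats` pools substrate instances over all conditions;
  per-condition topology contrasts are not currently emitted.
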