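# Methods

This note documents the models, numerical conventions and design choices
behind `ulcernet`, in the spirit of a statistical package's methods
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model

A discrete Bayesian network over variables `U = {x₁, …, xₙ}` is a DAG `B_s`
plus conditional probability tables (CPTs) `B_p = {Pr(u | Pa(u))}`. The
outcome node `pu` is binary. Throughout, `rᵢ` is the cardinality of `xᵢ`,
`qᵢ = Π_{p∈Pa(xᵢ)} r_p` the number of parent configurations, and
`N_ijk`/`N_ij` the family counts. Parent configurations are indexed in
mixed radix with the **first listed parent most significant**; this fixes
CPT row identity everywhere (sampling, scoring, estimation, serialization).

### Scores

All scores use natural logarithms (any fixed base is a rescaling) and are
family-decomposable; `ScoreValue` carries the per-family terms and the
invariant `total = Σ family` is asserted in tests.

* Log-likelihood: `LL = Σ N_ijk ln(N_ijk / N_ij)` with `0·ln 0 = 0`.
* MDL/BIC: `LL − (ln N / 2)·|B_s|`, `|B_s| = Σ (rᵢ−1) qᵢ`.
* BDeu with equivalent sample size `N′` (default 10, configurable): the
  standard log-gamma form with a uniform structure prior, whose constant
  `ln Pr(B_s)` term is set to 0. The default 10 reflects the general
  finding that larger equivalent sample sizes behave better on sparse
  clinical flags; the value is exposed, not hidden.

### Parameter estimation

`Pr(x=k | Pa(x)=j) = (N_ijk + N′_ijk)/(N_ij + N′_ij)` with a per-cell
pseudo-count (default 1, so unobserved states get small nonzero mass;
0 gives maximum likelihood, and unobserved parent configurations are then
reported as undefined rows rather than silently imputed).

### Prediction

With every non-outcome variable observed, `P(pu | evidence)` factorizes
over the outcome's own family and its children's families; all other
factors cancel. Accumulation is in the log domain with a single final
normalization — with 60+ binary factors the linear-space product
underflows. If both unnormalized masses are zero (possible with
zero-probability CPT cells under maximum likelihood), the record is scored
with the outcome's CPT row given its parents, falling back to 0.5 if that
row is itself undefined; occurrences are countable by the caller. Missing
evidence is an error by design: the pipeline treats records as complete,
and silent marginalization would mask upstream data problems.

## Structure search

Moves are single-edge `add`/`delete`/`reverse`, generated only when legal
(acyclic, within `max_parents`, default 4 — unbounded parent sets make `qᵢ`
explode on ~70-node cohorts). Enumeration order is fixed (kind, then
source index, then target index) and equal-delta moves resolve to the
first in that order, with a 1e-9 tolerance because BDeu score equivalence
makes *exact* ties common and floating-point noise should not decide them.
Deltas are incremental: add/delete re-score one family, reverse two;
per-family scores are memoized by `(variable, parent set)`, which is the
dominant cost saving and what keeps the duplication benchmarks affordable.

* **Hill climbing** applies the best strictly improving move until none
  exists. A known structural limitation, visible in the test suite: strict
  greedy ascent cannot traverse zero-delta score-equivalence ridges, so on
  data from some collider ground truths (v-structures whose child's tied
  first edge is oriented the wrong way by the deterministic tie-break) it
  terminates in a fork/complete-graph local optimum a few nats below the
  global one. This is precisely the failure mode the list-based and
  stochastic searches exist to escape.
* **Repeated hill climbing** restarts `restarts` times; restart `i`
  perturbs the best structure so far with `2·i` random legal moves (seeded),
  then climbs; the best result is returned.
* **Tabu search** takes the best non-tabu move even when it worsens the
  score; the inverse of each applied move enters a FIFO list (default
  length 10), so a just-added edge cannot be immediately deleted and a
  reversal cannot be immediately undone. It returns the best structure
  visited and stops after 50 non-improving steps (configurable).
* **Simulated annealing** proposes a uniformly random legal move and
  accepts with probability `min(1, exp(Δ/T))`; geometric cooling with
  `T₀ = 10`, factor 0.95, 50 proposals per temperature, `T_min = 0.01` —
  chosen so the sampler reliably recovers the three-node exhaustive
  optimum in the test fixtures while staying cheap.
* **Exhaustive enumeration** (≤ 4 variables, ≤ 543 DAGs) is the oracle the
  local searches are compared against; ties break toward fewer edges, then
  enumeration order.

Initialization is either the empty graph or naïve Bayes (outcome as sole
parent of every feature). Recovery is measured on the CPDAG: a learned DAG
is converted to its equivalence class by the compelled-edge labelling
algorithm (validated in tests against brute-force enumeration of
equivalent DAGs), and structural Hamming distance counts node pairs whose
adjacency or orientation class differs.

## Screening

Boundary conventions are literal: an ICU stay of exactly 36.0 h is kept; a
feature with exactly 10 positive records survives the frequency filter.
The test chooser uses Pearson χ² only when every expected 2×2 cell is
≥ 20, otherwise the two-sided Fisher exact test (point-probability method,
via `scipy.stats.fisher_exact`, cross-checked in tests against exact
rational-arithmetic enumeration). Both Pearson and likelihood-ratio (G)
variants of χ² are provided; the demographic summary table defaults to the
likelihood-ratio variant, which is the one consistent with the published
demographic statistic the acceptance script reproduces. Diagnosis
retention is `χ² > 20`, equivalently α = 0.001; when Fisher is chosen for
a diagnosis the rule falls back to `p < 0.001`. E/V-prefixed ICD-9 codes
keep their prefix and three-digit category (`E812.0 → E812`); a bare `707`
is treated as PU-qualifying (conservative: only .1/.8/.9 are chronic,
non-pressure ulcers).

## Synthetic cohort generator

The generator defines the study conditions under which everything is
tested: 7,717 admissions, target prevalence 590/7717 ≈ 0.0765, 18
medication + 61 diagnosis + 7 Braden features (6 subscales and the total;
the raw total 6–23 is carried for the threshold baseline, and a 5-band
ordinal version with cut points 9/12/14/18 — the clinical threshold 13
lies on a band edge — stands in as the network node, since an 18-state
node would be data-starved).

Ground-truth topology: the PU node has 2 diagnosis parents, 3 children
(friction & shear plus 2 diagnoses by default) and 2 co-parents, so its
Markov blanket is a strict, nontrivial subset; half the remaining
medication/diagnosis features attach as children of PU's children
(indirect, screenable signal), the rest are isolated; declared noise
features are always disconnected. Small feature pools degrade to 1 parent
/ 1 child / 1 co-parent, never less.

CPTs of outcome-linked families are fixed strong-effect tables rather than
Dirichlet draws (Dirichlet rows can render a family unidentifiable or
unrecoverable at 7.6% prevalence); isolated features get seeded marginals
in [0.03, 0.35]. Rare-row probabilities sit away from 0.5 deliberately:
at the study prevalence a `(pu=1, co-parent=1)` stratum holds only a few
percent of records, and mid-range probabilities there would make CPT
recovery at realistic sample sizes a coin flip. PU's CPT is logistic in
its parents with the intercept solved by bisection so the exact ancestral
marginal equals the target prevalence (parents are roots, so the marginal
is a finite mixture — no rejection sampling). The Braden total is the
deterministic sum of the six subscales in every record; it correlates with
the outcome through the friction & shear child.

Raw admission mode wraps the cohort in admission metadata (age,
hospitalization/ICU sequence numbers, ICU hours, full ICD-9 code strings
with a qualifying 707.x planted for PU cases) and injects, at configurable
rates, records that the filter must drop — each tagged with its
ground-truth drop reason so the filter can be checked exactly.

What the generator does *not* emulate: free-text, labs, vitals, temporal
trajectories, correlated missingness, miscoding, or realistic effect
sizes. The original cohort's effect sizes are unknown, so synthetic
effects are strong and model-faithful (data are drawn from a Bayesian
network); consequently absolute metric levels here say nothing about real
EHR performance — passing tests demonstrate correctness of the machinery
and qualitative orderings (e.g. network sensitivity ≥ logistic sensitivity
at matched AUC), not clinical accuracy.

## Evaluation protocol

Per trial: split (training size `floor(0.67·n)`, unstratified by default
to match a plain random split; stratification is a flag), univariate
screening on the **training fold only**, structure + CPT learning on the
training fold, posterior scoring of the validation fold. The positive
call threshold is posterior ≥ 0.5 (most probable class); under 7.6%
prevalence this yields the characteristic low-sensitivity/high-specificity
operating point for weak feature sets. AUC is the rank (Mann–Whitney)
statistic with half-credit ties. Zero-denominator metrics are excluded
from the mean with an explicit count rather than propagated as NaN;
"(SD)" columns use the sample (n−1) deviation. If screening retains no
features, the trial falls back to the outcome-only network (posterior =
training prevalence, AUC exactly 0.5) and is counted. Per-trial seeds
derive from `SeedSequence((plan_seed, trial))`; the logistic comparator
and the Braden baseline reuse the identical splits.

Problem sizes used by the default test suite and acceptance script —
full-size cohorts (7,717) for screening power and the model comparison,
50,000 samples for CPT recovery, 20,000-record 8-node cohorts for
structure recovery, 1,000-record three-node datasets for optimum-recovery
sweeps, 5,000-record cohorts for null calibration, and 2–5 trials where
the protocol's 100 would only tighten standard errors — were chosen as the
smallest sizes at which each check is statistically meaningful.

## Known limitations

* Inference is specialized to the fully observed outcome-posterior; there
  is no general hidden-variable engine (junction tree etc.) by design.
* Greedy hill climbing's equivalence-ridge trap (above) is inherent; use
  tabu search when optimum recovery matters.
* The CPDAG labelling assumes a DAG input; it is not a PDAG completion
  routine.
* `exhaustive_search` is intentionally capped at 4 variables.
* The generator's admission metadata (age, length of stay) are plausible
  but uncalibrated; only the filter logic consumes them.
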