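# ulcernet

Bayesian-network models of pressure-ulcer (PU) risk from ICU electronic
health record features.

Pressure ulcers are localized skin/tissue injuries over bony prominences;
ICU patients are at elevated risk, and the standard bedside instrument (the
Braden scale) has limited discrimination on its own. `ulcernet` implements a
three-stage pipeline for admission-level tabular EHR data — medication
category flags, three-digit ICD-9 discharge diagnoses and Braden subscale
scores — aimed at clinical-informatics researchers who want an
interpretable risk model rather than a black box:

1. **Cohort screening** — admission filters (age ≥ 18, no PU at admission,
   ICU stay ≥ 36 h, first hospitalization / first ICU admission), ICD-9
   truncation to three-digit categories with the 707-family special case
   (707.1/707.8/707.9 → a `707-nonPU` category; other 707.x codes define
   the outcome label), a frequency filter (< 10 positives removed), and a
   univariate χ²/Fisher screen: medications retained at α = 0.1,
   diagnoses at χ² > 20 (α = 0.001), deliberately without multiple-testing
   correction.
2. **Network learning** — score-based structure search over discrete
   Bayesian networks with the BDeu score

   `BDeu(B_s|D) = Σᵢ Σⱼ [ ln Γ(N′/qᵢ) − ln Γ(N_ij + N′/qᵢ) + Σₖ ( ln Γ(N_ijk + N′/(rᵢqᵢ)) − ln Γ(N′/(rᵢqᵢ)) ) ]`

   or the MDL/BIC score `LL(D|B_s) − (ln N / 2)·|B_s|`, searched by greedy
   hill climbing, repeated hill climbing, tabu search or simulated
   annealing from an empty or naïve-Bayes start; CPTs estimated as
   `Pr(x=k|Pa(x)=j) = (N_ijk + N′_ijk) / (N_ij + N′_ij)`.
3. **Risk factors and prediction** — the Markov blanket of the PU node
   (parents, children, children's other parents) is the compact risk-factor
   set; the PU posterior for a fully observed record needs only those
   families and is computed in the log domain.

An evaluation harness reproduces the repeated 67/33 train/validate protocol
(SENS/SPEC/PPV/NPV/AUC, mean ± SD over trials) with two comparators: the
clinical baseline that thresholds the Braden total at 13, and a
maximum-likelihood logistic regression on identical splits. Because the
original hospital cohort is not public, a synthetic EHR generator
(`ulcernet.simulate`) emulates its conditions — 7,717 admissions, ~7.6% PU
prevalence, 86 features (18 medications + 61 diagnoses + 7 Braden) — from a
known ground-truth network, so every stage is testable end to end.

## Worked example

```python
import ulcernet as un
from ulcernet.evaluate import TrialPlan, side_by_side
from ulcernet.search import SearchConfig

spec = un.CohortSpec()                       # 7,717 admissions, 86 features
net = un.make_ground_truth(spec)             # known generating network
cohort = un.sample_cohort(net, spec.n_admissions, seed=1)

plan = TrialPlan(n_trials=5, feature_set="BD",
                 search=SearchConfig(algorithm="tabu", score="bdeu",
                                     init="naive_bayes"),
                 seed=1)
print(side_by_side(cohort, plan, braden_threshold=13).round(3).to_string(index=False))
```

prints

```
 model  sens  spec   auc  n_trials
Braden 0.603 0.543 0.607         5
    LR 0.756 0.986 0.983         5
    BN 0.758 0.989 0.984         5
```

Reading: the single-score Braden-≤13 baseline trades sensitivity against
specificity around a mediocre AUC; the Bayesian network matches logistic
regression's AUC on identical splits while keeping sensitivity at least as
high — on this synthetic cohort both models are strong because the planted
effects are strong, so the comparison is qualitative, not a reproduction of
any real-data figures. Continuing,

```python
from ulcernet.evaluate import screen_features
from ulcernet.network import DiscreteDataset
from ulcernet.search import tabu_search

feats = screen_features(cohort, un.network_feature_columns(cohort, {"B", "D"}))
ds = DiscreteDataset.from_frame(cohort, ["pu", *feats])
st, score, _ = tabu_search(ds, SearchConfig(algorithm="tabu", score="bdeu",
                                            init="naive_bayes", seed=1),
                           pu_node="pu")
sorted(un.markov_blanket(st, "pu"))
# ['braden_friction_shear', 'dx_403', 'dx_428', 'dx_584', 'dx_585']
```

recovers five of the generator's seven true blanket members (the two
co-parents are marginally independent of PU, so the univariate screen —
faithfully — removes them before learning).

The same pipeline is scriptable from the shell:

```bash
ulcernet simulate --n 7717 --seed 1 --raw --out run/
ulcernet screen run/raw_admissions.csv --raw --out run/
ulcernet learn run/screened_cohort.csv --algorithm tabu --score bdeu \
         --init naive_bayes --out run/          # GraphML + DOT with the
                                                # Markov blanket highlighted
ulcernet evaluate run/screened_cohort.csv --trials 10 --baseline all --out run/
```

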