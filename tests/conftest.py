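"""Shared fixtures and independent oracles.

The oracle implementations here are deliberately naive (cell loops, exact
rational arithmetic, exhaustive enumeration) and never share code with the
package paths they check.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pytest

import ulcernet as un
from ulcernet.cohort import PU_COLUMN
from ulcernet.network import NetworkStructure, ParameterSet, Variable
from ulcernet.simulate import CohortSpec, make_ground_truth, sample_cohort


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def exact_fisher_p(table) -> float:
    """Two-sided Fisher p by exact hypergeometric enumeration (Fractions)."""
    (a, b), (c, d) = np.asarray(table).tolist()
    r0, r1, c0 = a + b, c + d, a + c
    n = r0 + r1
    if n == 0 or r0 == 0 or r1 == 0 or c0 == 0 or c0 == n:
        return 1.0
    denom = comb(n, c0)

    def p(k: int) -> Fraction:
        return Fraction(comb(r0, k) * comb(r1, c0 - k), denom)

    p_obs = p(a)
    lo, hi = max(0, c0 - r1), min(r0, c0)
    return float(sum(p(k) for k in range(lo, hi + 1) if p(k) <= p_obs))


def pearson_loop(table) -> float:
    """Pearson chi-square by explicit cell loops."""
    t = np.asarray(table, dtype=float)
    n = t.sum()
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = t[i].sum() * t[:, j].sum() / n
            stat += (t[i, j] - e) ** 2 / e
    return stat


def g_loop(table) -> float:
    """Likelihood-ratio chi-square by explicit cell loops."""
    t = np.asarray(table, dtype=float)
    n = t.sum()
    stat = 0.0
    for i in range(2):
        for j in range(2):
            if t[i, j] > 0:
                e = t[i].sum() * t[:, j].sum() / n
                stat += 2.0 * t[i, j] * np.log(t[i, j] / e)
    return stat


def pairwise_auc(labels, scores) -> float:
    """O(n^2) pairwise-comparison AUC with half credit for ties."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def joint_posterior(structure: NetworkStructure, params: ParameterSet, evidence: dict,
                    pu_node: str = PU_COLUMN) -> float | None:
    """P(pu=1 | full evidence) by summing the complete joint over pu."""
    order = structure.topological_order()
    mass = {}
    for k in (0, 1):
        assign = dict(evidence)
        assign[pu_node] = k
        p = 1.0
        for name in order:
            j = 0
            for par in structure.parents[name]:
                j = j * structure.cardinality(par) + assign[par]
            p *= params.tables[name][j, assign[name]]
        mass[k] = p
    tot = mass[0] + mass[1]
    return mass[1] / tot if tot > 0 else None


def enumerate_dags(variables):
    """Every DAG over the labelled variables, by brute pair-orientation."""
    names = [v.name for v in variables]
    pairs = [(names[i], names[j]) for i in range(len(names)) for j in range(i + 1, len(names))]
    out = []
    for combo in itertools.product((0, 1, 2), repeat=len(pairs)):
        parents = {n: [] for n in names}
        for s, (a, b) in zip(combo, pairs):
            if s == 1:
                parents[b].append(a)
            elif s == 2:
                parents[a].append(b)
        try:
            out.append(NetworkStructure(variables, parents))
        except ValueError:
            continue
    return out


def naive_family_counts(matrix, cards, var_idx, parent_idx):
    """Nested-loop N_ijk counter (first parent most significant)."""
    q = int(np.prod([cards[p] for p in parent_idx])) if parent_idx else 1
    table = np.zeros((q, cards[var_idx]), dtype=int)
    for row in matrix:
        j = 0
        for p in parent_idx:
            j = j * cards[p] + row[p]
        table[j, row[var_idx]] += 1
    return table


def random_dag(names, edge_prob, rng, cards=None, max_parents=None):
    """Random DAG with a randomized topological order."""
    cards = cards or {n: 2 for n in names}
    shuffled = list(rng.permutation(names))
    parents = {n: [] for n in names}
    for i, a in enumerate(shuffled):
        for b in shuffled[i + 1:]:
            if rng.random() < edge_prob and (max_parents is None or len(parents[b]) < max_parents):
                parents[b].append(a)
    return NetworkStructure([Variable(n, cards[n]) for n in names], parents)


def random_parameters(structure: NetworkStructure, rng) -> ParameterSet:
    tables = {
        v.name: rng.dirichlet(np.ones(v.cardinality), size=structure.q(v.name))
        for v in structure.variables
    }
    return ParameterSet(tables, 1.0)


def logistic_cpt_dataset(structure: NetworkStructure, n: int, rng) -> np.ndarray:
    """Sample binary data from ``structure`` with logistic CPTs whose
    per-parent effects are strong (|log-odds| in [1.5, 2.5]), so every edge
    is marginally detectable."""
    coeffs = {}
    for name in structure.names:
        ps = structure.parents[name]
        a = rng.uniform(-0.5, 0.5)
        b = rng.uniform(1.5, 2.5, size=len(ps)) * rng.choice([-1.0, 1.0], size=len(ps))
        coeffs[name] = (a, b)
    cols = {}
    for name in structure.topological_order():
        a, b = coeffs[name]
        lin = np.full(n, a)
        for w, par in zip(b, structure.parents[name]):
            lin = lin + w * cols[par]
        p = 1.0 / (1.0 + np.exp(-lin))
        cols[name] = (rng.random(n) < p).astype(int)
    return np.column_stack([cols[v.name] for v in structure.variables])


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def default_net():
    return make_ground_truth(CohortSpec())


@pytest.fixture(scope="session")
def default_cohort(default_net):
    return sample_cohort(default_net, 7717, seed=11)


@pytest.fixture(scope="session")
def net8():
    """Eight binary nodes: the outcome with 2 parents, 3 children, 2 co-parents."""
    return make_ground_truth(CohortSpec(n_med=0, n_dx=7, include_braden=False,
                                        target_prevalence=0.076))


@pytest.fixture(scope="session")
def chain_dataset():
    """n=10,000 samples from a strong A -> B -> C chain."""
    rng = np.random.default_rng(7)
    n = 10_000
    a = (rng.random(n) < 0.4).astype(int)
    b = np.where(a == 1, rng.random(n) < 0.85, rng.random(n) < 0.15).astype(int)
    c = np.where(b == 1, rng.random(n) < 0.80, rng.random(n) < 0.10).astype(int)
    return un.DiscreteDataset(
        np.column_stack([a, b, c]), [Variable("A", 2), Variable("B", 2), Variable("C", 2)]
    )
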