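"""Discrete Bayesian-network core.

Structures (DAGs over discrete variables), sufficient statistics
:math:`N_{ijk}`, the BDeu and MDL scoring functions, conditional probability
table (CPT) estimation with Dirichlet pseudo-counts, Markov blankets,
posterior prediction for the outcome node, DAG-to-CPDAG conversion and
GraphML/DOT export.

Conventions
-----------
* Natural logarithms throughout; all scores are comparable on that scale.
* Parent configurations are indexed in mixed radix with the *first listed
  parent most significant*, so CPT row ``j`` has a fixed, documented meaning.
* The BDeu structure prior is uniform, so the ``log Pr(B_s)`` term is a
  constant taken as 0.
"""

from __future__ import annotations

import json
import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln

from .cohort import PU_COLUMN, Variable, column_variable

__all__ = [
    "Variable",
    "NetworkStructure",
    "DiscreteDataset",
    "CountTable",
    "ScoreValue",
    "ParameterSet",
    "family_counts",
    "loglikelihood",
    "bdeu_score",
    "mdl_score",
    "FamilyScorer",
    "estimate_parameters",
    "markov_blanket",
    "predict_pu",
    "pu_posterior",
    "dag_to_cpdag",
    "shd_cpdag",
]


class NetworkStructure:
    """A DAG over named discrete variables with ordered parent lists.

    Parameters
    ----------
    variables:
        Ordered sequence of :class:`Variable`.
    parents:
        Optional map ``child -> iterable of parent names``; edges are checked
        for acyclicity as they are added.
    """

    __slots__ = ("variables", "parents", "_index")

    def __init__(
        self,
        variables: Sequence[Variable],
        parents: Mapping[str, Iterable[str]] | None = None,
    ) -> None:
        self.variables: tuple[Variable, ...] = tuple(variables)
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names")
        self._index: dict[str, int] = {n: i for i, n in enumerate(names)}
        self.parents: dict[str, tuple[str, ...]] = {n: () for n in names}
        if parents is not None:
            for child, ps in parents.items():
                for p in ps:
                    self.add_edge(p, child)

    # -- basic accessors ---------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def index(self, name: str) -> int:
        return self._index[name]

    def variable(self, name: str) -> Variable:
        return self.variables[self._index[name]]

    def cardinality(self, name: str) -> int:
        return self.variables[self._index[name]].cardinality

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def edges(self) -> list[tuple[str, str]]:
        return [(p, c) for c in self.names for p in self.parents[c]]

    def n_edges(self) -> int:
        return sum(len(ps) for ps in self.parents.values())

    def children(self, name: str) -> list[str]:
        return [c for c in self.names if name in self.parents[c]]

    def copy(self) -> "NetworkStructure":
        new = NetworkStructure.__new__(NetworkStructure)
        new.variables = self.variables
        new._index = self._index
        new.parents = dict(self.parents)
        return new

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, NetworkStructure)
            and self.variables == other.variables
            and self.parents == other.parents
        )

    def __hash__(self):  # pragma: no cover - structures are not dict keys
        return hash((self.variables, tuple(sorted(self.parents.items()))))

    # -- mutation ----------------------------------------------------------
    def _reaches(self, src: str, dst: str) -> bool:
        """True when a directed path ``src ~> dst`` exists (including src==dst)."""
        if src == dst:
            return True
        stack, seen = [src], {src}
        while stack:
            node = stack.pop()
            for child in self.children(node):
                if child == dst:
                    return True
                if child not in seen:
                    seen.add(child)
                    stack.append(child)
        return False

    def add_edge(self, parent: str, child: str) -> None:
        if parent not in self._index or child not in self._index:
            raise KeyError(f"unknown variable in edge {parent}->{child}")
        if parent == child:
            raise ValueError("self loops are not allowed")
        if parent in self.parents[child]:
            raise ValueError(f"edge {parent}->{child} already present")
        if self._reaches(child, parent):
            raise ValueError(f"edge {parent}->{child} would create a cycle")
        self.parents[child] = self.parents[child] + (parent,)

    def remove_edge(self, parent: str, child: str) -> None:
        if parent not in self.parents[child]:
            raise ValueError(f"edge {parent}->{child} not present")
        self.parents[child] = tuple(p for p in self.parents[child] if p != parent)

    def reverse_edge(self, parent: str, child: str) -> None:
        self.remove_edge(parent, child)
        self.add_edge(child, parent)

    # -- derived quantities ------------------------------------------------
    def q(self, name: str) -> int:
        """Number of parent configurations of ``name`` (1 when parentless)."""
        q = 1
        for p in self.parents[name]:
            q *= self.cardinality(p)
        return q

    def n_params(self) -> int:
        """Independent parameter count ``|B_s| = sum_i (r_i - 1) q_i``."""
        return sum((v.cardinality - 1) * self.q(v.name) for v in self.variables)

    def topological_order(self) -> list[str]:
        indeg = {n: len(self.parents[n]) for n in self.names}
        ready = deque(n for n in self.names if indeg[n] == 0)
        order: list[str] = []
        children: dict[str, list[str]] = {n: [] for n in self.names}
        for c in self.names:
            for p in self.parents[c]:
                children[p].append(c)
        while ready:
            node = ready.popleft()
            order.append(node)
            for c in children[node]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    ready.append(c)
        if len(order) != len(self.names):
            raise ValueError("structure contains a cycle")
        return order

    def descendants(self) -> dict[str, set[str]]:
        """Strict descendants of every node (one DFS per node)."""
        children: dict[str, list[str]] = {n: [] for n in self.names}
        for c in self.names:
            for p in self.parents[c]:
                children[p].append(c)
        out: dict[str, set[str]] = {}
        for n in reversed(self.topological_order()):
            desc: set[str] = set()
            for c in children[n]:
                desc.add(c)
                desc |= out[c]
            out[n] = desc
        return out

    # -- serialization -----------------------------------------------------
    def to_networkx(self, pu_node: str | None = None) -> nx.DiGraph:
        g = nx.DiGraph()
        if pu_node is not None:
            g.graph["pu_node"] = pu_node
        for v in self.variables:
            g.add_node(v.name, cardinality=v.cardinality, offset=v.offset)
        g.add_edges_from(self.edges())
        return g

    def to_graphml(self, path, pu_node: str | None = None) -> None:
        nx.write_graphml(self.to_networkx(pu_node), path)

    @classmethod
    def from_networkx(cls, g: nx.DiGraph) -> "NetworkStructure":
        variables = [
            Variable(n, int(d["cardinality"]), int(d.get("offset", 0)))
            for n, d in g.nodes(data=True)
        ]
        parents = {n: [] for n in g.nodes}
        for u, v in g.edges:
            parents[v].append(u)
        return cls(variables, parents)

    @classmethod
    def from_graphml(cls, path) -> "NetworkStructure":
        return cls.from_networkx(nx.read_graphml(path))

    def to_dot(self, highlight: Iterable[str] = (), pu_node: str | None = None) -> str:
        """Render as DOT text; ``highlight`` nodes (typically the Markov
        blanket of the outcome) are filled and carry a ``highlight`` attribute."""
        hl = set(highlight)
        lines = ["digraph bayesian_network {"]
        for v in self.variables:
            attrs = [f'cardinality="{v.cardinality}"']
            if v.name == pu_node:
                attrs.append('shape="doublecircle"')
            if v.name in hl:
                attrs.append('highlight="true"')
                attrs.append('style="filled"')
                attrs.append('fillcolor="lightgoldenrod"')
            lines.append(f'  "{v.name}" [{", ".join(attrs)}];')
        for u, v in self.edges():
            lines.append(f'  "{u}" -> "{v}";')
        lines.append("}")
        return "\n".join(lines) + "\n"


class DiscreteDataset:
    """Complete discrete data: an ``(n_records, n_variables)`` integer matrix
    of 0-based state codes plus the variable declarations."""

    def __init__(self, matrix: np.ndarray, variables: Sequence[Variable]) -> None:
        matrix = np.ascontiguousarray(matrix, dtype=np.int64)
        if matrix.ndim != 2 or matrix.shape[1] != len(variables):
            raise ValueError("matrix shape does not match variable list")
        self.matrix = matrix
        self.variables = tuple(variables)
        self.index = {v.name: i for i, v in enumerate(self.variables)}
        for v in self.variables:
            col = matrix[:, self.index[v.name]]
            if col.size and (col.min() < 0 or col.max() >= v.cardinality):
                raise ValueError(f"values of {v.name!r} outside its declared state space")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_frame(cls, df: pd.DataFrame, columns: Sequence[str] | None = None) -> "DiscreteDataset":
        """Encode cohort columns (outcome first by convention of the caller)."""
        if columns is None:
            columns = [c for c in df.columns if c not in ("patient_id",)]
        variables = [column_variable(c) for c in columns]
        mat = np.empty((len(df), len(columns)), dtype=np.int64)
        for i, v in enumerate(variables):
            mat[:, i] = df[v.name].to_numpy() - v.offset
        return cls(mat, variables)

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.index[name]]


@dataclass
class CountTable:
    """Sufficient statistics for one family: ``table[j, k]`` is ``N_ijk``."""

    variable: str
    parents: tuple[str, ...]
    table: np.ndarray  # shape (q, r)

    @property
    def nij(self) -> np.ndarray:
        return self.table.sum(axis=1)

    @property
    def n(self) -> int:
        return int(self.table.sum())


def parent_config_index(dataset: DiscreteDataset, parents: Sequence[str]) -> tuple[np.ndarray, int]:
    """Mixed-radix parent-configuration index ``j`` per record (first parent
    most significant) and the number of configurations ``q``."""
    n = dataset.n
    j = np.zeros(n, dtype=np.int64)
    q = 1
    for p in parents:
        r_p = dataset.variables[dataset.index[p]].cardinality
        j = j * r_p + dataset.column(p)
        q *= r_p
    return j, q


def family_counts(dataset: DiscreteDataset, variable: str, parents: Sequence[str]) -> CountTable:
    """Exact contingency counts ``N_ijk`` for one variable-family."""
    r = dataset.variables[dataset.index[variable]].cardinality
    j, q = parent_config_index(dataset, parents)
    code = j * r + dataset.column(variable)
    table = np.bincount(code, minlength=q * r).reshape(q, r)
    return CountTable(variable, tuple(parents), table)


@dataclass
class ScoreValue:
    """A decomposable network score: the total and its per-family terms."""

    total: float
    families: dict[str, float]
    kind: str = ""

    def check(self, tol: float = 1e-9) -> bool:
        return abs(self.total - math.fsum(self.families.values())) <= tol


def _family_ll(table: np.ndarray) -> float:
    nij = table.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = table * (np.log(table) - np.log(nij))
    return float(np.where(table > 0, terms, 0.0).sum())


def _family_bdeu(table: np.ndarray, ess: float) -> float:
    q, r = table.shape
    a_j = ess / q
    a_jk = ess / (r * q)
    nij = table.sum(axis=1)
    row_terms = gammaln(a_j) - gammaln(nij + a_j)
    cell_terms = gammaln(table + a_jk) - gammaln(a_jk)
    return float(row_terms.sum() + cell_terms.sum())


class FamilyScorer:
    """Decomposable scorer with per-family memoization.

    The cache key is ``(variable, frozenset(parents))`` -- family scores do
    not depend on parent order -- and it is the dominant saving in local
    search, where most neighbours share almost all families with the current
    structure.
    """

    def __init__(self, dataset: DiscreteDataset, score: str = "bdeu", ess: float = 10.0) -> None:
        if score not in ("bdeu", "mdl", "ll"):
            raise ValueError(f"unknown score {score!r}")
        if score == "bdeu" and ess <= 0:
            raise ValueError("equivalent sample size must be > 0")
        self.dataset = dataset
        self.score = score
        self.ess = float(ess)
        self._half_log_n = 0.5 * math.log(dataset.n) if dataset.n > 0 else 0.0
        self._cache: dict[tuple[str, frozenset], float] = {}

    def family_score(self, variable: str, parents: Iterable[str]) -> float:
        parents = tuple(parents)
        key = (variable, frozenset(parents))
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        ct = family_counts(self.dataset, variable, parents)
        if self.score == "bdeu":
            val = _family_bdeu(ct.table, self.ess)
        else:
            val = _family_ll(ct.table)
            if self.score == "mdl":
                q, r = ct.table.shape
                val -= self._half_log_n * (r - 1) * q
        self._cache[key] = val
        return val

    def structure_score(self, structure: NetworkStructure) -> ScoreValue:
        fams = {
            v.name: self.family_score(v.name, structure.parents[v.name])
            for v in structure.variables
        }
        return ScoreValue(math.fsum(fams.values()), fams, self.score)


def loglikelihood(dataset: DiscreteDataset, structure: NetworkStructure) -> ScoreValue:
    """Maximum-likelihood plug-in log-likelihood
    ``LL(D|B_s) = sum_ijk N_ijk ln(N_ijk / N_ij)`` (natural log)."""
    return FamilyScorer(dataset, "ll").structure_score(structure)


def bdeu_score(dataset: DiscreteDataset, structure: NetworkStructure, ess: float = 10.0) -> ScoreValue:
    """BDeu marginal log-likelihood with equivalent sample size ``ess`` and a
    uniform structure prior (the ``log Pr(B_s)`` constant is dropped)."""
    return FamilyScorer(dataset, "bdeu", ess).structure_score(structure)


def mdl_score(dataset: DiscreteDataset, structure: NetworkStructure) -> ScoreValue:
    """MDL/BIC score ``LL(D|B_s) - (ln N / 2) |B_s|``."""
    return FamilyScorer(dataset, "mdl").structure_score(structure)


@dataclass
class ParameterSet:
    """Conditional probability tables ``Pr(x = k | Pa(x) = j)``.

    ``tables[name][j, k]`` follows the mixed-radix row convention.  Rows that
    were unestimable (zero counts with a zero prior) are NaN and recorded in
    ``undefined_rows``.
    """

    tables: dict[str, np.ndarray]
    prior: float
    undefined_rows: list[tuple[str, int]] = field(default_factory=list)

    def to_json(self, structure: NetworkStructure) -> str:
        payload = {
            name: {
                "parents": list(structure.parents[name]),
                "cpt": np.nan_to_num(tab, nan=-1.0).tolist(),
            }
            for name, tab in self.tables.items()
        }
        return json.dumps({"prior": self.prior, "variables": payload}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ParameterSet":
        raw = json.loads(text)
        tables = {}
        for name, entry in raw["variables"].items():
            tab = np.asarray(entry["cpt"], dtype=float)
            tab[tab < 0] = np.nan
            tables[name] = tab
        undefined = [
            (name, int(j))
            for name, tab in tables.items()
            for j in np.nonzero(np.isnan(tab).any(axis=1))[0]
        ]
        return cls(tables, float(raw["prior"]), undefined)


def estimate_parameters(
    dataset: DiscreteDataset, structure: NetworkStructure, prior: float = 1.0
) -> ParameterSet:
    """Direct CPT estimates ``(N_ijk + N'_ijk) / (N_ij + N'_ij)``.

    ``prior`` is the per-cell pseudo-count ``N'_ijk`` (default 1, giving
    every unobserved state a small nonzero probability); ``prior = 0`` yields
    maximum-likelihood estimates, with unobserved parent configurations
    reported as undefined rows.
    """
    if prior < 0:
        raise ValueError("prior pseudo-count must be >= 0")
    tables: dict[str, np.ndarray] = {}
    undefined: list[tuple[str, int]] = []
    for v in structure.variables:
        ct = family_counts(dataset, v.name, structure.parents[v.name])
        num = ct.table + prior
        den = num.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            tab = num / den
        if prior == 0:
            empty = np.nonzero(ct.nij == 0)[0]
            for j in empty:
                tab[j, :] = np.nan
                undefined.append((v.name, int(j)))
        tables[v.name] = tab
    return ParameterSet(tables, float(prior), undefined)


def markov_blanket(structure: NetworkStructure, node: str) -> set[str]:
    """Parents, children and children's other parents of ``node``."""
    if node not in structure:
        raise KeyError(f"unknown node {node!r}")
    mb: set[str] = set(structure.parents[node])
    for child in structure.children(node):
        mb.add(child)
        mb.update(structure.parents[child])
    mb.discard(node)
    return mb


# ---------------------------------------------------------------------------
# Posterior prediction for the outcome node
# ---------------------------------------------------------------------------

def pu_posterior(
    structure: NetworkStructure,
    params: ParameterSet,
    dataset: DiscreteDataset,
    pu_node: str = PU_COLUMN,
) -> np.ndarray:
    """Posterior ``P(pu = 1 | evidence)`` for every record of ``dataset``.

    All non-outcome variables are observed, so the posterior factorizes over
    the outcome's own family and its children's families; everything else
    cancels.  Accumulation is in the log domain with one final normalization
    (the product over 60+ families underflows in linear space).  Records whose
    unnormalized masses are both zero fall back to the outcome's CPT row given
    its parents (the prior), or to 0.5 when that row is itself undefined.
    """
    if pu_node not in structure:
        raise KeyError(f"unknown outcome node {pu_node!r}")
    r_pu = structure.cardinality(pu_node)
    if r_pu != 2:
        raise ValueError("outcome node must be binary")
    n = dataset.n
    logp = np.zeros((n, 2))

    with np.errstate(divide="ignore", invalid="ignore"):
        # outcome's own family
        j_pu, _ = parent_config_index(dataset, structure.parents[pu_node])
        pu_rows = params.tables[pu_node][j_pu]  # (n, 2)
        logp += np.log(pu_rows)

        # each child family, with the outcome column forced to 0 then 1
        pu_idx = dataset.index[pu_node]
        for child in structure.children(pu_node):
            parents = structure.parents[child]
            tab = params.tables[child]
            x_c = dataset.column(child)
            for k in (0, 1):
                j = np.zeros(n, dtype=np.int64)
                for p in parents:
                    r_p = dataset.variables[dataset.index[p]].cardinality
                    col = np.full(n, k, dtype=np.int64) if p == pu_node else dataset.column(p)
                    j = j * r_p + col
                logp[:, k] += np.log(tab[j, x_c])

    # normalize; guard the all-zero / NaN cases
    m = np.nanmax(logp, axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        w = np.exp(logp - m)
    denom = w.sum(axis=1)
    post = np.full(n, 0.5)
    ok = np.isfinite(denom) & (denom > 0) & np.isfinite(m[:, 0])
    post[ok] = w[ok, 1] / denom[ok]
    # undefined joint mass: fall back to the outcome prior given its parents
    bad = ~ok
    if bad.any():
        prior_row = pu_rows[bad, 1]
        post[bad] = np.where(np.isfinite(prior_row), prior_row, 0.5)
    return post


def predict_pu(
    structure: NetworkStructure,
    params: ParameterSet,
    evidence: Mapping[str, int],
    pu_node: str = PU_COLUMN,
) -> float:
    """Posterior probability of ``pu = 1`` for a single fully observed record.

    ``evidence`` maps every non-outcome variable to its *raw* value (Braden
    subscales are 1-based); missing or out-of-range values raise.
    """
    row = np.zeros((1, len(structure.variables)), dtype=np.int64)
    for i, v in enumerate(structure.variables):
        if v.name == pu_node:
            continue
        if v.name not in evidence:
            raise KeyError(f"evidence missing for {v.name!r}")
        state = int(evidence[v.name]) - v.offset
        if not 0 <= state < v.cardinality:
            raise ValueError(f"evidence for {v.name!r} outside its state space")
        row[0, i] = state
    ds = DiscreteDataset(row, structure.variables)
    return float(pu_posterior(structure, params, ds, pu_node)[0])


# ---------------------------------------------------------------------------
# Equivalence classes
# ---------------------------------------------------------------------------

def dag_to_cpdag(structure: NetworkStructure) -> tuple[set[tuple[str, str]], set[frozenset]]:
    """Split a DAG's edges into compelled (directed) and reversible
    (undirected) sets -- the CPDAG of its Markov-equivalence class.

    Implements the edge-labelling characterization: process edges in an order
    compatible with a topological order of the nodes and propagate
    compelled-ness from each edge's parent side.
    """
    pos = {n: i for i, n in enumerate(structure.topological_order())}
    edges = sorted(structure.edges(), key=lambda e: (pos[e[1]], -pos[e[0]]))
    label: dict[tuple[str, str], str] = {}
    for x, y in edges:
        if (x, y) in label:
            continue
        resolved = False
        for w in structure.parents[x]:
            if label.get((w, x)) == "c":
                if w not in structure.parents[y]:
                    for p in structure.parents[y]:
                        label[(p, y)] = "c"
                    resolved = True
                    break
                label[(w, y)] = "c"
        if resolved:
            continue
        if any(z != x and z not in structure.parents[x] for z in structure.parents[y]):
            lab = "c"
        else:
            lab = "r"
        for p in structure.parents[y]:
            if (p, y) not in label:
                label[(p, y)] = lab
    directed = {e for e, l in label.items() if l == "c"}
    undirected = {frozenset(e) for e, l in label.items() if l == "r"}
    return directed, undirected


def shd_cpdag(a: NetworkStructure, b: NetworkStructure) -> int:
    """Structural Hamming distance between the CPDAGs of two DAGs.

    One unit per node pair whose adjacency differs, or whose shared edge
    differs in orientation class (directed vs undirected, or opposite
    direction).
    """

    def canon(st: NetworkStructure) -> dict[frozenset, str]:
        directed, undirected = dag_to_cpdag(st)
        out: dict[frozenset, str] = {}
        for u, v in directed:
            out[frozenset((u, v))] = f"{u}->{v}"
        for e in undirected:
            out[e] = "--"
        return out

    ca, cb = canon(a), canon(b)
    dist = 0
    for pair in set(ca) | set(cb):
        if ca.get(pair) != cb.get(pair):
            dist += 1
    return dist
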