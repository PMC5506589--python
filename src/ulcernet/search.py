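"""Score-based structure search.

Greedy hill climbing, repeated hill climbing with perturbation restarts,
tabu search and simulated annealing over the add/delete/reverse move
neighbourhood, plus an exhaustive-enumeration reference for tiny problems.

All algorithms share one :class:`~ulcernet.network.FamilyScorer`, so every
move is evaluated through incremental family-score deltas: adding or
deleting an edge re-scores only the child's family, reversing an edge
re-scores both endpoint families.  Moves are enumerated in a fixed order
(kind ``add`` < ``delete`` < ``reverse``, then source index, then target
index) and ties between equal deltas are broken by that order, which makes
every run reproducible.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .network import DiscreteDataset, FamilyScorer, NetworkStructure, ScoreValue

__all__ = [
    "SearchConfig",
    "Move",
    "init_structure",
    "neighborhood",
    "move_delta",
    "apply_move",
    "hill_climb",
    "repeated_hill_climb",
    "tabu_search",
    "simulated_annealing",
    "exhaustive_search",
    "learn_structure",
]

_KINDS = ("add", "delete", "reverse")


class Move(NamedTuple):
    kind: str  # add | delete | reverse
    source: str
    target: str

    def inverse(self) -> "Move":
        if self.kind == "add":
            return Move("delete", self.source, self.target)
        if self.kind == "delete":
            return Move("add", self.source, self.target)
        return Move("reverse", self.target, self.source)


@dataclass
class SearchConfig:
    """Knobs for all search algorithms; unused fields are ignored.

    ``tabu_length`` is the length of the FIFO list of forbidden (inverse)
    moves; ``tabu_patience`` the number of consecutive non-improving steps
    tolerated before stopping.  Annealing uses geometric cooling from ``t0``
    to ``t_min`` with ``steps_per_temp`` proposals per temperature.
    """

    algorithm: str = "tabu"
    score: str = "bdeu"
    ess: float = 10.0
    init: str = "empty"
    max_parents: int = 4
    max_iter: int = 10_000
    tabu_length: int = 10
    tabu_patience: int = 50
    restarts: int = 3
    t0: float = 10.0
    cooling: float = 0.95
    steps_per_temp: int = 50
    t_min: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ("hill_climb", "repeated_hill_climb", "tabu", "simulated_annealing"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.init not in ("empty", "naive_bayes"):
            raise ValueError(f"unknown init {self.init!r}")
        if self.max_parents < 1 and self.init == "naive_bayes":
            raise ValueError("naive_bayes init needs max_parents >= 1")
        if self.tabu_length < 1:
            raise ValueError("tabu_length must be >= 1")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if not (self.t0 > self.t_min > 0) or not (0 < self.cooling < 1):
            raise ValueError("annealing schedule requires t0 > t_min > 0 and cooling in (0,1)")


def init_structure(variables, kind: str, pu_node: str | None = None) -> NetworkStructure:
    """``empty``: no edges.  ``naive_bayes``: one edge ``pu_node -> f`` for
    every other variable (the outcome is the sole parent of every feature)."""
    st = NetworkStructure(variables)
    if kind == "empty":
        return st
    if kind == "naive_bayes":
        if pu_node is None or pu_node not in st:
            raise KeyError(f"naive_bayes init: unknown outcome node {pu_node!r}")
        for v in st.names:
            if v != pu_node:
                st.add_edge(pu_node, v)
        return st
    raise ValueError(f"unknown init {kind!r}")


def neighborhood(structure: NetworkStructure, config: SearchConfig) -> list[Move]:
    """All single-edge moves that keep the graph acyclic and within
    ``max_parents``, in the documented deterministic order."""
    names = structure.names
    desc = structure.descendants()
    moves: list[Move] = []
    # add
    for u in names:
        for v in names:
            if u == v or u in structure.parents[v]:
                continue
            if len(structure.parents[v]) >= config.max_parents:
                continue
            if u in desc[v]:  # v ~> u exists, adding u->v closes a cycle
                continue
            moves.append(Move("add", u, v))
    # delete
    for v in names:
        for u in structure.parents[v]:
            moves.append(Move("delete", u, v))
    # reverse: u->v becomes v->u; illegal when another path u ~> v remains
    for v in names:
        for u in structure.parents[v]:
            if len(structure.parents[u]) + 1 > config.max_parents:
                continue
            if any(w != v and v in desc[w] | {w} for w in structure.children(u)):
                continue
            moves.append(Move("reverse", u, v))
    idx = {n: i for i, n in enumerate(names)}
    moves.sort(key=lambda m: (_KINDS.index(m.kind), idx[m.source], idx[m.target]))
    return moves


def move_delta(scorer: FamilyScorer, structure: NetworkStructure, move: Move) -> float:
    """Incremental score change of ``move`` (only the touched families)."""
    u, v = move.source, move.target
    pa_v = structure.parents[v]
    if move.kind == "add":
        return scorer.family_score(v, pa_v + (u,)) - scorer.family_score(v, pa_v)
    if move.kind == "delete":
        return scorer.family_score(v, tuple(p for p in pa_v if p != u)) - scorer.family_score(v, pa_v)
    pa_u = structure.parents[u]
    return (
        scorer.family_score(v, tuple(p for p in pa_v if p != u))
        - scorer.family_score(v, pa_v)
        + scorer.family_score(u, pa_u + (v,))
        - scorer.family_score(u, pa_u)
    )


def apply_move(structure: NetworkStructure, move: Move) -> NetworkStructure:
    """Return a copy of ``structure`` with ``move`` applied."""
    st = structure.copy()
    if move.kind == "add":
        st.add_edge(move.source, move.target)
    elif move.kind == "delete":
        st.remove_edge(move.source, move.target)
    else:
        st.reverse_edge(move.source, move.target)
    return st


_EPS = 1e-10


def _resolve_init(dataset: DiscreteDataset, config: SearchConfig,
                  init: NetworkStructure | None, pu_node: str | None) -> NetworkStructure:
    if init is not None:
        return init.copy()
    return init_structure(dataset.variables, config.init, pu_node)


def hill_climb(
    dataset: DiscreteDataset,
    config: SearchConfig,
    init: NetworkStructure | None = None,
    pu_node: str | None = None,
    scorer: FamilyScorer | None = None,
) -> tuple[NetworkStructure, ScoreValue, list[dict]]:
    """Greedy hill climbing: repeatedly apply the best strictly improving
    move until none exists (a local optimum).  Returns the structure, its
    score and a per-step trace of ``(move, delta, total)``."""
    if dataset.n == 0:
        raise ValueError("empty dataset")
    scorer = scorer or FamilyScorer(dataset, config.score, config.ess)
    current = _resolve_init(dataset, config, init, pu_node)
    total = scorer.structure_score(current).total
    trace: list[dict] = []
    for _ in range(config.max_iter):
        moves = neighborhood(current, config)
        best_move, best_delta = None, _EPS
        for m in moves:
            d = move_delta(scorer, current, m)
            # ties within 1e-9 (score equivalence makes exact ties common)
            # resolve to the first move in enumeration order
            if d > best_delta + 1e-9:
                best_move, best_delta = m, d
        if best_move is None:
            break
        current = apply_move(current, best_move)
        total += best_delta
        trace.append({"move": best_move, "delta": best_delta, "total": total, "accepted": True})
    return current, scorer.structure_score(current), trace


def repeated_hill_climb(
    dataset: DiscreteDataset,
    config: SearchConfig,
    init: NetworkStructure | None = None,
    pu_node: str | None = None,
) -> tuple[NetworkStructure, ScoreValue]:
    """Best result over ``restarts`` hill climbs.  Restart ``i`` starts from
    the best structure so far perturbed by ``2*i`` random legal moves, so the
    search explores around the incumbent while staying reproducible."""
    scorer = FamilyScorer(dataset, config.score, config.ess)
    best, best_score, _ = hill_climb(dataset, config, init, pu_node, scorer)
    rng = np.random.default_rng(config.seed)
    for i in range(1, config.restarts):
        start = best.copy()
        for _ in range(2 * i):
            moves = neighborhood(start, config)
            if not moves:
                break
            start = apply_move(start, moves[rng.integers(len(moves))])
        cand, cand_score, _ = hill_climb(dataset, config, start, pu_node, scorer)
        if cand_score.total > best_score.total + _EPS:
            best, best_score = cand, cand_score
    return best, best_score


def tabu_search(
    dataset: DiscreteDataset,
    config: SearchConfig,
    init: NetworkStructure | None = None,
    pu_node: str | None = None,
) -> tuple[NetworkStructure, ScoreValue, list[dict]]:
    """Tabu search: take the best *non-tabu* move each step, even when it
    worsens the score; the inverse of each applied move enters a FIFO list of
    length ``tabu_length``.  Returns the best structure visited.  Stops after
    ``tabu_patience`` consecutive steps without improving the best score."""
    if dataset.n == 0:
        raise ValueError("empty dataset")
    scorer = FamilyScorer(dataset, config.score, config.ess)
    current = _resolve_init(dataset, config, init, pu_node)
    total = scorer.structure_score(current).total
    best, best_total = current, total
    tabu: deque[Move] = deque(maxlen=config.tabu_length)
    trace: list[dict] = []
    stall = 0
    for _ in range(config.max_iter):
        moves = [m for m in neighborhood(current, config) if m not in tabu]
        if not moves:
            break
        best_move, best_delta = None, -math.inf
        for m in moves:
            d = move_delta(scorer, current, m)
            if d > best_delta + 1e-9:  # enumeration-order tie-break
                best_move, best_delta = m, d
        current = apply_move(current, best_move)
        total += best_delta
        tabu.append(best_move.inverse())
        trace.append({"move": best_move, "delta": best_delta, "total": total,
                      "accepted": True, "tabu_size": len(tabu)})
        if total > best_total + _EPS:
            best, best_total = current, total
            stall = 0
        else:
            stall += 1
            if stall >= config.tabu_patience:
                break
    return best, scorer.structure_score(best), trace


def simulated_annealing(
    dataset: DiscreteDataset,
    config: SearchConfig,
    init: NetworkStructure | None = None,
    pu_node: str | None = None,
) -> tuple[NetworkStructure, ScoreValue]:
    """Simulated annealing: propose a uniformly random legal move, accept
    with probability ``min(1, exp(delta / T))``, cool geometrically from
    ``t0`` to ``t_min``.  Returns the best structure visited."""
    if dataset.n == 0:
        raise ValueError("empty dataset")
    scorer = FamilyScorer(dataset, config.score, config.ess)
    rng = np.random.default_rng(config.seed)
    current = _resolve_init(dataset, config, init, pu_node)
    total = scorer.structure_score(current).total
    best, best_total = current, total
    temp = config.t0
    moves = neighborhood(current, config)  # valid until the structure changes
    iters = 0
    while temp > config.t_min and iters < config.max_iter:
        for _ in range(config.steps_per_temp):
            iters += 1
            if not moves:
                break
            m = moves[rng.integers(len(moves))]
            d = move_delta(scorer, current, m)
            if d >= 0 or rng.random() < math.exp(d / temp):
                current = apply_move(current, m)
                total += d
                moves = neighborhood(current, config)
                if total > best_total + _EPS:
                    best, best_total = current, total
        temp *= config.cooling
    return best, scorer.structure_score(best)


def _all_dags(variables) -> Iterable[NetworkStructure]:
    """Every DAG on the given labelled variables (pair-orientation product,
    cycles filtered)."""
    names = [v.name for v in variables]
    pairs = [(names[i], names[j]) for i in range(len(names)) for j in range(i + 1, len(names))]
    n_pairs = len(pairs)
    for mask in range(3 ** n_pairs):
        parents: dict[str, list[str]] = {n: [] for n in names}
        m = mask
        for (a, b) in pairs:
            state = m % 3
            m //= 3
            if state == 1:
                parents[b].append(a)  # a -> b
            elif state == 2:
                parents[a].append(b)  # b -> a
        try:
            yield NetworkStructure(variables, parents)
        except ValueError:
            continue


def exhaustive_search(
    dataset: DiscreteDataset, score: str = "bdeu", ess: float = 10.0
) -> tuple[NetworkStructure, ScoreValue]:
    """Enumerate every DAG (at most 4 variables, 543 DAGs) and return the
    maximizer; ties go to the structure with fewest edges, then to the first
    enumerated."""
    if len(dataset.variables) > 4:
        raise ValueError("exhaustive search is limited to 4 variables")
    scorer = FamilyScorer(dataset, score, ess)
    best: NetworkStructure | None = None
    best_total = -math.inf
    best_edges = -1
    for st in _all_dags(dataset.variables):
        total = math.fsum(
            scorer.family_score(v.name, st.parents[v.name]) for v in st.variables
        )
        if total > best_total + 1e-9 or (
            abs(total - best_total) <= 1e-9 and st.n_edges() < best_edges
        ):
            best, best_total, best_edges = st, total, st.n_edges()
    assert best is not None
    return best, scorer.structure_score(best)


def learn_structure(
    dataset: DiscreteDataset,
    config: SearchConfig,
    pu_node: str | None = None,
) -> tuple[NetworkStructure, ScoreValue]:
    """Dispatch on ``config.algorithm``; the uniform entry point used by the
    evaluation harness and the CLI."""
    if config.algorithm == "hill_climb":
        st, sc, _ = hill_climb(dataset, config, pu_node=pu_node)
        return st, sc
    if config.algorithm == "repeated_hill_climb":
        return repeated_hill_climb(dataset, config, pu_node=pu_node)
    if config.algorithm == "tabu":
        st, sc, _ = tabu_search(dataset, config, pu_node=pu_node)
        return st, sc
    return simulated_annealing(dataset, config, pu_node=pu_node)


def write_trace(trace: Sequence[dict], path) -> None:
    """Tab-delimited search trace: step, kind, edge, delta, total, flags."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("step\tkind\tsource\ttarget\tdelta\ttotal\taccepted\ttabu_size\n")
        for i, rec in enumerate(trace):
            m = rec["move"]
            fh.write(
                f"{i}\t{m.kind}\t{m.source}\t{m.target}\t{rec['delta']:.6f}\t"
                f"{rec['total']:.6f}\t{int(rec.get('accepted', True))}\t{rec.get('tabu_size', '')}\n"
            )
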