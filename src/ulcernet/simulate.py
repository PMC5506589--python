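"""Synthetic ICU EHR generator.

Builds ground-truth Bayesian networks over pressure-ulcer (PU) outcome,
Braden-scale, medication-category and three-digit-diagnosis features, samples
admission cohorts from them by ancestral sampling, and optionally wraps the
cohort in raw admission records with planted exclusions so the downstream
screening stage can be exercised end to end without any protected data.

The default :class:`CohortSpec` emulates the study cohort this package is
built around: 7,717 admissions at ~7.6% PU prevalence over 86 features
(18 medication categories, 61 three-digit diagnoses, 7 Braden features).

Topology of the ground truth (see the methods note for rationale): the PU
node has two diagnosis parents, three children (friction & shear plus two
diagnoses by default) and two co-parents, so its Markov blanket is a strict
nontrivial subset of the variables; remaining features attach as children of
PU's children ("grandchildren", carrying indirect signal) or stay isolated;
declared noise features are always disconnected from PU.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort import (
    BRADEN_BAND,
    BRADEN_SUBSCALES,
    BRADEN_TOTAL,
    ID_COLUMN,
    PU_COLUMN,
    Variable,
    braden_band,
)
from .network import NetworkStructure, markov_blanket

__all__ = [
    "CohortSpec",
    "GroundTruthNetwork",
    "make_ground_truth",
    "sample_cohort",
    "emit_raw_admissions",
    "DEFAULT_EXCLUSION_RATES",
]

# Curated three-digit ICD-9 categories for diagnosis features (real categories
# frequently implicated in ICU pressure-ulcer cohorts come first; the list is
# padded with further numeric categories, never 707).
_CURATED_DX = [
    "428", "403", "584", "585", "250", "806", "995", "038", "482", "290",
    "730", "401", "486", "785", "599", "344", "507", "518", "324", "996",
    "276", "285", "287", "305", "311", "327", "357", "396", "410", "414",
    "424", "427", "431", "437", "438", "440", "443", "453", "458", "481",
    "491", "493", "511", "512", "519", "530", "536", "553", "560", "567",
    "570", "571", "572", "576", "577", "578", "579", "581", "583", "586",
    "593",
]

_CURATED_MED = [
    "vasoactive", "analgesia", "sedation", "anticoagulant", "antibiotic",
    "diuretic", "insulin", "steroid", "ppi", "antiarrhythmic",
    "beta_blocker", "statin", "bronchodilator", "antiemetic", "laxative",
    "antifungal", "antipsychotic", "benzodiazepine",
]

#: PU-qualifying full ICD-9 codes (any 707.x except .1/.8/.9)
_PU_CODES = ["707.00", "707.02", "707.03", "707.05", "707.07", "707.09",
             "707.20", "707.21", "707.22", "707.23", "707.24", "707.25"]

# --- fixed effect tables for families linked to the outcome ----------------
# Probabilities in the rare rows (PU-positive strata) deliberately sit away
# from 0.5 so that CPTs are recoverable from realistic sample sizes.
_PARENT_MARGINALS = (0.35, 0.30)
_COPARENT_MARGINALS = (0.50, 0.45)
_PU_BETAS = (1.6, 1.2)  # log-odds effects of the diagnosis parents on PU
# P(child=1 | pu, coparent), rows in mixed-radix order (pu, coparent)
_CHILD_WITH_COPARENT = (0.10, 0.30, 0.88, 0.97)
# P(child=1 | pu)
_CHILD_NO_COPARENT = (0.12, 0.85)
# P(friction_shear = s | pu); lower friction & shear score = higher risk
_FRICTION_GIVEN_PU = ((0.12, 0.33, 0.55), (0.60, 0.28, 0.12))
# P(grandchild=1 | binary parent) and | friction & shear state
_GRANDCHILD_BINARY = (0.08, 0.35)
_GRANDCHILD_FRICTION = (0.35, 0.18, 0.08)

_BRADEN_ROOT_MARGINALS = {
    "braden_sensory": (0.20, 0.30, 0.30, 0.20),
    "braden_moisture": (0.15, 0.30, 0.35, 0.20),
    "braden_activity": (0.50, 0.30, 0.15, 0.05),
    "braden_mobility": (0.30, 0.40, 0.20, 0.10),
    "braden_nutrition": (0.20, 0.35, 0.30, 0.15),
}

DEFAULT_EXCLUSION_RATES: dict[str, float] = {
    "underage": 0.01,
    "pu_at_admission": 0.01,
    "short_stay": 0.02,
    "repeat_hospitalization": 0.02,
    "repeat_icu": 0.02,
}


@dataclass(frozen=True)
class CohortSpec:
    """Conditions of a simulated study cohort.

    Defaults mirror the cohort the pipeline is designed for: 7,717 ICU
    admissions with 590 PU cases (prevalence 590/7717 ~ 0.0765) over 18
    medication, 61 diagnosis and 7 Braden features.
    """

    n_admissions: int = 7717
    target_prevalence: float = 590 / 7717
    n_med: int = 18
    n_dx: int = 61
    include_braden: bool = True
    noise_features: int = 0
    seed: int = 0
    raw_mode: bool = False
    #: symmetric Dirichlet concentration for marginals of isolated features
    dirichlet_concentration: float = 1.0

    def __post_init__(self) -> None:
        if self.n_admissions < 1:
            raise ValueError("n_admissions must be >= 1")
        if min(self.n_med, self.n_dx, self.noise_features) < 0:
            raise ValueError("feature counts must be >= 0")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError(
                f"target_prevalence must lie in (0, 1); got {self.target_prevalence}"
            )


@dataclass
class GroundTruthNetwork:
    """A generating Bayesian network: structure, CPTs and the outcome node.

    ``cpts[name]`` has shape ``(q, r)`` in the package-wide mixed-radix row
    convention; ``roles`` records each feature's structural role relative to
    the outcome (parent / child / coparent / grandchild / isolated / noise).
    """

    structure: NetworkStructure
    cpts: dict[str, np.ndarray]
    pu_node: str = PU_COLUMN
    roles: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        self.structure.topological_order()  # raises on cycles
        if self.pu_node not in self.structure:
            raise ValueError(f"outcome node {self.pu_node!r} missing")
        if self.structure.cardinality(self.pu_node) != 2:
            raise ValueError("outcome node must be binary")
        for v in self.structure.variables:
            tab = self.cpts[v.name]
            q, r = self.structure.q(v.name), v.cardinality
            if tab.shape != (q, r):
                raise ValueError(f"CPT of {v.name!r} has shape {tab.shape}, want {(q, r)}")
            if np.abs(tab.sum(axis=1) - 1.0).max() > 1e-12:
                raise ValueError(f"CPT rows of {v.name!r} do not sum to 1")

    def markov_blanket(self) -> set[str]:
        return markov_blanket(self.structure, self.pu_node)

    # -- serialization: GraphML for the DAG, JSON sidecar for the CPTs -----
    def save(self, graphml_path, cpt_path) -> None:
        self.structure.to_graphml(graphml_path, pu_node=self.pu_node)
        payload = {
            "pu_node": self.pu_node,
            "roles": self.roles,
            "cpts": {k: v.tolist() for k, v in self.cpts.items()},
        }
        with open(cpt_path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, graphml_path, cpt_path) -> "GroundTruthNetwork":
        structure = NetworkStructure.from_graphml(graphml_path)
        with open(cpt_path, encoding="utf-8") as fh:
            payload = json.load(fh)
        cpts = {k: np.asarray(v, dtype=float) for k, v in payload["cpts"].items()}
        net = cls(structure, cpts, payload["pu_node"], payload.get("roles", {}))
        net.validate()
        return net


def _binary_names(spec: CohortSpec) -> tuple[list[str], list[str], list[str]]:
    dx_codes = list(_CURATED_DX)
    nxt = 100
    while len(dx_codes) < spec.n_dx:
        code = f"{nxt:03d}"
        nxt += 1
        if code == "707" or code in dx_codes:
            continue
        dx_codes.append(code)
    dx = [f"dx_{c}" for c in dx_codes[: spec.n_dx]]
    meds = list(_CURATED_MED)
    while len(meds) < spec.n_med:
        meds.append(f"cat{len(meds) + 1:02d}")
    med = [f"med_{m}" for m in meds[: spec.n_med]]
    noise = [f"noise_{i}" for i in range(spec.noise_features)]
    return dx, med, noise


def _bernoulli_cpt(p: float) -> np.ndarray:
    return np.array([[1.0 - p, p]])


def _calibrate_pu_cpt(
    parent_marginals: Sequence[float], betas: Sequence[float], target: float
) -> np.ndarray:
    """PU's CPT rows are logistic in its (root) parents; the intercept is
    solved by bisection so that the exact ancestral marginal of PU equals
    ``target``."""
    n_par = len(parent_marginals)
    q = 2 ** n_par
    configs = [[(j >> (n_par - 1 - i)) & 1 for i in range(n_par)] for j in range(q)]
    weights = np.array(
        [
            math.prod(p if x else 1.0 - p for p, x in zip(parent_marginals, cfg))
            for cfg in configs
        ]
    )
    lin = np.array([sum(b * x for b, x in zip(betas, cfg)) for cfg in configs])

    def marginal(base: float) -> float:
        return float(weights @ (1.0 / (1.0 + np.exp(-(base + lin))))) - target

    base = brentq(marginal, -30.0, 30.0, xtol=1e-13)
    p1 = 1.0 / (1.0 + np.exp(-(base + lin)))
    return np.column_stack([1.0 - p1, p1])


def make_ground_truth(spec: CohortSpec, seed: int | None = None) -> GroundTruthNetwork:
    """Build the generating network for ``spec`` (seed controls only the
    marginals of isolated features; the outcome-linked effect tables are
    fixed study conditions).

    The PU node always ends up with at least one parent, one child and one
    co-parent, so its Markov blanket is nontrivial; noise features are never
    connected to it.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    dx, med, noise = _binary_names(spec)
    pool = dx + med
    min_pool = 2 if spec.include_braden else 3
    if len(pool) < min_pool:
        raise ValueError(
            f"need at least {min_pool} medication/diagnosis features to build "
            f"a nontrivial Markov blanket; got {len(pool)}"
        )

    # --- role assignment ---------------------------------------------------
    # Default motif: 2 parents, 3 children, 2 co-parents.  Small pools degrade
    # to 1 of each while always keeping one feature back for the mandatory
    # co-parent, so the Markov blanket is never trivial.
    free = list(pool)
    n_parents = 2 if len(free) >= (3 if spec.include_braden else 4) else 1
    parents = [free.pop(0) for _ in range(n_parents)]
    children: list[str] = []
    if spec.include_braden:
        children.append("braden_friction_shear")
    max_pool_children = 3 - len(children)
    while len(children) < 3 and len(free) > 1 and max_pool_children > 0:
        children.append(free.pop(0))
        max_pool_children -= 1
    # co-parents attach to the first (up to 2) binary children, falling back
    # to friction & shear when the pool is tight
    binary_children = [c for c in children if not c.startswith("braden_")]
    coparent_of: dict[str, str] = {}
    coparents: list[str] = []
    for tgt in (binary_children or children)[:2]:
        if not free:
            break
        cop = free.pop(0)
        coparents.append(cop)
        coparent_of[tgt] = cop
    if not coparents:
        raise ValueError("could not allocate a co-parent for the outcome node")

    roles: dict[str, str] = {PU_COLUMN: "outcome"}
    parents_map: dict[str, list[str]] = {PU_COLUMN: list(parents)}
    cpts: dict[str, np.ndarray] = {}

    for name, p in zip(parents, _PARENT_MARGINALS):
        roles[name] = "parent"
        cpts[name] = _bernoulli_cpt(p)
    cpts[PU_COLUMN] = _calibrate_pu_cpt(
        _PARENT_MARGINALS[: len(parents)], _PU_BETAS[: len(parents)], spec.target_prevalence
    )

    for child in children:
        roles[child] = "child"
        cop = coparent_of.get(child)
        if child == "braden_friction_shear":
            if cop is not None:
                # co-parent shifts friction & shear mildly within each PU stratum
                rows = []
                for pu in (0, 1):
                    base = np.array(_FRICTION_GIVEN_PU[pu])
                    for c in (0, 1):
                        row = base if c == 0 else np.array([base[0] + 0.15, base[1], base[2] - 0.15])
                        rows.append(row / row.sum())
                parents_map[child] = [PU_COLUMN, cop]
                cpts[child] = np.vstack(rows)
            else:
                parents_map[child] = [PU_COLUMN]
                cpts[child] = np.array(_FRICTION_GIVEN_PU)
        else:
            if cop is not None:
                parents_map[child] = [PU_COLUMN, cop]
                p1 = np.array(_CHILD_WITH_COPARENT)
            else:
                parents_map[child] = [PU_COLUMN]
                p1 = np.array(_CHILD_NO_COPARENT)
            cpts[child] = np.column_stack([1.0 - p1, p1])
    for name, p in zip(coparents, _COPARENT_MARGINALS):
        roles[name] = "coparent"
        cpts[name] = _bernoulli_cpt(p)

    # remaining pool features: alternately indirect signal carriers
    # (grandchildren of the outcome) and isolated background features
    for i, name in enumerate(free):
        if i % 2 == 0:
            anchor = children[(i // 2) % len(children)]
            roles[name] = "grandchild"
            parents_map[name] = [anchor]
            if anchor == "braden_friction_shear":
                p1 = np.array(_GRANDCHILD_FRICTION)
            else:
                p1 = np.array(_GRANDCHILD_BINARY)
            cpts[name] = np.column_stack([1.0 - p1, p1])
        else:
            roles[name] = "isolated"
            cpts[name] = _bernoulli_cpt(_isolated_marginal(rng, spec))
    for name in noise:
        roles[name] = "noise"
        cpts[name] = _bernoulli_cpt(_isolated_marginal(rng, spec))

    # Braden roots
    variables: list[Variable] = [Variable(PU_COLUMN, 2)]
    if spec.include_braden:
        for name, (lo, card) in BRADEN_SUBSCALES.items():
            variables.append(Variable(name, card, lo))
            if name not in roles:
                roles[name] = "braden_root"
                cpts[name] = np.asarray(_BRADEN_ROOT_MARGINALS[name], dtype=float)[None, :]
    for name in pool + noise:
        variables.append(Variable(name, 2))

    structure = NetworkStructure(variables, parents_map)
    net = GroundTruthNetwork(structure, cpts, PU_COLUMN, roles)
    net.validate()
    return net


def _isolated_marginal(rng: np.random.Generator, spec: CohortSpec) -> float:
    """Marginal positive rate of a feature unlinked to the outcome: a
    symmetric-Dirichlet draw rescaled into [0.03, 0.35], the range of flag
    prevalences a screening frequency filter should mostly keep."""
    u = rng.dirichlet([spec.dirichlet_concentration] * 2)[1]
    return 0.03 + 0.32 * float(u)


def sample_cohort(net: GroundTruthNetwork, n: int, seed: int = 0) -> pd.DataFrame:
    """Draw ``n`` admissions by ancestral sampling in a topological order.

    The returned cohort carries ``braden_total`` (always the exact sum of the
    six subscales) and its banded version whenever Braden variables are part
    of the network.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    net.validate()
    rng = np.random.default_rng(seed)
    st = net.structure
    sampled: dict[str, np.ndarray] = {}
    for name in st.topological_order():
        v = st.variable(name)
        j = np.zeros(n, dtype=np.int64)
        for p in st.parents[name]:
            j = j * st.cardinality(p) + sampled[p]
        cum = np.cumsum(net.cpts[name], axis=1)[j]
        u = rng.random(n)
        sampled[name] = np.minimum((u[:, None] > cum).sum(axis=1), v.cardinality - 1)

    data: dict[str, np.ndarray] = {
        ID_COLUMN: np.array([f"P{i:06d}" for i in range(n)]),
        PU_COLUMN: sampled[PU_COLUMN],
    }
    braden_cols = [c for c in BRADEN_SUBSCALES if c in st]
    for c in braden_cols:
        data[c] = sampled[c] + st.variable(c).offset
    if braden_cols:
        total = sum(data[c] for c in braden_cols)
        data[BRADEN_TOTAL] = total
        data[BRADEN_BAND] = braden_band(total)
    for v in st.variables:
        if v.name == PU_COLUMN or v.name in BRADEN_SUBSCALES:
            continue
        data[v.name] = sampled[v.name]
    return pd.DataFrame(data)


def _sample_icu_hours(rng: np.random.Generator, n: int) -> np.ndarray:
    """Lognormal ICU length of stay in hours (median ~7.5 days), floored at
    the 36-hour inclusion boundary for records meant to be kept."""
    hours = rng.lognormal(mean=math.log(180.0), sigma=0.8, size=n)
    return np.maximum(np.round(hours, 1), 36.0)


def emit_raw_admissions(
    cohort: pd.DataFrame,
    spec: CohortSpec,
    seed: int = 0,
    rates: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Wrap a sampled cohort in admission-level raw records and plant, at the
    given per-rule ``rates``, records that the screening stage must exclude:
    under-18 admissions, PU-present-at-admission, ICU stays under 36 hours,
    later hospitalizations and later ICU admissions within a hospitalization.

    Every row carries ``truth_keep`` (1 for the original cohort rows) and
    ``truth_drop_reason`` so tests can check the filter exactly.  Diagnosis
    flags are re-expressed as full ICD-9 code strings in ``icd9_codes``;
    PU-positive patients receive a qualifying 707.x code.
    """
    if not spec.raw_mode:
        raise ValueError("emit_raw_admissions requires spec.raw_mode")
    rates = dict(DEFAULT_EXCLUSION_RATES if rates is None else rates)
    rng = np.random.default_rng(seed)
    n = len(cohort)

    dx_cols = [c for c in cohort.columns if c.startswith("dx_")]
    passthrough = [
        c
        for c in cohort.columns
        if c.startswith(("med_", "braden_", "noise_")) and c != BRADEN_BAND and c != BRADEN_TOTAL
    ]

    def codes_for(row: pd.Series) -> str:
        codes = [f"{c[3:]}.{rng.integers(10)}" for c in dx_cols if row[c] == 1]
        if row[PU_COLUMN] == 1:
            codes.append(_PU_CODES[rng.integers(len(_PU_CODES))])
        rng.shuffle(codes)
        return ";".join(codes)

    base = pd.DataFrame(
        {
            ID_COLUMN: cohort[ID_COLUMN].to_numpy(),
            "age": np.clip(np.round(rng.normal(57.7, 15.9, n)), 18, 95).astype(int),
            "hosp_seq": 1,
            "icu_seq": 1,
            "icu_hours": _sample_icu_hours(rng, n),
            "pu_at_admission": 0,
            "icd9_codes": [codes_for(row) for _, row in cohort.iterrows()],
            "truth_keep": 1,
            "truth_drop_reason": "",
        }
    )
    for c in passthrough:
        base[c] = cohort[c].to_numpy()

    planted: list[pd.DataFrame] = []

    def plant(reason: str, count: int) -> pd.DataFrame | None:
        if count < 1:
            return None
        src = base.iloc[rng.integers(n, size=count)].copy().reset_index(drop=True)
        src["truth_keep"] = 0
        src["truth_drop_reason"] = reason
        if reason == "underage":
            src[ID_COLUMN] = [f"X{reason[:2]}{i:05d}" for i in range(count)]
            src["age"] = rng.integers(14, 18, size=count)
        elif reason == "pu_at_admission":
            src[ID_COLUMN] = [f"Xpa{i:05d}" for i in range(count)]
            src["pu_at_admission"] = 1
        elif reason == "short_stay":
            src[ID_COLUMN] = [f"Xss{i:05d}" for i in range(count)]
            src["icu_hours"] = np.round(rng.uniform(6.0, 35.9, size=count), 1)
        elif reason == "repeat_hospitalization":
            src["hosp_seq"] = 2  # same patient_id as a kept first admission
        elif reason == "repeat_icu":
            src["icu_seq"] = 2
        else:
            raise ValueError(f"unknown exclusion rule {reason!r}")
        return src

    for reason, rate in rates.items():
        extra = plant(reason, int(round(rate * n)))
        if extra is not None:
            planted.append(extra)

    raw = pd.concat([base, *planted], ignore_index=True)
    order = rng.permutation(len(raw))
    return raw.iloc[order].reset_index(drop=True)
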