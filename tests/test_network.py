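"""Network core: counts, scores, parameters, Markov blankets, prediction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ulcernet as un
from ulcernet.cohort import PU_COLUMN
from ulcernet.network import (
    DiscreteDataset,
    FamilyScorer,
    NetworkStructure,
    ParameterSet,
    Variable,
    dag_to_cpdag,
    family_counts,
    markov_blanket,
    predict_pu,
    pu_posterior,
    shd_cpdag,
)

from conftest import (
    joint_posterior,
    naive_family_counts,
    random_dag,
    random_parameters,
)


def _ds(matrix, cards):
    return DiscreteDataset(np.asarray(matrix), [Variable(f"v{i}", c) for i, c in enumerate(cards)])


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

def test_structure_rejects_cycles_and_duplicates():
    st_ = NetworkStructure([Variable("a", 2), Variable("b", 2), Variable("c", 2)])
    st_.add_edge("a", "b")
    st_.add_edge("b", "c")
    with pytest.raises(ValueError):
        st_.add_edge("c", "a")
    with pytest.raises(ValueError):
        st_.add_edge("a", "b")
    with pytest.raises(ValueError):
        st_.add_edge("a", "a")
    assert st_.topological_order() == ["a", "b", "c"]
    assert st_.q("c") == 2 and st_.q("a") == 1
    assert st_.n_params() == 1 + 2 + 2


def test_structure_graphml_round_trip(tmp_path):
    st_ = NetworkStructure(
        [Variable("pu", 2), Variable("braden_mobility", 4, 1), Variable("dx_428", 2)],
        {"dx_428": ["pu"], "braden_mobility": ["pu"]},
    )
    path = tmp_path / "net.graphml"
    st_.to_graphml(path, pu_node="pu")
    back = NetworkStructure.from_graphml(path)
    assert {v.name: (v.cardinality, v.offset) for v in back.variables} == {
        v.name: (v.cardinality, v.offset) for v in st_.variables
    }
    assert {k: set(v) for k, v in back.parents.items()} == {
        k: set(v) for k, v in st_.parents.items()
    }


def test_dot_export_highlights_markov_blanket():
    st_ = NetworkStructure(
        [Variable(n, 2) for n in "abcd"], {"c": ["a", "b"], "d": ["c"]}
    )
    mb = markov_blanket(st_, "c")
    dot = st_.to_dot(mb, pu_node="c")
    for n in mb:
        assert f'"{n}" [cardinality="2", highlight="true"' in dot
    assert '"c" [cardinality="2", shape="doublecircle"]' in dot
    assert '"a" -> "c";' in dot


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def test_family_counts_examples():
    ds = _ds([[1], [1], [0], [1]], [2])
    ct = family_counts(ds, "v0", [])
    assert ct.table.tolist() == [[1, 3]]
    assert ct.nij.tolist() == [4]

    ds2 = _ds([[0, 0], [0, 1], [1, 1], [1, 1]], [2, 2])
    ct2 = family_counts(ds2, "v1", ["v0"])
    assert ct2.table[1].tolist() == [0, 2]
    assert ct2.table.sum() == 4


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_family_counts_match_naive_loop(seed):
    rng = np.random.default_rng(seed)
    cards = [int(rng.integers(2, 4)) for _ in range(4)]
    mat = np.column_stack([rng.integers(c, size=30) for c in cards])
    ds = _ds(mat, cards)
    var = int(rng.integers(4))
    parents = [i for i in range(4) if i != var and rng.random() < 0.5]
    got = family_counts(ds, f"v{var}", [f"v{p}" for p in parents]).table
    want = naive_family_counts(mat, cards, var, parents)
    assert np.array_equal(got, want)


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------

def test_loglikelihood_fixture():
    ds = _ds([[1], [1], [0], [1]], [2])
    ll = un.loglikelihood(ds, NetworkStructure([Variable("v0", 2)]))
    assert ll.total == pytest.approx(3 * math.log(3 / 4) + math.log(1 / 4), abs=1e-12)
    assert ll.check()


def test_loglikelihood_deterministic_data_is_zero():
    ds = _ds([[1, 0], [1, 0], [1, 0], [1, 0]], [2, 2])
    st_ = NetworkStructure(ds.variables, {"v1": ["v0"]})
    assert un.loglikelihood(ds, st_).total == pytest.approx(0.0, abs=1e-12)


def test_loglikelihood_monotone_in_edges():
    rng = np.random.default_rng(3)
    for _ in range(20):
        mat = rng.integers(2, size=(40, 3))
        ds = _ds(mat, [2, 2, 2])
        empty = NetworkStructure(ds.variables)
        with_edge = NetworkStructure(ds.variables, {"v1": ["v0"]})
        assert un.loglikelihood(ds, with_edge).total >= un.loglikelihood(ds, empty).total - 1e-9


def test_bdeu_fixture_matches_beta_bernoulli():
    ds = _ds([[1], [1], [0], [1]], [2])
    got = un.bdeu_score(ds, NetworkStructure([Variable("v0", 2)]), ess=1.0)
    assert got.total == pytest.approx(math.log(0.9375 / 24), abs=1e-9)


def test_bdeu_empty_dataset_scores_zero():
    ds = _ds(np.empty((0, 2), dtype=int), [2, 2])
    st_ = NetworkStructure(ds.variables, {"v1": ["v0"]})
    assert un.bdeu_score(ds, st_, ess=4.0).total == pytest.approx(0.0, abs=1e-12)


def test_bdeu_score_equivalence_random_datasets():
    rng = np.random.default_rng(11)
    for _ in range(100):
        mat = rng.integers(2, size=(rng.integers(5, 40), 2))
        ds = _ds(mat, [2, 2])
        xy = un.bdeu_score(ds, NetworkStructure(ds.variables, {"v1": ["v0"]}), ess=3.0)
        yx = un.bdeu_score(ds, NetworkStructure(ds.variables, {"v0": ["v1"]}), ess=3.0)
        assert xy.total == pytest.approx(yx.total, abs=1e-9)


def test_bdeu_large_ess_approaches_uniform_limit():
    """With an overwhelming prior the BDeu predictive is uniform, so the
    score tends to N * ln(1/r)."""
    ds = _ds([[1], [1], [0], [1]], [2])
    st_ = NetworkStructure([Variable("v0", 2)])
    big = un.bdeu_score(ds, st_, ess=1e8).total
    assert big == pytest.approx(4 * math.log(0.5), abs=1e-4)


def test_bdeu_requires_positive_ess():
    ds = _ds([[0]], [2])
    with pytest.raises(ValueError):
        FamilyScorer(ds, "bdeu", 0.0)


def test_mdl_identity_and_penalty():
    ds = _ds([[1], [1], [0], [1]], [2])
    st_ = NetworkStructure([Variable("v0", 2)])
    mdl = un.mdl_score(ds, st_)
    ll = un.loglikelihood(ds, st_)
    assert mdl.total == pytest.approx(ll.total - math.log(4) / 2 * 1, abs=1e-12)
    # adding a binary parent raises |B_s| from 1 to 2
    rng = np.random.default_rng(0)
    mat = rng.integers(2, size=(64, 2))
    ds2 = _ds(mat, [2, 2])
    lone = NetworkStructure(ds2.variables)
    linked = NetworkStructure(ds2.variables, {"v1": ["v0"]})
    pen_delta = (un.loglikelihood(ds2, linked).total - un.mdl_score(ds2, linked).total) - (
        un.loglikelihood(ds2, lone).total - un.mdl_score(ds2, lone).total
    )
    assert pen_delta == pytest.approx(math.log(64) / 2, abs=1e-9)


def test_score_decomposability_incremental_equals_full():
    rng = np.random.default_rng(5)
    mat = rng.integers(2, size=(200, 4))
    ds = _ds(mat, [2, 2, 2, 2])
    scorer = FamilyScorer(ds, "bdeu", 10.0)
    st_ = NetworkStructure(ds.variables, {"v1": ["v0"], "v3": ["v1", "v2"]})
    base = scorer.structure_score(st_)
    assert base.check()
    st2 = st_.copy()
    st2.add_edge("v0", "v3")
    full = scorer.structure_score(st2).total
    incr = base.total - base.families["v3"] + scorer.family_score("v3", ("v1", "v2", "v0"))
    assert full == pytest.approx(incr, abs=1e-9)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

def test_estimate_parameters_fixtures():
    ds = _ds([[1], [1], [0], [1]], [2])
    st_ = NetworkStructure([Variable("v0", 2)])
    smoothed = un.estimate_parameters(ds, st_, prior=1.0)
    assert np.allclose(smoothed.tables["v0"], [[2 / 6, 4 / 6]])
    ml = un.estimate_parameters(ds, st_, prior=0.0)
    assert np.allclose(ml.tables["v0"], [[0.25, 0.75]])


def test_estimate_parameters_unobserved_rows():
    ds = _ds([[0, 0], [0, 1]], [2, 2])  # parent state 1 never observed
    st_ = NetworkStructure(ds.variables, {"v1": ["v0"]})
    smoothed = un.estimate_parameters(ds, st_, prior=1.0)
    assert np.allclose(smoothed.tables["v1"][1], [0.5, 0.5])  # uniform prior row
    ml = un.estimate_parameters(ds, st_, prior=0.0)
    assert ("v1", 1) in ml.undefined_rows
    assert np.isnan(ml.tables["v1"][1]).all()


def test_estimate_parameters_rows_sum_to_one():
    rng = np.random.default_rng(8)
    for _ in range(20):
        cards = [int(rng.integers(2, 4)) for _ in range(3)]
        mat = np.column_stack([rng.integers(c, size=50) for c in cards])
        ds = _ds(mat, cards)
        st_ = NetworkStructure(ds.variables, {"v2": ["v0", "v1"]})
        ps = un.estimate_parameters(ds, st_, prior=1.0)
        for tab in ps.tables.values():
            assert np.abs(tab.sum(axis=1) - 1.0).max() <= 1e-12


def test_parameter_set_json_round_trip():
    ds = _ds([[0, 0], [1, 1], [0, 1]], [2, 2])
    st_ = NetworkStructure(ds.variables, {"v1": ["v0"]})
    ps = un.estimate_parameters(ds, st_, prior=1.0)
    back = ParameterSet.from_json(ps.to_json(st_))
    assert back.prior == 1.0
    for k in ps.tables:
        assert np.allclose(back.tables[k], ps.tables[k])


def test_parameter_recovery_from_ground_truth(net8):
    """CPTs re-estimated from 50,000 ancestral samples on the true structure
    recover the generator's tables within 0.02 max absolute error."""
    coh = un.sample_cohort(net8, 50_000, seed=17)
    ds = DiscreteDataset.from_frame(coh, [v.name for v in net8.structure.variables])
    est = un.estimate_parameters(ds, net8.structure, prior=1.0)
    err = max(np.abs(est.tables[k] - net8.cpts[k]).max() for k in net8.cpts)
    assert err <= 0.02


# ---------------------------------------------------------------------------
# Markov blankets
# ---------------------------------------------------------------------------

def test_markov_blanket_examples():
    st_ = NetworkStructure([Variable(n, 2) for n in "abcd"], {"c": ["a", "b"], "d": ["c"]})
    assert markov_blanket(st_, "c") == {"a", "b", "d"}
    nb = NetworkStructure(
        [Variable(n, 2) for n in ["pu", "f1", "f2", "f3"]],
        {"f1": ["pu"], "f2": ["pu"], "f3": ["pu"]},
    )
    assert markov_blanket(nb, "pu") == {"f1", "f2", "f3"}
    iso = NetworkStructure([Variable("x", 2), Variable("y", 2)])
    assert markov_blanket(iso, "x") == set()
    with pytest.raises(KeyError):
        markov_blanket(iso, "zz")


def test_markov_blanket_symmetry_random_dags():
    rng = np.random.default_rng(19)
    names = list("abcdefgh")
    for _ in range(40):
        st_ = random_dag(names, 0.3, rng)
        for x in names:
            for y in names:
                if x != y:
                    assert (x in markov_blanket(st_, y)) == (y in markov_blanket(st_, x))


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def test_predict_pu_naive_bayes_hand_example():
    st_ = NetworkStructure(
        [Variable("pu", 2), Variable("f1", 2), Variable("f2", 2)],
        {"f1": ["pu"], "f2": ["pu"]},
    )
    tables = {
        "pu": np.array([[0.9, 0.1]]),
        "f1": np.array([[0.8, 0.2], [0.2, 0.8]]),
        "f2": np.array([[0.5, 0.5], [0.4, 0.6]]),
    }
    ps = ParameterSet(tables, 0.0)
    post = predict_pu(st_, ps, {"f1": 1, "f2": 1}, "pu")
    assert post == pytest.approx(0.048 / 0.138, abs=1e-12)


def test_predict_pu_disconnected_returns_prior():
    st_ = NetworkStructure([Variable("pu", 2), Variable("f", 2)])
    ps = ParameterSet({"pu": np.array([[0.93, 0.07]]), "f": np.array([[0.5, 0.5]])}, 0.0)
    assert predict_pu(st_, ps, {"f": 0}, "pu") == pytest.approx(0.07)


def test_predict_pu_validates_evidence():
    st_ = NetworkStructure([Variable("pu", 2), Variable("f", 3, 1)], {"f": ["pu"]})
    ps = ParameterSet({"pu": np.array([[0.9, 0.1]]),
                       "f": np.array([[0.5, 0.3, 0.2], [0.2, 0.3, 0.5]])}, 0.0)
    with pytest.raises(KeyError):
        predict_pu(st_, ps, {}, "pu")
    with pytest.raises(ValueError):
        predict_pu(st_, ps, {"f": 9}, "pu")
    assert 0 <= predict_pu(st_, ps, {"f": 3}, "pu") <= 1  # offset handled


def test_posterior_matches_joint_enumeration_random_networks():
    rng = np.random.default_rng(23)
    for _ in range(40):
        k = int(rng.integers(2, 9))
        names = ["pu"] + [f"x{i}" for i in range(k)]
        cards = {n: 2 if n == "pu" else int(rng.integers(2, 4)) for n in names}
        st_ = random_dag(names, 0.35, rng, cards=cards, max_parents=3)
        ps = random_parameters(st_, rng)
        ev = {n: int(rng.integers(cards[n])) for n in names if n != "pu"}
        mat = np.array([[ev.get(v.name, 0) for v in st_.variables]])
        got = pu_posterior(st_, ps, DiscreteDataset(mat, st_.variables), "pu")[0]
        want = joint_posterior(st_, ps, ev, "pu")
        assert got == pytest.approx(want, abs=1e-9)


def test_posterior_zero_mass_falls_back_to_prior():
    st_ = NetworkStructure([Variable("pu", 2), Variable("f", 2)], {"f": ["pu"]})
    ps = ParameterSet({
        "pu": np.array([[0.9, 0.1]]),
        "f": np.array([[1.0, 0.0], [1.0, 0.0]]),  # f=1 impossible under both pu states
    }, 0.0)
    assert predict_pu(st_, ps, {"f": 1}, "pu") == pytest.approx(0.1)


# ---------------------------------------------------------------------------
# CPDAGs
# ---------------------------------------------------------------------------

def test_cpdag_known_cases():
    # chain a->b->c: fully reversible
    chain = NetworkStructure([Variable(n, 2) for n in "abc"], {"b": ["a"], "c": ["b"]})
    directed, undirected = dag_to_cpdag(chain)
    assert directed == set()
    assert undirected == {frozenset(("a", "b")), frozenset(("b", "c"))}
    # collider a->c<-b: fully compelled
    coll = NetworkStructure([Variable(n, 2) for n in "abc"], {"c": ["a", "b"]})
    directed, undirected = dag_to_cpdag(coll)
    assert directed == {("a", "c"), ("b", "c")}
    assert undirected == set()


def test_shd_examples(net8):
    assert shd_cpdag(net8.structure, net8.structure) == 0
    st2 = net8.structure.copy()
    pu = net8.pu_node
    child = net8.structure.children(pu)[0]
    st2.remove_edge(pu, child)
    assert shd_cpdag(net8.structure, st2) >= 1
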