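"""True-structure derivation and SHD vs a breadth-first edit oracle."""

from collections import deque
from itertools import combinations, product

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gdbn import (
    DBNStructure,
    DimensionError,
    ScoreSpec,
    SliceNode,
    evaluate_learned,
    fixture_process,
    fold,
    network_score,
    shd,
    simulate_series,
    true_structure,
)
from gdbn.simulate import FIXTURE_MATRICES

NODES4 = tuple(SliceNode(v, 0) for v in "abcd")
PAIRS4 = list(combinations(NODES4, 2))


def _acyclic(arcs):
    adj = {}
    for u, v in arcs:
        adj.setdefault(u, []).append(v)
    state = {}

    def visit(x):
        state[x] = 1
        for y in adj.get(x, ()):
            if state.get(y) == 1 or (y not in state and visit(y)):
                return True
        state[x] = 2
        return False

    return not any(x not in state and visit(x) for x in list(adj))


def all_dags4():
    """Every DAG over 4 slice-0 nodes, as frozensets of arcs."""
    out = []
    for states in product(range(3), repeat=len(PAIRS4)):
        arcs = []
        for (u, v), s in zip(PAIRS4, states):
            if s == 1:
                arcs.append((u, v))
            elif s == 2:
                arcs.append((v, u))
        if _acyclic(arcs):
            out.append(frozenset(arcs))
    return out


DAGS4 = all_dags4()
DAG_INDEX = {g: i for i, g in enumerate(DAGS4)}


def bfs_edit_distance(a: frozenset, b: frozenset) -> int:
    """Minimum adds + deletes + reversals from a to b, staying acyclic.

    Breadth-first search over the full enumerated DAG space; entirely
    independent of the closed-form shd computation.
    """
    if a == b:
        return 0
    seen = {a}
    frontier = deque([(a, 0)])
    while frontier:
        g, d = frontier.popleft()
        for nxt in _neighbors(g):
            if nxt == b:
                return d + 1
            if nxt not in seen:
                seen.add(nxt)
                frontier.append((nxt, d + 1))
    raise AssertionError("edit space is connected; unreachable")


def _neighbors(g: frozenset):
    for u, v in PAIRS4:
        has_uv, has_vu = (u, v) in g, (v, u) in g
        if has_uv:
            yield g - {(u, v)}
            rev = (g - {(u, v)}) | {(v, u)}
            if rev in DAG_INDEX:
                yield rev
        elif has_vu:
            yield g - {(v, u)}
            rev = (g - {(v, u)}) | {(u, v)}
            if rev in DAG_INDEX:
                yield rev
        else:
            for arc in ((u, v), (v, u)):
                cand = g | {arc}
                if cand in DAG_INDEX:
                    yield cand


def test_true_structure_from_matrices():
    assert true_structure(np.zeros((3, 3))).arcs == set()
    g5 = true_structure(FIXTURE_MATRICES["k5"])
    assert len(g5.arcs) == 10  # nonzero count of the 5x5 matrix
    assert all(u.slice == 1 and v.slice == 0 for u, v in g5.arcs)
    gd = true_structure(np.diag([0.5, 0.5]))
    assert gd.arcs == {
        (SliceNode("X1", 1), SliceNode("X1", 0)),
        (SliceNode("X2", 1), SliceNode("X2", 0)),
    }


def test_shd_basic_identities():
    g5 = true_structure(FIXTURE_MATRICES["k5"])
    empty = DBNStructure(g5.nodes)
    assert shd(g5, g5) == 0
    assert shd(empty, g5) == 10
    assert shd(g5, empty) == 10
    with pytest.raises(DimensionError):
        shd(empty, DBNStructure([SliceNode("z", 0)]))


def test_single_reversal_costs_one():
    nodes = NODES4
    a = DBNStructure(nodes, [(NODES4[0], NODES4[1])])
    b = DBNStructure(nodes, [(NODES4[1], NODES4[0])])
    assert shd(a, b) == 1


@given(data=st.data())
def test_shd_matches_bfs_oracle(data):
    i = data.draw(st.integers(0, len(DAGS4) - 1))
    j = data.draw(st.integers(0, len(DAGS4) - 1))
    a, b = DAGS4[i], DAGS4[j]
    ga, gb = DBNStructure(NODES4, a), DBNStructure(NODES4, b)
    assert shd(ga, gb) == bfs_edit_distance(a, b)


@given(data=st.data())
def test_shd_metric_properties(data):
    idx = [data.draw(st.integers(0, len(DAGS4) - 1)) for _ in range(3)]
    ga, gb, gc = (DBNStructure(NODES4, DAGS4[i]) for i in idx)
    assert shd(ga, gb) == shd(gb, ga)
    assert shd(ga, gc) <= shd(ga, gb) + shd(gb, gc)
    assert (shd(ga, gb) == 0) == (ga.arcs == gb.arcs)


def test_evaluate_learned_beats_null(k5_process):
    # learning with BIC on ample data: SHD well below the empty graph's
    from gdbn import restrict, tabu_search, temporal_pattern
    from gdbn.constraint import iamb_blanket

    s = simulate_series(k5_process, 1000, seed=17)
    f = fold(s, 1)
    truth = true_structure(k5_process.C, s.variable_names)
    pattern = temporal_pattern(s.variable_names, 1)
    corr = f.correlation()
    blankets = {
        t: iamb_blanket(t, [nd for nd in f.nodes if nd != t], f, _corr=corr)
        for t in f.nodes
        if t.slice == 0
    }
    cons = restrict(blankets, pattern)
    learned = tabu_search(f, ScoreSpec("bic-g"), cons)
    rec = evaluate_learned(learned, f, truth, replicate=3, criterion_label="bic-g")
    assert rec.shd < shd(DBNStructure(f.nodes), truth)
    empty_score = network_score(DBNStructure(f.nodes), f, ScoreSpec("bic-g"))
    assert rec.eval_score >= empty_score
    assert rec.replicate == 3 and rec.n == f.n


def test_learning_consistency_trend(k5_process):
    # estimator sanity: mean SHD at n=2000 is <= mean SHD at n=100
    from gdbn import restrict, tabu_search, temporal_pattern
    from gdbn.constraint import iamb_blanket

    def mean_shd(n, reps=3):
        vals = []
        for r in range(reps):
            proc = fixture_process("k5", seed=100 + r)
            s = simulate_series(proc, n, seed=200 + r)
            f = fold(s, 1)
            truth = true_structure(proc.C, s.variable_names)
            pattern = temporal_pattern(s.variable_names, 1)
            corr = f.correlation()
            blankets = {
                t: iamb_blanket(t, [nd for nd in f.nodes if nd != t], f, _corr=corr)
                for t in f.nodes
                if t.slice == 0
            }
            g = tabu_search(f, ScoreSpec("bic-g"), restrict(blankets, pattern))
            vals.append(shd(g, truth))
        return np.mean(vals)

    assert mean_shd(2000) <= mean_shd(100)
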