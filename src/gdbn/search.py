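"""Maximize phase: Tabu search over temporally constrained DAGs.

The search walks the space of DAGs reachable by single-arc moves (add,
delete, reverse) that respect the constraint blacklist and acyclicity.
Because the score decomposes over nodes, each move is evaluated through
the delta of the affected child terms only, with local scores memoized
in a :class:`~gdbn.scores.ScoreCache`.  A fixed-length tabu list of
inverse-move attributes blocks immediate backtracking; a tabu move is
still taken if it beats the best structure seen so far (aspiration).
The incumbent best structure is returned, so the result never scores
below the empty graph it starts from.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Callable

from .constraint import ConstraintSet
from .core import DBNStructure, FoldedDataset, SliceNode
from .errors import ConfigurationError
from .scores import ScoreCache, ScoreSpec

__all__ = ["TabuParams", "tabu_search"]

Arc = tuple[SliceNode, SliceNode]


@dataclass(frozen=True)
class TabuParams:
    """Search-control knobs: list length, iteration cap, stall cap."""

    tabu_length: int = 10
    max_iter: int = 2000
    max_stall: int = 10

    def __post_init__(self) -> None:
        if min(self.tabu_length, self.max_iter, self.max_stall) < 1:
            raise ConfigurationError("all tabu parameters must be positive")


def _creates_cycle(
    parents: dict[SliceNode, frozenset[SliceNode]], u: SliceNode, v: SliceNode
) -> bool:
    """Would adding u -> v close a directed cycle?

    Only intra-slice arcs (slice 0 -> slice 0) can participate in cycles,
    so walk the slice-0 ancestors of u looking for v.
    """
    if u.slice != 0 or v.slice != 0:
        return False
    stack, seen = [u], {u}
    while stack:
        x = stack.pop()
        if x == v:
            return True
        for p in parents[x]:
            if p.slice == 0 and p not in seen:
                seen.add(p)
                stack.append(p)
    return False


def tabu_search(
    data: FoldedDataset,
    spec: ScoreSpec,
    constraints: ConstraintSet,
    params: TabuParams = TabuParams(),
    trace: Callable[[int, str, float, float], None] | None = None,
) -> DBNStructure:
    """Score-maximizing Tabu search from the empty graph.

    Deterministic for fixed inputs: the neighborhood is enumerated in
    sorted order and ties broken lexicographically.  Stops after
    ``max_stall`` consecutive iterations without improving the incumbent,
    or ``max_iter`` iterations, whichever comes first.  ``trace``, if
    given, receives (iteration, move description, move score, incumbent).
    """
    nodes = constraints.nodes
    if set(nodes) != set(data.nodes):
        raise ConfigurationError("constraint nodes do not match dataset columns")
    cache = ScoreCache(data, spec)
    allowed = set(constraints.allowed_arcs())

    parents: dict[SliceNode, frozenset[SliceNode]] = {nd: frozenset() for nd in nodes}
    local = {nd: cache.local(nd, parents[nd]) for nd in nodes}
    current_arcs: set[Arc] = set()
    current_score = sum(local.values())

    best_arcs = set(current_arcs)
    best_score = current_score

    if not allowed:
        return DBNStructure(nodes, best_arcs)

    tabu: deque = deque(maxlen=params.tabu_length)
    stall = 0

    for it in range(params.max_iter):
        # enumerate the full neighborhood with incremental score deltas
        moves = []  # (delta, kind, (u, v), attr, {node: new parent set})
        for u, v in sorted(allowed - current_arcs):
            if _creates_cycle(parents, u, v):
                continue
            new_ps = parents[v] | {u}
            delta = cache.local(v, new_ps) - local[v]
            moves.append((delta, "add", (u, v), ("add", u, v), {v: new_ps}))
        for u, v in sorted(current_arcs):
            new_ps = parents[v] - {u}
            delta = cache.local(v, new_ps) - local[v]
            moves.append((delta, "delete", (u, v), ("delete", u, v), {v: new_ps}))
            # reverse is legal only when the reversed arc is itself allowed
            # (inter-slice reversals would point backward in time and are
            # never in the allowed set) and does not close a cycle
            if (v, u) in allowed and (v, u) not in current_arcs:
                ps_v = parents[v] - {u}
                ps_u = parents[u] | {v}
                without = dict(parents)
                without[v] = ps_v
                if _creates_cycle(without, v, u):
                    continue
                delta = (
                    cache.local(v, ps_v) - local[v] + cache.local(u, ps_u) - local[u]
                )
                moves.append(
                    (delta, "reverse", (u, v), ("reverse", u, v), {v: ps_v, u: ps_u})
                )
        if not moves:
            break

        moves.sort(key=lambda m: (-m[0], m[1], m[2]))
        chosen = None
        for delta, kind, arc, attr, updates in moves:
            if attr not in tabu or current_score + delta > best_score:
                chosen = (delta, kind, arc, attr, updates)
                break
        if chosen is None:  # every move tabu and none aspires
            break
        delta, kind, arc, attr, updates = chosen

        u, v = arc
        if kind == "add":
            current_arcs.add(arc)
            tabu.append(("delete", u, v))
        elif kind == "delete":
            current_arcs.discard(arc)
            tabu.append(("add", u, v))
        else:
            current_arcs.discard(arc)
            current_arcs.add((v, u))
            tabu.append(("reverse", v, u))
        for nd, ps in updates.items():
            parents[nd] = ps
            local[nd] = cache.local(nd, ps)
        current_score += delta

        if current_score > best_score + 1e-12:
            best_score = current_score
            best_arcs = set(current_arcs)
            stall = 0
        else:
            stall += 1
        if trace is not None:
            trace(it, f"{kind} {u.name}->{v.name}", current_score, best_score)
        if stall >= params.max_stall:
            break

    return DBNStructure(nodes, best_arcs)
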