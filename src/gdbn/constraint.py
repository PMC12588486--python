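"""Restrict phase: Fisher-z tests, IAMB Markov blankets, temporal pattern.

The hybrid learner first shrinks the candidate arc set.  Conditional
independence between Gaussian variables is tested with the Fisher
z-transform of the partial correlation; IAMB grows a Markov blanket for
every slice-0 node by repeatedly adding the most associated candidate
that still tests dependent, then shrinks away false positives.  Blanket
membership is combined with the temporal arc pattern (arcs may only end
in slice 0) into a blacklist handed to the score-based search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import FoldedDataset, SliceNode
from .errors import ConfigurationError, DimensionError

__all__ = [
    "CITestResult",
    "ConstraintSet",
    "fisher_z_test",
    "iamb_blanket",
    "temporal_pattern",
    "restrict",
]

Arc = tuple[SliceNode, SliceNode]


@dataclass(frozen=True)
class CITestResult:
    x: SliceNode
    y: SliceNode
    conditioning_set: frozenset[SliceNode]
    partial_correlation: float
    statistic: float
    p_value: float


@dataclass
class ConstraintSet:
    """Forbidden (blacklist) and forced (whitelist) arcs for the search."""

    nodes: tuple[SliceNode, ...]
    blacklist: frozenset[Arc]
    whitelist: frozenset[Arc] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.blacklist & self.whitelist:
            raise ConfigurationError("blacklist and whitelist must be disjoint")

    def allowed_arcs(self) -> list[Arc]:
        out = []
        for u in self.nodes:
            for v in self.nodes:
                if u != v and (u, v) not in self.blacklist:
                    out.append((u, v))
        return sorted(out)

    def arcs_frame(self) -> pd.DataFrame:
        rows = sorted((u.name, v.name) for u, v in self.allowed_arcs())
        return pd.DataFrame(rows, columns=["from", "to"])


def _partial_correlation(
    corr: np.ndarray, i: int, j: int, cond: list[int]
) -> float:
    if not cond:
        return float(np.clip(corr[i, j], -1.0, 1.0))
    idx = [i, j, *cond]
    sub = corr[np.ix_(idx, idx)]
    try:
        prec = np.linalg.inv(sub)
    except np.linalg.LinAlgError:
        prec = np.linalg.pinv(sub)
    denom = np.sqrt(prec[0, 0] * prec[1, 1])
    if denom == 0:
        return 0.0
    r = -prec[0, 1] / denom
    return float(np.clip(r, -1.0, 1.0))


def fisher_z_test(
    x: SliceNode,
    y: SliceNode,
    Z,
    data: FoldedDataset,
    _corr: np.ndarray | None = None,
) -> CITestResult:
    """Fisher-z test of zero partial correlation between x and y given Z.

    The statistic ``z = atanh(r) * sqrt(n - |Z| - 3)`` is compared to a
    standard normal (two-sided).  If n is too small the test is refused by
    reporting independence (p = 1) with a warning.
    """
    Z = frozenset(Z)
    if x == y or x in Z or y in Z:
        raise DimensionError("x, y and Z must be distinct")
    n = data.n
    if n <= len(Z) + 3:
        warnings.warn(
            f"fisher-z refused: n={n} <= |Z|+3={len(Z) + 3}; treating "
            f"{x.name} and {y.name} as independent",
            stacklevel=2,
        )
        return CITestResult(x, y, Z, 0.0, 0.0, 1.0)
    corr = data.correlation() if _corr is None else _corr
    i, j = data.index_of(x), data.index_of(y)
    cond = sorted(data.index_of(z) for z in Z)
    r = _partial_correlation(corr, i, j, cond)
    scale = np.sqrt(n - len(Z) - 3)
    if abs(r) >= 1.0:
        stat = np.inf if r > 0 else -np.inf
        p = 0.0
    else:
        stat = float(np.arctanh(r) * scale)
        p = float(2.0 * stats.norm.sf(abs(stat)))
    return CITestResult(x, y, Z, r, stat, p)


def iamb_blanket(
    target: SliceNode,
    candidates,
    data: FoldedDataset,
    alpha: float = 0.05,
    _corr: np.ndarray | None = None,
) -> frozenset[SliceNode]:
    """Two-phase IAMB Markov-blanket discovery for ``target``.

    Grow: repeatedly admit the candidate with the largest Gaussian
    conditional mutual information with the target given the current
    blanket, ``-0.5 ln(1 - r^2)``, provided its Fisher-z test rejects
    independence at ``alpha``; all remaining candidates are re-ranked
    after every admission.  Shrink: drop any member that is independent
    of the target given the rest of the blanket.  Deterministic for
    fixed data (ties broken by column name).
    """
    candidates = sorted(set(candidates))
    if target in candidates:
        raise DimensionError("target must not be among its own candidates")
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError("alpha must lie strictly in (0, 1)")
    corr = data.correlation() if _corr is None else _corr
    blanket: set[SliceNode] = set()
    remaining = list(candidates)
    while remaining:
        best = None
        for c in remaining:
            res = fisher_z_test(target, c, blanket, data, _corr=corr)
            r2 = min(res.partial_correlation**2, 1.0 - 1e-15)
            assoc = -0.5 * np.log1p(-r2)
            key = (-assoc, c.name)
            if res.p_value < alpha and (best is None or key < best[0]):
                best = (key, c)
        if best is None:
            break
        blanket.add(best[1])
        remaining.remove(best[1])
    # shrink: remove false positives admitted early in the grow phase
    for c in sorted(blanket):
        rest = blanket - {c}
        res = fisher_z_test(target, c, rest, data, _corr=corr)
        if res.p_value >= alpha:
            blanket.discard(c)
    return frozenset(blanket)


def temporal_pattern(variables, p: int = 1) -> ConstraintSet:
    """Blacklist every arc a first-order transition network forbids.

    Allowed arcs: lag slice (s >= 1) into slice 0, and slice 0 into
    slice 0 (contemporaneous).  Everything else — any arc ending in a
    lag slice — is blacklisted.  ``variables`` may be a variable-name
    sequence or an integer count (names default to X1..Xk).
    """
    if isinstance(variables, int):
        variables = tuple(f"X{i + 1}" for i in range(variables))
    variables = tuple(variables)
    if not variables or p < 1:
        raise ConfigurationError("need at least one variable and p >= 1")
    nodes = tuple(SliceNode(v, s) for s in range(p + 1) for v in variables)
    blacklist = {
        (u, v)
        for u in nodes
        for v in nodes
        if u != v and v.slice != 0
    }
    return ConstraintSet(nodes=nodes, blacklist=frozenset(blacklist))


def restrict(
    blankets: dict[SliceNode, frozenset[SliceNode]],
    pattern: ConstraintSet,
    rule: str = "or",
) -> ConstraintSet:
    """Intersect Markov-blanket membership with the temporal pattern.

    An arc u -> v allowed by the pattern survives iff u is in v's
    blanket or v is in u's blanket ("or" rule, default) — or both under
    the stricter "and" rule.  Nodes without a computed blanket (lag
    slices) claim nothing.
    """
    if rule not in ("or", "and"):
        raise ConfigurationError("rule must be 'or' or 'and'")
    blacklist = set(pattern.blacklist)
    for u, v in pattern.allowed_arcs():
        in_v = u in blankets.get(v, frozenset())
        in_u = v in blankets.get(u, frozenset())
        if rule == "or":
            keep = in_v or in_u
        else:
            # a node without a computed blanket (lag slice) cannot veto
            keep = (in_v or v not in blankets) and (in_u or u not in blankets)
        if not keep:
            blacklist.add((u, v))
    return ConstraintSet(
        nodes=pattern.nodes,
        blacklist=frozenset(blacklist),
        whitelist=pattern.whitelist,
    )
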