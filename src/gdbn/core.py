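"""Transition-network representation and linear-Gaussian likelihoods.

A first-order dynamic Bayesian network over k variables is handled as a
static network over 2k *slice nodes*: for each base variable ``v`` the
folded dataset carries a column ``v_t_0`` (current value) and ``v_t_1``
(value one step earlier); higher Markov orders add further slices.  Local
models are linear-Gaussian: each node is regressed on its parents by OLS
and contributes a Gaussian log-likelihood term, so the network
log-likelihood decomposes over nodes.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DimensionError, InsufficientDataError, SingularFitError
from .simulate import TimeSeries

__all__ = [
    "SliceNode",
    "FoldedDataset",
    "DBNStructure",
    "NodeFit",
    "fold",
    "fit_node",
    "loglik_network",
    "to_model_string",
    "from_model_string",
]

#: Residual variances below this are clamped (exact linear dependence).
VARIANCE_FLOOR = 1e-12


@dataclass(frozen=True, order=True)
class SliceNode:
    """A base variable observed at a fixed lag (slice 0 = present)."""

    variable: str
    slice: int

    @property
    def name(self) -> str:
        return f"{self.variable}_t_{self.slice}"

    @classmethod
    def from_name(cls, name: str) -> "SliceNode":
        m = re.fullmatch(r"(.+)_t_(\d+)", name)
        if m is None:
            raise ValueError(f"{name!r} is not a slice-node column name")
        return cls(m.group(1), int(m.group(2)))

    def __str__(self) -> str:
        return self.name


class FoldedDataset:
    """A (p+1)-slice transition table derived from a time series.

    Row r pairs the series value at time r+p (slice 0) with its p lags
    (slices 1..p).  Centered cross-moments are cached so that any OLS
    node fit solves a small Gram system instead of touching the n rows.
    """

    def __init__(self, frame: pd.DataFrame, p: int, variables: tuple[str, ...]):
        self.frame = frame
        self.p = p
        self.variables = tuple(variables)
        self.n = len(frame)
        self.nodes: tuple[SliceNode, ...] = tuple(
            SliceNode(v, s) for s in range(p + 1) for v in variables
        )
        names = [nd.name for nd in self.nodes]
        if list(frame.columns) != names:
            raise DimensionError("folded frame columns do not match node layout")
        X = frame.to_numpy(dtype=float)
        self._index = {nd: i for i, nd in enumerate(self.nodes)}
        self._means = X.mean(axis=0)
        Xc = X - self._means
        self._gram = Xc.T @ Xc  # centered cross-moments, (2k)x(2k)

    @property
    def k(self) -> int:
        return len(self.variables)

    def column(self, node: SliceNode) -> np.ndarray:
        return self.frame[node.name].to_numpy()

    def index_of(self, node: SliceNode) -> int:
        try:
            return self._index[node]
        except KeyError:
            raise DimensionError(f"{node} is not a column of this dataset") from None

    def moments(self, nodes: list[SliceNode]) -> tuple[np.ndarray, np.ndarray]:
        idx = [self.index_of(nd) for nd in nodes]
        return self._gram[np.ix_(idx, idx)], self._means[idx]

    def correlation(self) -> np.ndarray:
        d = np.sqrt(np.diag(self._gram))
        d[d == 0] = 1.0
        return self._gram / np.outer(d, d)


def fold(series: TimeSeries, p: int) -> FoldedDataset:
    """Fold a series into its order-p transition dataset (n = T - p rows)."""
    if p < 1:
        raise DimensionError("markov order p must be >= 1")
    if series.T <= p:
        raise InsufficientDataError(
            f"series of length {series.T} cannot be folded at order {p}"
        )
    n = series.T - p
    cols = {}
    for s in range(p + 1):
        for j, v in enumerate(series.variable_names):
            # slice s holds the value s steps earlier than slice 0
            cols[f"{v}_t_{s}"] = series.values[p - s : p - s + n, j]
    order = [
        f"{v}_t_{s}" for s in range(p + 1) for v in series.variable_names
    ]
    frame = pd.DataFrame(cols)[order]
    return FoldedDataset(frame, p, tuple(series.variable_names))


class DBNStructure:
    """A DAG over slice nodes; every arc must end in slice 0."""

    def __init__(self, nodes, arcs=()):
        self.nodes: tuple[SliceNode, ...] = tuple(nodes)
        self._node_set = frozenset(self.nodes)
        self.arcs: set[tuple[SliceNode, SliceNode]] = set()
        for u, v in arcs:
            self.add_arc(u, v)

    def add_arc(self, u: SliceNode, v: SliceNode) -> None:
        if u not in self._node_set or v not in self._node_set:
            raise DimensionError(f"arc {u}->{v} references unknown nodes")
        if u == v:
            raise DimensionError(f"self-arc {u}->{v} is not allowed")
        if v.slice != 0:
            raise DimensionError(f"arc {u}->{v} does not terminate in slice 0")
        self.arcs.add((u, v))
        if not self.is_acyclic():
            self.arcs.discard((u, v))
            raise DimensionError(f"arc {u}->{v} would create a cycle")

    def remove_arc(self, u: SliceNode, v: SliceNode) -> None:
        self.arcs.discard((u, v))

    def parents(self, node: SliceNode) -> tuple[SliceNode, ...]:
        return tuple(sorted(u for u, v in self.arcs if v == node))

    def parent_map(self) -> dict[SliceNode, frozenset[SliceNode]]:
        out: dict[SliceNode, set[SliceNode]] = {nd: set() for nd in self.nodes}
        for u, v in self.arcs:
            out[v].add(u)
        return {nd: frozenset(ps) for nd, ps in out.items()}

    def is_acyclic(self) -> bool:
        # only intra-slice (slice-0 -> slice-0) arcs can participate in cycles
        adj: dict[SliceNode, list[SliceNode]] = {}
        for u, v in self.arcs:
            if u.slice == 0 and v.slice == 0:
                adj.setdefault(u, []).append(v)
        state: dict[SliceNode, int] = {}

        def visit(x: SliceNode) -> bool:
            state[x] = 1
            for y in adj.get(x, ()):
                s = state.get(y, 0)
                if s == 1 or (s == 0 and not visit(y)):
                    return False
            state[x] = 2
            return True

        return all(state.get(x, 0) == 2 or visit(x) for x in list(adj))

    def copy(self) -> "DBNStructure":
        return DBNStructure(self.nodes, set(self.arcs))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, DBNStructure)
            and self._node_set == other._node_set
            and self.arcs == other.arcs
        )

    def __repr__(self) -> str:
        return f"DBNStructure({len(self.nodes)} nodes, {len(self.arcs)} arcs)"

    def arcs_frame(self) -> pd.DataFrame:
        rows = sorted((u.name, v.name) for u, v in self.arcs)
        return pd.DataFrame(rows, columns=["from", "to"])


@dataclass(frozen=True)
class NodeFit:
    """OLS fit of one node on its parents (intercept always included)."""

    node: SliceNode
    parents: tuple[SliceNode, ...]
    intercept: float
    coefficients: np.ndarray
    residual_variance: float  # MLE, denominator n
    degenerate: bool = False

    @property
    def param_count(self) -> int:
        return len(self.parents) + 2  # coefficients + intercept + variance

    @property
    def loglik(self) -> float:
        n = self._n
        return -0.5 * n * (np.log(2 * np.pi * self.residual_variance) + 1.0)

    # set post-hoc by fit_node; kept off the public field list
    _n: int = field(default=0, compare=False)


def fit_node(
    data: FoldedDataset, node: SliceNode, parents
) -> NodeFit:
    """OLS of ``node`` on ``parents`` via the cached centered Gram system."""
    parents = tuple(sorted(parents))
    d = len(parents)
    if data.n <= d + 1:
        raise InsufficientDataError(
            f"{data.n} rows cannot support a fit with {d} parents"
        )
    cols = [node, *parents]
    G, means = data.moments(cols)
    n = data.n
    Syy = G[0, 0]
    if d == 0:
        rss = Syy
        coef = np.empty(0)
        intercept = means[0]
    else:
        Spp = G[1:, 1:]
        Spy = G[1:, 0]
        try:
            L = np.linalg.cholesky(Spp)
        except np.linalg.LinAlgError:
            bad = ", ".join(p.name for p in parents)
            raise SingularFitError(
                f"singular design fitting {node.name} on parents [{bad}]"
            ) from None
        coef = np.linalg.solve(L.T, np.linalg.solve(L, Spy))
        rss = max(Syy - Spy @ coef, 0.0)
        intercept = means[0] - coef @ means[1:]
    var = rss / n
    degenerate = var < VARIANCE_FLOOR
    if degenerate:
        warnings.warn(
            f"degenerate (near-zero variance) fit for {node.name}; "
            f"residual variance clamped to {VARIANCE_FLOOR:g}",
            stacklevel=2,
        )
        var = VARIANCE_FLOOR
    fit = NodeFit(
        node=node,
        parents=parents,
        intercept=float(intercept),
        coefficients=np.asarray(coef, dtype=float),
        residual_variance=float(var),
        degenerate=degenerate,
    )
    object.__setattr__(fit, "_n", n)
    return fit


def loglik_network(
    structure: DBNStructure, data: FoldedDataset
) -> tuple[float, int]:
    """Decomposable network log-likelihood and total parameter count.

    Every folded node contributes, including parentless lag-slice nodes,
    which are modelled as marginal Gaussians.
    """
    if set(structure.nodes) != set(data.nodes):
        raise DimensionError("structure nodes do not match dataset columns")
    pm = structure.parent_map()
    loglik = 0.0
    params = 0
    for nd in structure.nodes:
        fit = fit_node(data, nd, pm[nd])
        loglik += fit.loglik
        params += fit.param_count
    return loglik, params


# --- bracket model-string serialization ("[A_t_1][A_t_0|A_t_1:B_t_1]") ---

def to_model_string(structure: DBNStructure) -> str:
    pm = structure.parent_map()
    parts = []
    for nd in sorted(structure.nodes):
        ps = sorted(pm[nd])
        if ps:
            parts.append(f"[{nd.name}|{':'.join(p.name for p in ps)}]")
        else:
            parts.append(f"[{nd.name}]")
    return "".join(parts)


def from_model_string(s: str) -> DBNStructure:
    blocks = re.findall(r"\[([^\]]+)\]", s)
    if "".join(f"[{b}]" for b in blocks) != s.strip():
        raise ValueError(f"malformed model string: {s!r}")
    nodes = []
    arcs = []
    for b in blocks:
        head, _, tail = b.partition("|")
        child = SliceNode.from_name(head)
        nodes.append(child)
        if tail:
            for pname in tail.split(":"):
                arcs.append((SliceNode.from_name(pname), child))
    return DBNStructure(nodes, arcs)
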