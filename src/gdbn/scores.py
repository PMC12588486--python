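"""Penalized-likelihood network scores.

Eight criteria are supported, all decomposable over nodes and all
reported on the *higher-is-better* scale

    score = ln L - (c/2) * k_params,

where ``c`` is the per-parameter penalty factor of the criterion on the
conventional -2-log scale (-2 ln L + c * k_params):

============  =====================================
criterion     penalty factor c
============  =====================================
aic-g         2
kic           3
aic4          4
caic          ln(n) + 1
bic-g         ln(n)
bicadj        ln((n + 2) / 24)
hbic          ln(n / (2 pi))
bicq          ln(n) - 2 ln(q / (1 - q))
============  =====================================

``n`` is the number of rows of the folded dataset, i.e. the likelihood's
sample size.  BICQ coincides with BIC at q = 0.5 and penalizes
complexity more heavily for q < 0.5.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .core import DBNStructure, FoldedDataset, SliceNode, fit_node, loglik_network
from .errors import ConfigurationError

__all__ = ["CRITERIA", "ScoreSpec", "penalty_factor", "network_score", "ScoreCache"]

CRITERIA = ("aic-g", "kic", "aic4", "caic", "bic-g", "bicadj", "hbic", "bicq")

_ALIASES = {c.replace("-", "_"): c for c in CRITERIA}
_ALIASES.update({c: c for c in CRITERIA})
_ALIASES.update({"aic": "aic-g", "bic": "bic-g"})


def _normalize(name: str) -> str:
    key = name.strip().lower().replace("-", "_")
    key = {"aic_g": "aic-g", "bic_g": "bic-g"}.get(key, key)
    if key in _ALIASES:
        return _ALIASES[key]
    raise ConfigurationError(
        f"unknown criterion {name!r}; valid names: {', '.join(CRITERIA)}"
    )


@dataclass(frozen=True)
class ScoreSpec:
    """A criterion identity plus its parameters (q is used only by bicq)."""

    criterion: str
    q: float = 0.25

    def __post_init__(self) -> None:
        object.__setattr__(self, "criterion", _normalize(self.criterion))
        if not 0.0 < self.q < 1.0:
            raise ConfigurationError("q must lie strictly between 0 and 1")

    @property
    def label(self) -> str:
        if self.criterion == "bicq":
            return f"bicq(q={self.q:g})"
        return self.criterion


def penalty_factor(spec: ScoreSpec, n: int) -> float:
    """Per-parameter penalty ``c`` on the -2-log scale for sample size n."""
    if n < 1:
        raise ConfigurationError("sample size must be >= 1")
    crit = spec.criterion
    if crit == "aic-g":
        return 2.0
    if crit == "kic":
        return 3.0
    if crit == "aic4":
        return 4.0
    if crit == "caic":
        return math.log(n) + 1.0
    if crit == "bic-g":
        return math.log(n)
    if crit == "bicadj":
        c = math.log((n + 2) / 24.0)
        if c < 0:
            warnings.warn(
                f"bicadj penalty factor is negative at n={n} (rewards complexity)",
                stacklevel=2,
            )
        return c
    if crit == "hbic":
        return math.log(n / (2.0 * math.pi))
    if crit == "bicq":
        return math.log(n) - 2.0 * math.log(spec.q / (1.0 - spec.q))
    raise ConfigurationError(f"unknown criterion {crit!r}")  # pragma: no cover


def network_score(
    structure: DBNStructure, data: FoldedDataset, spec: ScoreSpec
) -> float:
    """Higher-is-better network score: ln L - (c/2) * total parameter count."""
    loglik, params = loglik_network(structure, data)
    return loglik - 0.5 * penalty_factor(spec, data.n) * params


class ScoreCache:
    """Decomposed local scores, memoized per (child, parent-set) pair.

    Used by the search: a single-arc move changes only the child node's
    term, so the network score is maintained incrementally.
    """

    def __init__(self, data: FoldedDataset, spec: ScoreSpec):
        self.data = data
        self.spec = spec
        self._c = penalty_factor(spec, data.n)
        self._cache: dict[tuple[SliceNode, frozenset[SliceNode]], float] = {}

    def local(self, node: SliceNode, parents: frozenset[SliceNode]) -> float:
        key = (node, parents)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        fit = fit_node(self.data, node, parents)
        val = fit.loglik - 0.5 * self._c * fit.param_count
        self._cache[key] = val
        return val

    def total(self, parent_map: dict[SliceNode, frozenset[SliceNode]]) -> float:
        return sum(self.local(nd, ps) for nd, ps in parent_map.items())
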