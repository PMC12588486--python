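"""Structural evaluation: ground-truth graphs and Hamming distance.

The generating VAR(1) coefficient matrix defines the true transition
structure: C[i][j] != 0 means variable j at lag 1 drives variable i at
lag 0.  Diagonal noise implies no contemporaneous (intra-slice) arcs.
Learned structures are compared to the truth with the structural
Hamming distance (SHD) on directed graphs — the number of single-arc
additions, deletions and reversals separating the two arc sets, a
reversal counting one edit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DBNStructure, FoldedDataset, SliceNode
from .errors import DimensionError
from .scores import ScoreSpec, network_score
from .simulate import default_names

__all__ = ["EvalRecord", "true_structure", "shd", "evaluate_learned"]


@dataclass(frozen=True)
class EvalRecord:
    """One learned structure's scorecard within a benchmark replicate."""

    replicate: int
    criterion: str
    n: int
    learned: DBNStructure
    eval_score: float
    shd: int


def true_structure(
    C: np.ndarray, variable_names: tuple[str, ...] | None = None
) -> DBNStructure:
    """Transition structure implied by the nonzero entries of ``C``.

    Arc ``vj_t_1 -> vi_t_0`` is present iff ``C[i][j] != 0`` (exact
    comparison; reference matrices carry exact zeros).  No intra-slice
    arcs: the noise covariance is diagonal.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise DimensionError(f"expected a square matrix, got shape {C.shape}")
    k = C.shape[0]
    names = variable_names if variable_names is not None else default_names(k)
    nodes = tuple(SliceNode(v, s) for s in range(2) for v in names)
    arcs = [
        (SliceNode(names[j], 1), SliceNode(names[i], 0))
        for i in range(k)
        for j in range(k)
        if C[i, j] != 0.0
    ]
    return DBNStructure(nodes, arcs)


def shd(a: DBNStructure, b: DBNStructure) -> int:
    """Structural Hamming distance between two directed graphs.

    Counts arc additions + deletions + reversals needed to turn ``a``
    into ``b``; a reversed arc costs 1, not 2.
    """
    if set(a.nodes) != set(b.nodes):
        raise DimensionError("structures are over different node sets")
    A, B = a.arcs, b.arcs
    sym_diff = (A - B) | (B - A)
    reversals = sum(
        1 for (u, v) in A - B if (v, u) in B - A
    )
    return len(sym_diff) - reversals


def evaluate_learned(
    learned: DBNStructure,
    data: FoldedDataset,
    truth: DBNStructure,
    eval_spec: ScoreSpec = ScoreSpec("bic-g"),
    replicate: int = 0,
    criterion_label: str = "",
) -> EvalRecord:
    """Re-score a learned structure and measure its SHD to the truth.

    The evaluation score is computed on the same data subset used for
    learning, under a single common criterion (default Gaussian BIC) so
    that scores are comparable across learners.
    """
    return EvalRecord(
        replicate=replicate,
        criterion=criterion_label,
        n=data.n,
        learned=learned,
        eval_score=network_score(learned, data, eval_spec),
        shd=shd(learned, truth),
    )
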