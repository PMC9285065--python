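"""Block-level decision metrics derived from a fitted multiblock model.

Two scalar scores support a-priori feature-block selection against a
designated target block T (e.g. a block of biological endpoints):

* redundancy      R_T   = sum_j R2Xj_T(j) * max_A |corr(t_jA, t_jT)|
* predictivity    P_A   = sum_j R2Xj_T(j) *       |corr(t_jA, t_jT)|

where the sums run over joint components j in which the target is a member,
R2Xj_T(j) is the target block's explained variance on component j, and
t_jA / t_jT are the member block score vectors.  Correlations are taken in
absolute value because score signs are only fixed up to a convention.  The
self-predictivity P(T, T) equals the target's total joint explained
variance, since the self-correlation is 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .decomposition import MocaModel
from .opls import _pearson

__all__ = [
    "score_correlation_matrix",
    "redundancy",
    "predictivity",
    "predictivity_from_contributions",
    "r2_overview",
    "block_metrics_table",
]


def score_correlation_matrix(model: MocaModel) -> dict[int, pd.DataFrame]:
    """Per joint component, the block-by-block Pearson correlation matrix.

    Entries for blocks that are not members of a component are NaN (absent),
    never zero.
    """
    out = {}
    for c in model.joint_components:
        names = model.block_names
        mat = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
        for a in c.member_blocks:
            for b in c.member_blocks:
                mat.loc[a, b] = _pearson(c.scores[a], c.scores[b])
        out[c.index] = mat
    return out


def _check_block(model: MocaModel, name: str) -> None:
    if name not in model.block_names:
        raise KeyError(f"unknown block {name!r}; model blocks: {model.block_names}")


def redundancy(model: MocaModel, target: str) -> float:
    """How well the target block's joint information is covered by the
    best-correlated other block, summed over joint components (Eq. R_T)."""
    _check_block(model, target)
    total = 0.0
    for c in model.joint_components:
        if target not in c.member_blocks:
            continue
        others = [b for b in c.member_blocks if b != target]
        if not others:
            continue  # sole member: nothing covers it
        best = max(abs(_pearson(c.scores[a], c.scores[target])) for a in others)
        total += c.r2_per_block[target] * best
    return total


def predictivity(model: MocaModel, descriptor_block: str, target_block: str) -> float:
    """Predictivity score P_A of a descriptor block for the target block."""
    _check_block(model, descriptor_block)
    _check_block(model, target_block)
    total = 0.0
    for c in model.joint_components:
        if target_block not in c.member_blocks or descriptor_block not in c.member_blocks:
            continue
        r = abs(_pearson(c.scores[descriptor_block], c.scores[target_block]))
        total += c.r2_per_block[target_block] * r
    return total


def predictivity_from_contributions(
    target_r2_contributions, correlations=None
) -> float:
    """Predictivity from tabulated per-component target contributions.

    ``target_r2_contributions`` are the target-block explained variances of
    the joint components; ``correlations`` the matching |corr| values
    (defaults to 1, the self-predictivity case).
    """
    r2 = np.asarray(target_r2_contributions, dtype=float)
    if correlations is None:
        correlations = np.ones_like(r2)
    c = np.abs(np.asarray(correlations, dtype=float))
    if r2.shape != c.shape:
        raise ValueError("contributions and correlations must have equal length")
    return float((r2 * c).sum())


def r2_overview(model: MocaModel) -> pd.DataFrame:
    """Tidy per-(block, component) explained-variance table with totals."""
    rows = []
    for c in model.components:
        for b in c.member_blocks:
            rows.append(
                {"block": b, "component": c.index, "kind": c.kind,
                 "r2": c.r2_per_block[b]}
            )
    for b in model.block_names:
        rows.append({"block": b, "component": 0, "kind": "total_joint",
                     "r2": model.r2xj[b]})
        rows.append({"block": b, "component": 0, "kind": "total_unique",
                     "r2": model.r2xu[b]})
        rows.append({"block": b, "component": 0, "kind": "residual",
                     "r2": model.r2_residual[b]})
    return pd.DataFrame(rows, columns=["block", "component", "kind", "r2"])


def block_metrics_table(model: MocaModel, target: str | None = None) -> pd.DataFrame:
    """Long-format metrics table (metric, block, target, value) for export."""
    rows = []
    for b in model.block_names:
        rows.append({"metric": "r2xj", "block": b, "target": "", "value": model.r2xj[b]})
        rows.append({"metric": "r2xu", "block": b, "target": "", "value": model.r2xu[b]})
        rows.append({"metric": "redundancy", "block": b, "target": "",
                     "value": redundancy(model, b)})
    if target is not None:
        _check_block(model, target)
        for b in model.block_names:
            rows.append({"metric": "predictivity", "block": b, "target": target,
                         "value": predictivity(model, b, target)})
    return pd.DataFrame(rows, columns=["metric", "block", "target", "value"])
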