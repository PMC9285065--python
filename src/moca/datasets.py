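"""Bundled reference tables for worked examples and validation.

Both tables come from a published block-wise analysis of 11 molecular
descriptor packages (computed with the MOCA implementation in a commercial
chemometrics package); they are small summary tables, bundled so that the
meta-analyses built on them are reproducible without any external download.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "strictness_sweep_table",
    "ecotox_predictivity_contributions",
]

_BLOCKS = [
    "RDKit", "CDK", "cddd", "QM", "Dragon", "PaDEL",
    "alva_add", "ECFP4", "unity", "MACCS", "Morgan",
]

# rows: (n_blocks, strictness); values: per-block fraction of joint variation
# R2Xj reported for six strictness settings of an 11-block and a 12-block model
_SWEEP_ROWS = [
    (11, -0.01, [0.394, 0.531, 0.331, 0.256, 0.592, 0.560, 0.000, 0.121, 0.239, 0.179, 0.122]),
    (11, -0.03, [0.634, 0.753, 0.416, 0.484, 0.630, 0.571, 0.608, 0.188, 0.309, 0.467, 0.187]),
    (11, -0.05, [0.725, 0.847, 0.435, 0.843, 0.634, 0.586, 0.667, 0.182, 0.302, 0.525, 0.187]),
    (11, -0.10, [0.767, 0.816, 0.426, 0.758, 0.634, 0.586, 0.761, 0.177, 0.317, 0.585, 0.182]),
    (11, -0.20, [0.799, 0.896, 0.435, 0.743, 0.634, 0.583, 0.836, 0.188, 0.323, 0.605, 0.192]),
    (11, -0.50, [0.865, 0.931, 0.452, 0.944, 0.634, 0.592, 0.929, 0.188, 0.343, 0.631, 0.186]),
    (12, -0.01, [0.673, 0.684, 0.358, 0.298, 0.619, 0.565, 0.000, 0.153, 0.258, 0.202, 0.153]),
    (12, -0.03, [0.632, 0.779, 0.419, 0.578, 0.633, 0.582, 0.641, 0.172, 0.327, 0.499, 0.183]),
    (12, -0.05, [0.727, 0.779, 0.418, 0.645, 0.625, 0.580, 0.558, 0.177, 0.300, 0.539, 0.177]),
    (12, -0.10, [0.786, 0.780, 0.436, 0.667, 0.624, 0.579, 0.744, 0.166, 0.316, 0.581, 0.165]),
    (12, -0.20, [0.800, 0.868, 0.435, 0.895, 0.620, 0.579, 0.858, 0.170, 0.329, 0.618, 0.169]),
    (12, -0.50, [0.865, 0.926, 0.454, 0.945, 0.638, 0.594, 0.929, 0.188, 0.344, 0.642, 0.187]),
]


def strictness_sweep_table() -> pd.DataFrame:
    """12-condition x 11-block table of joint-variance fractions (R2Xj).

    Rows are the six strictness settings {-0.01, -0.03, -0.05, -0.1, -0.2,
    -0.5} of an 11-block and a 12-block model; columns are the 11 descriptor
    blocks of interest.  The standard meta-analysis is a center-only PCA of
    this table (``decomposition.sweep_table_pca``).
    """
    idx = pd.MultiIndex.from_tuples(
        [(nb, s) for nb, s, _ in _SWEEP_ROWS], names=["n_blocks", "strictness"]
    )
    return pd.DataFrame(
        np.array([r for _, _, r in _SWEEP_ROWS]), index=idx, columns=_BLOCKS
    )


# per joint component: target-block explained variance multiplied by the
# |score correlation| between each block and the target ("bio") block; the
# bio column is the raw explained variance (self-correlation 1)
_ECOTOX = {
    "bio":    [0.52, 0.17, 0.09],
    "RDKit":  [0.32, 0.07, 0.00],
    "cddd":   [0.35, 0.13, 0.07],
    "QM":     [0.32, 0.00, 0.00],
    "Dragon": [0.37, 0.13, 0.00],
    "PaDEL":  [0.35, 0.12, 0.06],
}


def ecotox_predictivity_contributions() -> pd.DataFrame:
    """Per-component predictivity contributions toward an ecotoxicology block.

    Three joint components involve the 7-endpoint target block; each cell is
    already the product R2Xj(target) x |corr(t_block, t_target)|, so block
    predictivity scores are the column sums
    (``metrics.predictivity_from_contributions``).
    """
    return pd.DataFrame(_ECOTOX, index=pd.Index([1, 2, 3], name="component"))
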