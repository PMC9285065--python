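"""Block containers and column-wise preprocessing.

Blocked data tables (one block per descriptor package, one optional block of
biological endpoints) share a single observation index.  Before any latent
variable model is fitted, each column is mean-centered and usually scaled to
unit variance; means and scales are estimated over *observed* cells only so
that missing cells never influence the model (they carry zero residual in
every NIPALS fit downstream).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np

PreprocessState = Literal["raw", "centered", "centered_scaled"]
CenterMode = Literal["center_only", "center_and_uv_scale"]

__all__ = [
    "BlockMatrix",
    "MultiBlockData",
    "center_scale",
    "remove_constant_columns",
    "neg_log_molar",
]


@dataclass
class BlockMatrix:
    """One block's observation x variable matrix with an explicit missing mask.

    ``values`` holds NaN at missing cells; ``missing_mask`` is True where a
    cell is missing.  ``col_means`` / ``col_scales`` record the preprocessing
    applied (identity for raw blocks).
    """

    name: str
    values: np.ndarray
    missing_mask: np.ndarray
    var_names: list[str]
    obs_ids: list[str]
    col_means: np.ndarray = field(default=None)  # type: ignore[assignment]
    col_scales: np.ndarray = field(default=None)  # type: ignore[assignment]
    preprocessing: PreprocessState = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"block {self.name!r}: values must be 2-D")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != self.values.shape:
            raise ValueError(
                f"block {self.name!r}: mask shape {self.missing_mask.shape} "
                f"!= values shape {self.values.shape}"
            )
        n_obs, n_vars = self.values.shape
        if len(self.var_names) != n_vars:
            raise ValueError(f"block {self.name!r}: var_names length mismatch")
        if len(self.obs_ids) != n_obs:
            raise ValueError(f"block {self.name!r}: obs_ids length mismatch")
        if self.col_means is None:
            self.col_means = np.zeros(n_vars)
        if self.col_scales is None:
            self.col_scales = np.ones(n_vars)
        self.col_means = np.asarray(self.col_means, dtype=float)
        self.col_scales = np.asarray(self.col_scales, dtype=float)
        if np.any(self.col_scales <= 0):
            raise ValueError(f"block {self.name!r}: col_scales must be positive")

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_vars(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def filled(self, fill: float = 0.0) -> np.ndarray:
        """Values with missing cells replaced by ``fill`` (0 = zero residual)."""
        out = self.values.copy()
        out[self.missing_mask] = fill
        return out

    @property
    def observed(self) -> np.ndarray:
        return ~self.missing_mask

    def total_ss(self) -> float:
        """Observed-cell sum of squares (of the current, preprocessed values)."""
        return float(np.nansum(np.where(self.missing_mask, 0.0, self.values) ** 2))

    def copy(self) -> "BlockMatrix":
        return BlockMatrix(
            name=self.name,
            values=self.values.copy(),
            missing_mask=self.missing_mask.copy(),
            var_names=list(self.var_names),
            obs_ids=list(self.obs_ids),
            col_means=self.col_means.copy(),
            col_scales=self.col_scales.copy(),
            preprocessing=self.preprocessing,
        )


class MultiBlockData:
    """Ordered collection of blocks sharing one observation index."""

    def __init__(self, blocks: Iterable[BlockMatrix], target: str | None = None):
        self.blocks: list[BlockMatrix] = list(blocks)
        if not self.blocks:
            raise ValueError("MultiBlockData requires at least one block")
        names = [b.name for b in self.blocks]
        if len(set(names)) != len(names):
            raise ValueError("duplicate block names")
        ids0 = self.blocks[0].obs_ids
        for b in self.blocks[1:]:
            if b.obs_ids != ids0:
                raise ValueError(
                    f"block {b.name!r} does not share the observation index "
                    f"of block {self.blocks[0].name!r}"
                )
        if target is not None and target not in names:
            raise ValueError(f"target block {target!r} not among blocks {names}")
        self.target = target

    @property
    def block_names(self) -> list[str]:
        return [b.name for b in self.blocks]

    @property
    def obs_ids(self) -> list[str]:
        return self.blocks[0].obs_ids

    @property
    def n_obs(self) -> int:
        return self.blocks[0].n_obs

    def __getitem__(self, name: str) -> BlockMatrix:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(name)

    def __iter__(self):
        return iter(self.blocks)

    def __len__(self) -> int:
        return len(self.blocks)

    def center_scale(self, mode: CenterMode = "center_and_uv_scale") -> "MultiBlockData":
        """Apply identical column preprocessing to every block (target included)."""
        return MultiBlockData(
            [center_scale(b, mode) for b in self.blocks], target=self.target
        )


def _observed_moments(block: BlockMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    obs = block.observed
    counts = obs.sum(axis=0)
    vals = np.where(obs, block.values, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = vals.sum(axis=0) / counts
        centered = np.where(obs, block.values - means, 0.0)
        var = (centered**2).sum(axis=0) / np.maximum(counts - 1, 1)
    return counts, means, var


def center_scale(block: BlockMatrix, mode: CenterMode = "center_and_uv_scale") -> BlockMatrix:
    """Mean-center (and optionally scale to unit variance) every column.

    Moments are computed over observed cells only; the missing mask is
    untouched.  Unit-variance scaling uses the n-1 denominator, the
    chemometrics convention for UV scaling.
    """
    if block.preprocessing != "raw":
        raise ValueError(f"block {block.name!r} is already preprocessed")
    if mode not in ("center_only", "center_and_uv_scale"):
        raise ValueError(f"unknown mode {mode!r}")
    counts, means, var = _observed_moments(block)
    thin = counts < 2
    if np.any(thin):
        bad = block.var_names[int(np.argmax(thin))]
        raise ValueError(
            f"block {block.name!r}: column {bad!r} has fewer than 2 observed cells"
        )
    if mode == "center_and_uv_scale":
        zero = var <= 0
        if np.any(zero):
            bad = block.var_names[int(np.argmax(zero))]
            raise ValueError(
                f"block {block.name!r}: column {bad!r} has zero variance; "
                "apply remove_constant_columns before unit-variance scaling"
            )
        scales = np.sqrt(var)
        state: PreprocessState = "centered_scaled"
    else:
        scales = np.ones_like(means)
        state = "centered"
    new_values = (block.values - means) / scales
    new_values[block.missing_mask] = np.nan
    return BlockMatrix(
        name=block.name,
        values=new_values,
        missing_mask=block.missing_mask.copy(),
        var_names=list(block.var_names),
        obs_ids=list(block.obs_ids),
        col_means=means,
        col_scales=scales,
        preprocessing=state,
    )


def remove_constant_columns(
    block: BlockMatrix, tol: float = 1e-12
) -> tuple[BlockMatrix, list[str]]:
    """Drop columns whose observed-cell variance is <= ``tol``.

    Returns the filtered block (survivor order preserved) and the names of
    the removed columns.
    """
    if block.preprocessing != "raw":
        raise ValueError(f"block {block.name!r} must be raw")
    _, _, var = _observed_moments(block)
    keep = var > tol
    removed = [n for n, k in zip(block.var_names, keep) if not k]
    if not np.any(keep):
        raise ValueError(f"block {block.name!r} empty after filtering")
    if not removed:
        return block, []
    out = BlockMatrix(
        name=block.name,
        values=block.values[:, keep],
        missing_mask=block.missing_mask[:, keep],
        var_names=[n for n, k in zip(block.var_names, keep) if k],
        obs_ids=list(block.obs_ids),
        preprocessing="raw",
    )
    return out, removed


def neg_log_molar(
    values: Sequence[float], mode: Literal["neg_log", "log_only"] = "neg_log"
) -> list[float]:
    """Endpoint transform: -log10(x) (potency convention) or log10(x) (e.g. BCF)."""
    if mode not in ("neg_log", "log_only"):
        raise ValueError(f"unknown mode {mode!r}")
    out = []
    for i, v in enumerate(values):
        if not v > 0:
            raise ValueError(f"value at index {i} is not strictly positive: {v!r}")
        lg = math.log10(v)
        out.append(-lg if mode == "neg_log" else lg)
    return out
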