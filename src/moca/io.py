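"""Dataset reading/writing: CSV data tables plus block-definition configs.

The on-disk format is a single CSV (header row, first column = observation
IDs, empty cells or "NA" = missing) together with a YAML or JSON config
that assigns every data column to exactly one named block, optionally marks
one block as the target, and sets the preprocessing mode.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import (
    BlockMatrix,
    MultiBlockData,
    center_scale,
    remove_constant_columns,
)

log = logging.getLogger(__name__)

__all__ = ["BlockConfig", "read_dataset", "write_dataset"]

_MISSING_TOKENS = {"", "NA", "NaN", "nan", "na"}
_MODES = ("center_and_uv_scale", "center_only", "raw")


@dataclass
class BlockConfig:
    """Mapping block name -> column names (or inclusive "first:last" ranges)."""

    blocks: dict[str, list[str]]
    target: str | None = None
    preprocessing: str | dict[str, str] = "center_and_uv_scale"
    drop_constant: bool = True
    constant_tol: float = 1e-12

    @classmethod
    def from_file(cls, path: str | Path) -> "BlockConfig":
        path = Path(path)
        text = path.read_text()
        doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(doc, dict) or "blocks" not in doc:
            raise ValueError(f"config {path}: expected a mapping with a 'blocks' key")
        return cls(
            blocks={str(k): list(v) for k, v in doc["blocks"].items()},
            target=doc.get("target"),
            preprocessing=doc.get("preprocessing", "center_and_uv_scale"),
            drop_constant=bool(doc.get("drop_constant", True)),
            constant_tol=float(doc.get("constant_tol", 1e-12)),
        )

    def to_file(self, path: str | Path) -> None:
        doc = {"blocks": self.blocks, "preprocessing": self.preprocessing,
               "drop_constant": self.drop_constant}
        if self.target:
            doc["target"] = self.target
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(doc, indent=2))
        else:
            path.write_text(yaml.safe_dump(doc, sort_keys=False))

    def mode_for(self, block: str) -> str:
        mode = (
            self.preprocessing.get(block, "center_and_uv_scale")
            if isinstance(self.preprocessing, dict)
            else self.preprocessing
        )
        if mode not in _MODES:
            raise ValueError(f"unknown preprocessing mode {mode!r} for block {block!r}")
        return mode

    def resolve_columns(self, all_columns: list[str]) -> dict[str, list[str]]:
        """Expand ranges and validate the exactly-one-block partition."""
        pos = {c: i for i, c in enumerate(all_columns)}
        resolved: dict[str, list[str]] = {}
        owner: dict[str, str] = {}
        for bname, spec in self.blocks.items():
            cols: list[str] = []
            for item in spec:
                item = str(item)
                if ":" in item and item not in pos:
                    first, last = item.split(":", 1)
                    if first not in pos or last not in pos:
                        raise ValueError(
                            f"block {bname!r}: range {item!r} references unknown columns"
                        )
                    i0, i1 = pos[first], pos[last]
                    if i1 < i0:
                        raise ValueError(f"block {bname!r}: inverted range {item!r}")
                    cols.extend(all_columns[i0 : i1 + 1])
                else:
                    if item not in pos:
                        raise ValueError(f"block {bname!r}: unknown column {item!r}")
                    cols.append(item)
            for c in cols:
                if c in owner:
                    raise ValueError(
                        f"column {c!r} assigned to both {owner[c]!r} and {bname!r}"
                    )
                owner[c] = bname
            resolved[bname] = cols
        unassigned = [c for c in all_columns if c not in owner]
        if unassigned:
            raise ValueError(f"columns not assigned to any block: {unassigned}")
        if self.target is not None and self.target not in self.blocks:
            raise ValueError(f"target block {self.target!r} not defined")
        return resolved


def _parse_numeric(df: pd.DataFrame, path: str) -> tuple[np.ndarray, np.ndarray]:
    values = np.empty(df.shape, dtype=float)
    mask = np.zeros(df.shape, dtype=bool)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col].to_numpy()):
            s = "" if raw is None or (isinstance(raw, float) and np.isnan(raw)) else str(raw).strip()
            if s in _MISSING_TOKENS:
                values[i, j] = np.nan
                mask[i, j] = True
                continue
            try:
                values[i, j] = float(s)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {s!r} at row {df.index[i]!r}, "
                    f"column {col!r}"
                ) from None
    return values, mask


def read_dataset(
    data_path: str | Path,
    config_path: str | Path,
    preprocess: bool = True,
) -> MultiBlockData:
    """Load a CSV + block config into preprocessed blocks.

    Constant columns are removed (and logged) before unit-variance scaling;
    a load report (observations, per-block variables, missing fraction) is
    logged at INFO level.
    """
    config = BlockConfig.from_file(config_path)
    df = pd.read_csv(data_path, dtype=str, keep_default_na=False, index_col=0)
    obs_ids = [str(i) for i in df.index]
    if len(set(obs_ids)) != len(obs_ids):
        dupes = pd.Index(obs_ids)
        dup = dupes[dupes.duplicated()][0]
        raise ValueError(f"{data_path}: duplicate observation ID {dup!r}")
    resolved = config.resolve_columns(list(df.columns))
    values, mask = _parse_numeric(df, str(data_path))
    colpos = {c: i for i, c in enumerate(df.columns)}

    blocks = []
    for bname, cols in resolved.items():
        idx = [colpos[c] for c in cols]
        block = BlockMatrix(
            name=bname,
            values=values[:, idx],
            missing_mask=mask[:, idx],
            var_names=cols,
            obs_ids=obs_ids,
            preprocessing="raw",
        )
        removed: list[str] = []
        mode = config.mode_for(bname)
        if preprocess:
            if config.drop_constant and mode != "raw":
                block, removed = remove_constant_columns(block, config.constant_tol)
            if mode != "raw":
                block = center_scale(block, mode)  # type: ignore[arg-type]
        miss_pct = 100.0 * block.missing_mask.mean()
        log.info(
            "block %s: %d vars (%d constant removed), %.1f%% missing",
            bname, block.n_vars, len(removed), miss_pct,
        )
        blocks.append(block)
    log.info("loaded %d observations, %d blocks", len(obs_ids), len(blocks))
    return MultiBlockData(blocks, target=config.target)


def write_dataset(
    data: MultiBlockData,
    data_path: str | Path,
    config_path: str | Path,
    preprocessing: str = "center_and_uv_scale",
) -> None:
    """Write raw block values to CSV + a matching block config (NA = missing)."""
    frames = []
    blocks_cfg = {}
    for b in data:
        vals = np.where(b.missing_mask, np.nan, b.values)
        frames.append(pd.DataFrame(vals, index=data.obs_ids, columns=b.var_names))
        blocks_cfg[b.name] = list(b.var_names)
    table = pd.concat(frames, axis=1)
    table.index.name = "obs_id"
    table.to_csv(data_path, na_rep="NA")
    BlockConfig(
        blocks=blocks_cfg, target=data.target, preprocessing=preprocessing
    ).to_file(config_path)
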