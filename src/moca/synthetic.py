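"""Synthetic multiblock data with planted global/local/unique structure.

The generator emulates the structure of blocked descriptor tables: several
blocks of variables over shared observations, driven by orthonormal latent
factors that are global (loading on every block), local (a strict subset of
blocks) or unique (one block), plus i.i.d. Gaussian noise and optional
missing-at-random masking.  The planted truth (latent scores, memberships,
design and realized variance fractions) is returned alongside the data so
that recovery can be scored exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decomposition import MocaModel
from .opls import _pearson
from .preprocess import BlockMatrix, MultiBlockData

__all__ = [
    "SyntheticSpec",
    "Factor",
    "SyntheticTruth",
    "generate",
    "pesticide_like_fixture",
    "recovery_report",
]


@dataclass
class SyntheticSpec:
    n_obs: int
    blocks: list[tuple[str, int]]  # (name, n_vars)
    global_latents: int = 1
    local_latents: list[tuple[tuple[str, ...], int]] = field(default_factory=list)
    unique_latents: dict[str, int] | int = 1
    loading_scale: float = 1.0
    noise_sd: float = 0.3
    target_block: str | None = None
    missing_fraction: float | dict[str, float] = 0.0
    seed: int = 0
    # optional per-factor (or per-factor-per-block) loading scales, keyed by
    # factor name ("g1", "l1", "u_<block>_1", ...); values: float or {block: float}
    factor_strengths: dict[str, float | dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [n for n, _ in self.blocks]
        if len(set(names)) != len(names):
            raise ValueError("duplicate block names")
        for members, _ in self.local_latents:
            if not (2 <= len(members) < len(self.blocks)):
                raise ValueError(
                    "local latent member sets must have size >=2 and "
                    "< number of blocks"
                )
            for m in members:
                if m not in names:
                    raise ValueError(f"unknown block {m!r} in local latent")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.target_block is not None and self.target_block not in names:
            raise ValueError(f"unknown target block {self.target_block!r}")


@dataclass
class Factor:
    name: str
    kind: str  # "global" | "local" | "unique"
    members: list[str]
    scores: np.ndarray  # planted latent, ||z||^2 = n (unit variance)
    design_r2: dict[str, float]
    realized_r2: dict[str, float]


@dataclass
class SyntheticTruth:
    factors: list[Factor]
    latents: np.ndarray  # (n_obs, n_factors), columns ordered as factors

    def factor(self, name: str) -> Factor:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)


def _factor_layout(spec: SyntheticSpec) -> list[tuple[str, str, list[str]]]:
    names = [n for n, _ in spec.blocks]
    layout = []
    for g in range(spec.global_latents):
        layout.append((f"g{g + 1}", "global", list(names)))
    for li, (members, count) in enumerate(spec.local_latents):
        for c in range(count):
            layout.append((f"l{li + 1}_{c + 1}", "local", list(members)))
    uniq = spec.unique_latents
    for n_ in names:
        count = uniq.get(n_, 0) if isinstance(uniq, dict) else uniq
        for c in range(count):
            layout.append((f"u_{n_}_{c + 1}", "unique", [n_]))
    return layout


def _strength(spec: SyntheticSpec, factor: str, block: str) -> float:
    s = spec.factor_strengths.get(factor, spec.loading_scale)
    if isinstance(s, dict):
        return float(s.get(block, spec.loading_scale))
    return float(s)


def generate(spec: SyntheticSpec) -> tuple[MultiBlockData, SyntheticTruth]:
    """Generate blocks X_b = sum_f z_f w_f' + noise from a planted layout.

    Latent score vectors are centered, Gram-Schmidt orthogonalized and
    scaled to unit variance (Z'Z = n I).  Each member block receives a
    loading vector of exact norm strength*sqrt(p), drawn once and fixed.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    layout = _factor_layout(spec)
    n = spec.n_obs
    F = len(layout)
    if F > n:
        raise ValueError(f"{F} latent factors exceed n_obs={n}")
    for bname, p in spec.blocks:
        k = sum(1 for _, _, members in layout if bname in members)
        if k > min(n, p):
            raise ValueError(
                f"block {bname!r}: {k} latent factors exceed min(n_obs, n_vars)="
                f"{min(n, p)}"
            )
    Z = rng.standard_normal((n, F))
    Z -= Z.mean(axis=0)
    Q, _ = np.linalg.qr(Z)
    Z = Q * np.sqrt(n)  # columns: zero-mean (QR preserves the centered span), ||z||^2=n

    loadings: dict[str, dict[str, np.ndarray]] = {}
    for fi, (fname, kind, members) in enumerate(layout):
        loadings[fname] = {}
        for bname, p in spec.blocks:
            if bname in members:
                w = rng.standard_normal(p)
                w *= _strength(spec, fname, bname) * np.sqrt(p) / np.linalg.norm(w)
                loadings[fname][bname] = w

    blocks = []
    realized: dict[str, dict[str, float]] = {f[0]: {} for f in layout}
    design: dict[str, dict[str, float]] = {f[0]: {} for f in layout}
    for bname, p in spec.blocks:
        X = spec.noise_sd * rng.standard_normal((n, p))
        parts = {}
        for fi, (fname, kind, members) in enumerate(layout):
            if bname in members:
                part = np.outer(Z[:, fi], loadings[fname][bname])
                parts[fname] = part
                X = X + part
        Xc = X - X.mean(axis=0)
        total_ss = float((Xc**2).sum())
        var_sum = sum(
            _strength(spec, f, bname) ** 2
            for f, _, mem in layout
            if bname in mem
        ) + spec.noise_sd**2
        for fname, part in parts.items():
            realized[fname][bname] = float((part**2).sum()) / total_ss
            design[fname][bname] = _strength(spec, fname, bname) ** 2 / var_sum

        mf = spec.missing_fraction
        frac = mf.get(bname, 0.0) if isinstance(mf, dict) else mf
        if not (0 <= frac < 1):
            raise ValueError("missing_fraction must lie in [0, 1)")
        mask = np.zeros((n, p), dtype=bool)
        if frac > 0:
            mask = rng.random((n, p)) < frac
            # keep every column estimable: at least 3 observed cells
            for j in range(p):
                obs = np.flatnonzero(~mask[:, j])
                if obs.size < 3:
                    unmask = rng.choice(n, size=3, replace=False)
                    mask[unmask, j] = False
        vals = X.copy()
        vals[mask] = np.nan
        blocks.append(
            BlockMatrix(
                name=bname,
                values=vals,
                missing_mask=mask,
                var_names=[f"{bname}_v{j + 1}" for j in range(p)],
                obs_ids=[f"obs{i + 1}" for i in range(n)],
                preprocessing="raw",
            )
        )

    factors = [
        Factor(
            name=fname,
            kind=kind,
            members=members,
            scores=Z[:, fi].copy(),
            design_r2=design[fname],
            realized_r2=realized[fname],
        )
        for fi, (fname, kind, members) in enumerate(layout)
    ]
    data = MultiBlockData(blocks, target=spec.target_block)
    return data, SyntheticTruth(factors=factors, latents=Z)


def pesticide_like_fixture(seed: int = 0) -> tuple[MultiBlockData, SyntheticTruth]:
    """Descriptor-blocks-plus-endpoints fixture.

    Five descriptor-like blocks and one small 7-variable target ("bio")
    block: one strong global size-like factor loading on every block and
    every endpoint, one local factor shared by the descriptor blocks only,
    and two small factors joining the target with a subset of descriptor
    blocks.  About 30% of the target block is masked at random, emulating
    the sparsity of collected endpoint data.
    """
    spec = SyntheticSpec(
        n_obs=200,
        blocks=[
            ("rdk_like", 40),
            ("cdk_like", 30),
            ("dragon_like", 60),
            ("padel_like", 50),
            ("cddd_like", 45),
            ("bio", 7),
        ],
        global_latents=1,
        local_latents=[
            (("rdk_like", "cdk_like", "dragon_like", "padel_like", "cddd_like"), 1),
            (("bio", "dragon_like", "cddd_like"), 1),
            (("bio", "cddd_like", "padel_like"), 1),
        ],
        unique_latents={"rdk_like": 1, "cdk_like": 1, "dragon_like": 1,
                        "padel_like": 1, "cddd_like": 1, "bio": 0},
        noise_sd=0.4,
        target_block="bio",
        missing_fraction={"bio": 0.3},
        seed=seed,
        # strengths chosen so that the target's joint factors sit clearly
        # above the score-correlation ceiling of a 7-variable block with
        # 30% missing cells (see the methods note): a dominant size-like
        # factor, one mid-sized and one small target-joint factor
        factor_strengths={
            "g1": {"rdk_like": 0.75, "cdk_like": 0.75, "dragon_like": 0.7,
                   "padel_like": 0.7, "cddd_like": 0.6, "bio": 1.0},
            "l1_1": 0.55,
            "l2_1": {"bio": 0.85, "dragon_like": 0.4, "cddd_like": 0.4},
            "l3_1": {"bio": 0.42, "cddd_like": 0.35, "padel_like": 0.35},
        },
    )
    return generate(spec)


def recovery_report(model: MocaModel, truth: SyntheticTruth) -> pd.DataFrame:
    """Match planted factors to fitted components and score the recovery.

    Greedy one-to-one matching by descending |corr| between each planted
    latent and the component consensus scores; reports the correlation and
    whether the component kind and member set match the planted factor.
    """
    pairs = []
    for f in truth.factors:
        for c in model.components:
            pairs.append((abs(_pearson(f.scores, c.consensus_score)), f.name, c.index))
    pairs.sort(reverse=True)
    used_f, used_c = set(), set()
    match: dict[str, int] = {}
    for corr, fname, cidx in pairs:
        if fname in used_f or cidx in used_c:
            continue
        match[fname] = cidx
        used_f.add(fname)
        used_c.add(cidx)

    rows = []
    for f in truth.factors:
        if f.name in match:
            c = model.component(match[f.name])
            corr = abs(_pearson(f.scores, c.consensus_score))
            rows.append(
                {
                    "factor": f.name,
                    "kind": f.kind,
                    "matched_component": c.index,
                    "matched_kind": c.kind,
                    "corr": corr,
                    "kind_match": c.kind == f.kind,
                    "members_match": set(c.member_blocks) == set(f.members),
                }
            )
        else:
            rows.append(
                {
                    "factor": f.name,
                    "kind": f.kind,
                    "matched_component": -1,
                    "matched_kind": "none",
                    "corr": 0.0,
                    "kind_match": False,
                    "members_match": False,
                }
            )
    return pd.DataFrame(rows)
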